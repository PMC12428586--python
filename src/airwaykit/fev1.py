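"""FEV1 prediction from simulated large-airway outlet flow.

Each patient contributes a triple (a, b, c): the simulated outlet volume
flow rate of their stenotic airway model (a, L/s), the measured FEV1
(b, L/s) and the predicted normal FEV1 from the spirometer's reference
equation (c, L/s).  Normalizing by c removes inter-individual size effects,
giving the model

    y = beta1 * x + beta0,    x = a/c,  y = b/c,

fitted by ordinary least squares on the training patients.  A fitted model
predicts FEV1 as b = (beta1*(a/c) + beta0) * c.

Conventions deliberately follow the clinical workflow being reproduced:
RMSE is sqrt(SSres/n) (population form) on both training and test sets,
and the test R^2 is 1 - SSres/SStot computed on the test set itself.

The fitted model also inverts a dilation target: given per-alpha simulated
flows for a stenosis-to-normal transition series, it finds the smallest
dilation ratio alpha whose predicted FEV1 reaches the normality threshold
FEV1 >= target_ratio * predicted FVC (default 70 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class PatientRecord:
    """One patient's (a, b, c) triple, all in L/s; b may be absent for
    pure prediction."""

    id: str
    a: float
    c: float
    b: float | None = None

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError(f"patient {self.id}: a and c must be > 0")


# Training patients A-D: simulated stenotic-model outlet flow a, measured
# FEV1 b, predicted normal FEV1 c (L/s).
TRAINING_RECORDS: tuple[PatientRecord, ...] = (
    PatientRecord("A", a=3.210, b=2.29, c=3.33),
    PatientRecord("B", a=1.230, b=0.89, c=2.28),
    PatientRecord("C", a=1.079, b=0.73, c=1.86),
    PatientRecord("D", a=0.500, b=0.24, c=1.44),
)

# Held-out test patients E-F.
TEST_RECORDS: tuple[PatientRecord, ...] = (
    PatientRecord("E", a=1.135, b=0.700, c=2.250),
    PatientRecord("F", a=1.620, b=1.270, c=1.910),
)


def compute_ratios(record: PatientRecord) -> tuple[float, float | None]:
    """Normalized ratios (x, y) = (a/c, b/c); y is None when b is absent.
    Always computed from the unrounded a, b, c."""
    x = record.a / record.c
    y = None if record.b is None else record.b / record.c
    return x, y


@dataclass
class RegressionFit:
    """OLS fit of y = slope*x + intercept with its training diagnostics."""

    slope: float
    intercept: float
    n: int
    residuals: np.ndarray
    rmse: float                # sqrt(SSres/n)
    r2: float
    slope_se: float
    intercept_se: float
    resid_var: float           # SSres/(n-2)
    x_mean: float
    sxx: float

    def predict_y(self, x):
        return self.slope * np.asarray(x, float) + self.intercept

    def to_json(self, path: str | Path) -> None:
        doc = {"slope": self.slope, "intercept": self.intercept, "n": self.n,
               "rmse": self.rmse, "r2": self.r2, "slope_se": self.slope_se,
               "intercept_se": self.intercept_se, "resid_var": self.resid_var,
               "x_mean": self.x_mean, "sxx": self.sxx,
               "residuals": self.residuals.tolist()}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionFit":
        d = json.loads(Path(path).read_text())
        return cls(d["slope"], d["intercept"], d["n"],
                   np.asarray(d["residuals"], float), d["rmse"], d["r2"],
                   d["slope_se"], d["intercept_se"], d["resid_var"],
                   d["x_mean"], d["sxx"])


def _xy(records) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for r in records:
        x, y = compute_ratios(r)
        if y is None:
            raise ValueError(f"patient {r.id}: measured FEV1 (b) required")
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def fit_ols(records) -> RegressionFit:
    """Least-squares fit of y = slope*x + intercept on >= 3 records."""
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    x, y = _xy(records)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate design: all x equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(model.resid)
    n = len(x)
    return RegressionFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        n=n, residuals=resid,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        r2=float(model.rsquared),
        slope_se=float(model.bse[1]), intercept_se=float(model.bse[0]),
        resid_var=float(model.mse_resid),
        x_mean=float(x.mean()), sxx=float(np.sum((x - x.mean()) ** 2)))


def evaluate(fit: RegressionFit, records) -> tuple[float, float]:
    """(rmse, r2) of the fit on the given records: rmse = sqrt(SSres/n),
    r2 = 1 - SSres/SStot computed on these records themselves."""
    records = list(records)
    x, y = _xy(records)
    resid = y - fit.predict_y(x)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if len(records) < 2:
        raise ValueError("r2 undefined for a single record (rmse would be "
                         f"{rmse:.4g}); pass >= 2 records")
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(resid ** 2) / sstot)
    return rmse, r2


def predict(fit: RegressionFit, a: float, c: float) -> tuple[float, float]:
    """Predict (y, b): y = slope*(a/c) + intercept, b = y*c."""
    if c <= 0:
        raise ValueError(f"c must be > 0, got {c}")
    y = float(fit.predict_y(a / c))
    return y, y * c


def relative_error(predicted_b: float, measured_b: float) -> float:
    """Percent relative FEV1 prediction error, 100*|pred - meas|/meas."""
    if measured_b <= 0:
        raise ValueError(f"measured FEV1 must be > 0, got {measured_b}")
    return 100.0 * abs(predicted_b - measured_b) / measured_b


def loocv(records) -> pd.DataFrame:
    """Leave-one-out cross-validation.

    For each record, refit on the rest and predict the held-out y.
    Returns one row per fold with the held-out absolute error and the
    3-point refit's training R^2 (a held-out single point has no R^2 of
    its own).  Use ``df['abs_error'].agg(['min','max'])`` etc. for ranges.
    """
    records = list(records)
    if len(records) < 4:
        raise ValueError(f"LOOCV needs >= 4 records, got {len(records)}")
    rows = []
    for i, held in enumerate(records):
        rest = records[:i] + records[i + 1:]
        f = fit_ols(rest)
        x, y = compute_ratios(held)
        rows.append({"id": held.id, "abs_error": abs(y - float(f.predict_y(x))),
                     "refit_r2": f.r2})
    return pd.DataFrame(rows)


def prediction_interval(fit: RegressionFit, x: float,
                        level: float = 0.95) -> tuple[float, float]:
    """Two-sided OLS confidence interval for the mean response at x:
    yhat +/- t_{level, n-2} * s * sqrt(1/n + (x - xbar)^2 / Sxx)."""
    if fit.n < 3:
        raise ValueError("need n >= 3 for an interval")
    yhat = float(fit.predict_y(x))
    t = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    half = t * np.sqrt(fit.resid_var * (1.0 / fit.n
                                        + (x - fit.x_mean) ** 2 / fit.sxx))
    return (yhat - half, yhat + half)


@dataclass(frozen=True)
class DilationTargetSpec:
    """Normality target FEV1 >= target_ratio * predicted FVC."""

    predicted_fvc: float
    target_ratio: float = 0.70

    def __post_init__(self):
        if not (0.0 < self.target_ratio < 1.0):
            raise ValueError(f"target_ratio must be in (0,1), got {self.target_ratio}")
        if self.predicted_fvc <= 0:
            raise ValueError("predicted FVC must be > 0")

    @property
    def target_fev1(self) -> float:
        return self.target_ratio * self.predicted_fvc


def solve_dilation_target(alpha_flow_pairs, fit: RegressionFit, c: float,
                          spec: DilationTargetSpec) -> float:
    """Smallest dilation ratio alpha whose predicted FEV1 reaches the
    target, by monotone piecewise-linear interpolation of predicted FEV1
    over the supplied (alpha, simulated flow) grid.

    Small non-monotonicities (<= 1 % of the FEV1 span) are tolerated with a
    warning; larger ones raise.  An unreachable target (above the predicted
    FEV1 at the largest alpha) raises, reporting the shortfall.
    """
    import warnings

    pairs = sorted((float(a), float(q)) for a, q in alpha_flow_pairs)
    if len(pairs) < 2:
        raise ValueError("need >= 2 (alpha, flow) pairs")
    alphas = np.array([p[0] for p in pairs])
    fev1 = np.array([predict(fit, q, c)[1] for _, q in pairs])
    drops = np.diff(fev1)
    span = float(fev1.max() - fev1.min())
    if (drops < -0.01 * max(span, 1e-12)).any():
        raise ValueError("predicted FEV1 is not monotone in alpha")
    if (drops < 0).any():
        warnings.warn("small non-monotonicity in predicted FEV1; "
                      "using the running maximum")
        fev1 = np.maximum.accumulate(fev1)
    target = spec.target_fev1
    if target <= fev1[0]:
        return float(alphas[0])
    if target > fev1[-1]:
        raise ValueError(
            f"target FEV1 {target:.4g} L/s unreachable: predicted FEV1 at "
            f"alpha={alphas[-1]:g} is {fev1[-1]:.4g} L/s "
            f"(shortfall {target - fev1[-1]:.4g} L/s)")
    i = int(np.searchsorted(fev1, target))
    f0, f1 = fev1[i - 1], fev1[i]
    a0, a1 = alphas[i - 1], alphas[i]
    if f1 == f0:
        return float(a0)
    return float(a0 + (target - f0) / (f1 - f0) * (a1 - a0))


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    """Load patient records from a CSV with columns id,a,b,c (b optional)."""
    df = pd.read_csv(path)
    for col in ("id", "a", "c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        b = row["b"] if "b" in df.columns and pd.notna(row.get("b")) else None
        out.append(PatientRecord(str(row["id"]), float(row["a"]),
                                 float(row["c"]),
                                 None if b is None else float(b)))
    return out
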