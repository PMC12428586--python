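"""Config-driven orchestration of the full workflow:

skeleton -> dilation series -> convolution surfaces -> boundary-condition
files -> (external CFD, not run here) -> FEV1 regression -> dilation target.

The pipeline never solves flow itself; when the per-alpha CFD flow table is
absent the geometry and boundary-condition stages still complete and the
prediction stages are marked as awaiting the external run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import breathing, convsurface, dilation, fev1, skeleton as sk, synth

logger = logging.getLogger(__name__)


@dataclass
class CaseConfig:
    """Declarative description of one case run.

    File paths are optional: a missing skeleton falls back to a seeded
    synthetic tree, missing patients to the built-in training table, and a
    missing flow table simply leaves the dilation-target stage pending.
    """

    out_dir: str = "case_out"
    skeleton_path: str | None = None
    annotation_path: str | None = None
    patients_path: str | None = None
    flows_path: str | None = None      # CSV alpha,a of per-alpha CFD flows
    support_scale: float = 2.0
    spacing: float | None = None
    alphas: tuple[float, ...] = dilation.DEFAULT_ALPHAS
    total_flow_L_s: float = 2.25
    target_ratio: float = 0.70
    predicted_fvc: float | None = None
    patient_c: float | None = None
    build_surfaces: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "alphas" in doc:
            doc["alphas"] = tuple(doc["alphas"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_case(config: CaseConfig) -> dict:
    """Execute every stage the inputs allow and write a JSON case report.

    Returns the report dict; artifact paths and SHA-256 checksums are
    recorded so reruns can be audited for determinism.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "artifacts": {}, "seed": config.seed}

    def record(name: str, path: Path):
        report["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    # --- stage 1: skeleton + stenosis annotation -------------------------
    if config.skeleton_path:
        skel = sk.read_skeleton(config.skeleton_path)
        ann = (dilation.StenosisAnnotation.from_json(config.annotation_path)
               if config.annotation_path else None)
    else:
        tree = synth.make_bifurcating_tree(synth.TreeSpec(seed=config.seed))
        root = tree.root
        skel, ann = synth.insert_stenosis(
            tree, root.id, center_mm=root.length / 2.0,
            length_mm=root.length / 3.0, severity=0.5)
    skel_path = out / "skeleton.json"
    sk.write_skeleton(skel, skel_path)
    record("skeleton", skel_path)
    report["stages"]["skeleton"] = {
        "branches": len(skel.branches),
        "max_generation": max(b.generation for b in skel.branches)}

    # --- stage 2: dilation series ----------------------------------------
    if ann is not None:
        series = dilation.generate_transition_series(skel, ann, config.alphas)
        for a, s in series:
            p = out / f"skeleton_alpha_{int(round(a * 100)):03d}.json"
            sk.write_skeleton(s, p)
            record(f"skeleton_alpha_{a:g}", p)
        report["stages"]["dilation_series"] = {"alphas": list(config.alphas)}
    else:
        series = [(0.0, skel)]
        report["stages"]["dilation_series"] = {"skipped": "no annotation"}

    # --- stage 3: convolution surfaces -----------------------------------
    if config.build_surfaces:
        meshes = {}
        for a, s in series:
            mesh = convsurface.surface_from_skeleton(
                s, support_scale=config.support_scale, spacing=config.spacing)
            p = out / f"surface_alpha_{int(round(a * 100)):03d}.stl"
            convsurface.export_mesh(mesh, p)
            record(f"surface_alpha_{a:g}", p)
            meshes[a] = mesh
        report["stages"]["surfaces"] = {
            "count": len(meshes),
            "faces": {f"{a:g}": int(len(m.faces)) for a, m in meshes.items()}}
    else:
        report["stages"]["surfaces"] = {"skipped": "build_surfaces=false"}

    # --- stage 4: boundary conditions ------------------------------------
    table = breathing.load_segment_fractions()
    terminals = skel.terminal_branches()
    seg_names = list(table.fractions)
    outlets = []
    for i, b in enumerate(terminals):
        r = b.points[-1].radius
        outlets.append(breathing.Outlet(
            f"outlet_{b.id}", [seg_names[i % len(seg_names)]],
            area_mm2=float(3.14159265358979 * r * r)))
    # ensure every segment is drained by at least one outlet
    owned = {s for o in outlets for s in o.segments}
    for j, s in enumerate(seg_names):
        if s not in owned:
            outlets[j % len(outlets)].segments.append(s)
    omap = breathing.OutletMap(outlets)
    case = breathing.allocate_flows(config.total_flow_L_s, table, omap)
    bc_path = out / "bc_normal.csv"
    breathing.export_bc(case, bc_path, stage="normal_velocity_inlets")
    record("bc_normal", bc_path)
    report["stages"]["boundary_conditions"] = {
        "outlets": len(omap.outlets),
        "total_flow_L_s": config.total_flow_L_s}

    # --- stage 5: regression ----------------------------------------------
    records = (fev1.records_from_csv(config.patients_path)
               if config.patients_path else list(fev1.TRAINING_RECORDS))
    fit = fev1.fit_ols(records)
    fit_path = out / "fit.json"
    fit.to_json(fit_path)
    record("fit", fit_path)
    report["stages"]["regression"] = {
        "slope": fit.slope, "intercept": fit.intercept,
        "rmse": fit.rmse, "r2": fit.r2, "n": fit.n}

    # --- stage 6: dilation target (needs external CFD flows) -------------
    if config.flows_path:
        import pandas as pd
        flows = pd.read_csv(config.flows_path)
        c = config.patient_c or records[0].c
        fvc = config.predicted_fvc
        if fvc is None:
            raise ValueError("predicted_fvc required to solve a dilation target")
        spec = fev1.DilationTargetSpec(predicted_fvc=fvc,
                                       target_ratio=config.target_ratio)
        alpha_star = fev1.solve_dilation_target(
            list(zip(flows["alpha"], flows["a"])), fit, c, spec)
        report["stages"]["dilation_target"] = {
            "alpha_star": alpha_star, "target_fev1_L_s": spec.target_fev1}
    else:
        report["stages"]["dilation_target"] = {
            "status": "awaiting external CFD per-alpha flow table"}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("case report written to %s", report_path)
    return report
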