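"""Run the whole pipeline on a synthetic case with one call.

Skeleton (synthetic stenosed tree) -> dilation series -> convolution
surfaces -> boundary-condition files -> regression fit; the dilation
target stays pending because no external CFD flow table is supplied.
Every artifact is checksummed so reruns can be audited for determinism.
"""

import json

import airwaykit as ak

cfg = ak.CaseConfig(out_dir="case_out", seed=1, spacing=0.8,
                    alphas=(0.0, 0.5, 1.0))
report = ak.run_case(cfg)

print(json.dumps(report["stages"], indent=1))
print(f"\n{len(report['artifacts'])} artifacts written under case_out/")
# with flows_path= pointing at a per-alpha CFD flow CSV (columns alpha,a)
# and predicted_fvc set, the report would also contain alpha_star
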