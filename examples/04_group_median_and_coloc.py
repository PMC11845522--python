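"""Group medians and colocalization: the full demo pipeline on a cohort.

Generates a 8-subject distractor cohort, registers every subject with all
four methods, builds method-wise median volumes and quantifies each
median against the atlas (Costes thresholds, Manders split, Spearman rho,
regression).
"""

import tempfile

from labnorm import PipelineConfig, run_pipeline

config = PipelineConfig(n_subjects=8, seed=2)
with tempfile.TemporaryDirectory() as tmp:
    summary = run_pipeline(config, tmp)

print(f"{'method':6s} {'rho':>6s} {'tM1':>7s} {'tM2':>7s} {'slope':>6s}")
for method, info in summary["methods"].items():
    c = info["coloc"]
    print(f"{method:6s} {c['spearman_rho']:6.3f} {c['manders_tm1']:7.4f} "
          f"{c['manders_tm2']:7.4f} {c['regression_slope']:6.3f}")
print()
print("non-convergent registrations:", len(summary["failures"]))
# Higher Spearman rho / Manders coefficients and a regression slope closer
# to 1 mean the method's median volume colocalises better with the atlas.
# The mask-aided (TIE) and landmark (3P) methods outrank the unmasked
# baselines, whose median volumes blur the semicircular canals.
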