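"""Run the full analysis pipeline on a scaled synthetic study.

Generates a 12-participant masked-face recognition experiment with planted
ground truth, fits per-cell HMMs, clusters them into representative patterns
per phase, computes A-B scales, entropies, and d', and prints the planned
mask-use contrasts.  Takes a minute or two on one CPU.

The same analysis is available from the shell:
    gazehmm all -c config.yaml -w workdir/
"""

from gazehmm import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=5,
    n_participants=12,
    n_blocks=8,
    roi_range=[2, 3],
    vbem_restarts=2,
    vhem_restarts=2,
)
result = run_pipeline(config)
report = result.report()

for phase, info in report["patterns"].items():
    print(f"{phase}: {info['n_models']} models -> {info['n_group_rois']} group "
          f"ROIs; {info['n_pattern_a']} Pattern A / {info['n_pattern_b']} Pattern B")

print("\nplanned contrasts vs the unmasked-unmasked baseline (t statistics):")
for dv in ("dprime", "ab_scale", "h2_given_1", "h3_given_2"):
    row = {k: round(v["statistic"], 2)
           for k, v in report["planned_contrasts"][dv].items()}
    print(f"  {dv:12s} {row}")

# Expected qualitative pattern: negative d' contrasts (mask use impairs
# recognition, most reliably when learning/recognition mask conditions
# mismatch), negative A-B and conditional-entropy contrasts for masked-face
# recognition (participants become more eyes-focused and more consistent),
# and near-zero eye-movement contrasts for the learned-masked/recognized-
# unmasked scenario (eye movements follow the recognition-phase mask).
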