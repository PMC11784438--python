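"""Autoagglutination ratio from optical-density readings.

Cells that clump settle out of suspension; the percent drop in OD660 after
standing measures it: ratio = 100 x (initial - after) / initial.
"""

from methylstoich import ODMeasurement, autoagglutination_ratio, replicate_summary

initial = 1.0
replicate_ods_after = [0.45, 0.50, 0.55]

ratios = [
    autoagglutination_ratio(ODMeasurement(initial, after, timepoint_label="3 h"))
    for after in replicate_ods_after
]
summary = replicate_summary(ratios)
print(f"replicate ratios: {[f'{r:.1f}%' for r in ratios]}")
print(f"mean {summary.mean:.1f}% +- {summary.sd:.1f}% (n={summary.n})")
print("-> about half of the suspension's optical density was lost to")
print("   sedimentation after standing.")
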