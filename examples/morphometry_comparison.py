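"""Compare morphology of mononuclear vs multinucleated cells.

Generates one field of 100 mononuclear and one of 100 multinucleated
cells whose nucleus:cell area ratios follow the measured distributions
(mono 5.9 +/- 2.1 %; multi per-nucleus 2.4 +/- 0.6 %), measures every
cell and nucleus from the masks, and runs unpaired t-tests.
"""

from multinuc.config import PipelineConfig
from multinuc.pipeline import run_morphometry_stage

cells, nuclei, groups, comparisons = run_morphometry_stage(PipelineConfig(seed=0))

print("Group means (per-nucleus metrics use nuclei as the unit):")
cols = ["metric", "group", "n", "mean", "sd", "p", "significant"]
print(groups[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

mono = nuclei[nuclei.group == "mono"]["ratio_pct"]
multi = nuclei[nuclei.group == "multi"]["ratio_pct"]
summed = cells[cells.group == "multi"]["summed_ratio_pct"]
print(f"\nWilson ratio, mono:             {mono.mean():.2f}% (configured 5.9%)")
print(f"Wilson ratio, multi per-nucleus: {multi.mean():.2f}% (configured 2.4%)")
print(f"Wilson ratio, multi summed:      {summed.mean():.2f}%")
print("\nEach nucleus of a multinucleated cell claims a smaller share of "
      "the cell, but the summed nuclear area restores a near-constant "
      "nuclear-to-cytoplasmic ratio.")
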