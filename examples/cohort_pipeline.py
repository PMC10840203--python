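"""Full pipeline on a small phantom cohort: dataset -> cohort tables.

Generates a 4-subject phantom cohort in two breath-hold states (files
on disk in the plain-text mask dialect), runs the complete analysis,
and prints the volume table plus the between-state comparison for the
heart.  All outputs also land as CSV files under the output directory.
"""

import tempfile
from pathlib import Path

import cardiomotion as cm

tmp = Path(tempfile.mkdtemp(prefix="cardiomotion_demo_"))
spec = cm.default_phantom_spec(seed=42)

config = cm.RunConfig(
    output_dir=tmp,
    phantom_spec=spec,
    n_subjects=4,
    structures=("heart", "LV", "RV"),
    states=("EIBH", "DIBH"),
)
bundle = cm.run_pipeline(config)

t2 = bundle.table2_volume
print("volume table (mean over 4 subjects):")
for _, row in t2.iterrows():
    print(f"  {row.structure:6s} {row.state}: "
          f"mean {row.volume_ave_mean:6.1f} mL, "
          f"variation {row.variation_mean:5.1f} %, "
          f"max-vs-min p = {row.p_value:.2g}")

comp = bundle.comparisons
heart = comp[(comp.structure == "heart") & (comp.metric == "volume_ave_ml")].iloc[0]
print(f"\nheart volume, DIBH vs EIBH: {heart.percent_change:+.1f} % "
      f"({heart.test}, p = {heart.p_value:.3f})")
print(f"\nCSV reports in {tmp}")

# Deep inspiration compresses the heart: the DIBH rows show smaller mean
# volumes, and the within-state p-values confirm the per-cycle volume
# excursion (max vs min across the 20 phases) for every structure.
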