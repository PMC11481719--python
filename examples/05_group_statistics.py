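"""Group-comparison layer: assumption checks, Grubbs, mixed ANOVA, Tukey.

A small two-sex cohort with an early/late within-subject factor and an
injected sex-by-epoch interaction, plus one outlying animal, walks through
the full statistical path used to compare event statistics across groups.
"""

import numpy as np
import pandas as pd

import fearscope as fs

rng = np.random.default_rng(31)
rows = []
for sex, base, late_shift in (("f", 0.30, -0.10), ("m", 0.20, 0.08)):
    for i in range(6):
        subject = f"{sex}{i}"
        rows.append({"subject_id": subject, "between_factor": sex,
                     "within_factor": "early",
                     "value": base + 0.02 * rng.normal()})
        rows.append({"subject_id": subject, "between_factor": sex,
                     "within_factor": "late",
                     "value": base + late_shift + 0.02 * rng.normal()})
table = pd.DataFrame(rows)

checks = fs.normality_and_variance_checks(
    {sex: g.value.to_numpy() for sex, g in table.groupby("between_factor")})
print("Shapiro-Wilk p per sex:", {k: round(v, 3) for k, v in checks["shapiro_p"].items()})
print(f"Levene p: {checks['levene_p']:.3f}")

values = np.append(table.value.to_numpy()[:10], 5.0)  # one absurd animal
kept, removed = fs.grubbs_recurrent(values, alpha=0.05)
print(f"Grubbs removed {len(removed)} value(s) at index {removed} "
      "(the injected outlier)")

aov = fs.rm_anova_2way(table)
print("\nmixed ANOVA (sex x epoch):")
print(aov.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

tukey = fs.tukey_hsd(table.assign(group=table.between_factor + ":" +
                                  table.within_factor),
                     value="value", group="group")
sig = tukey[tukey.p_adj < 0.05]
print(f"\nTukey: {len(sig)} of {len(tukey)} pairwise comparisons significant "
      "at the family-wise 0.05 level")
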