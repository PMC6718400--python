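"""IC50 from the bundled published viability table.

Pools the Raman-predicted viable percentages of both batches (controls
averaged per batch into the zero-dose anchor) and fits the anchored
four-parameter log-logistic.
"""

from ramanviability import viability as vb
from ramanviability.datasets import (
    dox_thp1_viability_table,
    pooled_raman_dose_response,
)

table = dox_thp1_viability_table()
print(table.to_string(index=False), "\n")

doses, values = pooled_raman_dose_response()
fit = vb.fit_ic50(doses, values)
print(f"upper asymptote (mean control): {fit.upper:.1f}%")
print(f"lower asymptote: {fit.lower:.1f}%   slope: {fit.slope:.3f}")
print(f"IC50 = {fit.ic50:.3f} uM   (RSS {fit.rss:.1f})")
print(fit.per_point_fit.round(2).to_string(index=False))

cmp = vb.compare_assays(
    table.rename(columns={"raman_percent": "percent_viable"}),
    table[["condition_label", "batch", "reference_percent"]],
)
print(f"\nmax |Raman - reference assay| deviation: "
      f"{cmp.max_abs_deviation:.0f} percentage points")
print(
    "\nThe IC50 is the dose at which viability falls halfway between the "
    "asymptotes; the deviation summary compares the spectroscopic "
    "estimate with the dye-exclusion assay condition by condition."
)
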