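"""Bundled reference tables for the doxorubicin / THP-1 viability study.

The published study measured two biological replicates of DOX-treated
THP-1 monocytes and reported, per condition, the Raman-predicted viable
percentage next to the trypan-blue viability test.  That printed table is
the input to the dose-response and assay-comparison analyses and is
carried here as data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["dox_thp1_viability_table", "pooled_raman_dose_response"]

# condition, dose (uM), batch, Raman %, viability test %
_TABLE = [
    ("Control-1", 0.0, "batch-1", 85, 82),
    ("0.05 uM", 0.05, "batch-1", 81, 78),
    ("0.1 uM", 0.1, "batch-1", 73, 69),
    ("0.5 uM", 0.5, "batch-1", 64, 59),
    ("1.0 uM", 1.0, "batch-1", 63, 47),
    ("Control-2", 0.0, "batch-1", 91, 85),
    ("Control-1", 0.0, "batch-2", 99, 99),
    ("0.05 uM", 0.05, "batch-2", 78, 70),
    ("0.1 uM", 0.1, "batch-2", 69, 59),
    ("0.5 uM", 0.5, "batch-2", 36, 32),
    ("1.0 uM", 1.0, "batch-2", 22, 13),
    ("Control-2", 0.0, "batch-2", 97, 95),
]


def dox_thp1_viability_table() -> pd.DataFrame:
    """Published per-condition viability percentages for DOX-treated THP-1
    cells: Raman prediction vs trypan-blue reference, two batches, two
    control wells per batch."""
    return pd.DataFrame(
        _TABLE,
        columns=["condition_label", "dose", "batch", "raman_percent",
                 "reference_percent"],
    )


def pooled_raman_dose_response() -> tuple[np.ndarray, np.ndarray]:
    """(doses, Raman percent-viable) with both batches pooled and the two
    control wells of each batch averaged into that batch's zero-dose
    anchor — the input convention of the IC50 fit."""
    table = dox_thp1_viability_table()
    doses, values = [], []
    for _, grp in table.groupby("batch"):
        ctrl = grp.loc[grp["dose"] == 0, "raman_percent"].mean()
        doses.append(0.0)
        values.append(ctrl)
        treated = grp.loc[grp["dose"] > 0]
        doses.extend(treated["dose"].tolist())
        values.extend(treated["raman_percent"].tolist())
    return np.asarray(doses, dtype=float), np.asarray(values, dtype=float)
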