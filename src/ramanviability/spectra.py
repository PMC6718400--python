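"""Core container for single-cell Raman spectra.

A :class:`SpectraSet` bundles a shared wavenumber (or pixel) axis, an
intensity matrix with one row per cell, per-row metadata, and an
append-only provenance log of every operation applied so far.  All
pipeline stages consume and return this object.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["SpectraSet"]

#: metadata columns every SpectraSet carries (missing ones are added empty)
META_COLUMNS = ["condition_label", "dose", "batch", "well", "qc_flags"]


@dataclass
class SpectraSet:
    """Wavenumber axis + intensity matrix + per-row metadata + provenance.

    Parameters
    ----------
    axis
        Strictly increasing vector of channel positions, in cm^-1 for
        wavenumber-domain data or pixel indices for raw detector frames.
    intensities
        2-D array, shape ``(n_cells, n_channels)``.
    meta
        One record per row.  Standard columns: ``condition_label``,
        ``dose`` (µM), ``batch``, ``well``, ``qc_flags`` (semicolon-joined
        strings, empty when clean).  Extra columns pass through untouched.
    provenance
        Ordered list of ``{"op": name, "params": {...}}`` records.  Stages
        append, never rewrite.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.axis.ndim != 1:
            raise ValueError("axis must be one-dimensional")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"axis length {self.axis.size} != channel count "
                f"{self.intensities.shape[1]}"
            )
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows but intensities has "
                f"{self.intensities.shape[0]}"
            )
        self.meta = self.meta.reset_index(drop=True)
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = "" if col != "dose" else np.nan

    # ------------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def with_intensities(
        self, intensities: np.ndarray, op: str, params: dict[str, Any] | None = None
    ) -> "SpectraSet":
        """New set with replaced intensities and one provenance entry appended."""
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=np.asarray(intensities, dtype=float),
            meta=self.meta.copy(),
            provenance=self.provenance + [{"op": op, "params": dict(params or {})}],
        )

    def subset_rows(
        self, mask: np.ndarray, op: str, params: dict[str, Any] | None = None
    ) -> "SpectraSet":
        mask = np.asarray(mask, dtype=bool)
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=self.intensities[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            provenance=self.provenance + [{"op": op, "params": dict(params or {})}],
        )

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            axis=self.axis.copy(),
            intensities=self.intensities.copy(),
            meta=self.meta.copy(),
            provenance=copy.deepcopy(self.provenance),
        )

    def add_qc_flag(self, rows: np.ndarray, flag: str) -> None:
        """Append ``flag`` to qc_flags of the given boolean-row selection."""
        rows = np.asarray(rows, dtype=bool)
        current = self.meta["qc_flags"].fillna("").astype(str).to_numpy()
        updated = np.where(
            rows, np.where(current == "", flag, current + ";" + flag), current
        )
        self.meta["qc_flags"] = updated

    def has_qc_flag(self, flag: str) -> np.ndarray:
        flags = self.meta["qc_flags"].fillna("").astype(str)
        return flags.str.split(";").apply(lambda fl: flag in fl).to_numpy()
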