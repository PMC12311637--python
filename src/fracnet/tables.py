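"""Tabular containers for size-fractionated amplicon data.

The central object is :class:`AsvTable`, a thin wrapper around a
samples x ASVs :class:`pandas.DataFrame` of counts or relative
abundances, carrying per-sample metadata (season, layer, station) and
per-ASV annotation (taxonomy lineage and, for protists, trophic mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRACTIONS = ("bacteria", "pico", "nano")
SEASONS = ("winter", "spring", "summer", "autumn")
TROPHIC_MODES = (
    "photoautotroph",
    "heterotroph",
    "mixotroph",
    "symbiont",
    "parasite",
    "unknown",
)


@dataclass
class AsvTable:
    """Samples x ASVs abundance table for one size fraction.

    Parameters
    ----------
    data : DataFrame
        Rows are samples, columns are ASV ids.  Values are non-negative
        counts or relative abundances (rows summing to 1).
    fraction : str
        One of ``bacteria``, ``pico``, ``nano``.
    sample_metadata : DataFrame, optional
        Indexed like ``data``; typically carries ``season``, ``layer``
        and ``station`` columns.
    taxonomy : DataFrame, optional
        Indexed by ASV id; free-form lineage columns plus an optional
        ``trophic_mode`` column for protist fractions.
    is_relative : bool
        Whether ``data`` holds relative abundances rather than counts.
    """

    data: pd.DataFrame
    fraction: str = "bacteria"
    sample_metadata: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    is_relative: bool = False
    empty_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.data.columns.has_duplicates:
            raise ValueError("ASV ids must be unique")
        if self.sample_metadata is not None:
            missing = self.data.index.difference(self.sample_metadata.index)
            if len(missing):
                raise ValueError(
                    f"sample_metadata missing rows for samples: {list(missing)[:5]}"
                )
            self.sample_metadata = self.sample_metadata.loc[self.data.index]

    # -- convenience -------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def seasons(self) -> pd.Series:
        if self.sample_metadata is None or "season" not in self.sample_metadata:
            raise ValueError("table has no season metadata")
        return self.sample_metadata["season"]

    def copy(self) -> "AsvTable":
        return AsvTable(
            data=self.data.copy(),
            fraction=self.fraction,
            sample_metadata=None
            if self.sample_metadata is None
            else self.sample_metadata.copy(),
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
            is_relative=self.is_relative,
            empty_samples=list(self.empty_samples),
        )

    def subset_asvs(self, asv_ids) -> "AsvTable":
        """Return a copy restricted (and ordered) to ``asv_ids``."""
        asv_ids = [a for a in self.asv_ids if a in set(asv_ids)]
        out = self.copy()
        out.data = out.data[asv_ids]
        if out.taxonomy is not None:
            out.taxonomy = out.taxonomy.loc[
                out.taxonomy.index.intersection(asv_ids)
            ]
        return out


def validate_relative(table: AsvTable, atol: float = 1e-9) -> None:
    """Assert that every non-empty row of a relative table sums to 1."""
    sums = table.data.sum(axis=1).to_numpy()
    nonempty = sums > 0
    if not np.allclose(sums[nonempty], 1.0, atol=atol):
        raise ValueError("non-empty rows of a relative table must sum to 1")
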