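"""Cross-fraction ASV deduplication, network ASV selection and transforms.

Protist ASVs can show up in both the pico (0.8-2 um) and nano (2-20 um)
size fractions because cells dislodge from, or clog, the sequential
filters.  :func:`resolve_shared_asvs` applies the standard ratio rule:
for every ASV present in both fractions the ratio of its mean relative
abundance nano/pico is computed, and the minority fraction is dropped
when the ratio leaves the (0.5, 2) band.

:func:`select_network_asvs` retains the prevalent core used for network
inference: ASVs present in all seasons, in strictly more than a third of
samples, with mean relative abundance strictly above 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable


def relative_abundance(table: AsvTable) -> AsvTable:
    """Convert counts to per-sample relative abundances.

    All-zero rows stay all-zero and their sample ids are recorded in
    ``empty_samples`` on the returned table.
    """
    out = table.copy()
    sums = out.data.sum(axis=1)
    empty = sums[sums == 0].index.tolist()
    safe = sums.replace(0, 1.0)
    out.data = out.data.div(safe, axis=0)
    out.is_relative = True
    out.empty_samples = empty
    return out


def _as_relative(table: AsvTable) -> AsvTable:
    return table if table.is_relative else relative_abundance(table)


@dataclass
class SharedAsvReport:
    """Audit trail of the cross-fraction ratio filter."""

    ratio_basis: str = "mean relative abundance over all samples (nano/pico)"
    entries: list = field(default_factory=list)

    def add(self, asv_id, ratio: float, action: str) -> None:
        self.entries.append({"asv_id": asv_id, "ratio": ratio, "action": action})

    def to_records(self) -> list:
        return list(self.entries)


def resolve_shared_asvs(
    pico: AsvTable, nano: AsvTable
) -> tuple[AsvTable, AsvTable, SharedAsvReport]:
    """Apply the nano/pico abundance-ratio rule to ASVs shared by both fractions.

    For each shared ASV the ratio of its mean relative abundance in the
    nano fraction to that in the pico fraction is computed over all
    samples.  Ratio strictly above 2 drops the ASV from pico; strictly
    below 0.5 drops it from nano; otherwise it is kept in both.  A pico
    mean of zero with a positive nano mean counts as ratio +inf (drop
    from pico); both zero means no action.  Idempotent.
    """
    if not pico.samples.equals(nano.samples):
        raise ValueError("pico and nano tables must share an identical sample set")
    pico_rel = _as_relative(pico)
    nano_rel = _as_relative(nano)

    shared = pico.asv_ids.intersection(nano.asv_ids)
    report = SharedAsvReport()
    drop_pico, drop_nano = [], []
    for asv in shared:
        p_mean = float(pico_rel.data[asv].mean())
        n_mean = float(nano_rel.data[asv].mean())
        if p_mean == 0 and n_mean == 0:
            report.add(asv, float("nan"), "kept (absent in both)")
            continue
        ratio = math.inf if p_mean == 0 else n_mean / p_mean
        if ratio > 2:
            drop_pico.append(asv)
            report.add(asv, ratio, "removed from pico")
        elif ratio < 0.5:
            drop_nano.append(asv)
            report.add(asv, ratio, "removed from nano")
        else:
            report.add(asv, ratio, "kept in both")

    pico_out = pico.copy()
    nano_out = nano.copy()
    pico_out.data = pico_out.data.drop(columns=drop_pico)
    nano_out.data = nano_out.data.drop(columns=drop_nano)
    if pico_out.taxonomy is not None:
        pico_out.taxonomy = pico_out.taxonomy.drop(index=drop_pico, errors="ignore")
    if nano_out.taxonomy is not None:
        nano_out.taxonomy = nano_out.taxonomy.drop(index=drop_nano, errors="ignore")
    return pico_out, nano_out, report


def select_network_asvs(
    table: AsvTable,
    min_prevalence_fraction: float = 1 / 3,
    min_mean_relabund: float = 0.001,
    require_all_seasons: bool = True,
) -> AsvTable:
    """Keep the prevalent core of ASVs eligible for network inference.

    An ASV is retained when it (a) is present (non-zero) in at least one
    sample of every season, (b) occurs in strictly more than
    ``min_prevalence_fraction`` of all samples, and (c) has mean relative
    abundance strictly greater than ``min_mean_relabund``.  Column order
    is preserved and remaining columns are NOT renormalized.
    """
    rel = _as_relative(table)
    n = rel.n_samples
    if n == 0:
        raise ValueError("empty table")
    present = rel.data > 0
    prevalence_ok = present.sum(axis=0) > min_prevalence_fraction * n
    abundance_ok = rel.data.mean(axis=0) > min_mean_relabund

    if require_all_seasons:
        seasons = rel.seasons()
        season_ok = pd.Series(True, index=rel.asv_ids)
        for _, idx in rel.data.groupby(seasons, observed=True).groups.items():
            season_ok &= present.loc[idx].any(axis=0)
    else:
        season_ok = pd.Series(True, index=rel.asv_ids)

    keep = rel.asv_ids[prevalence_ok & abundance_ok & season_ok]
    return rel.subset_asvs(keep)


def hellinger_transform(table: AsvTable) -> pd.DataFrame:
    """Hellinger transform: sqrt of per-sample relative abundance.

    Rows of the result have unit Euclidean norm (all-zero rows stay
    zero).  Accepts counts or relative abundances.
    """
    rel = _as_relative(table)
    return np.sqrt(rel.data)


def aggregate_by_label(table: AsvTable, label: str) -> AsvTable:
    """Sum ASV columns within a taxonomy/trophic label.

    ``label`` names a column of ``table.taxonomy``.  Row sums are
    conserved, so relative abundances stay relative.  ASVs without a
    label are pooled under ``"unassigned"``.
    """
    if table.taxonomy is None or label not in table.taxonomy.columns:
        raise ValueError(f"taxonomy column {label!r} not present")
    labels = table.taxonomy[label].reindex(table.asv_ids).fillna("unassigned")
    grouped = table.data.T.groupby(labels.to_numpy()).sum().T
    out = table.copy()
    out.data = grouped
    out.taxonomy = None
    return out
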