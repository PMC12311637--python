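"""Levins' niche breadth and community-level means.

For a metacommunity of N communities (samples), an ASV j with
occupancy proportions P_ij (its abundance in community i divided by its
metacommunity total) has Levins' breadth B_j = 1 / sum_i P_ij^2, the
effective number of communities it occupies: B_j = 1 for a perfect
specialist, B_j = N for an ASV spread evenly over all communities.
The community-level index is the unweighted mean of B_j over the ASVs
present in a community; low values indicate specialist-dominated
communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable


@dataclass
class NicheBreadthResult:
    """Per-ASV Levins B within one metacommunity (e.g. a season)."""

    metacommunity: str
    n_communities: int
    breadth: pd.Series  # index: ASV id, value: B_j
    p_matrix: pd.DataFrame  # communities x ASVs occupancy proportions
    absent_asvs: list = field(default_factory=list)

    def community_means(self, weighted: bool = False) -> pd.Series:
        """Mean B over ASVs present (abundance > 0) in each community.

        ``weighted=True`` weights each B_j by the ASV's relative
        abundance in that community instead of the plain mean.
        Communities with no ASVs get NaN.
        """
        out = {}
        for sample in self.p_matrix.index:
            present = self.p_matrix.loc[sample] > 0
            asvs = self.breadth.index[present.reindex(self.breadth.index, fill_value=False)]
            if len(asvs) == 0:
                out[sample] = np.nan
            elif weighted:
                w = self.p_matrix.loc[sample, asvs]
                out[sample] = float((self.breadth[asvs] * w).sum() / w.sum())
            else:
                out[sample] = float(self.breadth[asvs].mean())
        return pd.Series(out, name="community_niche_breadth")


def levins_breadth(
    table: AsvTable, metacommunity_grouping: str = "season"
) -> dict[str, NicheBreadthResult]:
    """Levins' B per ASV, within each metacommunity defined by a grouping.

    Each level of ``metacommunity_grouping`` (a sample-metadata column,
    by default the season) defines a metacommunity whose member samples
    are its communities.  ASVs absent from a metacommunity are excluded
    there and listed in ``absent_asvs``.
    """
    if table.sample_metadata is None or metacommunity_grouping not in table.sample_metadata:
        raise ValueError(f"missing grouping column {metacommunity_grouping!r}")
    grouping = table.sample_metadata[metacommunity_grouping]
    results: dict[str, NicheBreadthResult] = {}
    for level, idx in table.data.groupby(grouping, observed=True).groups.items():
        sub = table.data.loc[idx]
        if sub.shape[0] == 0:
            raise ValueError(f"empty metacommunity {level!r}")
        totals = sub.sum(axis=0)
        present = totals > 0
        absent = totals.index[~present].tolist()
        p = sub.loc[:, present].div(totals[present], axis=1)
        b = 1.0 / (p**2).sum(axis=0)
        results[str(level)] = NicheBreadthResult(
            metacommunity=str(level),
            n_communities=sub.shape[0],
            breadth=b,
            p_matrix=p,
            absent_asvs=absent,
        )
    return results


def community_level_breadth(
    results: dict[str, NicheBreadthResult], weighted: bool = False
) -> pd.Series:
    """Concatenate per-community mean breadths over all metacommunities."""
    parts = [r.community_means(weighted=weighted) for r in results.values()]
    return pd.concat(parts)
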