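"""Carbon biomass conversion and predator/prey biomass ratios (PPBR).

Cytometry/microscopy abundances (cells mL^-1) are converted to carbon
biomass with literature per-cell factors: heterotrophic bacteria (HB)
20 fg C, Synechococcus (Syn) 178 fg C, photosynthetic picoeukaryotes
(PPE) 1500 fg C, heterotrophic and pigmented nanoflagellates (HNF,
PNF) 4700 fg C per cell.  PPBR is the biomass ratio of the
nanoflagellate predators (HNF) to their prey (HB or PPE), log10
transformed for modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_FACTORS = {"HB": 20.0, "Syn": 178.0, "PPE": 1500.0, "HNF": 4700.0, "PNF": 4700.0}


def abundance_to_biomass(
    table: pd.DataFrame, factors: dict[str, float] | None = None
) -> pd.DataFrame:
    """Add ``<group>_biomass`` columns (fg C mL^-1) for each abundance column.

    ``factors`` maps group name (column) to fg C per cell; defaults to
    the standard conversion factors above.  Abundances must be
    non-negative.
    """
    factors = dict(DEFAULT_FACTORS if factors is None else factors)
    out = table.copy()
    for group, factor in factors.items():
        if group not in table.columns:
            continue
        if (table[group] < 0).any():
            raise ValueError(f"negative abundance in column {group!r}")
        out[f"{group}_biomass"] = table[group] * factor
    return out


def ppbr(table: pd.DataFrame, factors: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-sample predator/prey biomass ratios HNF/HB and HNF/PPE.

    Returns columns ``ppbr_hnf_hb``, ``ppbr_hnf_ppe`` and their log10.
    Zero prey biomass yields NaN and the sample is listed in the
    DataFrame attribute ``flagged_zero_denominator``.
    """
    if "HNF_biomass" not in table.columns:
        table = abundance_to_biomass(table, factors)
    out = pd.DataFrame(index=table.index)
    flagged = []
    for prey, name in (("HB", "ppbr_hnf_hb"), ("PPE", "ppbr_hnf_ppe")):
        denom = table[f"{prey}_biomass"]
        zero = denom == 0
        flagged.extend(table.index[zero].tolist())
        ratio = table["HNF_biomass"].where(~zero) / denom.where(~zero)
        out[name] = ratio
        out[f"log10_{name}"] = np.log10(ratio.where(ratio > 0))
    out.attrs["flagged_zero_denominator"] = sorted(set(flagged))
    return out
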