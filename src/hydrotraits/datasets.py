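"""Packaged reference data.

The six-species trait-mean table (eight hydraulic/leaf traits with 95%
CI half-widths) for a southern African semi-arid savanna panel of six
co-occurring tree species: cavitation resistance
(P50, MPa), wood density (WD, g cm-3), turgor loss point (psi_tlp,
MPa), specific leaf area (SLA, cm2 g-1), standardized capacitance
(C_std, mol kg-1 MPa-1), shoot saturated water content (SWC_br, g g-1),
relative water content at turgor loss (RWC_tlp, g g-1) and minimum
conductance (g_min, mmol m-2 s-1).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_species_trait_means", "TRAIT_COLUMNS"]

TRAIT_COLUMNS = ("P50", "WD", "psi_tlp", "SLA", "C_std", "SWC_br",
                 "RWC_tlp", "g_min")


def load_species_trait_means(include_ci: bool = False) -> pd.DataFrame:
    """Species x trait means for the six-species savanna panel.

    Parameters
    ----------
    include_ci : bool
        Keep the ``*_ci95`` half-width columns alongside the means.
    """
    ref = resources.files("hydrotraits.data") / "species_trait_means.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="species")
    if not include_ci:
        df = df[list(TRAIT_COLUMNS)]
    return df
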