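"""Published 2014 cohort group means, bundled as package data.

``cohort_means_2014.csv`` holds the per-compound arithmetic means
(μg/berry) of the 2014 non-irrigated and irrigated populations of the
grape diversity panel. They serve two purposes: consistency checks of the
calculated composition variables against their published values, and
realistic per-compound abundance baselines for the synthetic-cohort
generator.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

from .io_model import QuantTable, UnitBasis
from .panel import CompoundPanel


def cohort_means_2014() -> pd.DataFrame:
    """Per-compound 2014 group means, μg/berry.

    Indexed by compound abbreviation, columns ``ni_ug_per_berry`` and
    ``ir_ug_per_berry``.
    """
    ref = importlib.resources.files("vitiphenol.data") / "cohort_means_2014.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, index_col="abbreviation")


def pseudo_sample_table(panel: CompoundPanel | None = None,
                        column: str = "ni_ug_per_berry",
                        sample_id: str = "cohort-mean") -> QuantTable:
    """A one-row per-berry QuantTable holding a column of the 2014 means.

    Feeding a group-mean vector through the index calculations exploits the
    linearity of the totals: the total of the means equals the mean of the
    totals.
    """
    panel = panel or CompoundPanel.builtin()
    means = cohort_means_2014()[column]
    values = means.reindex(panel.abbreviations).to_frame(name=sample_id).T
    return QuantTable(values, UnitBasis.PER_BERRY, panel)
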