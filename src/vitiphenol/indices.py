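"""The 17 calculated polyphenol composition variables.

Six totals (μg/berry or μg/g, same basis as the input table):

* ``s_AN_n`` — native anthocyanins (the 28 AN glycosides, dimers excluded)
* ``s_FO`` — flavonols; ``s_ST`` — stilbenes; ``s_HB`` — hydroxybenzoic
  acids; ``s_HC`` — hydroxycinnamic acids
* ``s_FA`` — flavan-3-ol (tannin) units released by phloroglucinolysis

Ten percentages (0–100) and the mean degree of polymerization ``dp_FA``
(total released units over terminal units, dimensionless ≥ 1). Membership
sets are derived from panel attributes (aglycone, B-ring hydroxylation,
methylation, acylation, conjugate, galloylation), so panel edits propagate.
Percentages and dp are ratios of like units and therefore invariant to the
unit basis; a zero denominator marks the ratio undefined (NaN value plus a
False entry in the ``defined`` mask) rather than raising.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import MetadataSet, QuantTable, UnitBasis
from .panel import CompoundPanel

TOTAL_VARIABLES = ("s_AN_n", "s_FO", "s_ST", "s_HB", "s_HC", "s_FA")
PERCENT_VARIABLES = ("p_AN_acyl", "p_AN_tri", "p_AN_met",
                     "p_FO_mono", "p_FO_di", "p_FO_tri", "p_FO_met",
                     "p_FO_glucur", "p_FA_tri", "p_FA_gall")
INDEX_VARIABLES = TOTAL_VARIABLES + PERCENT_VARIABLES + ("dp_FA",)


@dataclass
class IndexTable:
    """Samples × 17 calculated variables, with a defined-ness mask."""

    values: pd.DataFrame
    defined: pd.DataFrame
    unit_basis: UnitBasis

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# totals in table units ({self.unit_basis.value}); "
                     "percentages on the 0-100 scale; dp_FA dimensionless\n")
            self.values.to_csv(fh, index_label="sample_id")

    @classmethod
    def read_csv(cls, path, unit_basis: UnitBasis | str = UnitBasis.PER_BERRY) -> "IndexTable":
        df = pd.read_csv(path, index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df, df.notna(), UnitBasis.coerce(unit_basis))


def _sets(panel: CompoundPanel) -> dict[str, list[str]]:
    """Membership sets for every formula, derived from panel attributes."""
    an_native = panel.native_anthocyanins()
    an_nat = set(an_native)
    fa_units = panel.tannin_units()
    return {
        "an_native": an_native,
        "an_acyl": [a for a in panel.select(family="AN", acylated=True) if a in an_nat],
        "an_tri": [a for a in panel.select(family="AN", b_ring_oh=3) if a in an_nat],
        "an_met": [a for a in panel.select(family="AN", methylated=True) if a in an_nat],
        "fo": panel.family_members("FO"),
        "fo_mono": panel.select(family="FO", b_ring_oh=1),
        "fo_di": panel.select(family="FO", b_ring_oh=2),
        "fo_tri": panel.select(family="FO", b_ring_oh=3),
        "fo_met": panel.select(family="FO", methylated=True),
        "fo_glucur": panel.select(family="FO", conjugate="glucur"),
        "st": panel.family_members("ST"),
        "hb": panel.family_members("HB"),
        "hc": panel.family_members("HC"),
        "fa_units": fa_units,
        "fa_terminal": panel.terminal_units(),
        "fa_tri": panel.select(family="FA", tannin_unit=("terminal", "extension"),
                               b_ring_oh=3),
        "fa_gall": panel.select(family="FA", tannin_unit=("terminal", "extension"),
                                galloylated=True),
    }


def _ratio(num: pd.Series, den: pd.Series, percent: bool = True) -> pd.Series:
    out = pd.Series(np.nan, index=num.index, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok] * (100.0 if percent else 1.0)
    return out


def compute_indices(table: QuantTable) -> IndexTable:
    """Compute the 17 calculated variables for every sample of *table*."""
    s = _sets(table.panel)
    v = table.values

    def tot(key: str) -> pd.Series:
        return v[s[key]].sum(axis=1)

    out = pd.DataFrame(index=v.index, dtype=float)
    out["s_AN_n"] = tot("an_native")
    out["s_FO"] = tot("fo")
    out["s_ST"] = tot("st")
    out["s_HB"] = tot("hb")
    out["s_HC"] = tot("hc")
    out["s_FA"] = tot("fa_units")

    out["p_AN_acyl"] = _ratio(tot("an_acyl"), out["s_AN_n"])
    out["p_AN_tri"] = _ratio(tot("an_tri"), out["s_AN_n"])
    out["p_AN_met"] = _ratio(tot("an_met"), out["s_AN_n"])
    out["p_FO_mono"] = _ratio(tot("fo_mono"), out["s_FO"])
    out["p_FO_di"] = _ratio(tot("fo_di"), out["s_FO"])
    out["p_FO_tri"] = _ratio(tot("fo_tri"), out["s_FO"])
    out["p_FO_met"] = _ratio(tot("fo_met"), out["s_FO"])
    out["p_FO_glucur"] = _ratio(tot("fo_glucur"), out["s_FO"])
    out["p_FA_tri"] = _ratio(tot("fa_tri"), out["s_FA"])
    out["p_FA_gall"] = _ratio(tot("fa_gall"), out["s_FA"])
    out["dp_FA"] = _ratio(out["s_FA"], tot("fa_terminal"), percent=False)

    defined = out.notna()
    return IndexTable(out[list(INDEX_VARIABLES)], defined[list(INDEX_VARIABLES)],
                      table.unit_basis)


def mean_degree_of_polymerization(fa_units: pd.Series | dict,
                                  panel: CompoundPanel,
                                  terminal_set: str = "FA7-FA11") -> float:
    """Mean tannin chain length: total released units over terminal units.

    *fa_units* maps the nine phloroglucinolysis unit abbreviations to
    molar-proportional amounts. ``terminal_set`` selects the denominator:
    the default ``"FA7-FA11"`` uses all five terminal units (gallocatechin,
    epigallocatechin, epicatechin, epicatechin 3-gallate and catechin
    terminal units); ``"FA7-FA10"`` is an alternative that omits the
    catechin terminal unit, kept for comparison only.
    """
    fa_units = pd.Series(fa_units, dtype=float)
    units = panel.tannin_units()
    missing = [u for u in units if u not in fa_units.index]
    if missing:
        raise ValueError(f"missing tannin unit value(s): {missing}")
    terminal = panel.terminal_units()
    if terminal_set == "FA7-FA10":
        terminal = [t for t in terminal if panel[t].family_index <= 10]
    elif terminal_set != "FA7-FA11":
        raise ValueError(f"unknown terminal set {terminal_set!r}")
    total = float(fa_units[units].sum())
    term = float(fa_units[terminal].sum())
    if term <= 0:
        raise ValueError("zero terminal-unit sum: dp undefined")
    return total / term


def group_mean_table(indices: IndexTable, meta: MetadataSet,
                     table: QuantTable | None = None) -> pd.DataFrame:
    """Arithmetic group means by treatment × vintage, tidy long format.

    Totals are averaged directly, so mean-of-sums equals sum-of-column-means
    by linearity. Percentages and dp are averaged as mean of the per-sample
    ratios (which in general differs from the ratio of group means). When
    *table* is given, per-compound means are included as well.

    Returns a DataFrame with columns (variable, treatment, vintage, mean, n);
    undefined per-sample ratios are excluded from their group mean.
    """
    frames = []
    if table is not None:
        frames.append(table.values)
    frames.append(indices.values)
    wide = pd.concat(frames, axis=1)
    meta_df = meta.to_frame().loc[wide.index, ["treatment", "vintage"]]
    rows = []
    grouped = wide.groupby([meta_df["treatment"], meta_df["vintage"]])
    for (treatment, vintage), chunk in grouped:
        if len(chunk) == 0:
            raise ValueError(f"empty group {(treatment, vintage)}")
        means = chunk.mean(axis=0, skipna=True)
        counts = chunk.notna().sum(axis=0)
        for var in wide.columns:
            rows.append({"variable": var, "treatment": treatment,
                         "vintage": vintage, "mean": means[var],
                         "n": int(counts[var])})
    return pd.DataFrame(rows)
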