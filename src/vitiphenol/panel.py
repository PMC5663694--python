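"""Registry of the 105 targeted grape-skin phenolic compounds.

The panel describes each quantified compound: its family (native
anthocyanins AN, pyranoanthocyanins AP, anthocyanin-flavanol adducts AF,
caftaric-anthocyanin adducts AC, dihydroflavonols HF, flavonols FO,
stilbenes ST, flavan-3-ols/tannin units FA, hydroxybenzoic acids HB,
hydroxycinnamic acids HC, others OT), its position within the family,
structural attributes used to derive the composition indices (B-ring
hydroxylation, methylation, acylation, conjugate sugar, galloylation,
terminal/extension tannin unit), and the per-compound limit of
quantification (LOQ).

Compound identity throughout the package is the abbreviation string
(e.g. ``"AN-Mv-glc"``), case-sensitive; the panel file is the single
source of truth for attributes.
"""
from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

FAMILIES = ("AN", "AP", "AF", "AC", "HF", "FO", "ST", "FA", "HB", "HC", "OT")

#: expected family sizes for the builtin 105-compound panel
_FAMILY_SIZES = {"AN": 30, "AP": 8, "AF": 15, "AC": 2, "HF": 2, "FO": 12,
                 "ST": 7, "FA": 15, "HB": 5, "HC": 6, "OT": 3}

CONJUGATES = ("glc", "diglc", "acglc", "coumglc", "caffglc", "glucur",
              "aglycone", "other")


@dataclass(frozen=True)
class CompoundEntry:
    """One compound of the quantification panel."""

    global_code: int
    abbreviation: str
    family: str
    family_index: int
    aglycone: str  # "" when not applicable (adducts, acids…)
    b_ring_oh: int  # 0 when not applicable
    methylated: bool
    acylated: bool
    conjugate: str
    tannin_unit: str  # "terminal", "extension" or ""
    galloylated: bool
    loq: float  # limit of quantification, table units

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.conjugate not in CONJUGATES:
            raise ValueError(f"unknown conjugate {self.conjugate!r}")
        if self.tannin_unit not in ("", "terminal", "extension"):
            raise ValueError(f"bad tannin_unit {self.tannin_unit!r}")
        if self.loq < 0:
            raise ValueError(f"negative LOQ for {self.abbreviation}")


class CompoundPanel:
    """Ordered collection of :class:`CompoundEntry`, indexed by abbreviation."""

    def __init__(self, entries: Iterable[CompoundEntry], validate_full: bool = False):
        self.entries: list[CompoundEntry] = sorted(entries, key=lambda e: e.global_code)
        codes = [e.global_code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate global codes in panel")
        abbrs = [e.abbreviation for e in self.entries]
        if len(set(abbrs)) != len(abbrs):
            raise ValueError("duplicate abbreviations in panel")
        for fam in FAMILIES:
            fidx = [e.family_index for e in self.entries if e.family == fam]
            if len(set(fidx)) != len(fidx):
                raise ValueError(f"duplicate family_index within {fam}")
        if validate_full:
            if codes != list(range(1, 106)):
                raise ValueError("full panel must cover global codes 1..105")
            sizes = {fam: len([e for e in self.entries if e.family == fam])
                     for fam in FAMILIES}
            if sizes != _FAMILY_SIZES:
                raise ValueError(f"unexpected family sizes: {sizes}")
        self._by_abbr = {e.abbreviation: e for e in self.entries}

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._by_abbr

    def __getitem__(self, abbreviation: str) -> CompoundEntry:
        try:
            return self._by_abbr[abbreviation]
        except KeyError:
            raise KeyError(f"compound {abbreviation!r} not in panel") from None

    @property
    def abbreviations(self) -> list[str]:
        """Abbreviations in global-code order (the canonical column order)."""
        return [e.abbreviation for e in self.entries]

    def loqs(self) -> dict[str, float]:
        return {e.abbreviation: e.loq for e in self.entries}

    # -- selection helpers (membership sets derived from attributes) --
    def family_members(self, family: str) -> list[str]:
        return [e.abbreviation for e in self.entries if e.family == family]

    def select(self, **criteria) -> list[str]:
        """Abbreviations of entries matching all attribute criteria.

        A criterion value may be a single value or a set/tuple of
        admissible values, e.g. ``select(family="FO", conjugate="glucur")``
        or ``select(family="AN", aglycone=("Dp", "Pt", "Mv"))``.
        """
        out = []
        for e in self.entries:
            ok = True
            for attr, want in criteria.items():
                val = getattr(e, attr)
                if isinstance(want, (set, tuple, list, frozenset)):
                    ok = val in want
                else:
                    ok = val == want
                if not ok:
                    break
            if ok:
                out.append(e.abbreviation)
        return out

    def native_anthocyanins(self) -> list[str]:
        """The 28 native anthocyanins (AN1-AN28; the two dimers excluded)."""
        return [e.abbreviation for e in self.entries
                if e.family == "AN" and e.family_index <= 28]

    def tannin_units(self) -> list[str]:
        """The nine phloroglucinolysis unit variables (FA7-FA15)."""
        return self.select(family="FA", tannin_unit=("terminal", "extension"))

    def terminal_units(self) -> list[str]:
        """Terminal flavan-3-ol units (FA7-FA11)."""
        return self.select(family="FA", tannin_unit="terminal")

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict], **kw) -> "CompoundPanel":
        entries = [
            CompoundEntry(
                global_code=int(r["global_code"]),
                abbreviation=str(r["abbreviation"]),
                family=str(r["family"]),
                family_index=int(r["family_index"]),
                aglycone=str(r.get("aglycone", "") or ""),
                b_ring_oh=int(r.get("b_ring_oh", 0) or 0),
                methylated=bool(int(r.get("methylated", 0) or 0)),
                acylated=bool(int(r.get("acylated", 0) or 0)),
                conjugate=str(r.get("conjugate", "other") or "other"),
                tannin_unit=str(r.get("tannin_unit", "") or ""),
                galloylated=bool(int(r.get("galloylated", 0) or 0)),
                loq=float(r.get("loq", 0.0) or 0.0),
            )
            for r in records
        ]
        return cls(entries, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "CompoundPanel":
        with open(path, newline="") as fh:
            return cls.from_records(csv.DictReader(fh), **kw)

    @classmethod
    def from_yaml(cls, path: str | Path, **kw) -> "CompoundPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_records(doc["compounds"], **kw)

    def to_yaml(self, path: str | Path) -> None:
        doc = {"compounds": [
            {"global_code": e.global_code, "abbreviation": e.abbreviation,
             "family": e.family, "family_index": e.family_index,
             "aglycone": e.aglycone, "b_ring_oh": e.b_ring_oh,
             "methylated": int(e.methylated), "acylated": int(e.acylated),
             "conjugate": e.conjugate, "tannin_unit": e.tannin_unit,
             "galloylated": int(e.galloylated), "loq": e.loq}
            for e in self.entries]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def builtin(cls) -> "CompoundPanel":
        """The builtin 105-compound grape-skin panel.

        LOQ values are synthetic placeholders (2% of the 2014 non-irrigated
        cohort mean per compound); real panels should supply instrument LOQs.
        """
        ref = importlib.resources.files("vitiphenol.data") / "panel.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p, validate_full=True)


def default_panel() -> CompoundPanel:
    return CompoundPanel.builtin()
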