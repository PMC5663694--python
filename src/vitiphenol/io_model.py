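"""Data model and I/O: quantification tables, sample metadata, censoring
imputation, unit conversion, and paired-cohort assembly.

A quantification table is samples × compounds, in μg/berry or μg/g fresh
berry. Values reported below the per-compound limit of quantification are
replaced by LOQ/2 (the censoring mask records which entries were imputed).
The paired cohort retains only cultivars observed under both irrigation
regimes with complete berry weights, logging every exclusion.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import CompoundPanel


class UnitBasis(enum.Enum):
    PER_BERRY = "per_berry"  # μg/berry
    PER_GRAM = "per_gram"    # μg/g fresh berry

    @classmethod
    def coerce(cls, value) -> "UnitBasis":
        if isinstance(value, cls):
            return value
        return cls(str(value))


COLORS = ("black", "red", "pink", "white")
COLORED = frozenset({"black", "red", "pink"})
GENETIC_GROUPS = ("WW", "WE", "TE")
TREATMENTS = ("IR", "NI")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample record: one cultivar × treatment × vintage observation."""

    sample_id: str
    cultivar: str
    color: str
    genetic_group: str
    treatment: str
    vintage: int
    berry_weight: float | None  # g, may be missing
    brix: float | None = None
    delta13c: float | None = None  # ‰, typically −27 (no deficit) to −20
    harvest_date: str | None = None  # ISO date

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown berry color {self.color!r}")
        if self.genetic_group not in GENETIC_GROUPS:
            raise ValueError(f"unknown genetic group {self.genetic_group!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.berry_weight is not None and not (self.berry_weight > 0):
            raise ValueError("berry weight must be > 0 g when present")

    @property
    def colored(self) -> bool:
        return self.color in COLORED


class MetadataSet:
    """Collection of :class:`SampleMetadata`, unique per sample id.

    (cultivar, treatment, vintage) identifies at most one sample.
    """

    def __init__(self, records: Iterable[SampleMetadata]):
        self.records: list[SampleMetadata] = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in metadata")
        keys = [(r.cultivar, r.treatment, r.vintage) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (cultivar, treatment, vintage) in metadata")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def vintages(self) -> list[int]:
        return sorted({r.vintage for r in self.records})

    def cultivars(self) -> list[str]:
        return sorted({r.cultivar for r in self.records})

    def lookup(self, cultivar: str, treatment: str, vintage: int) -> SampleMetadata | None:
        for r in self.records:
            if (r.cultivar, r.treatment, r.vintage) == (cultivar, treatment, vintage):
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("sample_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetadataSet":
        recs = []
        for sid, row in df.iterrows():
            def opt(key):
                v = row.get(key)
                if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                    return None
                return v
            bw = opt("berry_weight")
            recs.append(SampleMetadata(
                sample_id=str(sid), cultivar=str(row["cultivar"]),
                color=str(row["color"]), genetic_group=str(row["genetic_group"]),
                treatment=str(row["treatment"]), vintage=int(row["vintage"]),
                berry_weight=None if bw is None else float(bw),
                brix=None if opt("brix") is None else float(row["brix"]),
                delta13c=None if opt("delta13c") is None else float(row["delta13c"]),
                harvest_date=None if opt("harvest_date") is None else str(row["harvest_date"]),
            ))
        return cls(recs)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "MetadataSet":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class QuantTable:
    """Samples × compounds concentration matrix with a declared unit basis.

    ``values``: DataFrame indexed by sample id, columns = panel
    abbreviations in global-code order. ``censored``: boolean mask, True
    where the original value was below the LOQ (and is now LOQ/2).
    """

    values: pd.DataFrame
    unit_basis: UnitBasis
    panel: CompoundPanel
    censored: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.unit_basis = UnitBasis.coerce(self.unit_basis)
        order = [a for a in self.panel.abbreviations if a in self.values.columns]
        missing = [a for a in self.panel.abbreviations if a not in self.values.columns]
        if missing:
            raise ValueError(f"table missing panel compounds: {missing[:5]}"
                             + ("…" if len(missing) > 5 else ""))
        self.values = self.values[order].astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in quantification table")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite values in quantification table")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative concentrations in quantification table")
        if self.censored is None:
            self.censored = pd.DataFrame(False, index=self.values.index,
                                         columns=self.values.columns)
        else:
            self.censored = self.censored.reindex(index=self.values.index,
                                                  columns=self.values.columns).fillna(False).astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.unit_basis, self.panel,
                          self.censored.copy())


def read_quant_table(path: str | Path, panel: CompoundPanel,
                     unit_basis: UnitBasis | str, sep: str = ",") -> QuantTable:
    """Read a delimited samples × compounds table.

    Header row holds compound abbreviations matching the panel; first column
    holds sample ids. Unknown columns are dropped with a note on the returned
    table (attribute ``unknown_columns``); missing panel compounds are an
    error. The unit basis is declared by the caller, never inferred.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    known = set(panel.abbreviations)
    unknown = [c for c in df.columns if c not in known]
    missing = [a for a in panel.abbreviations if a not in df.columns]
    if missing:
        raise ValueError(f"input table is missing panel compound(s): {missing}")
    table = QuantTable(df.drop(columns=unknown), UnitBasis.coerce(unit_basis), panel)
    table.unknown_columns = unknown  # type: ignore[attr-defined]
    return table


def write_quant_table(table: QuantTable, path: str | Path, sep: str = ",",
                      mask_path: str | Path | None = None) -> None:
    """Write values (and optionally the censoring mask) as delimited text."""
    table.values.to_csv(path, sep=sep, index_label="sample_id")
    if mask_path is not None:
        table.censored.astype(int).to_csv(mask_path, sep=sep, index_label="sample_id")


def read_censoring_mask(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0).astype(bool)
    df.index.name = None
    return df


def impute_below_loq(table: QuantTable) -> QuantTable:
    """Replace values below the quantification threshold by LOQ/2.

    The comparison is strict (value < LOQ); values equal to the LOQ are
    kept. Imputation is idempotent: LOQ/2 < LOQ, so re-applying flags the
    same entries and rewrites the same value.
    """
    loqs = table.panel.loqs()
    loq_row = np.array([loqs[a] for a in table.values.columns])
    vals = table.values.to_numpy(copy=True)
    below = vals < loq_row[None, :]
    vals[below] = np.broadcast_to(loq_row[None, :] / 2.0, vals.shape)[below]
    values = pd.DataFrame(vals, index=table.values.index, columns=table.values.columns)
    censored = table.censored | pd.DataFrame(below, index=values.index,
                                             columns=values.columns)
    return QuantTable(values, table.unit_basis, table.panel, censored)


def convert_units(table: QuantTable, meta: MetadataSet,
                  target_basis: UnitBasis | str) -> QuantTable:
    """Convert between per-berry and per-gram bases using berry weight (g)."""
    target = UnitBasis.coerce(target_basis)
    if target == table.unit_basis:
        raise ValueError("table already on the requested unit basis")
    weights = []
    for sid in table.sample_ids:
        rec = meta[sid]
        if rec.berry_weight is None:
            raise ValueError(f"missing berry weight for sample {sid!r}")
        weights.append(rec.berry_weight)
    w = np.asarray(weights)[:, None]
    if target == UnitBasis.PER_GRAM:
        values = table.values / w
    else:
        values = table.values * w
    return QuantTable(values, target, table.panel, table.censored.copy())


@dataclass
class PairedCohort:
    """Cultivars with both IR and NI observations (and berry weights) in a vintage."""

    vintage: int
    cultivars: list[str]
    ir_samples: dict[str, str]  # cultivar -> sample id
    ni_samples: dict[str, str]
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (cultivar, reason)

    def __post_init__(self) -> None:
        for c in self.cultivars:
            if c not in self.ir_samples or c not in self.ni_samples:
                raise ValueError(f"cultivar {c!r} lacks a paired sample")

    def __len__(self) -> int:
        return len(self.cultivars)

    def sample_ids(self) -> list[str]:
        out = []
        for c in self.cultivars:
            out.extend([self.ir_samples[c], self.ni_samples[c]])
        return out

    def write_exclusion_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cultivar, reason in self.exclusions:
                fh.write(f"{cultivar}\t{reason}\n")


def select_paired_cohort(table: QuantTable, meta: MetadataSet,
                         vintage: int) -> PairedCohort:
    """Retain cultivars with both IR and NI samples and complete berry weights.

    Output is independent of input row order (cultivars are processed in
    sorted order). Every dropped cultivar is logged with a reason.
    """
    if vintage not in meta.vintages():
        raise ValueError(f"vintage {vintage} absent from metadata")
    present = set(table.sample_ids)
    retained, exclusions = [], []
    ir_samples: dict[str, str] = {}
    ni_samples: dict[str, str] = {}
    vintage_cultivars = sorted({r.cultivar for r in meta if r.vintage == vintage})
    for cultivar in vintage_cultivars:
        recs = {}
        for treatment in TREATMENTS:
            rec = meta.lookup(cultivar, treatment, vintage)
            if rec is not None and rec.sample_id in present:
                recs[treatment] = rec
        missing_trt = [t for t in TREATMENTS if t not in recs]
        if missing_trt:
            exclusions.append((cultivar, f"missing {' and '.join(missing_trt)} sample"))
            continue
        no_weight = [t for t in TREATMENTS if recs[t].berry_weight is None]
        if no_weight:
            exclusions.append((cultivar, "missing berry weight"))
            continue
        retained.append(cultivar)
        ir_samples[cultivar] = recs["IR"].sample_id
        ni_samples[cultivar] = recs["NI"].sample_id
    return PairedCohort(vintage=vintage, cultivars=retained,
                        ir_samples=ir_samples, ni_samples=ni_samples,
                        exclusions=exclusions)
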