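"""Synthetic grape-skin polyphenol cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-compound abundances are log-normal on the log10 scale around
realistic per-berry baselines (the published 2014 cohort means), with a
block correlation within each compound family, a global correlation floor
linking families, and a cultivar-level random effect shared across
treatments and vintages (which produces the high irrigated/not-irrigated
correlations seen in real data). White cultivars carry only trace levels
of anthocyanins and of B-ring trihydroxylated flavonols. Under the
non-irrigated (NI) regime, selected families are shifted by multiplicative
treatment effects scaled by the vintage stress intensity, berry weight
shrinks and δ13C rises. Values falling below the per-compound LOQ are
flagged as censored; imputation is left to the I/O layer so the pipeline's
censoring behaviour stays testable.

Randomness is fully reproducible: one seed in the configuration, with
per-cultivar and per-sample substreams derived deterministically so that
outputs are stable when the cultivar count changes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import MetadataSet, QuantTable, SampleMetadata, UnitBasis
from .panel import FAMILIES, CompoundPanel
from . import reference

#: families cycled through when planting >2 contrast patterns
_PLANT_FAMILIES = ("AN", "FO", "HC")


@dataclass
class VintageSpec:
    year: int
    stress_intensity: float  # σ ∈ [0, 1]: 0 = no water deficit under NI

    def __post_init__(self) -> None:
        if not 0.0 <= self.stress_intensity <= 1.0:
            raise ValueError("stress_intensity must be in [0, 1]")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 279 cultivars from three
    genetic pools, two vintages (a marked water contrast in 2014, a very
    limited one in 2015), per-berry baselines from the published 2014
    cohort means, and NI treatment effects matching the observed family
    level NI/IR ratios of the stressed vintage.
    """

    n_cultivars: int = 279
    fraction_white: float = 0.35
    genetic_group_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    vintages: list[VintageSpec] = field(default_factory=lambda: [
        VintageSpec(2014, 1.0), VintageSpec(2015, 0.1)])
    #: per-compound log10 mean abundance (μg/berry); None → published means
    baseline_log_mean: dict[str, float] | None = None
    #: marginal between-sample log10 sd, single value or per compound
    baseline_log_sd: float | dict[str, float] = 0.3
    #: within-family correlation of log abundances, per family code
    family_block_correlation: dict[str, float] = field(
        default_factory=lambda: {fam: 0.6 for fam in FAMILIES})
    #: correlation between compounds of different families
    global_correlation_floor: float = 0.1
    #: fraction of log variance carried by the cultivar random effect
    #: (shared across treatments and vintages)
    cultivar_effect_share: float = 0.7
    #: multiplicative effect on the mean under NI relative to IR at σ=1,
    #: keyed by family code or compound abbreviation (scaled as factor**σ)
    treatment_effects: dict[str, float] = field(default_factory=lambda: {
        "FA": 0.88, "HC": 0.88, "ST": 0.96, "FO": 0.98})
    #: per-group overrides planted by :func:`plant_response_groups`
    group_treatment_effects: list[dict[str, float]] | None = None
    #: scale factor for anthocyanins and trihydroxylated flavonols in whites
    white_trace_factor: float = 1e-3
    berry_weight_mean_g: float = 2.67
    berry_weight_sd_g: float = 0.55
    #: fractional berry-weight loss under NI at σ=1
    stress_shrinkage: float = 0.28
    delta13c_baseline: float = -25.4
    #: δ13C increase (‰) under NI at σ=1
    delta13c_stress_shift: float = 1.6
    delta13c_sd: float = 0.8
    brix_mean: float = 20.0
    brix_sd: float = 0.4
    #: mean harvest day-of-year and between-cultivar spread
    harvest_doy_mean: float = 255.0
    harvest_doy_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultivars < 1:
            raise ValueError("n_cultivars must be >= 1")
        if not 0.0 <= self.fraction_white <= 1.0:
            raise ValueError("fraction_white must be in [0, 1]")
        if abs(sum(self.genetic_group_probs) - 1.0) > 1e-9:
            raise ValueError("genetic_group_probs must sum to 1")
        sds = (self.baseline_log_sd.values()
               if isinstance(self.baseline_log_sd, dict) else [self.baseline_log_sd])
        if any(s < 0 for s in sds):
            raise ValueError("log sds must be >= 0")
        for fam, rho in self.family_block_correlation.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"family correlation for {fam} must be in [0, 1]")
            if rho < self.global_correlation_floor:
                raise ValueError("family correlation below the global floor")
        if not 0.0 <= self.global_correlation_floor <= 1.0:
            raise ValueError("global_correlation_floor must be in [0, 1]")
        if not 0.0 <= self.cultivar_effect_share <= 1.0:
            raise ValueError("cultivar_effect_share must be in [0, 1]")
        for key, eff in self.treatment_effects.items():
            if eff <= 0:
                raise ValueError(f"treatment effect for {key} must be > 0")
        if self.group_treatment_effects is not None:
            for dct in self.group_treatment_effects:
                if any(e <= 0 for e in dct.values()):
                    raise ValueError("planted group effects must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    #: variables × groups true NI/IR multiplicative effect at σ=1
    effects: pd.DataFrame
    #: cultivar → planted response-group label (1-based)
    group_labels: dict[str, int]
    #: per-sample uncensored values (same shape/basis as the emitted table)
    uncensored: pd.DataFrame


def _resolve_effects(panel: CompoundPanel, base: dict[str, float],
                     override: dict[str, float] | None) -> np.ndarray:
    """Per-compound NI/IR effect at σ=1, from family- or compound-level keys."""
    merged = dict(base)
    if override:
        merged.update(override)
    eff = np.ones(len(panel))
    for key, value in merged.items():
        fam = key[2:] if key.startswith("s_") else key
        if key in panel:
            eff[panel.abbreviations.index(key)] = value
        elif fam in FAMILIES:
            for i, e in enumerate(panel.entries):
                if e.family == fam:
                    eff[i] = value
        else:
            raise ValueError(f"treatment effect key {key!r} matches neither a "
                             "compound abbreviation nor a family code")
    return eff


def _block_normal(rng: np.random.Generator, fam_idx: np.ndarray,
                  n_fam: int, rho: np.ndarray, floor: np.ndarray | float
                  ) -> np.ndarray:
    """Standard normals with within-family correlation rho and a global floor.

    z_i = a·g + b_i·f_fam(i) + c_i·ε_i with a² = floor, b² = ρ_fam − floor,
    c² = 1 − ρ_fam, so corr within a family is ρ_fam, across families the
    floor, and each marginal is N(0, 1).
    """
    g = rng.normal()
    f = rng.normal(size=n_fam)
    eps = rng.normal(size=fam_idx.size)
    a = np.sqrt(floor)
    b = np.sqrt(np.maximum(rho - floor, 0.0))
    c = np.sqrt(np.maximum(1.0 - rho, 0.0))
    return a * g + b * f[fam_idx] + c * eps


def _split_correlation(rho_total: np.ndarray, share: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Split a target correlation between the cultivar and sample levels.

    Family co-regulation is a genetic (cultivar-level) property, so the
    block correlation is carried by the cultivar effect as far as its
    variance share allows; only the remainder spills into the per-sample
    residual. The total within-family correlation of log abundances stays
    share·ρ_cult + (1−share)·ρ_sample = ρ_total.
    """
    rho_total = np.asarray(rho_total, dtype=float)
    if share >= 1.0:
        return rho_total, np.zeros_like(rho_total)
    if share <= 0.0:
        return np.zeros_like(rho_total), rho_total
    rho_cult = np.minimum(1.0, rho_total / share)
    rho_samp = (rho_total - share * rho_cult) / (1.0 - share)
    return rho_cult, np.clip(rho_samp, 0.0, 1.0)


def plant_response_groups(config: SimConfig, k_groups: int,
                          amplitude: float = 2.0) -> SimConfig:
    """Plant contrasting drought-response cultivar groups.

    With two groups the planted contrast mirrors the archetypal opposite
    responses: group 1 has stilbenes down / tannins up under NI (i.e.
    stilbenes up and tannins down under irrigation), group 2 the reverse.
    Additional groups flip further family signs. *amplitude* is the planted
    NI/IR fold change (2.0 ⇒ a two-fold contrast between groups at σ=1).

    ``k_groups=1`` leaves the configuration unchanged apart from uniform
    labels.
    """
    if k_groups < 1:
        raise ValueError("k_groups must be >= 1")
    if k_groups > config.n_cultivars:
        raise ValueError("more planted groups than cultivars")
    if k_groups == 1:
        return dataclasses.replace(config, group_treatment_effects=[{}])
    groups = []
    for g in range(k_groups):
        up = amplitude
        down = 1.0 / amplitude
        eff = {"ST": down, "FA": up} if g % 2 == 0 else {"ST": up, "FA": down}
        for j, fam in enumerate(_PLANT_FAMILIES):
            if (g >> (1 + j)) & 1:
                eff[fam] = down if g % 2 == 0 else up
        groups.append(eff)
    return dataclasses.replace(config, group_treatment_effects=groups)


def generate_cohort(config: SimConfig, panel: CompoundPanel | None = None
                    ) -> tuple[QuantTable, MetadataSet, GroundTruth]:
    """Draw a synthetic cohort: quantification table (μg/berry, censoring
    flagged but not imputed), sample metadata, and the planted ground truth.
    """
    panel = panel or CompoundPanel.builtin()
    abbrs = panel.abbreviations
    n_comp = len(abbrs)

    if config.baseline_log_mean is None:
        means = reference.cohort_means_2014()["ni_ug_per_berry"]
        log_mean = np.log10(means.reindex(abbrs).to_numpy())
    else:
        log_mean = np.array([config.baseline_log_mean[a] for a in abbrs])
    if isinstance(config.baseline_log_sd, dict):
        log_sd = np.array([config.baseline_log_sd[a] for a in abbrs])
    else:
        log_sd = np.full(n_comp, float(config.baseline_log_sd))

    fam_list = sorted({e.family for e in panel.entries})
    fam_of = {f: i for i, f in enumerate(fam_list)}
    fam_idx = np.array([fam_of[e.family] for e in panel.entries])
    rho = np.array([config.family_block_correlation.get(e.family, 0.6)
                    for e in panel.entries])
    share = config.cultivar_effect_share
    rho_cult, rho_samp = _split_correlation(rho, share)
    floor_cult, floor_samp = _split_correlation(
        np.full(1, config.global_correlation_floor), share)
    floor_cult, floor_samp = float(floor_cult[0]), float(floor_samp[0])

    # compounds scaled to trace level in white cultivars: all anthocyanins
    # plus the B-ring trihydroxylated flavonols (red-cultivar markers)
    white_trace = np.array([
        e.family == "AN" or (e.family == "FO" and e.b_ring_oh == 3)
        for e in panel.entries])

    k_groups = (len(config.group_treatment_effects)
                if config.group_treatment_effects else 1)
    group_eff = {}
    for g in range(k_groups):
        override = (config.group_treatment_effects[g]
                    if config.group_treatment_effects else None)
        group_eff[g] = _resolve_effects(panel, config.treatment_effects, override)

    loq = np.array([panel[a].loq for a in abbrs])

    rows, row_ids, meta_records = [], [], []
    group_labels: dict[str, int] = {}
    n_digits = len(str(config.n_cultivars))
    for ci in range(config.n_cultivars):
        crng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(ci,)))
        cultivar = f"cv{ci + 1:0{n_digits}d}"
        group = ci % k_groups
        group_labels[cultivar] = group + 1
        white = crng.random() < config.fraction_white
        color = "white" if white else \
            str(crng.choice(["black", "red", "pink"], p=[0.7, 0.2, 0.1]))
        genetic_group = str(crng.choice(["WW", "WE", "TE"],
                                        p=list(config.genetic_group_probs)))
        z_cult = _block_normal(crng, fam_idx, len(fam_list), rho_cult, floor_cult)
        base_weight = max(0.3, crng.normal(config.berry_weight_mean_g,
                                           config.berry_weight_sd_g))
        doy = crng.normal(config.harvest_doy_mean, config.harvest_doy_sd)

        base_log = log_mean.copy()
        if white:
            base_log = base_log + np.where(white_trace,
                                           np.log10(config.white_trace_factor), 0.0)

        for vi, vintage in enumerate(config.vintages):
            sigma = vintage.stress_intensity
            for ti, treatment in enumerate(("IR", "NI")):
                srng = np.random.default_rng(np.random.SeedSequence(
                    config.seed, spawn_key=(ci, vi + 1, ti + 1)))
                z_s = _block_normal(srng, fam_idx, len(fam_list), rho_samp,
                                    floor_samp)
                z = np.sqrt(share) * z_cult + np.sqrt(1.0 - share) * z_s
                logv = base_log + log_sd * z
                if treatment == "NI":
                    logv = logv + sigma * np.log10(group_eff[group])
                values = 10.0 ** logv
                rows.append(values)
                sid = f"{cultivar}-{vintage.year}-{treatment}"
                row_ids.append(sid)

                weight = base_weight * float(np.exp(srng.normal(0.0, 0.05)))
                if treatment == "NI":
                    weight *= max(1e-3, 1.0 - config.stress_shrinkage * sigma)
                d13c = config.delta13c_baseline + srng.normal(0.0, config.delta13c_sd)
                if treatment == "NI":
                    d13c += config.delta13c_stress_shift * sigma
                brix = srng.normal(config.brix_mean, config.brix_sd)
                sample_doy = int(round(doy + srng.normal(0.0, 3.0)))
                sample_doy = min(max(sample_doy, 1), 365)
                date = (pd.Timestamp(f"{vintage.year}-01-01")
                        + pd.Timedelta(days=sample_doy - 1))
                meta_records.append(SampleMetadata(
                    sample_id=sid, cultivar=cultivar, color=color,
                    genetic_group=genetic_group, treatment=treatment,
                    vintage=vintage.year, berry_weight=round(weight, 4),
                    brix=round(float(brix), 2), delta13c=round(float(d13c), 3),
                    harvest_date=date.date().isoformat()))

    values = pd.DataFrame(np.vstack(rows), index=row_ids, columns=abbrs)
    censored = values.lt(loq, axis=1)
    table = QuantTable(values.copy(), UnitBasis.PER_BERRY, panel, censored)
    effects = pd.DataFrame({f"group{g + 1}": group_eff[g] for g in range(k_groups)},
                           index=abbrs)
    truth = GroundTruth(effects=effects, group_labels=group_labels,
                        uncensored=values)
    return table, MetadataSet(meta_records), truth
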