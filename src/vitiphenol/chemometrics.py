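"""Univariate screening and multivariate overview statistics.

One-way fixed-effects ANOVA of the irrigation contrast with
Student-Newman-Keuls (SNK) letter grouping at α = 0.05; Pearson stability
correlations between irrigation regimes and vintages; PCA of the
composition matrix; and chi-square enrichment of categorical traits in
cultivar subgroups against whole-population proportions.
"""
from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PairedCohort


# --------------------------------------------------------------------------
# one-way ANOVA + SNK
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    variable: str
    groups: list[str]
    means: dict[str, float]
    n: dict[str, int]
    f_statistic: float
    p_value: float
    snk_groups: dict[str, str]  # group -> letter(s) at α = 0.05
    zero_variance: bool = False


def _snk_letters(labels: Sequence[str], means: np.ndarray, ns: np.ndarray,
                 mse: float, df_error: int, alpha: float = 0.05) -> dict[str, str]:
    """Student-Newman-Keuls homogeneous-subset letters.

    Means are sorted; ranges are tested stepwise against the studentized
    range at span-dependent critical values; a non-significant range is
    declared homogeneous without testing its sub-ranges (the SNK
    protection rule). Unequal group sizes use the two-group harmonic mean.
    """
    order = np.argsort(means)
    m = means[order]
    n = ns[order]
    labs = [labels[i] for i in order]
    k = len(labs)
    runs: list[tuple[int, int]] = []

    def homogeneous(i: int, j: int) -> bool:
        span = j - i + 1
        nh = 2.0 / (1.0 / n[i] + 1.0 / n[j])
        se = np.sqrt(mse / nh)
        if se == 0:
            return m[j] == m[i]
        q = (m[j] - m[i]) / se
        crit = stats.studentized_range.ppf(1.0 - alpha, span, df_error)
        return bool(q <= crit)

    def mark(i: int, j: int) -> None:
        if i >= j:
            runs.append((i, j))
            return
        if homogeneous(i, j):
            runs.append((i, j))
            return
        mark(i, j - 1)
        mark(i + 1, j)

    mark(0, k - 1)
    # keep maximal runs only, in left-to-right order
    runs = sorted(set(runs))
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters: dict[str, str] = {lab: "" for lab in labs}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(maximal):
        for idx in range(i, j + 1):
            letters[labs[idx]] += alphabet[li % len(alphabet)]
    return letters


def one_way_anova(groups: Mapping[str, Sequence[float]],
                  variable: str = "", alpha: float = 0.05) -> AnovaResult:
    """Fixed-effects one-way ANOVA with SNK grouping.

    With two groups the F statistic equals the square of the pooled
    two-sample t statistic, and the SNK letters are distinct exactly when
    p < α. Zero total variance returns F = 0, p = 1, flagged.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    n_tot = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(labels) - 1
    df_w = n_tot - len(labels)
    if ss_between + ss_within == 0.0:
        letters = {lab: "a" for lab in labels}
        return AnovaResult(variable, labels, dict(zip(labels, means)),
                           dict(zip(labels, ns.tolist())), 0.0, 1.0,
                           letters, zero_variance=True)
    mse = ss_within / df_w
    if mse == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    letters = _snk_letters(labels, means, ns, mse, df_w, alpha)
    return AnovaResult(variable, labels, dict(zip(labels, means)),
                       dict(zip(labels, ns.tolist())), float(f), p, letters)


def irrigation_anova(values: pd.Series, cohort: PairedCohort,
                     variable: str = "", alpha: float = 0.05) -> AnovaResult:
    """IR vs NI one-way ANOVA across the cohort's cultivars.

    *values* is indexed by sample id. The test is unpaired across
    cultivars, matching the published screening design, even though the
    samples are cultivar-matched; see :func:`paired_t` for the paired
    alternative.
    """
    ir = values.loc[[cohort.ir_samples[c] for c in cohort.cultivars]]
    ni = values.loc[[cohort.ni_samples[c] for c in cohort.cultivars]]
    return one_way_anova({"IR": ir.to_numpy(), "NI": ni.to_numpy()},
                         variable=variable, alpha=alpha)


def paired_t(values: pd.Series, cohort: PairedCohort) -> tuple[float, float]:
    """Paired IR-vs-NI t test across cultivars (off by default in screening)."""
    ir = values.loc[[cohort.ir_samples[c] for c in cohort.cultivars]].to_numpy()
    ni = values.loc[[cohort.ni_samples[c] for c in cohort.cultivars]].to_numpy()
    t, p = stats.ttest_rel(ir, ni)
    return float(t), float(p)


def screen_variables(matrix: pd.DataFrame, cohort: PairedCohort,
                     alpha: float = 0.05) -> pd.DataFrame:
    """One ANOVA per column of *matrix* (samples × variables), tidy output."""
    rows = []
    for var in matrix.columns:
        col = matrix[var].dropna()
        have = set(col.index)
        cultivars = [c for c in cohort.cultivars
                     if cohort.ir_samples[c] in have and cohort.ni_samples[c] in have]
        if len(cultivars) < 2:
            continue
        sub = PairedCohort(cohort.vintage, cultivars,
                           {c: cohort.ir_samples[c] for c in cultivars},
                           {c: cohort.ni_samples[c] for c in cultivars})
        res = irrigation_anova(col, sub, variable=var, alpha=alpha)
        rows.append({"variable": var, "mean_IR": res.means["IR"],
                     "mean_NI": res.means["NI"], "n": res.n["IR"] + res.n["NI"],
                     "F": res.f_statistic, "p": res.p_value,
                     "snk_IR": res.snk_groups["IR"], "snk_NI": res.snk_groups["NI"],
                     "significant": res.p_value < alpha})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stability correlations
# --------------------------------------------------------------------------

def stability_correlations(values: Mapping[tuple[str, int], pd.Series],
                           colored: Mapping[str, bool] | None = None,
                           colored_only: bool = False) -> pd.DataFrame:
    """Pearson correlations across irrigation regimes and vintages.

    *values* maps (treatment, vintage) — with both "IR" and "NI" in two
    vintages — to cultivar-indexed vectors of one variable. Four pairings
    are computed: within-vintage IR/NI for each vintage, and
    between-vintage under IR and under NI. Each pairing uses the cultivars
    present in both members; ``colored_only`` restricts to black/red/pink
    cultivars (anthocyanin variables are meaningless in whites).
    """
    vintages = sorted({v for (_, v) in values})
    if len(vintages) != 2:
        raise ValueError("exactly two vintages are required")
    y1, y2 = vintages
    pairings = [
        (f"{y1} I/NI", ("IR", y1), ("NI", y1)),
        (f"{y2} I/NI", ("IR", y2), ("NI", y2)),
        (f"I {y1}/{y2}", ("IR", y1), ("IR", y2)),
        (f"NI {y1}/{y2}", ("NI", y1), ("NI", y2)),
    ]
    rows = []
    for name, ka, kb in pairings:
        a, b = values[ka], values[kb]
        common = a.index.intersection(b.index)
        if colored_only:
            if colored is None:
                raise ValueError("colored_only requires a cultivar color map")
            common = pd.Index([c for c in common if colored[c]])
        x = a.loc[common].to_numpy(dtype=float)
        y = b.loc[common].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"fewer than 3 common cultivars for pairing {name}")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance vector in pairing {name}")
        r = float(stats.pearsonr(x, y).statistic)
        rows.append({"pairing": name, "r": r, "n": int(x.size)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples × components
    loadings: pd.DataFrame     # variables × components
    variance_explained: np.ndarray  # fraction per component, full rank sums to 1
    center: bool
    scale: bool
    mean: pd.Series
    std: pd.Series
    dropped: list[str] = field(default_factory=list)

    def reconstruct(self) -> pd.DataFrame:
        """Back-project scores through the loadings, undoing preprocessing."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        if self.scale:
            x = x * self.std.to_numpy()[None, :]
        if self.center:
            x = x + self.mean.to_numpy()[None, :]
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def run_pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True,
            n_components: int | None = None) -> PcaResult:
    """PCA by SVD of the (centered, optionally unit-variance) data.

    Equivalent to eigendecomposition of the covariance matrix (correlation
    matrix when ``scale``). Loadings columns are orthonormal, signed so the
    largest-magnitude loading of each component is positive. Constant
    columns are dropped with a warning when scaling. Scaling to unit
    variance is the default because composition variables span four orders
    of magnitude.
    """
    if matrix.isna().any().any():
        raise ValueError("PCA input contains missing values")
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.astype(float)
    dropped: list[str] = []
    std = x.std(axis=0, ddof=1)
    if scale:
        dropped = list(std.index[std == 0.0])
        if dropped:
            warnings.warn(f"dropping constant column(s) for scaled PCA: {dropped}")
            x = x.drop(columns=dropped)
            std = std.drop(index=dropped)
    mean = x.mean(axis=0)
    xp = x - mean if center else x.copy()
    if scale:
        xp = xp / std
    u, s, vt = np.linalg.svd(xp.to_numpy(), full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    k = len(s) if n_components is None else min(n_components, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=x.index, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=x.columns, columns=comps)
    return PcaResult(scores, loadings, frac[:k], center, scale,
                     mean, std if scale else x.std(axis=0, ddof=1), dropped)


# --------------------------------------------------------------------------
# chi-square subgroup enrichment
# --------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    subgroup: str
    trait: str
    categories: list[str]
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p_value: float
    significant_010: bool
    significant_005: bool


def chi2_enrichment(subgroups: Mapping[str, str], trait: Mapping[str, str],
                    trait_name: str = "trait") -> list[EnrichmentResult]:
    """Goodness-of-fit chi-square of each subgroup against the population.

    For every subgroup, the observed category counts are compared with the
    counts expected from whole-population category proportions (no
    continuity correction). Expected counts below 5 trigger a warning, not
    an error. Results are flagged at both p < 0.1 and p < 0.05.
    """
    cultivars = list(subgroups)
    missing = [c for c in cultivars if c not in trait]
    if missing:
        raise ValueError(f"no trait category for cultivar(s) {missing[:5]}")
    categories = sorted({trait[c] for c in cultivars})
    if len(categories) < 2:
        raise ValueError("trait has a single category (df = 0)")
    pop_counts = {cat: sum(trait[c] == cat for c in cultivars) for cat in categories}
    n_pop = len(cultivars)
    props = {cat: pop_counts[cat] / n_pop for cat in categories}

    results = []
    for sub in sorted(set(subgroups.values())):
        members = [c for c in cultivars if subgroups[c] == sub]
        if not members:
            raise ValueError(f"subgroup {sub!r} is empty")
        obs = {cat: sum(trait[c] == cat for c in members) for cat in categories}
        exp = {cat: props[cat] * len(members) for cat in categories}
        if any(e < 5 for e in exp.values()):
            warnings.warn(f"subgroup {sub!r}: expected count below 5; "
                          "chi-square approximation is rough")
        chi2 = sum((obs[c] - exp[c]) ** 2 / exp[c] for c in categories if exp[c] > 0)
        df = len(categories) - 1
        p = float(stats.chi2.sf(chi2, df))
        results.append(EnrichmentResult(
            subgroup=sub, trait=trait_name, categories=categories,
            observed=obs, expected=exp, chi2=float(chi2), df=df, p_value=p,
            significant_010=p < 0.1, significant_005=p < 0.05))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"subgroup": r.subgroup, "trait": r.trait, "chi2": r.chi2,
                     "df": r.df, "p": r.p_value, "sig_p0.10": r.significant_010,
                     "sig_p0.05": r.significant_005,
                     "observed": ";".join(f"{c}={r.observed[c]}" for c in r.categories),
                     "expected": ";".join(f"{c}={r.expected[c]:.2f}" for c in r.categories)})
    return pd.DataFrame(rows)


def harvest_week(date: str) -> str:
    """ISO week-of-year bin for harvest-date enrichment (e.g. ``"W37"``)."""
    d = _dt.date.fromisoformat(date)
    return f"W{d.isocalendar().week:02d}"
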