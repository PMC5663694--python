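"""Shared fixtures and helpers for the vitiphenol test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vitiphenol as vp
from vitiphenol.io_model import UnitBasis

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def panel():
    return vp.CompoundPanel.builtin()


@pytest.fixture(scope="session")
def small_sim():
    """A 24-cultivar two-vintage cohort used across read-only tests."""
    cfg = vp.SimConfig(n_cultivars=24, seed=7)
    return vp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_meta(small_sim):
    return small_sim[1]


@pytest.fixture(scope="session")
def imputed(small_table):
    return vp.impute_below_loq(small_table)


@pytest.fixture(scope="session")
def cohort2014(imputed, small_meta):
    return vp.select_paired_cohort(imputed, small_meta, 2014)


@pytest.fixture(scope="session")
def indices(imputed):
    return vp.compute_indices(imputed)


@pytest.fixture
def ones_table(panel):
    """All concentrations exactly 1 μg/berry: closed-form index values."""
    values = pd.DataFrame(1.0, index=["s1", "s2"], columns=panel.abbreviations)
    return vp.QuantTable(values, UnitBasis.PER_BERRY, panel)


def adjusted_rand_index(a: dict, b: dict) -> float:
    """ARI between two labelings given as item -> label mappings."""
    items = sorted(a)
    la = [a[i] for i in items]
    lb = [b[i] for i in items]
    ua, ub = sorted(set(la)), sorted(set(lb))
    n = len(items)
    table = np.zeros((len(ua), len(ub)))
    for x, y in zip(la, lb):
        table[ua.index(x), ub.index(y)] += 1

    def comb2(v):
        return v * (v - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))
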