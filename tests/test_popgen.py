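"""Diversity statistics: allele frequencies, MLH/SLH, HWE, F_IS, g2."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hetmig as hm
from hetmig.popgen import (
    allele_frequencies,
    fis,
    g2_identity_disequilibrium,
    heterozygosity_profile,
    hwe_exact_test,
)

from conftest import table_from_calls


# -- allele frequencies ------------------------------------------------------

def test_allele_frequency_counting():
    g = table_from_calls([("a", [("A", "A")]), ("b", [("A", "B")])], ["L1"])
    f = allele_frequencies(g)
    assert f.freqs["L1"] == {"A": 0.75, "B": 0.25}
    assert f.n_copies["L1"] == 4


def test_monomorphic_locus_frequency_one():
    g = table_from_calls([("a", [("A", "A")]), ("b", [("A", "A")])], ["L1"])
    assert allele_frequencies(g).freqs["L1"] == {"A": 1.0}


def test_frequencies_match_brute_force_tally(default_sim):
    _, table, _ = default_sim
    f = allele_frequencies(table)
    for j, locus in enumerate(table.locus_names):
        tally: dict = {}
        for i in range(table.n_individuals):
            for a in table.calls[i, j, :]:
                if a is not None:
                    tally[a] = tally.get(a, 0) + 1
        total = sum(tally.values())
        expected = {a: c / total for a, c in tally.items()}
        assert f.freqs[locus] == pytest.approx(expected)
        assert sum(f.freqs[locus].values()) == pytest.approx(1.0, abs=1e-12)


def test_entirely_missing_locus_errors():
    g = table_from_calls([("a", [("A", "A"), None]), ("b", [("A", "B"), None])], ["L1", "L2"])
    with pytest.raises(ValueError, match="L2"):
        allele_frequencies(g)


# -- heterozygosity ----------------------------------------------------------

def test_mlh_half_heterozygous_with_missing():
    genos = [("A", "B")] * 8 + [("A", "A")] * 8 + [None]
    g = table_from_calls([("x", genos), ("y", [("A", "B")] * 17)], [f"L{i}" for i in range(17)])
    prof = heterozygosity_profile(g)
    assert prof.mlh[0] == pytest.approx(0.5)
    assert prof.n_typed[0] == 16
    assert math.isnan(prof.slh.iloc[0, 16])


def test_fully_homozygous_individual():
    g = table_from_calls([("x", [("A", "A"), ("B", "B")]), ("y", [("A", "B"), ("B", "C")])],
                         ["L1", "L2"])
    prof = heterozygosity_profile(g)
    assert prof.mlh[0] == 0.0
    assert (prof.slh.iloc[0] == 0).all()


def test_untyped_individual_errors():
    g = table_from_calls([("x", [None]), ("y", [("A", "B")])], ["L1"])
    with pytest.raises(ValueError, match="x"):
        heterozygosity_profile(g)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_mlh_equals_mean_of_nonmissing_slh(seed):
    """MLH is exactly the mean of the non-missing SLH indicators."""
    cfg = hm.SimConfig(seed=seed, n_individuals=12, n_loci=6, missing_rate=0.2,
                       group_sizes=(3, 3, 3, 3))
    table, _ = hm.simulate_genotypes(cfg)
    try:
        prof = heterozygosity_profile(table)
    except ValueError:
        return  # an all-missing individual; precondition violated by chance
    slh = prof.slh.to_numpy()
    recount = np.nanmean(slh, axis=1)
    assert np.allclose(prof.mlh, recount, equal_nan=True)


def test_mlh_matches_truth_recount(default_sim):
    _, table, truth = default_sim
    prof = heterozygosity_profile(table)
    # where nothing is missing, observed SLH equals the simulator's truth
    typed = ~table.missing_mask()
    obs = prof.slh.to_numpy()
    tru = truth.het_true.to_numpy()
    assert np.array_equal(obs[typed], tru[typed])


# -- Hardy-Weinberg exact test ----------------------------------------------

def test_hwe_conformant_counts_large_p(hwe_table):
    p = hwe_exact_test(hwe_table, "L1", seed=0)
    assert p > 0.5


def test_hwe_enumeration_matches_closed_form():
    """AA=1, AB=0, BB=1: enumeration over the two arrays with nA=nB=2
    gives P(AB=2)=2/3, P(AA=1,BB=1)=1/3, so p = 1/3."""
    g = table_from_calls([("x", [("A", "A")]), ("y", [("B", "B")])], ["L1"])
    assert hwe_exact_test(g, "L1", seed=0) == pytest.approx(1 / 3)


def test_hwe_monte_carlo_agrees_with_enumeration(hwe_table):
    p_exact = hwe_exact_test(hwe_table, "L1", seed=0)
    n_mc = 4000
    p_mc = hwe_exact_test(hwe_table, "L1", n_mc=n_mc, seed=1, max_enumeration=1)
    se = math.sqrt(p_exact * (1 - p_exact) / n_mc)
    assert abs(p_mc - p_exact) < 3 * se + 2 / n_mc


def test_hwe_monomorphic_warns_p_one():
    g = table_from_calls([("x", [("A", "A")]), ("y", [("A", "A")])], ["L1"])
    with pytest.warns(UserWarning, match="monomorphic"):
        assert hwe_exact_test(g, "L1", seed=0) == 1.0


# -- F_IS --------------------------------------------------------------------

def test_fis_all_heterozygotes_is_minus_one():
    g = table_from_calls([(f"i{k}", [("A", "B")]) for k in range(20)], ["L1"])
    assert fis(g) == pytest.approx(-1.0)


def test_fis_near_zero_at_hwe_proportions(hwe_table):
    assert abs(fis(hwe_table)) < 0.02


def test_fis_monomorphic_errors():
    g = table_from_calls([("x", [("A", "A")]), ("y", [("A", "A")])], ["L1"])
    with pytest.raises(ValueError, match="monomorphic"):
        fis(g)


def test_fis_hwe_simulation_centred_on_zero():
    """Mean F_IS over replicate random-mating simulations is ~0."""
    rng = np.random.default_rng(99)
    vals = []
    for _ in range(100):
        n, freqs = 60, rng.dirichlet(np.ones(5))
        calls = np.empty((n, 1, 2), dtype=object)
        draws = rng.choice(5, size=(n, 2), p=freqs)
        for i in range(n):
            calls[i, 0, 0] = str(draws[i, 0])
            calls[i, 0, 1] = str(draws[i, 1])
        g = hm.GenotypeTable([f"i{i}" for i in range(n)], ["L1"], calls)
        try:
            vals.append(fis(g))
        except ValueError:
            continue  # monomorphic draw
    assert abs(np.mean(vals)) < 0.02


def test_fis_by_group_uses_group_labels(default_sim):
    _, table, _ = default_sim
    out = hm.fis_by_group(table)
    assert set(out) == {"NM", "NR", "RG", "SM"}
    for v in out.values():
        assert np.isfinite(v)


# -- g2 identity disequilibrium ---------------------------------------------

def test_g2_null_close_to_zero():
    """Random union of gametes from one pool: no inbreeding variance."""
    cfg = hm.SimConfig(seed=5, n_individuals=500, inbred_fraction=0.0,
                       group_sizes=(125, 125, 125, 125))
    table, _ = hm.simulate_genotypes(cfg)
    res = g2_identity_disequilibrium(table, n_permutations=300, seed=1)
    # permutation spread as the scale for "close to zero"
    assert abs(res.g2) < 0.005
    assert res.p_value > 0.01


def test_g2_detects_inbreeding_mixture():
    """Half the individuals from full-sib matings: var(f) > 0, g2 > 0."""
    cfg = hm.SimConfig(seed=6, n_individuals=500, inbred_fraction=0.5,
                       group_sizes=(125, 125, 125, 125))
    table, truth = hm.simulate_genotypes(cfg)
    # var(f) = 0.5 * 0.5 * 0.25^2 ~ 0.016 for the half-and-half mixture
    assert truth.individuals["f_true"].var() > 0.012
    res = g2_identity_disequilibrium(table, n_permutations=300, seed=2)
    assert res.g2 > 0
    assert res.p_value < 0.05


def test_g2_requires_polymorphism_and_sample():
    g = table_from_calls([(f"i{k}", [("A", "A"), ("A", "B")]) for k in range(12)],
                         ["L1", "L2"])
    with pytest.raises(ValueError, match="polymorphic"):
        g2_identity_disequilibrium(g, 10, seed=0)


def test_g2_deterministic_under_seed(default_sim):
    _, table, _ = default_sim
    a = g2_identity_disequilibrium(table, 50, seed=7)
    b = g2_identity_disequilibrium(table, 50, seed=7)
    assert a.g2 == b.g2 and a.p_value == b.p_value
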