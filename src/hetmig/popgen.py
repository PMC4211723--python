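"""Single-population diversity statistics for microsatellite panels.

Implements the per-individual heterozygosity measures used in
heterozygosity-fitness screens (multilocus heterozygosity, MLH, and the
per-locus 0/1 indicator, SLH), a Hardy-Weinberg exact test with
exhaustive enumeration or Monte-Carlo evaluation, the Weir & Cockerham
(1984) within-population inbreeding coefficient F_IS, and the David et
al. (2007) g2 estimator of identity disequilibrium with a permutation
test.

g2 measures the covariance of heterozygosity among loci.  A population
with no variance in inbreeding has g2 = 0; g2 > 0 indicates that
individual inbreeding levels vary, which is the condition under which an
MLH-fitness correlation can reflect inbreeding depression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "HeterozygosityProfile",
    "G2Result",
    "allele_frequencies",
    "heterozygosity_profile",
    "hwe_exact_test",
    "fis",
    "fis_by_group",
    "g2_identity_disequilibrium",
]


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequency maps plus the number of typed gene copies."""

    freqs: dict[str, dict[str, float]]
    n_copies: dict[str, int]

    def __post_init__(self) -> None:
        for locus, fmap in self.freqs.items():
            total = sum(fmap.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if any(p <= 0 for p in fmap.values()):
                raise ValueError(f"non-positive frequency at {locus}")


@dataclass
class HeterozygosityProfile:
    """Per-individual MLH and per-locus SLH indicators.

    ``slh`` is an (individuals x loci) frame of {0.0, 1.0, NaN}; ``mlh``
    is the mean of the non-missing SLH entries per individual.
    """

    individual_ids: list[str]
    mlh: np.ndarray
    slh: pd.DataFrame
    n_typed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.slh.copy()
        out.insert(0, "mlh", self.mlh)
        out.insert(1, "n_typed", self.n_typed)
        return out


@dataclass
class G2Result:
    g2: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.g2):
            raise ValueError("g2 is not finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")


# ---------------------------------------------------------------------------
# allele frequencies / heterozygosity
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeTable) -> AlleleFrequencies:
    """Allele frequencies per locus from all typed gene copies."""
    freqs: dict[str, dict[str, float]] = {}
    n_copies: dict[str, int] = {}
    for j, locus in enumerate(g.locus_names):
        col = g.calls[:, j, :].ravel()
        alleles = [a for a in col if a is not None]
        if not alleles:
            raise ValueError(f"locus {locus} is entirely missing")
        n = len(alleles)
        counts: dict[str, int] = {}
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
        freqs[locus] = {a: c / n for a, c in sorted(counts.items())}
        n_copies[locus] = n
    return AlleleFrequencies(freqs, n_copies)


def heterozygosity_profile(g: GenotypeTable) -> HeterozygosityProfile:
    """MLH and SLH per individual.

    MLH averages SLH over the individual's typed loci only; individuals
    typed at zero loci are an error.
    """
    a = g.calls[:, :, 0]
    b = g.calls[:, :, 1]
    typed = a != None  # noqa: E711
    slh = np.where(typed, (a != b).astype(float), np.nan)
    n_typed = typed.sum(axis=1)
    if np.any(n_typed == 0):
        bad = g.individual_ids[int(np.argmin(n_typed))]
        raise ValueError(f"individual {bad} has no typed loci")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mlh = np.nanmean(slh, axis=1)
    return HeterozygosityProfile(
        list(g.individual_ids),
        mlh,
        pd.DataFrame(slh, index=g.individual_ids, columns=g.locus_names),
        n_typed,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _log_levene(geno_counts: np.ndarray, allele_counts: np.ndarray) -> float:
    """Log conditional probability of a genotype-count array given allele counts.

    Levene (1949): P = n! * prod(n_a!) * 2^H / ((2n)! / ... * prod(n_ab!))
    with H the number of heterozygous genotypes.
    """
    n = int(geno_counts.sum())
    two_n = int(allele_counts.sum())
    k = len(allele_counts)
    het = 0
    log_prod_nab = 0.0
    idx = np.triu_indices(k)
    for a, b in zip(*idx):
        c = int(geno_counts[a, b])
        log_prod_nab += math.lgamma(c + 1)
        if a != b:
            het += c
    return (
        math.lgamma(n + 1)
        + sum(math.lgamma(int(c) + 1) for c in allele_counts)
        + het * math.log(2.0)
        - math.lgamma(two_n + 1)
        - log_prod_nab
    )


def _enumerate_arrays(allele_counts: np.ndarray, limit: int):
    """Yield all genotype-count arrays consistent with ``allele_counts``.

    Enumerates heterozygote counts n_ab (a < b) recursively; homozygote
    counts follow by parity.  Raises RuntimeError if more than ``limit``
    arrays would be produced.
    """
    k = len(allele_counts)
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    out: list[np.ndarray] = []

    def rec(p: int, remaining: np.ndarray, current: np.ndarray) -> None:
        if p == len(pairs):
            if np.all(remaining % 2 == 0):
                arr = current.copy()
                for a in range(k):
                    arr[a, a] = remaining[a] // 2
                out.append(arr)
                if len(out) > limit:
                    raise RuntimeError("enumeration limit exceeded")
            return
        a, b = pairs[p]
        # upper bound: cannot use more copies than remain of either allele
        for nab in range(min(remaining[a], remaining[b]) + 1):
            current[a, b] = nab
            remaining[a] -= nab
            remaining[b] -= nab
            rec(p + 1, remaining, current)
            remaining[a] += nab
            remaining[b] += nab
        current[a, b] = 0

    rec(0, allele_counts.copy(), np.zeros((k, k), dtype=int))
    return out


def _genotype_counts(g: GenotypeTable, locus: str) -> tuple[np.ndarray, np.ndarray]:
    codes, typed, alleles = g.encoded(locus)
    k = len(alleles)
    geno = np.zeros((k, k), dtype=int)
    for i in np.nonzero(typed)[0]:
        a, b = sorted(codes[i])
        geno[a, b] += 1
    allele_counts = np.zeros(k, dtype=int)
    for a in range(k):
        allele_counts[a] = 2 * geno[a, a] + geno[a, :].sum() + geno[:, a].sum() - 2 * geno[a, a]
    return geno, allele_counts


def hwe_exact_test(
    g: GenotypeTable,
    locus: str,
    n_mc: int = 10_000,
    seed: int = 0,
    max_enumeration: int = 100_000,
) -> float:
    """Exact test of Hardy-Weinberg proportions at one locus.

    Full enumeration of genotype arrays (conditional on allele counts,
    Levene distribution) when the array count is below
    ``max_enumeration``; otherwise a Monte-Carlo test that shuffles gene
    copies.  The p-value sums the probability of arrays no more probable
    than the observed one.
    """
    geno, allele_counts = _genotype_counts(g, locus)
    n_typed = int(geno.sum())
    if n_typed < 2:
        raise ValueError(f"fewer than 2 typed individuals at locus {locus}")
    if len(allele_counts) < 2:
        warnings.warn(f"locus {locus} is monomorphic; HWE p-value set to 1")
        return 1.0
    log_obs = _log_levene(geno, allele_counts)
    tol = 1e-9

    # upper bound on the number of arrays: product over allele pairs of the
    # possible heterozygote counts; skip enumeration when clearly too large
    k = len(allele_counts)
    bound = 1.0
    for a in range(k):
        for b in range(a + 1, k):
            bound *= min(allele_counts[a], allele_counts[b]) + 1
            if bound > max_enumeration:
                break
        if bound > max_enumeration:
            break
    arrays = None
    if bound <= max_enumeration:
        try:
            arrays = _enumerate_arrays(allele_counts, max_enumeration)
        except RuntimeError:
            arrays = None

    if arrays is not None:
        logps = np.array([_log_levene(a, allele_counts) for a in arrays])
        p = float(np.exp(logps[logps <= log_obs + tol]).sum() / np.exp(logps).sum())
        return min(p, 1.0)

    # Monte-Carlo: permute the multiset of gene copies into genotypes
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(len(allele_counts)), allele_counts)
    k = len(allele_counts)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(copies)
        pairs = copies.reshape(-1, 2)
        arr = np.zeros((k, k), dtype=int)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        np.add.at(arr, (lo, hi), 1)
        if _log_levene(arr, allele_counts) <= log_obs + tol:
            hits += 1
    return (1 + hits) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_IS
# ---------------------------------------------------------------------------

def fis(g: GenotypeTable, group: Optional[str] = None) -> float:
    """Weir & Cockerham (1984) multilocus within-population f.

    Variance components are summed over alleles and loci before the
    final ratio (ratio-of-sums).  Negative values indicate an excess of
    heterozygotes relative to Hardy-Weinberg expectation.
    """
    if group is not None:
        sub = g.subset(g.groups()[group])
    else:
        sub = g
    sum_b = 0.0
    sum_c = 0.0
    any_poly = False
    for locus in sub.locus_names:
        codes, typed, alleles = sub.encoded(locus)
        n = int(typed.sum())
        if n < 2 or len(alleles) < 2:
            continue
        any_poly = True
        cod = codes[typed]
        for a in range(len(alleles)):
            p = float((cod == a).sum()) / (2 * n)
            hbar = float(((cod[:, 0] == a) ^ (cod[:, 1] == a)).mean())
            b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * hbar)
            c = hbar / 2.0
            sum_b += b
            sum_c += c
    if not any_poly:
        raise ValueError("all loci monomorphic (or <2 typed) in the requested group")
    denom = sum_b + sum_c
    if denom == 0:
        raise ValueError("undefined F_IS: zero variance components")
    return float(1.0 - sum_c / denom)


def fis_by_group(g: GenotypeTable) -> dict[str, float]:
    """F_IS for every group label in the table."""
    return {grp: fis(g, grp) for grp in sorted(set(g.group or []))}


# ---------------------------------------------------------------------------
# g2 identity disequilibrium
# ---------------------------------------------------------------------------

def _g2_from_het(h: np.ndarray, typed: np.ndarray) -> float:
    """David et al. (2007) multilocus g2 from a 0/1 het matrix with missingness.

    Pools numerators (same-individual cross-locus products) and
    denominators (cross-individual products) over all locus pairs before
    the final ratio.
    """
    h0 = np.where(typed, h, 0.0)
    t = typed.astype(float)
    n_kl = t.T @ t                      # typed at both loci, same individual
    x = h0.T @ h0                       # sum_i h_ik h_il
    hs = h0.sum(axis=0)
    n_l = t.sum(axis=0)
    cross_pairs = np.outer(n_l, n_l) - n_kl   # (i, j) i != j both typed
    off = ~np.eye(h.shape[1], dtype=bool)
    valid = off & (n_kl > 0) & (cross_pairs > 0)
    num = (x[valid] / n_kl[valid]).sum()
    den = ((np.outer(hs, hs) - x)[valid] / cross_pairs[valid]).sum()
    if den == 0:
        return 0.0
    return float(num / den - 1.0)


def g2_identity_disequilibrium(
    g: GenotypeTable, n_permutations: int = 1000, seed: int = 0
) -> G2Result:
    """g2 with a permutation p-value.

    The null distribution permutes each locus's SLH column independently
    across individuals, destroying among-locus covariance while keeping
    per-locus heterozygosity and missingness;
    p = (1 + #{g2_perm >= g2_obs}) / (n_permutations + 1).
    """
    prof = heterozygosity_profile(g)
    slh = prof.slh.to_numpy()
    typed = ~np.isnan(slh)
    poly = np.array([np.nanstd(slh[:, j]) > 0 for j in range(slh.shape[1])])
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for g2")
    if g.n_individuals < 10:
        raise ValueError("need at least 10 individuals for g2")
    h = np.nan_to_num(slh, nan=0.0)
    obs = _g2_from_het(h, typed)
    rng = np.random.default_rng(seed)
    n, L = slh.shape
    hits = 0
    for _ in range(n_permutations):
        hp = np.empty_like(slh)
        for j in range(L):
            hp[:, j] = slh[rng.permutation(n), j]
        tp = ~np.isnan(hp)
        if _g2_from_het(np.nan_to_num(hp, nan=0.0), tp) >= obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return G2Result(g2=obs, p_value=p, n_permutations=n_permutations, seed=seed)
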