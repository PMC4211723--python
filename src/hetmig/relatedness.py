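"""Pairwise Queller-Goodnight (1989) relatedness.

The estimator compares allele sharing between two individuals with the
sharing expected from population allele frequencies.  Per dyad and
locus, with focal genotype (a, b) and partner genotype (c, d):

    numerator   = 0.5 * (d_ac + d_ad + d_bc + d_bd) - p_a - p_b
    denominator = 1 + d_ab - p_a - p_b

where d_xy is the Kronecker delta and p the reference frequency.
Numerators and denominators are summed over loci before dividing
(ratio-of-sums, the multilocus convention of the standard relatedness
software), and the two directed estimates of a dyad are averaged.
Expectation is ~0.5 for parent-offspring, ~0.25 for half sibs and ~0
for unrelated pairs drawn from the reference population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotypes import GenotypeTable
from .matrices import PairwiseMatrix
from .popgen import AlleleFrequencies, allele_frequencies

__all__ = ["RelatednessMatrix", "queller_goodnight"]

#: Dyads sharing fewer typed loci than this are flagged (not dropped).
MIN_SHARED_LOCI = 5


@dataclass
class RelatednessMatrix:
    """Square symmetric QG coefficients; diagonal is not applicable (NaN)."""

    ids: list[str]
    values: np.ndarray
    low_overlap_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix shape mismatch")
        if not np.array_equal(
            np.nan_to_num(self.values, nan=np.inf),
            np.nan_to_num(self.values.T, nan=np.inf),
        ):
            raise ValueError("relatedness matrix not exactly symmetric")

    def as_pairwise(self) -> PairwiseMatrix:
        return PairwiseMatrix(self.ids, self.values, kind="similarity", units="unitless")

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals))


def queller_goodnight(
    g: GenotypeTable, freqs: Optional[AlleleFrequencies] = None
) -> RelatednessMatrix:
    """QG relatedness matrix over all dyads in ``g``.

    Reference allele frequencies default to the full sample (the focal
    dyad is not excluded).  Dyads sharing no typed locus get NaN.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if freqs is None:
        freqs = allele_frequencies(g)
    n = g.n_individuals
    num = np.zeros((n, n))   # directed: row = focal
    den = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    any_poly = False
    for j, locus in enumerate(g.locus_names):
        codes, typed, alleles = g.encoded(locus)
        if len(alleles) < 2:
            if len(alleles) == 1:
                # monomorphic locus: numerator and denominator are both 0
                shared += np.outer(typed, typed)
            continue
        any_poly = True
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        a1, a2 = codes[:, 0], codes[:, 1]
        # pairwise allele sharing S_xy = 0.5 * sum of the four deltas
        s = 0.5 * (
            (a1[:, None] == a1[None, :]).astype(float)
            + (a1[:, None] == a2[None, :])
            + (a2[:, None] == a1[None, :])
            + (a2[:, None] == a2[None, :])
        )
        pa = np.where(typed, p[np.where(typed, a1, 0)] + p[np.where(typed, a2, 0)], 0.0)
        num_l = s - pa[:, None]
        den_l = (1.0 + (a1 == a2) - pa)[:, None] * np.ones((1, n))
        ok = np.outer(typed, typed)
        num += np.where(ok, num_l, 0.0)
        den += np.where(ok, den_l, 0.0)
        shared += ok
    if not any_poly:
        raise ValueError("all loci monomorphic; QG undefined")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        directed = np.where(den != 0, num / np.where(den == 0, 1.0, den), np.nan)
        r = (directed + directed.T) / 2.0
    r[shared == 0] = np.nan
    np.fill_diagonal(r, np.nan)
    # exact symmetry despite float rounding
    iu = np.triu_indices(n, k=1)
    r[(iu[1], iu[0])] = r[iu]

    ids = list(g.individual_ids)
    low = [
        (ids[i], ids[k])
        for i, k in zip(*iu)
        if 0 < shared[i, k] < MIN_SHARED_LOCI
    ]
    return RelatednessMatrix(ids, r, low)
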