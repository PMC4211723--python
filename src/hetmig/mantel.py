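"""Mantel and partial Mantel tests with permutation p-values and
id-level bootstrap confidence limits.

The Mantel statistic is the Pearson correlation over the n(n-1)/2
off-diagonal upper-triangle pairs of two aligned square matrices.  The
null distribution jointly permutes rows and columns of one matrix
(permuting sample units, not cells).  Confidence limits resample the
ids with replacement and recompute r on the induced submatrix; pairs
formed by two copies of the same original id are excluded, as are
masked (NaN) dyads.

The partial Mantel statistic (Smouse-Long-Sokal) correlates the
element-wise residuals of a ~ c and b ~ c; permutations are applied to
the residualized first matrix re-wrapped in matrix form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrices import PairwiseMatrix

__all__ = ["MantelResult", "mantel_r", "mantel_test", "partial_mantel_test"]


@dataclass
class MantelResult:
    r: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_permutations: int
    n_boot: int
    seed: int
    partial: bool = False
    conditioning: Optional[str] = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")


def _check_aligned(*mats: PairwiseMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("matrices have mismatched ids (align() them first)")
    if len(ids) < 4:
        raise ValueError("need at least 4 ids")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 usable pairs")
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        raise ValueError("zero variance in a matrix triangle")
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def mantel_r(a: PairwiseMatrix, b: PairwiseMatrix) -> float:
    """Pearson correlation over the aligned upper triangles of a and b."""
    _check_aligned(a, b)
    iu = a.upper_pairs()
    return _pearson(a.values[iu], b.values[iu])


def _batched_perm_r(
    av: np.ndarray, bv: np.ndarray, perms: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Mantel r for each permutation (rows of ``perms``) applied to ``bv``."""
    a_tri = av[iu]
    out = np.empty(len(perms))
    chunk = max(1, int(2e7 // max(1, a_tri.size)))
    for s in range(0, len(perms), chunk):
        p = perms[s : s + chunk]
        b_tri = bv[p[:, iu[0]], p[:, iu[1]]]          # (chunk, m)
        ok = np.isfinite(a_tri)[None, :] & np.isfinite(b_tri)
        aa = np.where(ok, a_tri[None, :], 0.0)
        bb = np.where(ok, b_tri, 0.0)
        cnt = ok.sum(axis=1)
        am = aa.sum(axis=1) / cnt
        bm = bb.sum(axis=1) / cnt
        ac = np.where(ok, aa - am[:, None], 0.0)
        bc = np.where(ok, bb - bm[:, None], 0.0)
        denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        out[s : s + chunk] = (ac * bc).sum(axis=1) / denom
    return out


def _bootstrap_ci(
    av: np.ndarray, bv: np.ndarray, n: int, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile CI from resampling ids with replacement.

    Pairs where the two resampled slots hold the same original id are
    self-comparisons and are excluded.
    """
    iu = np.triu_indices(n, k=1)
    rs = np.empty(n_boot)
    for t in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ri, rj = idx[iu[0]], idx[iu[1]]
        keep = ri != rj
        x = av[ri[keep], rj[keep]]
        y = bv[ri[keep], rj[keep]]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            rs[t] = np.nan
            continue
        rs[t] = np.corrcoef(x, y)[0, 1]
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return float("nan"), float("nan")
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def mantel_test(
    a: PairwiseMatrix,
    b: PairwiseMatrix,
    n_permutations: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: two-sided permutation p-value and 95% bootstrap CI.

    p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1).
    """
    _check_aligned(a, b)
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations; p-value resolution is poor")
    rng = np.random.default_rng(seed)
    n = a.n
    iu = a.upper_pairs()
    r_obs = mantel_r(a, b)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    r_perm = _batched_perm_r(a.values, b.values, perms, iu)
    p = (1 + int((np.abs(r_perm) >= abs(r_obs) - 1e-15).sum())) / (n_permutations + 1)
    lo, hi = _bootstrap_ci(a.values, b.values, n, n_boot, rng)
    return MantelResult(r_obs, lo, hi, p, n_permutations, n_boot, seed)


def _residual_matrix(y: PairwiseMatrix, c: PairwiseMatrix) -> np.ndarray:
    """Symmetric matrix of OLS residuals of y's triangle on c's triangle."""
    iu = y.upper_pairs()
    yt, ct = y.values[iu], c.values[iu]
    ok = np.isfinite(yt) & np.isfinite(ct)
    slope, intercept = np.polyfit(ct[ok], yt[ok], 1)
    res_t = yt - (intercept + slope * ct)
    out = np.full_like(y.values, np.nan)
    out[iu] = res_t
    out[(iu[1], iu[0])] = res_t
    np.fill_diagonal(out, 0.0)
    return out


def partial_mantel_test(
    a: PairwiseMatrix,
    b: PairwiseMatrix,
    c: PairwiseMatrix,
    n_permutations: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test of a vs b controlling for c.

    Residualizes a and b on c (element-wise OLS over triangles), then
    runs the Mantel machinery on the residual matrices, permuting the
    residualized a.
    """
    _check_aligned(a, b, c)
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations; p-value resolution is poor")
    rng = np.random.default_rng(seed)
    ra = _residual_matrix(a, c)
    rb = _residual_matrix(b, c)
    iu = a.upper_pairs()
    for name, (orig, res) in (("a", (a, ra)), ("b", (b, rb))):
        vals = res[iu]
        vals = vals[np.isfinite(vals)]
        base = orig.values[iu]
        base_sd = float(base[np.isfinite(base)].std())
        if vals.std() <= 1e-8 * max(base_sd, 1e-30):
            raise ValueError(f"matrix {name} is collinear with c (zero residual variance)")
    r_obs = _pearson(ra[iu], rb[iu])
    n = a.n
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    r_perm = _batched_perm_r(rb, ra, perms, iu)  # permute residualized a
    p = (1 + int((np.abs(r_perm) >= abs(r_obs) - 1e-15).sum())) / (n_permutations + 1)
    lo, hi = _bootstrap_ci(ra, rb, n, n_boot, rng)
    return MantelResult(
        r_obs, lo, hi, p, n_permutations, n_boot, seed, partial=True, conditioning=c.units
    )
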