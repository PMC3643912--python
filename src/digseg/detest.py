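"""Exact two-library differential-expression testing.

The design has no replicates: one library per genotype per stage. The
Audic–Claverie statistic treats the two mapped-read counts x, y of a gene as
Poisson draws and conditions on their sum; given x reads in a library of N1
total mapped reads, the count in the second library (N2 total) follows

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

a negative-binomial tail model in y. The reported p-value is the doubled
smaller of the lower tail (observed point included) and its complement:

    p = min(1, 2 * min( sum_{k<=y} P(k|x), sum_{k>y} P(k|x) ))

This split — rather than including the observed point in both tails — is
what makes the statistic exactly symmetric in its two libraries
(p(x, y, N1, N2) = p(y, x, N2, N1), via the identity
P(K > y | x; N2/N1) = P(K <= x | y; N1/N2)), the signature property of the
test: which library is called "first" cannot change the verdict.

All probability terms are evaluated in log space through the log-gamma
function; each tail is accumulated in linear space from its smallest terms
upward, and the larger tail is obtained from the exact complement
(the conditional distribution sums to one). A p-value that would underflow
to zero is reported as the smallest positive normal float, keeping
p in (0, 1].

Significance is then controlled per stage by the Benjamini–Hochberg step-up
FDR over exactly the genes tested at that stage, and direction/magnitude by
log2(XX_RPKM / XY_RPKM), with +/-inf when one side is zero.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

_TINY = np.finfo(float).tiny
_REL_TOL = 1e-17
_BLOCK = 512


def audic_logpmf(k, x: int, n1: int, n2: int):
    """log P(k | x) of the conditional count distribution (vectorised in k)."""
    k = np.asarray(k, dtype=float)
    log_r = math.log(n2) - math.log(n1 + n2)
    log_1mr = math.log(n1) - math.log(n1 + n2)
    return (
        gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        + k * log_r
        + (x + 1) * log_1mr
    )


def _sum_ascending(terms: np.ndarray) -> float:
    return float(np.sort(terms).sum())


def _lower_tail(y: int, x: int, n1: int, n2: int) -> float:
    """sum_{k<=y} P(k|x) by direct summation."""
    logs = audic_logpmf(np.arange(y + 1), x, n1, n2)
    m = logs.max()
    if not np.isfinite(m):
        return 0.0
    lower = _sum_ascending(np.exp(logs - m)) * math.exp(m)
    return min(lower, 1.0)


def _upper_tail_strict(y: int, x: int, n1: int, n2: int) -> float:
    """sum_{k>y} P(k|x) by direct summation from k = y + 1 upward.

    Only called when y exceeds the conditional mean, where terms decrease
    monotonically; a geometric bound on the remainder decides convergence.
    """
    r = n2 / (n1 + n2)
    total = 0.0
    k0 = y + 1
    while True:
        ks = np.arange(k0, k0 + _BLOCK)
        terms = np.exp(audic_logpmf(ks, x, n1, n2))
        total += _sum_ascending(terms[::-1])
        last_k = int(ks[-1])
        last_t = float(terms[-1])
        rho = r * (x + last_k + 2) / (last_k + 2)
        if rho < 1.0:
            remainder_bound = last_t * rho / (1.0 - rho)
            if remainder_bound <= _REL_TOL * max(total, _TINY):
                break
        if last_t == 0.0:
            break
        k0 += _BLOCK
    return min(total, 1.0)


def audic_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for counts x, y in libraries of sizes n1, n2.

    p = min(1, 2 * min(P(K <= y | x), P(K > y | x))); exactly symmetric
    under (x, n1) <-> (y, n2) exchange; p is in (0, 1]. Whichever tail is
    the smaller one is computed by direct summation; the other as its
    complement, so no catastrophic cancellation occurs.
    """
    if x < 0 or y < 0:
        raise ValidationError(f"counts must be non-negative, got x={x}, y={y}")
    if n1 < 1 or n2 < 1:
        raise ValidationError(f"library sizes must be positive, got {n1}, {n2}")
    x, y = int(x), int(y)
    mean = (x + 1) * n2 / n1
    if y <= mean:
        lower = _lower_tail(y, x, n1, n2)
        upper = 1.0 - lower
    else:
        upper = _upper_tail_strict(y, x, n1, n2)
        lower = 1.0 - upper
    p = min(1.0, 2.0 * min(lower, upper))
    return p if p > 0.0 else _TINY


def audic_pvalues(
    xs: Sequence[int], ys: Sequence[int], n1: int, n2: int
) -> np.ndarray:
    """Vectorised :func:`audic_pvalue` with memoisation of repeated pairs."""
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(len(xs))
    for i, (x, y) in enumerate(zip(xs.tolist(), ys.tolist())):
        key = (x, y)
        p = cache.get(key)
        if p is None:
            p = audic_pvalue(x, y, n1, n2)
            cache[key] = p
        out[i] = p
    return out


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values (same order as input).

    ``method`` is ``"bh"`` (Benjamini–Hochberg step-up, the default) or
    ``"by"`` (Benjamini–Yekutieli, valid under arbitrary dependence).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValidationError(f"p-values must lie in (0, 1], got {bad!r}")
    if p.size == 0:
        return p.copy()
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if sm_method is None:
        raise ValidationError(f"unknown FDR method {method!r} (use 'bh' or 'by')")
    return multipletests(p, method=sm_method)[1]


def log2_ratio(rpkm_a: float, rpkm_b: float) -> float:
    """log2(a/b) with the zero conventions of the dual criterion.

    +inf when only b is zero, -inf when only a is zero, NaN (undefined) when
    both are zero — such a gene is not expressed and never reaches the
    fold-change criterion.
    """
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValidationError("RPKM values must be non-negative")
    if rpkm_a == 0 and rpkm_b == 0:
        return math.nan
    if rpkm_b == 0:
        return math.inf
    if rpkm_a == 0:
        return -math.inf
    return math.log2(rpkm_a / rpkm_b)


def log2_ratios(rpkm_a: np.ndarray, rpkm_b: np.ndarray) -> np.ndarray:
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("RPKM values must be non-negative")
    out = np.full(a.shape, np.nan)
    both = (a > 0) & (b > 0)
    out[both] = np.log2(a[both] / b[both])
    out[(a > 0) & (b == 0)] = np.inf
    out[(a == 0) & (b > 0)] = -np.inf
    return out


def _stage_pair(libraries: pd.DataFrame, stage: str, groups: tuple[str, str]):
    stage = str(stage)
    st = libraries[libraries["stage"].astype(str) == stage]
    if st.empty:
        raise ValidationError(f"no libraries at stage {stage!r}")
    libs = []
    for g in groups:
        rows = st[st["group"] == g]
        if len(rows) != 1:
            raise ValidationError(
                f"expected exactly one {g!r} library at stage {stage!r}, "
                f"found {len(rows)}"
            )
        libs.append(rows.index[0])
    return libs[0], libs[1]


def test_stage(
    counts: pd.DataFrame,
    rpkm: pd.DataFrame,
    libraries: pd.DataFrame,
    stage: str,
    groups: tuple[str, str] = ("XX", "XY"),
    min_count: int = 1,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Pairwise exact test for the two-group comparison at one stage.

    Tests every gene detected (count >= ``min_count``) in at least one of the
    two libraries; p-values come from the exact test on raw counts with the
    libraries' total mapped reads, q-values from the FDR step-up over exactly
    the genes tested at this stage. log2 ratio is log2(group1/group2), so
    positive means biased toward ``groups[0]``.
    """
    lib1, lib2 = _stage_pair(libraries, stage, groups)
    n1 = int(libraries.loc[lib1, "total_mapped_reads"])
    n2 = int(libraries.loc[lib2, "total_mapped_reads"])
    x = counts[lib1]
    y = counts[lib2]
    tested = (x >= min_count) | (y >= min_count)
    idx = counts.index[tested]
    xs = x[tested].to_numpy()
    ys = y[tested].to_numpy()
    p = audic_pvalues(xs, ys, n1, n2)
    q = bh_fdr(p, method=fdr_method)
    g1, g2 = (g.lower() for g in groups)
    out = pd.DataFrame(
        {
            "x": xs,
            "y": ys,
            "n1": n1,
            "n2": n2,
            f"rpkm_{g1}": rpkm.loc[idx, lib1].to_numpy(),
            f"rpkm_{g2}": rpkm.loc[idx, lib2].to_numpy(),
            "log2_ratio": log2_ratios(
                rpkm.loc[idx, lib1].to_numpy(), rpkm.loc[idx, lib2].to_numpy()
            ),
            "p_value": p,
            "q_value": q,
        },
        index=idx,
    )
    out.index.name = "gene_id"
    return out
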