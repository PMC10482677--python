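"""Per-gene enrichment statistics for phenotype-sorted gene-trap screens.

For each gene the disruptive insertion counts in the high and low sorted
populations form the 2x2 table ``[[a, H - a], [b, L - b]]``, where ``H`` and
``L`` are the totals of unique disruptive insertions per population.  The
mutational index is the leave-one-out odds ratio

    MI = (a / (H - a)) / (b / (L - b)),

and enrichment is tested with a two-sided Fisher's exact test on the same
table.  Genes significant at P < alpha with MI > 1 have their disruptive
mutations enriched in the high tail: by the loss-of-function logic of a
haploid gene-trap screen such genes are *negative regulators* (suppressors)
of the sorted phenotype, while MI < 1 marks positive regulators.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

ENRICHED_HIGH = "enriched_high"
ENRICHED_LOW = "enriched_low"
NO_DIRECTION = "none"

_LABEL = {ENRICHED_HIGH: "negative regulator", ENRICHED_LOW: "positive regulator", NO_DIRECTION: ""}

#: relative slack when deciding whether a table is "at most as probable" as
#: the observed one; guards against spurious exclusion of exact ties under
#: floating-point log-probabilities
_TIE_RTOL = 1e-7


def _check_counts(a: int, H: int, b: int, L: int) -> None:
    for name, v in (("a", a), ("H", H), ("b", b), ("L", L)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if a > H:
        raise ValueError(f"a={a} exceeds its population total H={H}")
    if b > L:
        raise ValueError(f"b={b} exceeds its population total L={L}")


def mutational_index(a: int, H: int, b: int, L: int, exact: bool = False) -> float | Fraction:
    """Leave-one-out odds ratio of disruptive insertions, high over low.

    ``a = 0`` gives 0; ``b = 0`` (or ``a = H``) with a nonzero numerator gives
    ``+inf``; ``a = b = 0`` is undefined and returns NaN so callers can flag
    and exclude it.  With ``exact=True`` the finite values are returned as
    :class:`fractions.Fraction` (0 and undefined still come back as float).
    """
    _check_counts(a, H, b, L)
    if a == 0 and b == 0:
        return math.nan
    if a == 0:
        return Fraction(0) if exact else 0.0
    if b == 0 or a == H:
        return math.inf
    num = Fraction(a, H - a)
    den = Fraction(b, L - b)
    mi = num / den
    return mi if exact else float(mi)


def fisher_exact_pvalue(a: int, H: int, b: int, L: int) -> float:
    """Two-sided Fisher's exact P for the table [[a, H-a], [b, L-b]].

    The P value is the sum of hypergeometric probabilities of all tables with
    the same margins whose probability does not exceed that of the observed
    table (minimum-likelihood definition), accumulated in log-space.
    """
    _check_counts(a, H, b, L)
    n = a + b
    N = H + L
    if n == 0 or H == 0 or L == 0 or n == N:
        return 1.0
    k = np.arange(max(0, n - L), min(n, H) + 1)
    logp = hypergeom.logpmf(k, N, H, n)
    log_obs = float(logp[np.searchsorted(k, a)])
    include = logp <= log_obs + math.log1p(_TIE_RTOL)
    p = float(np.exp(logsumexp(logp[include])))
    return min(p, 1.0)


def analyze_screen(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    pseudocount: str = "none",
    fdr: bool = False,
) -> pd.DataFrame:
    """Compute MI, Fisher P and regulator calls for a per-gene count table.

    Parameters
    ----------
    counts:
        DataFrame with columns gene_id, a, b, H, L (one row per gene).
    alpha:
        Significance cutoff; the comparison is strict (P < alpha).
    pseudocount:
        Policy for the log2 MI column: "none" leaves log2 of 0/inf as
        -inf/+inf; "haldane" adds 0.5 to a and b (only) in the ratio so every
        gene gets a finite log2 MI.  The exact ``mi`` column is unaffected.
    fdr:
        When True, add a Benjamini-Hochberg ``q_value`` column and base the
        significance call on q < alpha instead of raw P.
    """
    if pseudocount not in ("none", "haldane"):
        raise ValueError(f"unknown pseudocount policy {pseudocount!r}")
    res = counts.copy()
    mi = np.array(
        [mutational_index(r.a, r.H, r.b, r.L) for r in counts.itertuples()], dtype=float
    )
    pvals = np.array(
        [fisher_exact_pvalue(r.a, r.H, r.b, r.L) for r in counts.itertuples()], dtype=float
    )
    res["mi"] = mi
    res["log2_mi"] = log2_mi(counts["a"], counts["H"], counts["b"], counts["L"], pseudocount)
    res["p_value"] = pvals
    if fdr:
        res["q_value"] = _benjamini_hochberg(pvals)
        res["significant"] = res["q_value"] < alpha
    else:
        res["significant"] = res["p_value"] < alpha
    res.loc[np.isnan(mi), "significant"] = False
    direction = np.where(mi > 1, ENRICHED_HIGH, np.where(mi < 1, ENRICHED_LOW, NO_DIRECTION))
    res["direction"] = np.where(res["significant"], direction, NO_DIRECTION)
    res["regulator"] = res["direction"].map(_LABEL)
    res["total_insertions"] = res["a"] + res["b"]
    res.attrs["alpha"] = alpha
    res.attrs["pseudocount"] = pseudocount
    res.attrs["fdr"] = fdr
    return res


def log2_mi(a, H, b, L, pseudocount: str = "none") -> np.ndarray:
    """log2 mutational index with the chosen zero-count policy (vectorized)."""
    a = np.asarray(a, dtype=float)
    H = np.asarray(H, dtype=float)
    b = np.asarray(b, dtype=float)
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # cross-products keep integer counts exact in floating point
        if pseudocount == "haldane":
            ratio = ((a + 0.5) * (L - b)) / ((H - a) * (b + 0.5))
        else:
            ratio = (a * (L - b)) / ((H - a) * b)
        out = np.log2(ratio)
    out = np.where((a == 0) & (b == 0) & (pseudocount == "none"), np.nan, out)
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def fishtail_table(results: pd.DataFrame, pseudocount: str = "haldane") -> pd.DataFrame:
    """Plot-ready table: x = total insertions, y = log2 MI, color by call.

    Genes with undefined MI (a = b = 0) are excluded; the pseudocount policy
    (default Haldane) makes the y axis finite for genes with one-sided zero
    counts and is stamped into ``attrs``.  Rows are ordered by gene_id.
    """
    if results.empty:
        out = pd.DataFrame(columns=["gene_id", "x", "y", "significant", "direction"])
        out.attrs["pseudocount"] = pseudocount
        return out
    keep = ~((results["a"] == 0) & (results["b"] == 0))
    sub = results[keep].sort_values("gene_id").reset_index(drop=True)
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "x": sub["a"] + sub["b"],
            "y": log2_mi(sub["a"], sub["H"], sub["b"], sub["L"], pseudocount),
            "significant": sub["significant"],
            "direction": sub["direction"],
        }
    )
    out.attrs["pseudocount"] = pseudocount
    return out


def compare_screens(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    min_insertions: int = 30,
    pseudocount: str = "none",
) -> pd.DataFrame:
    """Per-gene difference in log2 MI between two screens.

    Only genes with at least ``min_insertions`` disruptive insertions
    (a + b) in *both* screens receive a ``delta_log2_mi``; the others are
    carried with ``passes_filter = False`` and NaN delta.
    """
    shared = set(results1["gene_id"]) & set(results2["gene_id"])
    if not shared:
        raise ValueError("screens share no genes")
    m = results1.merge(results2, on="gene_id", suffixes=("_1", "_2"), how="outer")
    n1 = m["a_1"] + m["b_1"]
    n2 = m["a_2"] + m["b_2"]
    passes = (n1 >= min_insertions) & (n2 >= min_insertions)
    passes = passes.fillna(False)
    y1 = log2_mi(m["a_1"], m["H_1"], m["b_1"], m["L_1"], pseudocount)
    y2 = log2_mi(m["a_2"], m["H_2"], m["b_2"], m["L_2"], pseudocount)
    out = pd.DataFrame(
        {
            "gene_id": m["gene_id"],
            "log2_mi_screen1": y1,
            "log2_mi_screen2": y2,
            "delta_log2_mi": np.where(passes, y1 - y2, np.nan),
            "n_insertions_screen1": n1,
            "n_insertions_screen2": n2,
            "passes_filter": passes,
        }
    ).sort_values("gene_id").reset_index(drop=True)
    out.attrs["min_insertions"] = min_insertions
    out.attrs["pseudocount"] = pseudocount
    return out
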