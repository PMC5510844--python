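"""Unreplicated two-library differential expression.

With a single library per condition the only exact null model is conditional:
under no differential expression, the count in condition A given the total
n = xA + xB is Binomial(n, pi0) with pi0 = NA / (NA + NB) set by the library
sizes. The two-sided p-value sums the probabilities of all outcomes no more
likely than the observed one (minimum-likelihood convention, ties included),
which is deterministic and oracle-checkable. A normal-approximation z-test on
the same conditional model is available as method="ma-z".

The fold change is depth-normalized with a pseudocount applied to the counts
only — never to the test statistic — so the test stays exact while log2fc is
finite:

    log2fc = log2((xA + c) / NA) - log2((xB + c) / NB),  c = 1 by default.

Benjamini-Hochberg adjustment is applied across all testable genes of one
contrast; a gene is called up in either direction only when padj <= alpha and
|log2fc| >= lfc_min (defaults alpha = 0.005, lfc_min = 1.0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.005
DEFAULT_LFC_MIN = 1.0

# Relative tolerance for pmf ties in the minimum-likelihood summation
# (same convention as R's binom.test).
_TIE_RTOL = 1e-7

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NOT_SIG = "not_significant"
UNTESTABLE = "untestable"


def exact_binom_p(x: int, n: int, pi0: float) -> float:
    """Two-sided exact binomial p by minimum-likelihood summation.

    Sums Pr(k) over all k in 0..n with Pr(k) <= Pr(x) * (1 + 1e-7); the slack
    keeps floating-point ties (e.g. the symmetric outcome at pi0 = 1/2) inside
    the rejection set.
    """
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    pmf = stats.binom.pmf(np.arange(n + 1), n, pi0)
    return float(min(1.0, pmf[pmf <= pmf[x] * (1 + _TIE_RTOL)].sum()))


def binomial_de_test(
    xA: int, xB: int, NA: float, NB: float, pseudocount: float = 1.0
) -> tuple[float, float]:
    """Exact conditional test of one gene between two libraries.

    Returns ``(p, log2fc)``. Raises if the gene is untestable (xA + xB = 0);
    batch interfaces skip such genes with an "untestable" status instead.
    """
    if NA <= 0 or NB <= 0:
        raise ValueError("library sizes must be > 0")
    if xA < 0 or xB < 0:
        raise ValueError("counts must be >= 0")
    n = xA + xB
    if n == 0:
        raise ValueError("untestable gene: xA + xB = 0")
    pi0 = NA / (NA + NB)
    p = exact_binom_p(xA, n, pi0)
    lfc = _log2fc(xA, xB, NA, NB, pseudocount)
    return p, lfc


def _log2fc(xA, xB, NA, NB, pseudocount=1.0):
    return float(
        np.log2((np.asarray(xA) + pseudocount) / NA)
        - np.log2((np.asarray(xB) + pseudocount) / NB)
    )


def ma_z_p(x: np.ndarray, n: np.ndarray, pi0: float) -> np.ndarray:
    """Normal-approximation two-sided p on the same conditional model."""
    mu = n * pi0
    sd = np.sqrt(n * pi0 * (1 - pi0))
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def _exact_p_batch(x: np.ndarray, n: np.ndarray, pi0: float) -> np.ndarray:
    """Vectorized minimum-likelihood p; pmf vectors cached per total count n."""
    out = np.empty(len(x), dtype=float)
    cache: dict[int, np.ndarray] = {}
    for i, (xi, ni) in enumerate(zip(x, n)):
        pmf = cache.get(ni)
        if pmf is None:
            pmf = stats.binom.pmf(np.arange(ni + 1), ni, pi0)
            cache[ni] = pmf
        out[i] = min(1.0, pmf[pmf <= pmf[xi] * (1 + _TIE_RTOL)].sum())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    padj: np.ndarray,
    log2fc: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> np.ndarray:
    """Direction calls: significant iff padj <= alpha and |log2fc| >= lfc_min."""
    padj = np.asarray(padj, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    sig = (padj <= alpha) & (np.abs(log2fc) >= lfc_min)
    calls = np.where(sig & (log2fc > 0), UP_IN_A, NOT_SIG)
    calls = np.where(sig & (log2fc < 0), UP_IN_B, calls)
    return calls.astype(object)


def de_contrast(
    xA: np.ndarray,
    xB: np.ndarray,
    NA: float,
    NB: float,
    gene_ids=None,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    pseudocount: float = 1.0,
    method: str = "exact",
) -> pd.DataFrame:
    """Run one two-library contrast over a vector of genes.

    Genes with xA + xB = 0 are reported with status "untestable" (p, padj and
    log2fc set to NaN) and excluded from the BH family. Returns a DataFrame
    with columns xA, xB, log2fc, pvalue, padj, call.
    """
    xA = np.asarray(xA, dtype=np.int64)
    xB = np.asarray(xB, dtype=np.int64)
    if xA.shape != xB.shape:
        raise ValueError("xA and xB must have equal length")
    if NA <= 0 or NB <= 0:
        raise ValueError("library sizes must be > 0")
    n = xA + xB
    testable = n > 0
    pi0 = NA / (NA + NB)

    p = np.full(len(xA), np.nan)
    if method == "exact":
        p[testable] = _exact_p_batch(xA[testable], n[testable], pi0)
    elif method == "ma-z":
        p[testable] = ma_z_p(xA[testable], n[testable], pi0)
    else:
        raise ValueError(f"unknown method: {method!r}")

    lfc = np.full(len(xA), np.nan)
    lfc[testable] = (
        np.log2((xA[testable] + pseudocount) / NA)
        - np.log2((xB[testable] + pseudocount) / NB)
    )

    padj = np.full(len(xA), np.nan)
    padj[testable] = bh_adjust(p[testable])

    calls = np.full(len(xA), UNTESTABLE, dtype=object)
    calls[testable] = call_degs(padj[testable], lfc[testable], alpha, lfc_min)

    index = gene_ids if gene_ids is not None else pd.RangeIndex(len(xA))
    return pd.DataFrame(
        {
            "xA": xA,
            "xB": xB,
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
            "call": calls,
        },
        index=pd.Index(index, name="gene_id"),
    )
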