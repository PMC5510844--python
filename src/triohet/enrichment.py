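"""Over-representation (term enrichment) analysis of gene sets.

One engine serves GO-style and pathway-style analyses alike — both reduce to
the hypergeometric over-representation test. For a term containing K of the N
universe genes, with n selected (e.g. differentially expressed) genes of which
k fall in the term, the one-sided p is the hypergeometric upper tail
P(X >= k), BH-adjusted across all terms represented in the universe;
enrichment is called at padj < 0.05.

:func:`length_bias_null` offers a Monte-Carlo selection-bias correction: long
genes accumulate more reads and are easier to call differentially expressed,
so a term of long genes can look enriched for length alone. The null resamples
gene sets with per-gene weights from a monotone (isotonic-smoothed, 10
quantile bins) selection-probability-vs-length curve and reports empirical
upper-tail p-values. This is a deliberately simple sampling null, not a
Wallenius-distribution approximation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .de import bh_adjust
from .errors import InvalidConfigError, ParseError

ENRICH_ALPHA = 0.05


def read_term_map_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id), '#' comments allowed."""
    term_to_genes: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            gene, term = fields
            term_to_genes.setdefault(term, set()).add(gene)
    return term_to_genes


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    term_to_genes: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 fields")
            term_to_genes[fields[0]] = set(fields[2:])
    return term_to_genes


def write_term_map_tsv(term_to_genes: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# gene_id\tterm_id\n")
        for term in sorted(term_to_genes):
            for gene in sorted(term_to_genes[term]):
                fh.write(f"{gene}\t{term}\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives 1 by convention."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    de_genes: set[str],
    universe: set[str],
    term_to_genes: dict[str, set[str]],
    alpha: float = ENRICH_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` per term.

    Terms are restricted to the universe; terms with no universe genes are
    skipped. BH across tested terms; ``enriched`` flags padj < alpha.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = de_genes - universe
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(de_genes)
    rows = []
    for term, members in term_to_genes.items():
        in_uni = members & universe
        K = len(in_uni)
        if K == 0:
            continue
        k = len(in_uni & de_genes)
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_upper_tail(k, K, n, N)}
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["enriched"] = res["padj"] < alpha
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def _length_selection_weights(
    selected: np.ndarray, lengths: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Monotone smoothed selection-probability-vs-length curve.

    Genes are split into length quantile bins; the per-bin selection fraction
    is isotonic-smoothed against the bin mean length and interpolated back to
    each gene. A small floor keeps every gene sampleable.
    """
    order = np.argsort(lengths, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_len = np.array([lengths[b].mean() for b in bins])
    bin_frac = np.array([selected[b].mean() for b in bins])
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    smooth = iso.fit(bin_len, bin_frac)
    w = smooth.predict(lengths.astype(float))
    w = np.maximum(w, 1e-6)
    return w / w.sum()


def length_bias_null(
    de_genes: set[str],
    universe: set[str],
    lengths: pd.Series,
    term_to_genes: dict[str, set[str]],
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-term enrichment p under a length-aware sampling null.

    Resamples ``len(de_genes)``-sized gene sets without replacement, with
    per-gene probabilities from the fitted length curve, and reports the
    add-one empirical upper-tail p for each term's observed overlap.
    """
    if n_resamples < 1:
        raise InvalidConfigError("n_resamples must be >= 1")
    missing = universe - set(lengths.index)
    if missing:
        raise ValueError(f"lengths missing for universe genes: {sorted(missing)[:5]}")
    genes = np.array(sorted(universe))
    lens = lengths.reindex(genes).to_numpy(dtype=float)
    selected = np.isin(genes, list(de_genes))
    n_sel = int(selected.sum())
    if n_sel == 0:
        raise ValueError("no selected genes in universe")
    weights = _length_selection_weights(selected, lens)

    terms = [(t, members & universe) for t, members in term_to_genes.items()]
    terms = [(t, m) for t, m in terms if m]
    term_masks = np.array([np.isin(genes, sorted(m)) for _, m in terms])
    k_obs = term_masks @ selected

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=np.int64)
    for _ in range(n_resamples):
        draw = rng.choice(len(genes), size=n_sel, replace=False, p=weights)
        mask = np.zeros(len(genes), dtype=bool)
        mask[draw] = True
        exceed += (term_masks @ mask) >= k_obs
    p_emp = (1 + exceed) / (1 + n_resamples)
    res = pd.DataFrame(
        {
            "term": [t for t, _ in terms],
            "k": k_obs,
            "K": term_masks.sum(axis=1),
            "n": n_sel,
            "N": len(genes),
            "p_empirical": p_emp,
        }
    )
    res["padj"] = bh_adjust(res["p_empirical"].to_numpy())
    return res.sort_values("p_empirical", kind="stable").reset_index(drop=True)
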