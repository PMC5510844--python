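"""Twelve-pattern expression classification of a parent/hybrid/parent trio.

A gene's behaviour in an F1 hybrid relative to its two parents is summarized
by three signed significance calls from pairwise contrasts:

    s_pp : maternal vs paternal   (+1 = maternal significantly higher)
    s_hm : hybrid  vs maternal    (+1 = hybrid significantly higher)
    s_hp : hybrid  vs paternal    (+1 = hybrid significantly higher)

The 27 sign triples partition into 12 interpretable patterns (Roman numerals
I-XII) grouped into four categories, one all-flat "null" triple, and 14
internally inconsistent "ambiguous" triples:

    additivity                 I, XII       hybrid strictly between differing parents
    parental_dominance         II, XI, IV, IX   hybrid matches exactly one parent, parents differ
    transgressive_down         III, VII, X  hybrid significantly below both parents
    transgressive_up           V, VI, VIII  hybrid significantly above both parents

The numeral-to-triple table below is a canonical constant of this package:
the category groupings are the established ones, but the assignment of
numerals *within* the transgressive categories (by the sign of the parental
contrast) is a documented convention. Downstream analyses should rely on
categories, not numerals.

A fourth contrast — hybrid vs an *in silico* mid-parent built by pooling the
parental libraries — flags nonadditive genes: pooled counts with summed
library size give the depth-weighted average of the parental rates, i.e. the
additive null expectation, while preserving the count nature of the data for
the exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de
from .expression import CountMatrix

CATEGORY_ADDITIVITY = "additivity"
CATEGORY_DOMINANCE = "parental_dominance"
CATEGORY_TRANS_DOWN = "transgressive_down"
CATEGORY_TRANS_UP = "transgressive_up"
CATEGORY_NONE = "none"

CATEGORIES = (
    CATEGORY_ADDITIVITY,
    CATEGORY_DOMINANCE,
    CATEGORY_TRANS_DOWN,
    CATEGORY_TRANS_UP,
)

#: Canonical triple -> (pattern numeral, category) decision table.
#: Keys are (s_pp, s_hm, s_hp).
PATTERN_TABLE: dict[tuple[int, int, int], tuple[str, str]] = {
    # additivity: parents differ, hybrid strictly between
    (+1, -1, +1): ("I", CATEGORY_ADDITIVITY),     # maternal > hybrid > paternal
    (-1, +1, -1): ("XII", CATEGORY_ADDITIVITY),   # maternal < hybrid < paternal
    # parental expression level dominance: hybrid equals exactly one parent
    (+1, 0, +1): ("II", CATEGORY_DOMINANCE),      # hybrid = maternal > paternal
    (-1, 0, -1): ("XI", CATEGORY_DOMINANCE),      # hybrid = maternal < paternal
    (+1, -1, 0): ("IV", CATEGORY_DOMINANCE),      # maternal > hybrid = paternal
    (-1, +1, 0): ("IX", CATEGORY_DOMINANCE),      # maternal < hybrid = paternal
    # transgressive down-regulation: hybrid below both parents
    (0, -1, -1): ("III", CATEGORY_TRANS_DOWN),
    (+1, -1, -1): ("VII", CATEGORY_TRANS_DOWN),
    (-1, -1, -1): ("X", CATEGORY_TRANS_DOWN),
    # transgressive up-regulation: hybrid above both parents
    (+1, +1, +1): ("V", CATEGORY_TRANS_UP),
    (0, +1, +1): ("VI", CATEGORY_TRANS_UP),
    (-1, +1, +1): ("VIII", CATEGORY_TRANS_UP),
}

PATTERN_NUMERALS = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
)

PATTERN_NULL = "null"
PATTERN_AMBIGUOUS = "ambiguous"


def classify_trio(s_pp: int, s_hm: int, s_hp: int) -> tuple[str, str]:
    """Map one sign triple to a (pattern, category) pair.

    The table is total over the 27 triples: 12 patterns, the all-zero null
    triple, and 14 ambiguous triples (e.g. hybrid above one parent while the
    parents and the other comparison are flat).
    """
    triple = (int(s_pp), int(s_hm), int(s_hp))
    for s in triple:
        if s not in (-1, 0, 1):
            raise ValueError(f"signs must be in {{-1, 0, +1}}, got {triple}")
    if triple in PATTERN_TABLE:
        return PATTERN_TABLE[triple]
    if triple == (0, 0, 0):
        return PATTERN_NULL, CATEGORY_NONE
    return PATTERN_AMBIGUOUS, CATEGORY_NONE


def build_mid_parent(
    counts_maternal: np.ndarray,
    counts_paternal: np.ndarray,
    N_m: float,
    N_p: float,
) -> tuple[np.ndarray, float]:
    """Pool the parental libraries into an in-silico mid-parent pseudo-sample.

    mid(g) = maternal(g) + paternal(g), N_mid = N_m + N_p. The pooled rate is
    the depth-weighted average of the parental rates; at equal depths it equals
    the arithmetic mean of normalized parental expression — the additive null.
    """
    cm = np.asarray(counts_maternal)
    cp = np.asarray(counts_paternal)
    if cm.shape != cp.shape:
        raise ValueError("parental count vectors must have equal length")
    if N_m <= 0 or N_p <= 0:
        raise ValueError("library sizes must be > 0")
    return cm + cp, float(N_m + N_p)


@dataclass
class TrioClassification:
    """Per-gene assignments plus the per-contrast DE tables and a summary."""

    assignments: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    summary: dict


def _signs(calls: np.ndarray) -> np.ndarray:
    s = np.zeros(len(calls), dtype=np.int8)
    s[calls == de.UP_IN_A] = 1
    s[calls == de.UP_IN_B] = -1
    return s


def classify_all(
    cm: CountMatrix,
    roles: dict[str, str],
    alpha: float = de.DEFAULT_ALPHA,
    lfc_min: float = de.DEFAULT_LFC_MIN,
    method: str = "exact",
) -> TrioClassification:
    """Run the four contrasts and classify every gene of a trio.

    ``roles`` maps {"maternal", "hybrid", "paternal"} to sample names of
    ``cm``. BH correction is applied within each contrast across its testable
    genes. The summary counts patterns and categories over genes significant
    in at least one of the four contrasts, mirroring a per-pattern count table,
    and reports the nonadditive set (hybrid vs mid-parent significant).
    """
    for role in ("maternal", "hybrid", "paternal"):
        if role not in roles:
            raise ValueError(f"missing role mapping: {role!r}")
        if roles[role] not in cm.samples:
            raise ValueError(f"sample {roles[role]!r} for role {role!r} not in matrix")

    lib = cm.library_sizes
    m, h, p = roles["maternal"], roles["hybrid"], roles["paternal"]
    xm = cm.counts[m].to_numpy()
    xh = cm.counts[h].to_numpy()
    xp = cm.counts[p].to_numpy()
    Nm, Nh, Np = float(lib[m]), float(lib[h]), float(lib[p])
    x_mid, N_mid = build_mid_parent(xm, xp, Nm, Np)

    kw = dict(gene_ids=cm.gene_ids, alpha=alpha, lfc_min=lfc_min, method=method)
    contrasts = {
        "maternal_vs_paternal": de.de_contrast(xm, xp, Nm, Np, **kw),
        "hybrid_vs_maternal": de.de_contrast(xh, xm, Nh, Nm, **kw),
        "hybrid_vs_paternal": de.de_contrast(xh, xp, Nh, Np, **kw),
        "hybrid_vs_midparent": de.de_contrast(xh, x_mid, Nh, N_mid, **kw),
    }

    s_pp = _signs(contrasts["maternal_vs_paternal"]["call"].to_numpy())
    s_hm = _signs(contrasts["hybrid_vs_maternal"]["call"].to_numpy())
    s_hp = _signs(contrasts["hybrid_vs_paternal"]["call"].to_numpy())
    s_hmid = _signs(contrasts["hybrid_vs_midparent"]["call"].to_numpy())

    pats = np.empty(cm.n_genes, dtype=object)
    cats = np.empty(cm.n_genes, dtype=object)
    for i in range(cm.n_genes):
        pats[i], cats[i] = classify_trio(s_pp[i], s_hm[i], s_hp[i])

    assignments = pd.DataFrame(
        {
            "s_pp": s_pp,
            "s_hm": s_hm,
            "s_hp": s_hp,
            "s_hmid": s_hmid,
            "pattern": pats,
            "category": cats,
            "nonadditive": s_hmid != 0,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )

    in_universe = (
        (s_pp != 0) | (s_hm != 0) | (s_hp != 0) | (s_hmid != 0)
    )
    uni = assignments[in_universe]
    pattern_counts = {num: int((uni["pattern"] == num).sum()) for num in PATTERN_NUMERALS}
    category_counts = {cat: int((uni["category"] == cat).sum()) for cat in CATEGORIES}
    summary = {
        "alpha": alpha,
        "lfc_min": lfc_min,
        "n_genes": int(cm.n_genes),
        "n_in_universe": int(in_universe.sum()),
        "pattern_counts": pattern_counts,
        "category_counts": category_counts,
        "n_ambiguous": int((uni["pattern"] == PATTERN_AMBIGUOUS).sum()),
        "n_nonadditive": int(assignments["nonadditive"].sum()),
    }
    return TrioClassification(assignments=assignments, contrasts=contrasts, summary=summary)


def common_degs(
    assignments_a: pd.DataFrame, assignments_b: pd.DataFrame
) -> dict[str, dict]:
    """Per-category intersection of two hybrids' assignments.

    A gene is common to a category when it carries that category in both
    hybrids; the analogue of a shared-DEG row across two crosses.
    """
    shared = assignments_a.index.intersection(assignments_b.index)
    if len(shared) == 0:
        warnings.warn("assignment tables share no genes; empty intersection")
    out: dict[str, dict] = {}
    for cat in CATEGORIES:
        set_a = set(assignments_a.index[assignments_a["category"] == cat])
        set_b = set(assignments_b.index[assignments_b["category"] == cat])
        genes = sorted(set_a & set_b)
        out[cat] = {"count": len(genes), "genes": genes}
    return out
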