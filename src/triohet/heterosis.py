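"""Mid-parent and best-parent heterosis statistics on plant-level trait tables.

For a trait with hybrid mean F1 and parental means P1, P2:

    MP  = (P1 + P2) / 2                       mid-parent value
    HP  = better(P1, P2)                      best-parent value (max by default)
    MPH = (F1 - MP) / MP * 100                mid-parent heterosis, percent
    HPH = (F1 - HP) / HP * 100                best-parent heterosis, percent

With positive parental means and HP = max, HPH <= MPH algebraically. "Better"
is trait-specific in practice (e.g. shorter plants can be agronomically
better), so :func:`heterosis_table` accepts a per-trait override rather than
guessing intent.

Hypothesis tests are Welch's two-sample t (unequal variances, two-sided):
hybrid plant values against the better parent's plant values, and against
per-plant mid-parent pseudo-values formed by rank-matching the two parents'
plants within each block and averaging each pair.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .errors import UndefinedStatisticError

TRAIT_ID_COLS = ("genotype", "block", "plant")


def mph(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Mid-parent heterosis, percent."""
    mp = (p1_mean + p2_mean) / 2.0
    if mp == 0:
        raise UndefinedStatisticError("mid-parent value is zero; MPH undefined")
    return (f1_mean - mp) / mp * 100.0


def hph(f1_mean: float, p1_mean: float, p2_mean: float, better: str = "max") -> float:
    """Best-parent heterosis, percent; ``better`` selects the reference parent."""
    if better == "max":
        hp = max(p1_mean, p2_mean)
    elif better == "min":
        hp = min(p1_mean, p2_mean)
    else:
        raise ValueError(f"better must be 'max' or 'min', got {better!r}")
    if hp == 0:
        raise UndefinedStatisticError("best-parent value is zero; HPH undefined")
    return (f1_mean - hp) / hp * 100.0


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sided p with the degenerate-variance contract: when both
    groups are constant, p = 1 for equal means and 0 otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def midparent_plant_values(
    p1_values: pd.DataFrame, p2_values: pd.DataFrame, trait: str
) -> np.ndarray:
    """Per-plant mid-parent pseudo-values: rank-match parents within block.

    Within each block the two parents' plant values are sorted and paired by
    rank (truncating to the shorter parent), and each pair is averaged.
    """
    mids = []
    blocks = sorted(set(p1_values["block"]) & set(p2_values["block"]))
    for blk in blocks:
        a = np.sort(p1_values.loc[p1_values["block"] == blk, trait].to_numpy())
        b = np.sort(p2_values.loc[p2_values["block"] == blk, trait].to_numpy())
        k = min(len(a), len(b))
        mids.append((a[:k] + b[:k]) / 2.0)
    if not mids:
        raise ValueError("parents share no blocks; cannot build mid-parent values")
    return np.concatenate(mids)


def heterosis_table(
    traits: pd.DataFrame,
    hybrid: str,
    parents: tuple[str, str],
    better: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-trait heterosis statistics for one hybrid and its two parents.

    ``traits`` is a plant-level table with columns genotype, block, plant and
    one column per trait. ``better`` maps trait name to "max"/"min" for the
    best-parent direction (default "max"). Percentages are returned at full
    precision; round for reporting.
    """
    better = better or {}
    p1, p2 = parents
    for g in (hybrid, p1, p2):
        if g not in set(traits["genotype"]):
            raise ValueError(f"genotype {g!r} missing from trait table")
    trait_cols = [c for c in traits.columns if c not in TRAIT_ID_COLS]
    sub = {g: traits[traits["genotype"] == g] for g in (hybrid, p1, p2)}
    rows = []
    for trait in trait_cols:
        f1v = sub[hybrid][trait].to_numpy(dtype=float)
        p1v = sub[p1][trait].to_numpy(dtype=float)
        p2v = sub[p2][trait].to_numpy(dtype=float)
        if min(len(f1v), len(p1v), len(p2v)) < 2:
            raise ValueError(f"trait {trait!r}: every genotype needs >= 2 plants")
        f1m, p1m, p2m = f1v.mean(), p1v.mean(), p2v.mean()
        direction = better.get(trait, "max")
        hp_parent = p1 if (p1m >= p2m) == (direction == "max") else p2
        hpv = sub[hp_parent][trait].to_numpy(dtype=float)
        midv = midparent_plant_values(sub[p1], sub[p2], trait)
        rows.append(
            {
                "trait": trait,
                "f1_mean": f1m,
                "f1_sd": f1v.std(ddof=1),
                "p1_mean": p1m,
                "p1_sd": p1v.std(ddof=1),
                "p2_mean": p2m,
                "p2_sd": p2v.std(ddof=1),
                "mp": (p1m + p2m) / 2.0,
                "hp": hpv.mean(),
                "hp_parent": hp_parent,
                "mph_pct": mph(f1m, p1m, p2m),
                "hph_pct": hph(f1m, p1m, p2m, better=direction),
                "p_vs_mp": _welch_p(f1v, midv),
                "p_vs_hp": _welch_p(f1v, hpv),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def letter_groups(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, str]:
    """Compact-letter display from pairwise Welch tests with BH at ``alpha``.

    Greedy assignment: genotypes sharing a letter are not significantly
    different. Reported for convenience only; not a primary statistic.
    """
    names = list(groups)
    pairs = list(combinations(names, 2))
    if not pairs:
        return {names[0]: "a"} if names else {}
    praw = [_welch_p(groups[a], groups[b]) for a, b in pairs]
    padj = bh_adjust(praw)
    differ = {pair: adj <= alpha for pair, adj in zip(pairs, padj)}

    def differs(a: str, b: str) -> bool:
        return differ.get((a, b), differ.get((b, a), False))

    order = sorted(names, key=lambda g: -np.mean(groups[g]))
    letter_sets: list[list[str]] = []
    for g in order:
        placed = False
        for members in letter_sets:
            if not any(differs(g, m) for m in members):
                members.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    out = {g: "" for g in names}
    for i, members in enumerate(letter_sets):
        for g in members:
            out[g] += chr(ord("a") + i)
    return out
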