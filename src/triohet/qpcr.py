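"""Relative quantification of qPCR data by the 2^-ddCt method.

A target gene's Ct in each sample is normalized to the arithmetic mean of the
reference genes' Cts (equivalent to the geometric mean of reference
quantities):

    dCt(s)  = Ct_target(s) - mean(Ct_refs(s))
    ddCt    = dCt(sample) - dCt(calibrator)
    ratio   = 2 ** (-ddCt)

Amplification efficiency is fixed at 2, the classic form of the method.
Technical replicates are averaged (mean Ct) first; biological replicates are
summarized as mean +/- SD of per-replicate ratios against the calibrator's
mean dCt.

Validation against RNA-seq uses Pearson correlation of paired log2 fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, UndefinedStatisticError

CT_COLUMNS = ("sample", "gene", "replicate", "ct")


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Ct table TSV with columns sample, gene, replicate, ct and optionally
    tech_rep; '#' comment lines ignored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ParseError(f"{path}: Ct values must be finite and > 0")
    return df


def _mean_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates, keeping one Ct per (sample, gene,
    biological replicate)."""
    return (
        df.groupby(["sample", "gene", "replicate"], as_index=False)["ct"].mean()
    )


def _delta_ct(df: pd.DataFrame, sample: str, target: str, references: list[str]):
    """Per-biological-replicate dCt for one sample; requires the target and
    every reference measured in each replicate."""
    sub = df[df["sample"] == sample]
    if sub.empty:
        raise UndefinedStatisticError(f"sample {sample!r} not in Ct table")
    reps = sorted(sub["replicate"].unique())
    out = {}
    for rep in reps:
        r = sub[sub["replicate"] == rep].set_index("gene")["ct"]
        if target not in r.index:
            continue
        missing = [g for g in references if g not in r.index]
        if missing:
            raise UndefinedStatisticError(
                f"sample {sample!r} replicate {rep!r}: missing reference(s) {missing}"
            )
        out[rep] = float(r[target] - np.mean([r[g] for g in references]))
    if not out:
        raise UndefinedStatisticError(
            f"target {target!r} not measured in sample {sample!r}"
        )
    return out


@dataclass
class RelativeExpression:
    target: str
    sample: str
    calibrator: str
    ratio_mean: float
    ratio_sd: float
    per_replicate: dict


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    sample: str,
    calibrator: str,
    references: list[str],
) -> RelativeExpression:
    """Fold change of ``target_gene`` in ``sample`` relative to ``calibrator``.

    ddCt uses the calibrator's replicate-mean dCt; per-replicate ratios in the
    sample give the mean and SD of the fold change.
    """
    if not references:
        raise ValueError("at least one reference gene required")
    df = _mean_ct(ct_table)
    dct_sample = _delta_ct(df, sample, target_gene, references)
    dct_cal = _delta_ct(df, calibrator, target_gene, references)
    dct_cal_mean = float(np.mean(list(dct_cal.values())))
    ratios = {rep: 2.0 ** -(d - dct_cal_mean) for rep, d in dct_sample.items()}
    vals = np.array(list(ratios.values()))
    return RelativeExpression(
        target=target_gene,
        sample=sample,
        calibrator=calibrator,
        ratio_mean=float(vals.mean()),
        ratio_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        per_replicate=ratios,
    )


def validate_correlation(rnaseq_log2fc, qpcr_log2fc) -> tuple[float, float, float]:
    """Pearson correlation of paired fold changes: returns (r, r^2, p)."""
    x = np.asarray(rnaseq_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fold-change vectors must be 1-D with equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired fold changes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold changes must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)
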