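"""Count-matrix data model, FPKM normalization, and Pearson-correlation sample QC.

The central container is :class:`CountMatrix`: integer read counts per gene and
sample together with gene lengths in bp. Library size is defined as the column
sum of the supplied counts, which keeps normalization self-contained and
reproducible (alignment-level mapped-read totals are out of scope).

FPKM (fragments per kilobase of transcript per million mapped reads) is

    FPKM(g, s) = counts(g, s) * 1e9 / (length_bp(g) * library_size(s))

with 1e9 = 1e3 (kb) * 1e6 (million reads); no effective-length correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UndefinedStatisticError

FPKM_SCALE = 1e9

# r^2 below this flags a sample pair in QC (expression QC convention).
QC_R2_MIN = 0.8


@dataclass
class CountMatrix:
    """Gene x sample read counts with per-gene lengths.

    Parameters
    ----------
    counts
        Integer-valued DataFrame, genes in rows (index = gene ids), samples in
        columns. Values must be non-negative and integral.
    lengths
        Per-gene length in bp, indexed like ``counts``; all > 0.
    """

    counts: pd.DataFrame
    lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicated gene ids: {dupes}")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()
                raise ValueError(f"genes without a length: {missing[:5]}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if (self.lengths.to_numpy() <= 0).any():
            raise ValueError("gene lengths must be > 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample library size = column sum of counts."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Depth- and length-normalized expression for every gene and sample.

    Raises
    ------
    UndefinedStatisticError
        If any sample used has a zero library size.
    """
    lib = cm.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise UndefinedStatisticError(f"zero library size for samples: {bad}")
    fpkm = (
        cm.counts.to_numpy(dtype=float)
        * FPKM_SCALE
        / (cm.lengths.to_numpy(dtype=float)[:, None] * lib.to_numpy(dtype=float)[None, :])
    )
    return pd.DataFrame(fpkm, index=cm.gene_ids, columns=cm.counts.columns)


def sample_correlation(
    profile: pd.DataFrame, transform: str = "log2p1"
) -> tuple[pd.DataFrame, list[dict]]:
    """Pearson correlation between samples of an expression profile, with QC flags.

    ``transform`` is ``"log2p1"`` (correlate ``log2(x + 1)``, the stable
    convention for expression QC) or ``"none"``. A flag is raised for every
    sample pair with r^2 < 0.8.

    Returns the symmetric correlation matrix and a list of flag dicts
    ``{"sample_a", "sample_b", "r", "r2"}``.
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least two samples")
    if transform == "log2p1":
        data = np.log2(profile.to_numpy(dtype=float) + 1.0)
    elif transform == "none":
        data = profile.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    sd = data.std(axis=0)
    if (sd == 0).any():
        bad = [profile.columns[i] for i in np.flatnonzero(sd == 0)]
        raise UndefinedStatisticError(
            f"correlation undefined for constant samples: {bad}"
        )
    r = np.corrcoef(data, rowvar=False)
    corr = pd.DataFrame(r, index=profile.columns, columns=profile.columns)
    flags = []
    cols = list(profile.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if r[i, j] ** 2 < QC_R2_MIN:
                flags.append(
                    {
                        "sample_a": cols[i],
                        "sample_b": cols[j],
                        "r": float(r[i, j]),
                        "r2": float(r[i, j] ** 2),
                    }
                )
    return corr, flags


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a count matrix TSV: columns gene_id, length_bp, then one per sample.

    Lines beginning ``#`` are comments. Parse failures name the 1-based line
    number; duplicated gene ids are an error listing the ids.
    """
    path = Path(path)
    header: list[str] | None = None
    gene_ids: list[str] = []
    lengths: list[int] = []
    rows: list[list[int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:2] != ["gene_id", "length_bp"] or len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: header must be gene_id, length_bp, <samples...>"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                length = int(fields[1])
                counts = [int(v) for v in fields[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive gene length {length}")
            if any(c < 0 for c in counts):
                raise ParseError(f"{path}:{lineno}: negative count")
            lengths.append(length)
            rows.append(counts)
    if header is None:
        raise ParseError(f"{path}: empty file, header row required")
    index = pd.Index(gene_ids, name="gene_id")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene ids: {dupes}")
    counts_df = pd.DataFrame(rows, index=index, columns=header[2:], dtype=np.int64)
    lengths_s = pd.Series(lengths, index=index, name="length_bp")
    return CountMatrix(counts=counts_df, lengths=lengths_s)


def write_counts_tsv(cm: CountMatrix, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a CountMatrix as TSV (round-trips with :func:`read_counts_tsv`)."""
    path = Path(path)
    with path.open("w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("gene_id\tlength_bp\t" + "\t".join(cm.samples) + "\n")
        lengths = cm.lengths.to_numpy()
        vals = cm.counts.to_numpy()
        for i, gid in enumerate(cm.gene_ids):
            fh.write(
                f"{gid}\t{int(lengths[i])}\t" + "\t".join(str(int(v)) for v in vals[i]) + "\n"
            )


def write_fpkm_tsv(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def write_qc_report(corr: pd.DataFrame, flags: list[dict], path: str | Path) -> None:
    report = {
        "r2_threshold": QC_R2_MIN,
        "n_samples": int(corr.shape[0]),
        "flagged_pairs": flags,
        "correlation": {
            a: {b: float(corr.loc[a, b]) for b in corr.columns} for a in corr.index
        },
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
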