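"""End-to-end orchestration: simulate/load -> QC -> DE -> classify -> heterosis
-> enrichment -> report bundle.

A run is described by a :class:`PipelineConfig` (typically loaded from a YAML
file). Each stage writes its outputs to ``.partial`` files that are renamed in
place on stage success, so an aborted run leaves identifiable partial output;
a failing stage raises :class:`StageError` naming the stage. All randomness
flows from the single recorded seed, and output files carry no timestamps, so
reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, de, enrichment, heterosis, patterns, simulate
from .errors import TriohetError
from .expression import (
    CountMatrix,
    compute_fpkm,
    read_counts_tsv,
    sample_correlation,
    write_counts_tsv,
    write_fpkm_tsv,
    write_qc_report,
)

DEFAULT_ROLES = {"maternal": "maternal", "hybrid": "hybrid", "paternal": "paternal"}


class StageError(TriohetError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class TrioSpec:
    """One hybrid trio: either a counts TSV path or a simulation config."""

    name: str
    counts: str | None = None
    simulate: dict | None = None
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))


@dataclass
class PipelineConfig:
    trios: list[TrioSpec]
    outdir: str = "triohet_out"
    seed: int = 0
    alpha: float = de.DEFAULT_ALPHA
    lfc: float = de.DEFAULT_LFC_MIN
    enrich_alpha: float = enrichment.ENRICH_ALPHA
    method: str = "exact"
    traits: str | None = None
    trait_roles: dict | None = None  # {hybrid: name, parents: [p1, p2]}
    terms: str | None = None
    enrich_category: str = patterns.CATEGORY_TRANS_UP

    def __post_init__(self) -> None:
        if not self.trios:
            raise TriohetError("config needs at least one trio")
        if not (0 < self.alpha < 1) or self.lfc < 0 or not (0 < self.enrich_alpha < 1):
            raise TriohetError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        trios = [TrioSpec(**t) for t in raw.pop("trios")]
        return cls(trios=trios, **raw)


def _commit(path: Path) -> Path:
    """Promote a .partial file written by a successful stage."""
    final = path.with_suffix("")
    path.replace(final)
    return final


def _load_trio(spec: TrioSpec, base_seed: int, index: int) -> CountMatrix:
    if (spec.counts is None) == (spec.simulate is None):
        raise TriohetError(f"trio {spec.name!r}: give exactly one of counts/simulate")
    if spec.counts is not None:
        return read_counts_tsv(spec.counts)
    sim_kwargs = dict(spec.simulate)
    sim_kwargs.setdefault("seed", base_seed + index)
    cfg = simulate.TrioSimConfig(**sim_kwargs)
    cm, _ = simulate.generate_trio_counts(cfg)
    return cm


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "triohet",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "lfc": config.lfc,
            "enrich_alpha": config.enrich_alpha,
            "method": config.method,
        },
        "trios": [t.name for t in config.trios],
        "outputs": [],
    }
    classifications: dict[str, patterns.TrioClassification] = {}

    for i, spec in enumerate(config.trios):
        stage = f"classify[{spec.name}]"
        try:
            cm = _load_trio(spec, config.seed, i)
            if spec.simulate is not None:
                p = out / f"{spec.name}.counts.tsv.partial"
                write_counts_tsv(cm, p, comments=[f"seed={config.seed + i}"])
                manifest["outputs"].append(str(_commit(p)))
            fpkm = compute_fpkm(cm)
            p = out / f"{spec.name}.fpkm.tsv.partial"
            write_fpkm_tsv(fpkm, p)
            manifest["outputs"].append(str(_commit(p)))
            corr, flags = sample_correlation(fpkm)
            p = out / f"{spec.name}.qc.json.partial"
            write_qc_report(corr, flags, p)
            manifest["outputs"].append(str(_commit(p)))

            cls = patterns.classify_all(
                cm, spec.roles, alpha=config.alpha, lfc_min=config.lfc,
                method=config.method,
            )
            classifications[spec.name] = cls
            for cname, table in cls.contrasts.items():
                p = out / f"{spec.name}.de.{cname}.tsv.partial"
                table.to_csv(p, sep="\t", float_format="%.6g")
                manifest["outputs"].append(str(_commit(p)))
            p = out / f"{spec.name}.assignments.tsv.partial"
            cls.assignments.to_csv(p, sep="\t")
            manifest["outputs"].append(str(_commit(p)))
            p = out / f"{spec.name}.summary.json.partial"
            p.write_text(json.dumps(cls.summary, indent=2) + "\n")
            manifest["outputs"].append(str(_commit(p)))
        except Exception as exc:  # noqa: BLE001 - stage names the failure
            raise StageError(stage, exc) from exc

    if len(classifications) >= 2:
        try:
            names = list(classifications)
            common = patterns.common_degs(
                classifications[names[0]].assignments,
                classifications[names[1]].assignments,
            )
            p = out / "common_degs.json.partial"
            p.write_text(json.dumps(common, indent=2) + "\n")
            manifest["outputs"].append(str(_commit(p)))
        except Exception as exc:
            raise StageError("common_degs", exc) from exc

    if config.traits is not None:
        try:
            troles = config.trait_roles or {}
            table = pd.read_csv(config.traits, sep="\t", comment="#")
            het = heterosis.heterosis_table(
                table,
                hybrid=troles["hybrid"],
                parents=tuple(troles["parents"]),
                better=troles.get("better"),
            )
            p = out / "heterosis.tsv.partial"
            het.to_csv(p, sep="\t", float_format="%.6g")
            manifest["outputs"].append(str(_commit(p)))
        except Exception as exc:
            raise StageError("heterosis", exc) from exc

    if config.terms is not None:
        try:
            term_map = enrichment.read_term_map_tsv(config.terms)
            first = next(iter(classifications.values()))
            assign = first.assignments
            universe = set(assign.index)
            de_set = set(assign.index[assign["category"] == config.enrich_category])
            if de_set:
                res = enrichment.fisher_enrich(
                    de_set, universe, term_map, alpha=config.enrich_alpha
                )
                p = out / "enrichment.tsv.partial"
                res.to_csv(p, sep="\t", index=False, float_format="%.6g")
                manifest["outputs"].append(str(_commit(p)))
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    p = out / "manifest.json.partial"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _commit(p)
    return manifest
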