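"""Synthetic data with planted ground truth for every pipeline stage.

Three generators:

* :func:`generate_trio_counts` — a maternal/hybrid/paternal count matrix with
  genes planted in known expression categories. Baseline per-gene expression
  rates are log-normal (heavy-tailed, like real expression spreads); planted
  genes shift the per-sample means on the log2 scale by ``effect_log2fc``;
  counts are negative binomial with a user dispersion (0 = Poisson). Each
  library's expected total is scaled to ``depth_per_library``.
* :func:`generate_trait_table` — plant-level trait replicates per genotype and
  block, normal(mean, SD) per trait.
* :func:`generate_term_map` — random gene-to-term memberships with one planted
  term over-represented in a designated gene set by a chosen factor.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .expression import CountMatrix

CATEGORY_KEYS = (
    "null",
    "additivity",
    "dominance_maternal",
    "dominance_paternal",
    "transgressive_up",
    "transgressive_down",
)

#: Expected sign triples (s_pp, s_hm, s_hp) per planted category; "high"
#: applies when the randomized elevated parent is the maternal one.
_TRUTH_SIGNS = {
    ("null", True): (0, 0, 0),
    ("additivity", True): (1, -1, 1),
    ("additivity", False): (-1, 1, -1),
    ("dominance_maternal", True): (1, 0, 1),
    ("dominance_maternal", False): (-1, 0, -1),
    ("dominance_paternal", True): (1, -1, 0),
    ("dominance_paternal", False): (-1, 1, 0),
    ("transgressive_up", True): (0, 1, 1),
    ("transgressive_down", True): (0, -1, -1),
}


def _default_fractions() -> dict[str, float]:
    # mostly-null genome with a few percent planted effects, echoing the
    # small patterned fraction seen in real hybrid transcriptomes
    return {
        "null": 0.97,
        "additivity": 0.01,
        "dominance_maternal": 0.005,
        "dominance_paternal": 0.005,
        "transgressive_up": 0.005,
        "transgressive_down": 0.005,
    }


@dataclass(frozen=True)
class TrioSimConfig:
    """Parameters of the trio count simulation.

    depth_per_library is the expected total count per sample; real libraries
    run to tens of millions of reads — the default of one million is that
    design scaled down. dispersion is the negative-binomial overdispersion
    (variance = mu + dispersion * mu^2); 0 gives Poisson counts.
    effect_log2fc must clear the DE fold-change gate (|log2FC| >= 1) to be
    recoverable. Baseline rates are log-normal with the given log-scale sigma.
    """

    n_genes: int = 20_000
    depth_per_library: float = 1_000_000.0
    dispersion: float = 0.05
    effect_log2fc: float = 2.0
    category_fractions: dict[str, float] = field(default_factory=_default_fractions)
    gene_length_range: tuple[int, int] = (200, 5_000)
    baseline_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if self.depth_per_library <= 0:
            raise InvalidConfigError("depth_per_library must be positive")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.effect_log2fc < 0:
            raise InvalidConfigError("effect_log2fc must be >= 0")
        unknown = set(self.category_fractions) - set(CATEGORY_KEYS)
        if unknown:
            raise InvalidConfigError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"category fractions sum to {total}, not 1")
        if any(f < 0 for f in self.category_fractions.values()):
            raise InvalidConfigError("category fractions must be >= 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("gene_length_range must be a positive interval")

    def with_(self, **kwargs) -> "TrioSimConfig":
        return replace(self, **kwargs)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_trio_counts(config: TrioSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a maternal/hybrid/paternal count matrix with planted patterns.

    Returns the matrix and a per-gene truth table with columns ``category``,
    ``maternal_high`` (which parent got the elevated level, where relevant)
    and the expected sign triple ``s_pp/s_hm/s_hp``.

    Mean construction per planted category (b = baseline rate, d = effect):
    additivity — parents at b*2^(±d/2), hybrid at their arithmetic mean;
    dominance — parents separated by d, hybrid equal to the named parent;
    transgressive — parents equal at b, hybrid at b*2^(±d); null — all b.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    cats = rng.choice(
        CATEGORY_KEYS,
        size=n,
        p=[config.category_fractions.get(k, 0.0) for k in CATEGORY_KEYS],
    )
    maternal_high = rng.random(n) < 0.5
    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )

    half = 2.0 ** (config.effect_log2fc / 2.0)
    full = 2.0 ** config.effect_log2fc
    mu = np.tile(baseline[:, None], (1, 3)).astype(float)  # maternal, hybrid, paternal

    hi_parent = np.where(maternal_high, 0, 2)
    lo_parent = np.where(maternal_high, 2, 0)
    idx = np.arange(n)

    sel = cats == "additivity"
    mu[idx[sel], hi_parent[sel]] = baseline[sel] * half
    mu[idx[sel], lo_parent[sel]] = baseline[sel] / half
    mu[sel, 1] = (mu[idx[sel], 0] + mu[idx[sel], 2]) / 2.0

    for dom_cat, dom_col in (("dominance_maternal", 0), ("dominance_paternal", 2)):
        sel = cats == dom_cat
        mu[idx[sel], hi_parent[sel]] = baseline[sel] * half
        mu[idx[sel], lo_parent[sel]] = baseline[sel] / half
        mu[sel, 1] = mu[idx[sel], dom_col]

    sel = cats == "transgressive_up"
    mu[sel, 1] = baseline[sel] * full
    sel = cats == "transgressive_down"
    mu[sel, 1] = baseline[sel] / full

    # scale each library's expected total to the configured depth
    mu *= config.depth_per_library / mu.sum(axis=0, keepdims=True)
    counts = _nb_draw(rng, mu, config.dispersion)

    gene_ids = pd.Index([f"gene{i:06d}" for i in range(n)], name="gene_id")
    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=gene_ids, columns=["maternal", "hybrid", "paternal"],
            dtype=np.int64,
        ),
        lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
    )
    signs = np.array(
        [
            _TRUTH_SIGNS[(c, True if c in ("null", "transgressive_up", "transgressive_down") else mh)]
            for c, mh in zip(cats, maternal_high)
        ],
        dtype=np.int8,
    )
    truth = pd.DataFrame(
        {
            "category": cats,
            "maternal_high": maternal_high,
            "s_pp": signs[:, 0],
            "s_hm": signs[:, 1],
            "s_hp": signs[:, 2],
        },
        index=gene_ids,
    )
    return cm, truth


def generate_trait_table(
    genotypes: list[tuple[str, dict[str, float], dict[str, float]]],
    n_plants: int = 10,
    n_blocks: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant-level trait table: normal(mean, SD) draws per genotype and block.

    ``genotypes`` is a list of (name, trait->mean, trait->SD). n_plants is per
    block; the default 10 plants x 3 blocks mirrors a replicated field trial.
    """
    if n_plants < 2:
        raise InvalidConfigError("n_plants must be >= 2 (t-tests undefined below)")
    if n_blocks < 1:
        raise InvalidConfigError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    trait_names = list(genotypes[0][1])
    rows = []
    for name, means, sds in genotypes:
        if set(means) != set(trait_names) or set(sds) != set(trait_names):
            raise InvalidConfigError(f"genotype {name!r}: trait keys differ")
        if any(s < 0 for s in sds.values()):
            raise InvalidConfigError(f"genotype {name!r}: negative SD")
        for blk in range(1, n_blocks + 1):
            draws = {
                t: rng.normal(means[t], sds[t], size=n_plants) for t in trait_names
            }
            for plant in range(1, n_plants + 1):
                row = {"genotype": name, "block": blk, "plant": plant}
                row.update({t: draws[t][plant - 1] for t in trait_names})
                rows.append(row)
    return pd.DataFrame(rows)


def generate_term_map(
    n_genes: int,
    n_terms: int,
    planted_term_size: int,
    enrichment_factor: float,
    seed: int = 0,
    target_set_size: int | None = None,
    background_term_size: tuple[int, int] = (10, 100),
) -> tuple[dict[str, set[str]], str, set[str]]:
    """Random gene-to-term map with one planted enriched term.

    Returns ``(term_to_genes, planted_term_id, target_gene_set)``. Genes in
    the target set are ``enrichment_factor`` times as likely to be drawn into
    the planted term; factor 1 gives a null (uniform) draw.
    """
    if n_genes <= 0 or n_terms <= 0 or planted_term_size <= 0:
        raise InvalidConfigError("sizes must be positive")
    if planted_term_size > n_genes:
        raise InvalidConfigError("planted_term_size exceeds n_genes")
    if enrichment_factor < 1:
        raise InvalidConfigError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i:06d}" for i in range(n_genes)])
    if target_set_size is None:
        target_set_size = max(10, n_genes // 10)
    target = set(rng.choice(genes, size=min(target_set_size, n_genes), replace=False))

    weights = np.where(np.isin(genes, list(target)), enrichment_factor, 1.0)
    weights = weights / weights.sum()
    planted = set(rng.choice(genes, size=planted_term_size, replace=False, p=weights))

    term_to_genes: dict[str, set[str]] = {"TERM_PLANTED": planted}
    lo, hi = background_term_size
    for t in range(1, n_terms):
        size = int(rng.integers(lo, min(hi, n_genes) + 1))
        term_to_genes[f"TERM{t:04d}"] = set(rng.choice(genes, size=size, replace=False))
    return term_to_genes, "TERM_PLANTED", target
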