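import numpy as np
import pytest
from scipy import stats

from triohet import (
    TrioSimConfig,
    generate_term_map,
    generate_trait_table,
    generate_trio_counts,
    mph,
)
from triohet.enrichment import fisher_enrich
from triohet.errors import InvalidConfigError
from triohet.expression import write_counts_tsv


class TestTrioSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            TrioSimConfig(n_genes=0)
        with pytest.raises(InvalidConfigError):
            TrioSimConfig(depth_per_library=0)
        with pytest.raises(InvalidConfigError):
            TrioSimConfig(category_fractions={"null": 0.9})  # sums to 0.9
        with pytest.raises(InvalidConfigError):
            TrioSimConfig(category_fractions={"null": 0.5, "bogus": 0.5})
        with pytest.raises(InvalidConfigError):
            TrioSimConfig(dispersion=-0.1)


class TestTrioCounts:
    def test_deterministic_byte_for_byte(self, tmp_path):
        cfg = TrioSimConfig(n_genes=500, depth_per_library=5e4, seed=7)
        payloads = []
        for run in range(2):
            cm, _ = generate_trio_counts(cfg)
            path = tmp_path / f"run{run}.tsv"
            write_counts_tsv(cm, path)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]

    def test_truth_labels_complete(self):
        cfg = TrioSimConfig(n_genes=1000, depth_per_library=1e5, seed=1)
        cm, truth = generate_trio_counts(cfg)
        assert len(truth) == cm.n_genes
        assert truth["category"].isin(
            [
                "null",
                "additivity",
                "dominance_maternal",
                "dominance_paternal",
                "transgressive_up",
                "transgressive_down",
            ]
        ).all()

    def test_category_proportions_match_fractions(self):
        fracs = {
            "null": 0.7,
            "additivity": 0.1,
            "dominance_maternal": 0.05,
            "dominance_paternal": 0.05,
            "transgressive_up": 0.05,
            "transgressive_down": 0.05,
        }
        cfg = TrioSimConfig(
            n_genes=20_000, depth_per_library=2e5, category_fractions=fracs, seed=3
        )
        _, truth = generate_trio_counts(cfg)
        obs = truth["category"].value_counts(normalize=True)
        for cat, f in fracs.items():
            # ~5 sigma multinomial sampling band
            tol = 5 * np.sqrt(f * (1 - f) / 20_000)
            assert abs(obs[cat] - f) < tol

    def test_planted_effect_realized_in_counts(self):
        """Mean log2 hybrid/maternal ratio over transgressive-up genes hits
        the planted effect within 0.1 at depth 1e6.

        Planted fractions stay at the defaults' percent scale: each library is
        scaled to a common depth, so a large one-sided planted fraction would
        shift every normalized ratio (composition bias) — real mixtures behave
        the same way."""
        fracs = {"null": 0.99, "transgressive_up": 0.01}
        fracs = {**{k: 0.0 for k in ("additivity", "dominance_maternal",
                                     "dominance_paternal", "transgressive_down")},
                 **fracs}
        cfg = TrioSimConfig(
            n_genes=4000, depth_per_library=1e6, dispersion=0.0,
            effect_log2fc=2.0, category_fractions=fracs, seed=5,
        )
        cm, truth = generate_trio_counts(cfg)
        up = truth["category"] == "transgressive_up"
        lib = cm.library_sizes
        norm = cm.counts / lib
        ratio = np.log2(
            (norm["hybrid"][up.values] + 1e-9) / (norm["maternal"][up.values] + 1e-9)
        )
        assert abs(ratio.mean() - 2.0) < 0.1

    def test_library_depth_close_to_target(self):
        cfg = TrioSimConfig(n_genes=2000, depth_per_library=1e5, seed=2)
        cm, _ = generate_trio_counts(cfg)
        np.testing.assert_allclose(cm.library_sizes.to_numpy(), 1e5, rtol=0.05)


class TestTraitTable:
    def test_zero_sd_equals_means(self):
        genos = [("A", {"x": 5.0, "y": 2.0}, {"x": 0.0, "y": 0.0})]
        table = generate_trait_table(genos, n_plants=4, n_blocks=2, seed=0)
        assert (table["x"] == 5.0).all() and (table["y"] == 2.0).all()
        assert len(table) == 8

    def test_reproducible_for_fixed_seed(self):
        genos = [("A", {"x": 5.0}, {"x": 1.0}), ("B", {"x": 7.0}, {"x": 1.0})]
        t1 = generate_trait_table(genos, n_plants=3, n_blocks=1, seed=11)
        t2 = generate_trait_table(genos, n_plants=3, n_blocks=1, seed=11)
        assert t1.equals(t2)

    def test_too_few_plants_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_trait_table([("A", {"x": 1.0}, {"x": 0.0})], n_plants=1)

    def test_law_of_large_numbers_mph(self):
        """Sample MPH from simulated plants converges to the closed form."""
        genos = [
            ("p1", {"NSP": 77.8}, {"NSP": 9.0}),
            ("p2", {"NSP": 107.0}, {"NSP": 8.1}),
            ("f1", {"NSP": 145.3}, {"NSP": 11.1}),
        ]
        table = generate_trait_table(genos, n_plants=10_000, n_blocks=1, seed=4)
        means = table.groupby("genotype")["NSP"].mean()
        est = mph(means["f1"], means["p1"], means["p2"])
        assert est == pytest.approx(57.25, abs=0.5)


class TestTermMap:
    def test_full_coverage_term_not_enriched(self):
        tm, planted, target = generate_term_map(
            n_genes=50, n_terms=3, planted_term_size=50, enrichment_factor=2.0, seed=0
        )
        assert len(tm[planted]) == 50
        universe = {f"gene{i:06d}" for i in range(50)}
        res = fisher_enrich(target, universe, {planted: tm[planted]})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_oversized_term_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_term_map(10, 2, 11, 1.0)
        with pytest.raises(InvalidConfigError):
            generate_term_map(10, 2, 5, 0.5)

    def test_reproducible_for_fixed_seed(self):
        a = generate_term_map(200, 10, 30, 3.0, seed=9)
        b = generate_term_map(200, 10, 30, 3.0, seed=9)
        assert a[0] == b[0] and a[2] == b[2]

    def test_null_factor_gives_uniform_p(self):
        """With enrichment_factor 1 the planted term's p is ~Uniform(0,1)."""
        universe = {f"gene{i:06d}" for i in range(300)}
        pvals = []
        for seed in range(300):
            tm, planted, target = generate_term_map(
                n_genes=300, n_terms=1, planted_term_size=30,
                enrichment_factor=1.0, seed=seed, target_set_size=40,
            )
            res = fisher_enrich(target, universe, {planted: tm[planted]})
            pvals.append(res["p"].iloc[0])
        # hypergeometric p is discrete and conservative; empirical CDF must
        # not exceed uniform at common levels
        pvals = np.asarray(pvals)
        for a in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= a).mean() < a + 4 * np.sqrt(a * (1 - a) / 300)
        assert pvals.mean() > 0.4
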