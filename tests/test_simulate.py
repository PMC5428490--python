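import numpy as np
import pandas as pd
import pytest

from heterosis import (
    MotifPattern,
    RelationConfig,
    SimulationConfig,
    classify_transcriptome,
    read_expression,
    scan_sequence,
    simulate_pathways,
    simulate_promoters,
    simulate_trio,
    write_expression,
)
from heterosis.errors import ConfigError


class TestSimulateTrio:
    def test_bit_identical_for_identical_seeds(self):
        xs1, t1 = simulate_trio(SimulationConfig(n_genes=50, seed=5))
        xs2, t2 = simulate_trio(SimulationConfig(n_genes=50, seed=5))
        assert np.array_equal(xs1.values, xs2.values)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        xs3, _ = simulate_trio(SimulationConfig(n_genes=50, seed=6))
        assert not np.array_equal(xs1.values, xs3.values)

    def test_zero_noise_recovers_every_planted_class(self):
        cfg = SimulationConfig(n_genes=300, noise_cv=0.0, seed=1)
        xs, truth = simulate_trio(cfg)
        records, _ = classify_transcriptome(xs, RelationConfig())
        got = np.array([r.class_id for r in records])
        assert np.array_equal(got, truth.genes["class_id"].to_numpy())

    def test_planted_counts_are_bookkept(self):
        cfg = SimulationConfig(n_genes=400, seed=9)
        xs, truth = simulate_trio(cfg)
        assert len(truth.genes) == 400
        assert set(truth.genes["class_id"]) <= set(range(1, 9))
        # planted group means respect the class templates exactly
        s = cfg.separation
        cls1 = truth.genes[truth.genes["class_id"] == 1]
        lp = np.minimum(cls1["mean_pA"], cls1["mean_pB"])
        hp = np.maximum(cls1["mean_pA"], cls1["mean_pB"])
        assert np.allclose(hp, s * s * lp)
        assert np.allclose(cls1["mean_H"], s * lp)

    def test_nonadditive_truth_follows_templates(self):
        _, truth = simulate_trio(SimulationConfig(n_genes=500, seed=3))
        g = truth.genes
        # class 4 is additive by construction; every other template departs from MPV
        assert not g.loc[g["class_id"] == 4, "nonadditive"].any()
        assert g.loc[g["class_id"] != 4, "nonadditive"].all()

    def test_round_trips_through_io(self, tmp_path):
        xs, _ = simulate_trio(SimulationConfig(n_genes=30, seed=4))
        write_expression(xs, tmp_path / "m.tsv", tmp_path / "d.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "d.tsv")
        assert back.gene_ids == xs.gene_ids
        assert np.array_equal(back.values, xs.values)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(class_proportions=(0.5, 0.5, 0, 0, 0, 0, 0, 0.1))
        with pytest.raises(ConfigError):
            SimulationConfig(separation=1.5)  # below the fold threshold


class TestSimulatePromoters:
    def test_planted_positions_all_recovered(self):
        cfg = SimulationConfig(n_promoters=60, motif_rate=0.6, seed=8)
        promoters, truth = simulate_promoters(cfg)
        planted = truth.promoters[truth.promoters["planted"]]
        assert len(planted) > 0
        for row in planted.itertuples():
            hits = scan_sequence(promoters.records[row.gene_id], cfg.motif)
            assert (row.start, row.strand) in {(h.start, h.strand) for h in hits}

    def test_clean_background_presence_equals_planting_record(self):
        cfg = SimulationConfig(n_promoters=80, motif_rate=0.5, seed=12)
        promoters, truth = simulate_promoters(cfg)
        for row in truth.promoters.itertuples():
            has = bool(scan_sequence(promoters.records[row.gene_id], cfg.motif))
            assert has == row.planted

    def test_spurious_rate_matches_analytic_probability(self):
        """Unscrubbed background: the AW-box has 5 constrained positions, so a
        random window matches a given strand with probability 4^-5; expected
        hits over all windows and both strands follow."""
        cfg = SimulationConfig(
            n_promoters=400, motif_rate=0.0, promoter_length=200,
            clean_background=False, seed=15,
        )
        promoters, _ = simulate_promoters(cfg)
        n_hits = sum(len(scan_sequence(s, cfg.motif)) for s in promoters.records.values())
        windows = cfg.n_promoters * (cfg.promoter_length - len(cfg.motif) + 1)
        expected = windows * 2 * 0.25**5
        assert abs(n_hits - expected) < 5 * np.sqrt(expected)

    def test_deterministic_and_seed_sensitive(self):
        p1, _ = simulate_promoters(SimulationConfig(n_promoters=10, seed=2))
        p2, _ = simulate_promoters(SimulationConfig(n_promoters=10, seed=2))
        p3, _ = simulate_promoters(SimulationConfig(n_promoters=10, seed=3))
        assert p1.records == p2.records
        assert p1.records != p3.records


class TestSimulatePathways:
    def _truth(self, seed=7, n=400):
        _, truth = simulate_trio(SimulationConfig(n_genes=n, seed=seed))
        return truth

    def test_requires_genes(self):
        from heterosis import TruthTable

        cfg = SimulationConfig(pathway_spec=(("p", 10, 0.5),))
        with pytest.raises(ConfigError):
            simulate_pathways(cfg, TruthTable())

    def test_size_zero_pathway_rejected(self):
        truth = self._truth()
        cfg = SimulationConfig(n_genes=400, pathway_spec=(("p", 0, 0.5),))
        with pytest.raises(ConfigError, match="infeasible"):
            simulate_pathways(cfg, truth)

    def test_rate_one_limited_by_nonadditive_pool(self):
        truth = self._truth()
        n_na = int(truth.genes["nonadditive"].sum())
        cfg = SimulationConfig(n_genes=400, pathway_spec=(("p", n_na + 1, 1.0),))
        with pytest.raises(ConfigError, match="exceeds"):
            simulate_pathways(cfg, truth)

    def test_rate_one_draws_only_nonadditive_genes(self):
        truth = self._truth()
        na = set(truth.genes.loc[truth.genes["nonadditive"], "gene_id"])
        cfg = SimulationConfig(n_genes=400, pathway_spec=(("p", 20, 1.0),))
        cat = simulate_pathways(cfg, truth)
        assert cat.pathways["p"] <= na

    def test_enrichment_flag_recorded(self):
        truth = self._truth()
        background = truth.genes["nonadditive"].mean()
        cfg = SimulationConfig(
            n_genes=400,
            pathway_spec=(("hot", 20, 0.95), ("null", 20, float(background))),
        )
        simulate_pathways(cfg, truth)
        flags = dict(zip(truth.pathways["name"], truth.pathways["enriched"]))
        assert flags == {"hot": True, "null": False}
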