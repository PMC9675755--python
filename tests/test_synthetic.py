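"""The synthetic-data generator: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from enhancersens import motif as motif_mod
from enhancersens import synthetic as syn
from enhancersens.synthetic import SimulationConfig, _nb_draw


@pytest.fixture(scope="module")
def tiny_config():
    return SimulationConfig(
        chrom_count=2,
        chrom_length=400_000,
        enhancers_per_group=10,
        n_background_sites=12,
        linked_genes_per_group=4,
        n_pool_genes=210,
    )


@pytest.fixture(scope="module")
def planted(tiny_config, ppre_pwm):
    genome = syn.generate_genome(tiny_config, seed=3)
    return syn.plant_enhancers(genome, ppre_pwm, tiny_config, seed=3)


class TestGenome:
    def test_deterministic(self, tiny_config):
        a = syn.generate_genome(tiny_config, seed=1)
        b = syn.generate_genome(tiny_config, seed=1)
        assert a.sequences == b.sequences
        c = syn.generate_genome(tiny_config, seed=2)
        assert c.sequences != a.sequences

    def test_lengths(self, tiny_config):
        g = syn.generate_genome(tiny_config, seed=1)
        assert g.lengths == {"chr1": 400_000, "chr2": 400_000}

    def test_gc_fraction_near_half(self):
        cfg = SimulationConfig(chrom_count=1, chrom_length=1_000_000)
        g = syn.generate_genome(cfg, seed=5)
        s = g.sequences["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.5) < 0.01  # ~20 binomial sigmas


class TestPlanting:
    def test_zero_mismatch_config_gives_consensus(self, tiny_config, ppre_pwm):
        cfg = SimulationConfig(
            **{
                **tiny_config.__dict__,
                "mismatches": {
                    g: {"ext5": 0, "ppar_hs": 0, "rxr_hs": 0}
                    for g in [*syn.TARGET_GROUPS, "nontarget"]
                },
            }
        )
        genome = syn.generate_genome(cfg, seed=1)
        _, truth = syn.plant_enhancers(genome, ppre_pwm, cfg, seed=1)
        assert (truth.enhancers["motif"] == ppre_pwm.consensus).all()

    def test_truth_reproducible(self, tiny_config, ppre_pwm):
        g = syn.generate_genome(tiny_config, seed=3)
        _, t1 = syn.plant_enhancers(g, ppre_pwm, tiny_config, seed=3)
        _, t2 = syn.plant_enhancers(g, ppre_pwm, tiny_config, seed=3)
        pd.testing.assert_frame_equal(t1.enhancers, t2.enhancers)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_motifs_written_into_genome(self, planted, ppre_pwm):
        genome, truth = planted
        L = ppre_pwm.length
        for _, e in truth.enhancers.head(20).iterrows():
            start = e["center"] - L // 2
            assert genome.sequences[e["chrom"]][start : start + L] == e["motif"]

    def test_hinge_groups_have_stronger_ext5(self, planted, ppre_pwm):
        # recompute segment scores from the planted strings themselves
        _, truth = planted
        lo = motif_mod.logodds(ppre_pwm)

        def ext5(seq):
            return sum(lo["ACGT".index(b), i] for i, b in enumerate(seq[:4]))

        scores = truth.enhancers.set_index("enhancer_id").apply(
            lambda e: ext5(e["motif"]), axis=1
        )
        grp = truth.enhancers.set_index("enhancer_id")["group"]
        strong = scores[grp.isin(["R212Q_only", "dual"])].mean()
        weak = scores[grp == "insensitive"].mean()
        assert strong > weak

    def test_capacity_error(self, ppre_pwm):
        cfg = SimulationConfig(chrom_count=1, chrom_length=50_000)
        genome = syn.generate_genome(cfg, seed=1)
        with pytest.raises(ValueError, match="too small"):
            syn.plant_enhancers(genome, ppre_pwm, cfg, seed=1)

    def test_mutant_rates_follow_penalties(self, planted, tiny_config):
        _, truth = planted
        e = truth.enhancers
        for group, pen in tiny_config.penalties.items():
            sub = e[e["group"] == group]
            if len(sub) == 0:
                continue
            assert np.allclose(sub["PPARg_E379K"], sub["PPARg_WT"] * pen["E379K"])
            assert np.allclose(sub["PPARg_R212Q"], sub["PPARg_WT"] * pen["R212Q"])


class TestNbDraw:
    def test_poisson_limit_variance(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(20_000, 50.0), dispersion=1e-12)
        assert np.mean(draws) == pytest.approx(50.0, rel=0.02)
        assert np.var(draws) == pytest.approx(50.0, rel=0.05)

    def test_overdispersion(self):
        rng = np.random.default_rng(1)
        m, d = 50.0, 0.1
        draws = _nb_draw(rng, np.full(50_000, m), dispersion=d)
        assert np.var(draws) == pytest.approx(m + d * m * m, rel=0.05)


class TestChipTags:
    def test_deterministic(self, planted, tiny_config):
        _, truth = planted
        a = syn.simulate_chip_tags(truth, "PPARg", "WT", 1, tiny_config, seed=4)
        b = syn.simulate_chip_tags(truth, "PPARg", "WT", 1, tiny_config, seed=4)
        for c in a.positions:
            assert np.array_equal(a.positions[c], b.positions[c])

    def test_control_receptor_track_background_only(self, planted, tiny_config):
        _, truth = planted
        t = syn.simulate_chip_tags(truth, "PPARg", "control", 1, tiny_config, seed=4)
        # no enhancer-centered excess: window counts comparable to background
        win = 500
        bg_per_win = tiny_config.chip_background_rate * win
        counts = [
            t.count(e["chrom"], e["center"] - 250, e["center"] + 250)
            for _, e in truth.enhancers.iterrows()
        ]
        assert np.mean(counts) == pytest.approx(bg_per_win, rel=0.35)

    def test_planted_fold_recovered(self, planted, tiny_config):
        _, truth = planted
        e0 = truth.enhancers.iloc[0]
        mu = e0["PPARg_WT"]
        obs = []
        for rep in range(200):
            t = syn.simulate_chip_tags(truth, "PPARg", "WT", rep, tiny_config, seed=6)
            obs.append(t.count(e0["chrom"], e0["center"] - 250, e0["center"] + 250))
        bg = tiny_config.chip_background_rate * 500
        expected = mu + bg
        sd = np.std(obs) / np.sqrt(len(obs))
        assert abs(np.mean(obs) - expected) < 4 * sd + 0.05 * expected

    def test_unknown_assay_rejected(self, planted, tiny_config):
        _, truth = planted
        with pytest.raises(ValueError):
            syn.simulate_chip_tags(truth, "CTCF", "WT", 1, tiny_config, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_chip_tags(truth, "PPARg", "S383R", 1, tiny_config, seed=1)


class TestAtac:
    def test_length_filter_keeps_sub_component(self, planted, tiny_config):
        _, truth = planted
        frags = syn.simulate_atac(truth, "control", 1, tiny_config, seed=2)
        kept = frags[frags["length"] <= 120]
        assert len(kept) > 0
        # both mixture components are present in the raw output
        assert (frags["length"] > 150).sum() > 0
        # the filtered set is essentially the sub-nucleosomal component:
        # its mean matches N(70, 25) truncated at 120 (~68.4), far from the
        # mono mode at 180; mono leakage below 120 is ~0.13% of that component
        assert kept["length"].mean() == pytest.approx(68.4, abs=3.0)

    def test_closed_sites_fewer_nucfree_fragments(self, planted, tiny_config):
        _, truth = planted
        frags = syn.simulate_atac(truth, "control", 1, tiny_config, seed=2)
        t = syn.atac_track(frags, truth.chrom_lengths, "control", 1)
        e = truth.enhancers
        def mean_count(sub):
            return np.mean(
                [t.count(r["chrom"], r["center"] - 250, r["center"] + 250) for _, r in sub.iterrows()]
            )
        closed = mean_count(e[~e["accessible"]])
        open_ = mean_count(e[e["accessible"] & (e["group"] != "nontarget")])
        assert closed < open_

    def test_deterministic(self, planted, tiny_config):
        _, truth = planted
        a = syn.simulate_atac(truth, "WT", 2, tiny_config, seed=5)
        b = syn.simulate_atac(truth, "WT", 2, tiny_config, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestExpression:
    def test_dual_gene_penalty_arithmetic(self, planted, tiny_config):
        _, truth = planted
        g = truth.genes
        linked = g[g["linked_enhancer"] != ""].merge(
            truth.enhancers[["enhancer_id", "group"]],
            left_on="linked_enhancer",
            right_on="enhancer_id",
        )
        dual = linked[linked["group"] == "dual"]
        pen = tiny_config.penalties["dual"]["E379K"]
        assert np.allclose(dual["expr_E379K"] / dual["expr_WT"], pen)

    def test_deterministic(self, planted, tiny_config):
        _, truth = planted
        a = syn.simulate_expression(truth, "WT", tiny_config, seed=8)
        b = syn.simulate_expression(truth, "WT", tiny_config, seed=8)
        assert np.array_equal(a.counts, b.counts)

    def test_null_conditions_exchangeable(self, planted, tiny_config):
        # pool genes have identical means in every condition: per-gene fold
        # between control and WT should be centered at zero
        _, truth = planted
        a = syn.simulate_expression(truth, "control", tiny_config, seed=9)
        b = syn.simulate_expression(truth, "WT", tiny_config, seed=9)
        pool = truth.genes["linked_enhancer"] == ""
        fa = a.counts[pool.to_numpy()].mean(axis=1)
        fb = b.counts[pool.to_numpy()].mean(axis=1)
        l2fc = np.log2((fb + 0.5) / (fa + 0.5))
        assert abs(np.mean(l2fc)) < 0.05
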