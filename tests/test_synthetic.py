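import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipoplacenta import (SimulationConfig, assign_groups, go_enrichment,
                           simulate_annotation, simulate_anthropometrics,
                           simulate_counts, simulate_network, simulate_qpcr,
                           simulate_reference, small_config)
from adipoplacenta import io as apio


class TestConfigValidation:
    def test_planted_classes_must_fit(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_shared_concordant=5,
                             n_shared_discordant=5, n_le_unique=5,
                             n_ob_unique=5).validate()

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=0.0).validate()


class TestCounts:
    def test_default_group_sizes_match_study_design(self):
        md = simulate_anthropometrics(SimulationConfig(seed=3))
        sizes = md.groupby(["maternal_group", "adiposity_class"]).size()
        assert sizes[("LE", "LA")] == 20
        assert sizes[("LE", "HA")] == 19
        assert sizes[("OB", "LA")] == 20
        assert sizes[("OB", "HA")] == 20

    def test_no_planted_effects_means_all_null(self):
        cfg = small_config(seed=1, n_shared_concordant=0,
                           n_shared_discordant=0, n_le_unique=0,
                           n_ob_unique=0)
        _, _, truth = simulate_counts(cfg)
        assert set(truth.gene_class.values()) == {"null"}
        assert all(v == 0 for v in truth.log2fc_le.values())
        assert all(v == 0 for v in truth.log2fc_ob.values())

    def test_seeded_determinism(self):
        cfg = small_config(seed=42)
        c1, m1, t1 = simulate_counts(cfg)
        c2, m2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.gene_class == t2.gene_class

    def test_poisson_limit_mean(self):
        # tiny dispersion, unit depth, fixed baseline 100, no effects:
        # per-gene sample means should sit within 3 standard errors of 100
        cfg = SimulationConfig(
            n_per_group=(50, 50, 50, 50), n_mid_per_stratum=(0, 0),
            n_genes=30, n_shared_concordant=0, n_shared_discordant=0,
            n_le_unique=0, n_ob_unique=0, dispersion=1e-6,
            depth_range=(1.0, 1.0), baseline_log_mean=np.log(100.0),
            baseline_log_sd=0.0, sex_effect_fraction=0.0, seed=5)
        counts, md, _ = simulate_counts(cfg)
        n = counts.shape[1]
        assert n == 200
        se = np.sqrt(100.0 / n)
        means = counts.mean(axis=1)
        assert (np.abs(means - 100.0) < 3 * se + 1e-9).mean() > 0.95

    def test_nb_mean_variance_relation(self):
        # many samples per cell: empirical variance tracks mu + alpha mu^2
        alpha = 0.5
        cfg = SimulationConfig(
            n_per_group=(5000, 0, 0, 0), n_mid_per_stratum=(5000, 0),
            n_genes=5, n_shared_concordant=0, n_shared_discordant=0,
            n_le_unique=0, n_ob_unique=0, dispersion=alpha,
            depth_range=(1.0, 1.0), baseline_log_mean=np.log(80.0),
            baseline_log_sd=0.0, sex_effect_fraction=0.0, seed=7)
        counts, _, _ = simulate_counts(cfg)
        m = counts.mean(axis=1).to_numpy()
        v = counts.var(axis=1, ddof=1).to_numpy()
        expected = m + alpha * m ** 2
        assert np.all(np.abs(v - expected) / expected < 0.1)

    def test_naive_estimator_recovers_planted_log2fc(self):
        cfg = small_config(seed=9, n_per_group=(20, 20, 20, 20))
        counts, md, truth = simulate_counts(cfg)
        le = md[md["maternal_group"] == "LE"]
        la = le.loc[le["adiposity_class"] == "LA", "sample_id"]
        ha = le.loc[le["adiposity_class"] == "HA", "sample_id"]
        est = np.log2(counts[ha].mean(axis=1) + 0.5) - np.log2(
            counts[la].mean(axis=1) + 0.5)
        planted = [g for g, c in truth.gene_class.items()
                   if truth.log2fc_le[g] != 0]
        err = np.abs(est[planted].to_numpy()
                     - np.array([truth.log2fc_le[g] for g in planted]))
        assert err.mean() < 0.3


class TestAnthropometrics:
    def test_tertile_split_recovers_intended_labels(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            md = simulate_anthropometrics(SimulationConfig(seed=seed))
            assigned = assign_groups(md)
            intended_ha = set(md.loc[md["adiposity_class"] == "HA",
                                     "sample_id"])
            got_ha = set(assigned.loc[assigned["adiposity_class"] == "HA",
                                      "sample_id"])
            hits += intended_ha == got_ha
        assert hits / n_seeds >= 0.95

    def test_pct_fat_spans_realistic_range(self):
        md = simulate_anthropometrics(SimulationConfig(seed=2))
        assert md["pct_body_fat"].min() >= 5.0
        assert md["pct_body_fat"].max() <= 21.0
        assert md["pct_body_fat"].max() - md["pct_body_fat"].min() > 6.0

    def test_positive_anthropometrics(self):
        md = simulate_anthropometrics(SimulationConfig(seed=4))
        for col in ("birth_weight_kg", "length_cm", "flank_skinfold_mm",
                    "pregravid_bmi"):
            assert (md[col] > 0).all()


class TestAnnotation:
    def test_designated_set_contains_shared_genes(self):
        cfg = small_config(seed=6)
        _, _, truth = simulate_counts(cfg)
        sets = simulate_annotation(cfg, truth)
        assert len(sets) >= 5
        designated = sets["PLANTED_SHARED_RESPONSE"]
        shared = set(truth.shared_genes)
        frac = len(designated & shared) / len(shared)
        assert frac >= cfg.annotation_fraction - 0.05

    def test_designated_set_is_detectable_by_ora(self):
        cfg = small_config(seed=6)
        _, _, truth = simulate_counts(cfg)
        sets = simulate_annotation(cfg, truth)
        res = go_enrichment(set(truth.shared_genes),
                            set(truth.gene_class), sets)
        top = res.iloc[0]
        assert top["term_id"] == "PLANTED_SHARED_RESPONSE"
        assert top["p_hypergeometric"] < 0.05

    def test_no_designated_set_without_shared_genes(self):
        cfg = small_config(seed=6, n_shared_concordant=0,
                           n_shared_discordant=0)
        _, _, truth = simulate_counts(cfg)
        sets = simulate_annotation(cfg, truth)
        assert "PLANTED_SHARED_RESPONSE" not in sets

    def test_seeded_determinism(self):
        cfg = small_config(seed=8)
        _, _, truth = simulate_counts(cfg)
        assert simulate_annotation(cfg, truth) == simulate_annotation(cfg,
                                                                      truth)


class TestNetworkGenerator:
    def test_clique_nodes_have_clique_degree(self):
        cfg = small_config(seed=10)
        _, _, truth = simulate_counts(cfg)
        edges = simulate_network(cfg, truth)
        deg = pd.concat([edges["node1"], edges["node2"]]).value_counts()
        clique_genes = deg[deg >= cfg.clique_size - 1]
        assert len(clique_genes) >= cfg.clique_size

    def test_zero_background_density_gives_pure_clique(self):
        cfg = small_config(seed=10, edge_density=0.0, clique_size=6)
        _, _, truth = simulate_counts(cfg)
        edges = simulate_network(cfg, truth)
        assert len(edges) == 6 * 5 // 2

    def test_oversized_clique_rejected(self):
        cfg = small_config(seed=10, clique_size=100)
        _, _, truth = simulate_counts(cfg)
        with pytest.raises(ValueError):
            simulate_network(cfg, truth)

    def test_seeded_determinism(self):
        cfg = small_config(seed=12)
        _, _, truth = simulate_counts(cfg)
        pd.testing.assert_frame_equal(simulate_network(cfg, truth),
                                      simulate_network(cfg, truth))


class TestReferenceGenerator:
    def test_designated_type_is_argmax_for_planted_genes(self):
        cfg = small_config(seed=13)
        _, _, truth = simulate_counts(cfg)
        ref = simulate_reference(cfg, truth)
        argmax = ref[truth.shared_genes].idxmax(axis=0)
        assert (argmax == "Neutrophil").mean() >= 0.9

    def test_seeded_determinism(self):
        cfg = small_config(seed=14)
        _, _, truth = simulate_counts(cfg)
        pd.testing.assert_frame_equal(simulate_reference(cfg, truth),
                                      simulate_reference(cfg, truth))


class TestQpcrGenerator:
    def test_zero_noise_gives_perfect_monotone_map(self):
        cfg = small_config(seed=15, qpcr_noise_sd=0.0)
        counts, md, truth = simulate_counts(cfg)
        gene = counts.index[0]
        ct = simulate_qpcr(cfg, counts, target_genes=[gene])
        tgt = ct[ct["gene"] == gene].set_index("sample_id")["ct"]
        libsize = counts.sum(axis=0)
        sf = libsize / np.exp(np.mean(np.log(libsize)))
        norm = np.log2(counts.loc[gene] / sf + 1.0)
        rho, _ = stats.spearmanr(-tgt[norm.index], norm)
        assert rho == pytest.approx(1.0)

    def test_large_noise_attenuates_correlation(self):
        rhos = []
        for seed in range(5):
            cfg = small_config(seed=seed, qpcr_noise_sd=50.0)
            counts, _, _ = simulate_counts(cfg)
            gene = counts.index[0]
            ct = simulate_qpcr(cfg, counts, target_genes=[gene])
            tgt = ct[ct["gene"] == gene].set_index("sample_id")["ct"]
            rho, _ = stats.spearmanr(-tgt.to_numpy(),
                                     counts.loc[gene].to_numpy())
            rhos.append(abs(rho))
        assert np.mean(rhos) < 0.5

    def test_seeded_determinism(self):
        cfg = small_config(seed=16)
        counts, _, _ = simulate_counts(cfg)
        pd.testing.assert_frame_equal(simulate_qpcr(cfg, counts),
                                      simulate_qpcr(cfg, counts))


class TestRoundTrips:
    def test_counts_tsv_and_mtx(self, tmp_path, small_sim):
        _, counts, _, _ = small_sim
        p = tmp_path / "counts.tsv"
        apio.write_counts_tsv(counts, str(p))
        pd.testing.assert_frame_equal(apio.read_counts_tsv(str(p)), counts)
        m = tmp_path / "counts.mtx"
        apio.write_counts_mtx(counts, str(m))
        back = apio.read_counts_mtx(str(m))
        assert (back.to_numpy() == counts.to_numpy()).all()
        assert list(back.index) == list(counts.index)
        assert list(back.columns) == list(counts.columns)

    def test_metadata_gmt_edges_reference_ct(self, tmp_path, small_sim):
        cfg, counts, md, truth = small_sim
        p = tmp_path / "md.csv"
        apio.write_metadata_csv(md, str(p))
        back = apio.read_metadata_csv(str(p))
        assert list(back["sample_id"]) == list(md["sample_id"])

        sets = simulate_annotation(cfg, truth)
        g = tmp_path / "sets.gmt"
        apio.write_gmt(sets, str(g))
        assert apio.read_gmt(str(g)) == sets

        edges = simulate_network(cfg, truth)
        e = tmp_path / "edges.tsv"
        apio.write_edges_tsv(edges, str(e))
        back_e = apio.read_edges_tsv(str(e))
        assert len(back_e) == len(edges)

        ref = simulate_reference(cfg, truth)
        r = tmp_path / "ref.tsv"
        apio.write_reference_tsv(ref, str(r))
        pd.testing.assert_frame_equal(apio.read_reference_tsv(str(r)), ref)

        ct = simulate_qpcr(cfg, counts)
        c = tmp_path / "ct.csv"
        apio.write_ct_csv(ct, str(c))
        back_ct = apio.read_ct_csv(str(c))
        assert np.allclose(back_ct["ct"], ct["ct"])
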