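"""The generators plant exactly the structure they claim to plant."""

import numpy as np
import pandas as pd
import pytest

import cispairs as cp
from cispairs.synth import GeneratorError


def pairwise_tss_distances(annotation):
    """Brute-force all lncRNA x coding TSS distances (None across chromosomes)."""
    t = annotation.tss_table()
    lnc = t[t.biotype == "lncRNA"]
    cod = t[t.biotype == "coding"]
    out = {}
    for _, a in lnc.iterrows():
        for _, b in cod.iterrows():
            d = (
                abs(int(a.tss) - int(b.tss))
                if a.chromosome == b.chromosome
                else None
            )
            out[(a.transcript_id, b.transcript_id)] = d
    return out


class TestAnnotation:
    def test_planted_pair_count_and_divergence(self, annotation, default_config):
        planted = annotation.truth["planted_pairs"]
        assert len(planted) == default_config.n_planted_pairs
        for p in planted:
            lnc = annotation.get(p["lnc_id"])
            mrna = annotation.get(p["mrna_id"])
            assert lnc.chromosome == mrna.chromosome
            assert abs(lnc.tss - mrna.tss) == p["distance"] < default_config.planted_max_distance
            assert cp.classify_orientation(lnc, mrna) == "divergent"

    def test_decoy_spacing_by_exhaustive_scan(self, annotation, default_config):
        planted = {
            frozenset((p["lnc_id"], p["mrna_id"]))
            for p in annotation.truth["planted_pairs"]
        }
        threshold = default_config.planted_max_distance
        for (lnc_id, cod_id), d in pairwise_tss_distances(annotation).items():
            if frozenset((lnc_id, cod_id)) in planted:
                assert d is not None and d < threshold
            else:
                assert d is None or d >= threshold

    def test_coordinates_within_chromosomes(self, annotation, default_config):
        for r in annotation.records():
            assert 1 <= r.start < r.end <= default_config.chrom_sizes[r.chromosome]

    def test_determinism(self, default_config):
        a = cp.generate_annotation(default_config)
        b = cp.generate_annotation(GeneratorConfig_copy(default_config))
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.truth == b.truth

    def test_chromosome_too_small_names_it(self):
        cfg = cp.GeneratorConfig(seed=0, chrom_sizes={"chrTiny": 100_000})
        with pytest.raises(GeneratorError, match="chrTiny"):
            cp.generate_annotation(cfg)

    def test_planted_exceeding_gene_counts_rejected(self):
        with pytest.raises(GeneratorError):
            cp.GeneratorConfig(n_coding=2, n_lnc=5, n_planted_pairs=3)


def GeneratorConfig_copy(cfg):
    return cp.GeneratorConfig(seed=cfg.seed)


class TestArrayExperiment:
    def test_noiseless_ratio_is_exact(self, default_config):
        cfg = cp.GeneratorConfig(seed=default_config.seed, noise_sd=0.0)
        ann = cp.generate_annotation(cfg)
        mat = cp.generate_array_experiment(ann, cfg)
        groups = mat.conditions()
        for lnc_id in mat.truth["lnc_up"]:
            probes = [p for p, f in mat.probe_map.items() if f == lnc_id]
            sub = mat.values.loc[probes]
            ratio = sub[groups["treated"]].mean(axis=1) / sub[groups["control"]].mean(axis=1)
            assert np.allclose(ratio, cfg.lnc_fc)
        for mrna_id in mat.truth["mrna_down"]:
            probes = [p for p, f in mat.probe_map.items() if f == mrna_id]
            sub = mat.values.loc[probes]
            ratio = sub[groups["control"]].mean(axis=1) / sub[groups["treated"]].mean(axis=1)
            assert np.allclose(ratio, cfg.mrna_fc)

    def test_monte_carlo_planted_ratio_at_defaults(self):
        # 50 planted lncRNAs at default noise: empirical mean ratio near 2.5
        cfg = cp.GeneratorConfig(seed=7, n_coding=50, n_lnc=50, n_planted_pairs=50)
        ann = cp.generate_annotation(cfg)
        mat = cp.generate_array_experiment(ann, cfg)
        groups = mat.conditions()
        ratios = []
        for lnc_id in mat.truth["lnc_up"]:
            probes = [p for p, f in mat.probe_map.items() if f == lnc_id]
            sub = mat.values.loc[probes]
            ratios.append(
                float(
                    sub[groups["treated"]].mean(axis=1).mean()
                    / sub[groups["control"]].mean(axis=1).mean()
                )
            )
        assert abs(np.mean(ratios) - cfg.lnc_fc) / cfg.lnc_fc < 0.15

    def test_some_features_fall_below_floor(self, array_matrix):
        below = (array_matrix.values < 50.0).all(axis=1)
        assert below.any()

    def test_determinism(self, annotation, default_config, array_matrix):
        again = cp.generate_array_experiment(annotation, default_config)
        pd.testing.assert_frame_equal(array_matrix.values, again.values)


class TestPairedCohort:
    def test_null_correlation(self):
        cfg = cp.GeneratorConfig(seed=5, cohort_n=5000, target_r=0.0)
        coh = cp.generate_paired_cohort(cfg)
        r = np.corrcoef(coh.tumor_a, coh.tumor_b)[0, 1]
        assert abs(r) < 0.05

    def test_planted_negative_correlation_at_large_n(self):
        cfg = cp.GeneratorConfig(seed=5, cohort_n=5000, target_r=-0.27)
        coh = cp.generate_paired_cohort(cfg)
        r = np.corrcoef(coh.tumor_a, coh.tumor_b)[0, 1]
        assert abs(r - (-0.27)) < 0.05

    def test_noiseless_ratios_exact(self):
        cfg = cp.GeneratorConfig(seed=5, cohort_n=20, noise_sd=0.0)
        coh = cp.generate_paired_cohort(cfg)
        assert np.allclose(coh.tumor_a / coh.normal_a, cfg.cohort_up_fc)
        assert np.allclose(coh.normal_b / coh.tumor_b, cfg.cohort_down_fc)

    def test_invalid_target_r(self):
        with pytest.raises(GeneratorError):
            cp.GeneratorConfig(target_r=1.0)

    def test_smoker_count(self):
        cfg = cp.GeneratorConfig(seed=5)
        coh = cp.generate_paired_cohort(cfg)
        assert (coh.smoking == "smoker").sum() == round(cfg.smoker_fraction * cfg.cohort_n)


class TestSingleCell:
    def test_stratum_sizes_exact(self):
        spec = [cp.StratumSpec("AT2", "never", 200, -0.05), cp.StratumSpec("AT2", "smoker", 77, -0.09)]
        cells = cp.generate_single_cell(cp.GeneratorConfig(seed=2, strata_spec=spec))
        counts = cells.groupby(["cell_type", "exposure"]).size()
        assert counts[("AT2", "never")] == 200
        assert counts[("AT2", "smoker")] == 77

    def test_weak_negative_r_recovered(self):
        spec = [cp.StratumSpec("AT1", "never", 20000, -0.08)]
        cells = cp.generate_single_cell(cp.GeneratorConfig(seed=2, strata_spec=spec))
        r = np.corrcoef(cells.value_a, cells.value_b)[0, 1]
        assert abs(r - (-0.08)) < 0.02

    def test_positive_r_falls_back_to_shared_latent(self, caplog):
        import logging

        spec = [cp.StratumSpec("AT1", "never", 20000, 0.3)]
        with caplog.at_level(logging.WARNING, logger="cispairs.synth"):
            cells = cp.generate_single_cell(cp.GeneratorConfig(seed=2, strata_spec=spec))
        assert any("shared-latent" in m for m in caplog.messages)
        r = np.corrcoef(cells.value_a, cells.value_b)[0, 1]
        assert abs(r - 0.3) < 0.03

    def test_determinism(self):
        cfg1 = cp.GeneratorConfig(seed=9)
        cfg2 = cp.GeneratorConfig(seed=9)
        pd.testing.assert_frame_equal(
            cp.generate_single_cell(cfg1), cp.generate_single_cell(cfg2)
        )

    def test_empty_strata_rejected(self):
        with pytest.raises(GeneratorError):
            cp.generate_single_cell(cp.GeneratorConfig(seed=0, strata_spec=[]))
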