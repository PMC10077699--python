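"""Synthetic-data generator: determinism, planted structure, count models."""

import numpy as np
import pandas as pd
import pytest

from meripkit.annotation import scan_rrach
from meripkit.synthetic import (
    ConfigurationError,
    SimConfig,
    simulate_dataset,
    simulate_expression,
    simulate_merip_counts,
    simulate_transcriptome,
)


class TestConfig:
    def test_module_overcommit_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=100, n_modules=4, module_size=30).validate()

    def test_trait_corr_bound(self):
        with pytest.raises(ConfigurationError):
            SimConfig(trait_module_corr=1.0).validate()

    @pytest.mark.parametrize("field,value", [
        ("frac_methylated_genes", 1.5), ("nb_dispersion", -0.1), ("n_genes", 0),
    ])
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            SimConfig(**{field: value}).validate()


class TestTranscriptome:
    def test_deterministic_under_seed(self):
        a = simulate_transcriptome(SimConfig(n_genes=50, n_modules=1, module_size=10, seed=3))
        b = simulate_transcriptome(SimConfig(n_genes=50, n_modules=1, module_size=10, seed=3))
        assert a.sequences == b.sequences
        assert a.models.equals(b.models)
        assert [p.__dict__ for p in a.truth.planted_peaks] == \
               [p.__dict__ for p in b.truth.planted_peaks]

    def test_full_stop_codon_bias_places_sites_at_stop(self):
        cfg = SimConfig(n_genes=80, n_modules=2, module_size=10, frac_methylated_genes=1.0,
                        stop_codon_bias=1.0, stop_codon_window=50, seed=5)
        tx = simulate_transcriptome(cfg)
        for p in tx.truth.planted_peaks:
            l5, lc, _ = tx.truth.region_lengths[p.gene]
            mid = (p.tx_start + p.tx_end) // 2
            # 3 sigma of the half-window jitter, clipped into the transcript
            assert abs(mid - (l5 + lc)) <= 3 * cfg.stop_codon_window / 2 + cfg.peak_width

    def test_planted_sites_carry_rrach_for_scanner(self):
        tx = simulate_transcriptome(SimConfig(n_genes=100, n_modules=2, module_size=20, seed=9))
        assert tx.truth.planted_peaks
        for p in tx.truth.planted_peaks:
            tid = "tx_" + p.gene.split("_")[1]
            seq = tx.sequences[tid][p.tx_start:p.tx_end]
            hits = scan_rrach(seq)
            assert hits, f"no RRACH under planted site of {p.gene}"
            mid = (p.tx_start + p.tx_end) // 2 - p.tx_start
            assert any(off == mid for off, _ in hits)

    def test_peaks_lie_within_gene_span(self):
        tx = simulate_transcriptome(SimConfig(n_genes=100, n_modules=2, module_size=20, seed=2))
        for p in tx.truth.planted_peaks:
            chrom, gs, ge = tx.truth.gene_spans[p.gene]
            assert p.chrom == chrom and gs <= p.start < p.end <= ge


class TestMeripCounts:
    def test_null_effect_log2_ratio_centers_on_zero(self):
        from meripkit.methylation import depth_matrix, differential_methylation
        cfg = SimConfig(n_genes=400, n_modules=2, module_size=20,
                        frac_methylated_genes=0.5, dm_log2fc=0.0,
                        nb_dispersion=0.02, seed=4)
        tx = simulate_transcriptome(cfg)
        m = simulate_merip_counts(tx.truth, cfg)
        assert all(p.group_effect == 0 for p in tx.truth.planted_peaks)
        planted_ids = [pid for pid, peak in zip(m.panel.ids, m.panel.peaks)
                       if any(p.chrom == peak.chrom and peak.start < p.end and
                              p.start < peak.end for p in tx.truth.planted_peaks)]
        depth = depth_matrix(m.ip_counts, m.input_counts, m.panel)
        groups = {c: ("High" if c.startswith("H") else "Low") for c in depth.columns}
        res = differential_methylation(depth, groups).loc[planted_ids]
        # center of the null log2FC distribution is 0 (robust statistics:
        # peaks with a near-zero floored mean produce huge-magnitude tails)
        assert abs(res["log2fc"].median()) < 0.1
        assert abs(res["log2fc"].clip(-1, 1).mean()) < 0.1
        assert res["significant"].mean() < 0.15

    def test_counts_near_analytic_means_at_low_dispersion(self):
        cfg = SimConfig(n_genes=300, n_modules=2, module_size=20, nb_dispersion=0.0,
                        mean_library_size=5_000_000, seed=6)
        tx = simulate_transcriptome(cfg)
        m = simulate_merip_counts(tx.truth, cfg)
        mu = m.expected_input_mu.to_numpy()
        obs = m.input_counts.to_numpy().astype(float)
        big = mu > 5000
        assert big.sum() > 100
        rel = np.abs(obs[big] - mu[big]) / mu[big]
        assert np.mean(rel) < 0.01

    def test_seed_changes_counts_not_schema(self):
        cfg1 = SimConfig(n_genes=100, n_modules=2, module_size=20, seed=1)
        cfg2 = SimConfig(n_genes=100, n_modules=2, module_size=20, seed=2)
        tx1, tx2 = simulate_transcriptome(cfg1), simulate_transcriptome(cfg2)
        m1 = simulate_merip_counts(tx1.truth, cfg1)
        m2 = simulate_merip_counts(tx2.truth, cfg2)
        assert list(m1.ip_counts.columns) == list(m2.ip_counts.columns)
        assert list(m1.sample_sheet.columns) == list(m2.sample_sheet.columns)
        assert not m1.ip_counts.reset_index(drop=True).equals(
            m2.ip_counts.reset_index(drop=True))

    def test_library_totals_equal_column_sums(self, small_dataset):
        m = small_dataset.merip
        sheet = m.sample_sheet.set_index(["role", "sample"])["total_reads"]
        for s in m.ip_counts.columns:
            assert sheet.loc[("IP", s)] == m.ip_counts[s].sum()
            assert sheet.loc[("input", s)] == m.input_counts[s].sum()

    def test_counts_nonnegative_integers(self, small_dataset):
        for df in (small_dataset.merip.ip_counts, small_dataset.merip.input_counts,
                   small_dataset.expression.counts):
            arr = df.to_numpy()
            assert (arr >= 0).all()
            assert np.issubdtype(arr.dtype, np.integer)


class TestExpression:
    def test_zero_noise_unit_loading_gives_perfect_latent_correlation(self):
        cfg = SimConfig(n_genes=120, n_modules=2, module_size=30,
                        expr_noise_sd=0.0, nb_dispersion=0.0, seed=8)
        tx = simulate_transcriptome(cfg)
        e = simulate_expression(tx.truth, cfg)
        mod1 = [g for g, m in tx.truth.module_assignment.items() if m == 1]
        lat = e.latent_log2_mu.loc[mod1].to_numpy()
        cors = np.corrcoef(lat)
        assert np.all(cors > 0.999)

    def test_trait_correlation_calibrated(self):
        # Monte-Carlo: mean sample correlation near the planted population value
        target = 0.9
        rs = []
        for seed in range(40):
            cfg = SimConfig(n_genes=60, n_modules=1, module_size=30,
                            trait_module_corr=target, seed=seed)
            tx = simulate_transcriptome(cfg)
            e = simulate_expression(tx.truth, cfg)
            f = e.module_factors.loc["module_1"]
            rs.append(np.corrcoef(f, e.traits["imf_pct"])[0, 1])
        assert abs(np.mean(rs) - target) < 0.1

    def test_trait_signs_opposite(self):
        rs1, rs2 = [], []
        for seed in range(20):
            cfg = SimConfig(n_genes=60, n_modules=1, module_size=30, seed=seed)
            tx = simulate_transcriptome(cfg)
            e = simulate_expression(tx.truth, cfg)
            f = e.module_factors.loc["module_1"]
            rs1.append(np.corrcoef(f, e.traits["imf_pct"])[0, 1])
            rs2.append(np.corrcoef(f, e.traits["m6a_ratio"])[0, 1])
        assert np.mean(rs1) > 0.3
        assert np.mean(rs2) < -0.2

    def test_traits_one_row_per_sample_no_missing(self, small_dataset):
        traits = small_dataset.expression.traits
        assert len(traits) == 2 * small_dataset.config.n_samples_per_group
        assert traits["sample"].is_unique
        assert not traits.isna().any().any()


def test_dataset_write_is_deterministic(tmp_path):
    cfg = SimConfig(n_genes=60, n_modules=2, module_size=20, seed=11)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_dataset(cfg, d1)
    simulate_dataset(cfg, d2)
    for name in ("transcripts.fa", "models.gtf", "peaks_high.bed", "peaks_low.bed",
                 "ip_counts.tsv", "input_counts.tsv", "expr_counts.tsv",
                 "traits.tsv", "truth.json", "peak_panel.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
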