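"""Simulator behaviour: generative invariants, downsampling, evaluation,
and agreement between the read-level and composition-level paths."""

import numpy as np
import pytest

from umicall.filters import FilterConfig
from umicall.model import call_locus
from umicall.pileup import write_vcf
from umicall.simulate import (
    SimConfig,
    simulate_locus_indices,
    simulate_pileups,
    simulate_truth,
    downsample_barcodes,
    downsample_rpb,
    evaluate_calls,
    normalize_variant,
)

ERROR_FREE = dict(first_cycle_error_rate=0.0, later_cycle_error_rate=0.0, phred_q=60)


class TestSimulateTruth:
    def test_zero_variants(self):
        truth = simulate_truth(SimConfig(region_length=500), n_snv=0)
        assert truth.variants == []
        assert len(truth.reference) == 500

    def test_deterministic_under_seed(self):
        cfg = SimConfig(region_length=5000)
        t1 = simulate_truth(cfg, n_snv=20, n_indel=5, seed=11)
        t2 = simulate_truth(cfg, n_snv=20, n_indel=5, seed=11)
        assert t1.reference == t2.reference
        assert t1.variants == t2.variants

    def test_spacing_and_capacity(self):
        cfg = SimConfig(region_length=10_000)
        truth = simulate_truth(cfg, n_snv=100, min_spacing=50, seed=1)
        positions = sorted(v.pos for v in truth.variants)
        assert len(positions) == 100
        assert min(b - a for a, b in zip(positions, positions[1:])) >= 50
        with pytest.raises(ValueError, match="cannot hold"):
            simulate_truth(SimConfig(region_length=400), n_snv=100, min_spacing=50)

    def test_indel_alleles_well_formed(self):
        cfg = SimConfig(region_length=5000)
        truth = simulate_truth(cfg, n_snv=0, n_indel=10, seed=2)
        for v in truth.variants:
            assert v.alt[0] in "+-"
            assert 1 <= len(v.alt) - 1 <= 10
            if v.alt[0] == "-":
                assert truth.reference[v.pos : v.pos + len(v.alt) - 1] == v.alt[1:]


class TestSimulatePileups:
    def test_error_free_alt_fraction(self):
        cfg = SimConfig(region_length=100, allele_fraction=0.5,
                        mean_barcode_depth=800, rpb_mean=2.0, **ERROR_FREE)
        truth = simulate_truth(cfg, n_snv=1, seed=5)
        (v,) = truth.variants
        (pu,) = simulate_pileups(truth, cfg, positions=[v.pos], seed=6)
        alt_fams = sum(
            1 for f in pu.families if f.observations[0].allele == v.alt
        )
        n = pu.barcode_depth
        assert abs(alt_fams / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_no_errors_no_noise(self):
        cfg = SimConfig(region_length=50, allele_fraction=0.0,
                        mean_barcode_depth=100, rpb_mean=3.0, **ERROR_FREE)
        truth = simulate_truth(cfg, n_snv=0, seed=7)
        pileups = simulate_pileups(truth, cfg, positions=range(1, 11), seed=8)
        for pu in pileups:
            for fam in pu.families:
                assert all(o.allele == pu.ref for o in fam.observations)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(region_length=100, allele_fraction=0.05,
                        mean_barcode_depth=50, rpb_mean=3.0)
        truth = simulate_truth(cfg, n_snv=1, seed=9)
        a = simulate_pileups(truth, cfg, positions=[1, 2], seed=10)
        b = simulate_pileups(truth, cfg, positions=[1, 2], seed=10)
        canon = lambda pus: [
            [(f.barcode, [(o.allele, o.phred_q, o.strand) for o in f.observations])
             for f in pu.families]
            for pu in pus
        ]
        assert canon(a) == canon(b)

    def test_rpb_distribution_mean_and_floor(self):
        cfg = SimConfig(region_length=50, mean_barcode_depth=2000, rpb_mean=8.6)
        truth = simulate_truth(cfg, n_snv=0, seed=1)
        (pu,) = simulate_pileups(truth, cfg, positions=[1], seed=2)
        sizes = np.array([len(f) for f in pu.families])
        assert sizes.min() >= 1
        assert abs(sizes.mean() - 8.6) < 3 * sizes.std() / np.sqrt(sizes.size)


class TestDownsampling:
    def _pileups(self, n_fam=10_000, rpb=4.0):
        cfg = SimConfig(region_length=50, mean_barcode_depth=n_fam, rpb_mean=rpb)
        truth = simulate_truth(cfg, n_snv=0, seed=3)
        return simulate_pileups(truth, cfg, positions=[1], seed=4)

    def test_fraction_one_is_identity(self):
        pus = self._pileups(n_fam=200)
        out = downsample_barcodes(pus, 1.0, seed=5)
        assert [f.barcode for f in out[0].families] == [
            f.barcode for f in pus[0].families
        ]

    def test_binomial_thinning(self):
        pus = self._pileups()
        out = downsample_barcodes(pus, 0.5, seed=6)
        kept = out[0].barcode_depth
        n = pus[0].barcode_depth
        assert abs(kept - 0.5 * n) < 3 * np.sqrt(n * 0.25)

    def test_thinning_deterministic(self):
        pus = self._pileups(n_fam=500)
        a = downsample_barcodes(pus, 0.3, seed=7)
        b = downsample_barcodes(pus, 0.3, seed=7)
        assert [f.barcode for f in a[0].families] == [f.barcode for f in b[0].families]

    def test_rpb_target_mean_within_five_percent(self):
        pus = self._pileups(rpb=8.0)
        out = downsample_rpb(pus, 2.0, seed=8)
        sizes = [len(f) for f in out[0].families]
        assert min(sizes) >= 1
        assert abs(np.mean(sizes) - 2.0) / 2.0 < 0.05

    def test_rpb_near_one_collapses_families(self):
        pus = self._pileups(rpb=8.0)
        out = downsample_rpb(pus, 1.1, seed=9)
        sizes = np.array([len(f) for f in out[0].families])
        assert (sizes == 1).mean() > 0.8

    def test_rpb_above_mean_rejected(self):
        pus = self._pileups(n_fam=100, rpb=2.0)
        with pytest.raises(ValueError, match="target rpb"):
            downsample_rpb(pus, 6.0)


class TestEvaluateCalls:
    def _truth(self, tmp_path, n=10):
        cfg = SimConfig(region_length=5000, allele_fraction=0.01)
        truth = simulate_truth(cfg, n_snv=n, seed=12)
        path = str(tmp_path / "truth.vcf")
        truth.to_vcf(path)
        return truth, path

    def test_perfect_calls(self, tmp_path):
        truth, tpath = self._truth(tmp_path)
        df = evaluate_calls(tpath, tpath, target_size=5000)
        row = df.iloc[0]
        assert row.sensitivity == 1.0 and row.fp_per_mb == 0.0 and row.ppv == 1.0

    def test_empty_calls(self, tmp_path):
        truth, tpath = self._truth(tmp_path)
        empty = simulate_truth(SimConfig(region_length=5000), n_snv=0)
        epath = str(tmp_path / "empty.vcf")
        empty.to_vcf(epath)
        df = evaluate_calls(epath, tpath, target_size=5000)
        row = df.iloc[0]
        assert row.sensitivity == 0.0 and row.fp_per_mb == 0.0 and row.tp == 0

    def test_fp_per_mb_unit_conversion(self, tmp_path):
        truth_empty = simulate_truth(SimConfig(region_length=1000), n_snv=0)
        tpath = str(tmp_path / "t.vcf")
        truth_empty.to_vcf(tpath)
        one_call = simulate_truth(SimConfig(region_length=1000), n_snv=1, seed=4)
        cpath = str(tmp_path / "c.vcf")
        one_call.to_vcf(cpath)
        df = evaluate_calls(cpath, tpath, target_size=1_000_000)
        assert df.iloc[0].fp_per_mb == pytest.approx(1.0)

    def test_zero_target_size_rejected(self, tmp_path):
        _, tpath = self._truth(tmp_path)
        with pytest.raises(ValueError):
            evaluate_calls(tpath, tpath, target_size=0)

    def test_normalization_trims_representation(self):
        assert normalize_variant("c", 10, "TCG", "TG") == ("c", 10, "TC", "T")
        assert normalize_variant("c", 10, "ATT", "GTT") == ("c", 10, "A", "G")


class TestErrorFreeLimit:
    def test_caller_recovers_all_variants_without_false_positives(self, tmp_path):
        """With all error rates at zero every variant with >= 10 expected
        alternative barcodes is recovered and no wild-type locus is called."""
        cfg = SimConfig(region_length=3000, allele_fraction=0.1,
                        mean_barcode_depth=200, rpb_mean=3.0, **ERROR_FREE)
        truth = simulate_truth(cfg, n_snv=5, n_indel=2, seed=13)
        variant_pos = [v.pos for v in truth.variants]
        wild_type = [p for p in range(1, 201) if p not in variant_pos]
        pileups = simulate_pileups(
            truth, cfg, positions=sorted(variant_pos + wild_type), seed=14
        )
        calls = [call_locus(pu, threshold=14.0) for pu in pileups]
        called_pos = {c.pos for c in calls if c.candidate_alleles}
        assert called_pos == set(variant_pos)
        # and the called alleles are the truth alleles
        by_pos = truth.by_pos()
        for c in calls:
            if c.candidate_alleles:
                assert c.candidate_alleles == [by_pos[c.pos].alt]

    def test_alt_fraction_estimator_unbiased(self):
        cfg = SimConfig(region_length=100, allele_fraction=0.3,
                        mean_barcode_depth=500, rpb_mean=2.0, **ERROR_FREE)
        truth = simulate_truth(cfg, n_snv=1, seed=15)
        (v,) = truth.variants
        fractions = []
        for seed in range(10):
            (pu,) = simulate_pileups(truth, cfg, positions=[v.pos], seed=20 + seed)
            call = call_locus(pu, threshold=5.0)
            fractions.append(call.consensus_counts.get(v.alt, 0) / call.n_barcodes)
        mean_f = np.mean(fractions)
        sem = np.sqrt(0.3 * 0.7 / (500 * 10))
        assert abs(mean_f - 0.3) < 3 * sem


class TestCompositionScan:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(allele_fraction=0.02, mean_barcode_depth=200, rpb_mean=4.0)
        a = simulate_locus_indices(50, cfg, seed=30)
        b = simulate_locus_indices(50, cfg, seed=30)
        assert np.array_equal(a.index, b.index)
        assert np.array_equal(a.strong, b.strong)

    def test_agrees_with_read_level_pipeline(self):
        """The composition path and the read-level path draw from the same
        generative distributions: mean prediction index of the truth allele
        must agree within sampling error."""
        cfg = SimConfig(region_length=10_000, allele_fraction=0.1,
                        mean_barcode_depth=150, rpb_mean=3.0)
        scan = simulate_locus_indices(400, cfg, seed=31)
        scan_mean = scan.index[:, 0].mean()
        scan_sem = scan.index[:, 0].std() / np.sqrt(scan.index.shape[0])

        truth = simulate_truth(cfg, n_snv=60, seed=32)
        pileups = simulate_pileups(
            truth, cfg, positions=[v.pos for v in truth.variants], seed=33
        )
        by_pos = truth.by_pos()
        indices = []
        for pu in pileups:
            call = call_locus(pu, threshold=1.0)
            indices.append(call.prediction_index.get(by_pos[pu.pos].alt, 0.0))
        read_mean = np.mean(indices)
        read_sem = np.std(indices) / np.sqrt(len(indices))
        assert abs(scan_mean - read_mean) < 3.5 * np.hypot(scan_sem, read_sem)

    def test_wild_type_scan_is_quiet(self):
        cfg = SimConfig(allele_fraction=0.0, mean_barcode_depth=500, rpb_mean=4.0)
        scan = simulate_locus_indices(2000, cfg, seed=34)
        assert scan.alt_families.sum() == 0
        # background indices stay far below any realistic cutoff
        assert scan.index.max() < 14.0
        assert not scan.candidates(14.0).any()

    def test_passing_applies_strong_barcode_filter(self):
        cfg = SimConfig(allele_fraction=0.02, mean_barcode_depth=400, rpb_mean=6.0)
        scan = simulate_locus_indices(60, cfg, seed=35)
        threshold = 14.0
        passing = scan.passing(threshold, seed=36)
        cands = scan.candidates(threshold)
        assert (passing & ~cands).sum() == 0  # passing is a subset of candidates
        mismatch = FilterConfig(strong_barcode_min_evidence=3.0)
        with pytest.raises(ValueError, match="tau"):
            scan.passing(threshold, filter_config=mismatch)
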