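import numpy as np
import pytest

from mmplocus.accessibility import (
    DifferentialPeakClassifier,
    PeakSet,
    annotate_peaks,
    consensus_peaks,
    differential_peaks,
    hypergeom_upper_tail,
    normalize_counts,
    representation_factor,
    tss_delta_profiles,
    windowed_enrichment,
)
from mmplocus.genome import ElementAnnotation, GeneAnnotation, GenomicInterval
from mmplocus.simulate import SimulationConfig, simulate_peaksets, synthetic_anchor


def iv(start, end, chrom="chr1", strand=".", name=None):
    return GenomicInterval(chrom, start, end, strand, name)


def peakset(peaks, wt, dis):
    return PeakSet(peaks, {"wt": np.asarray(wt), "disrupted": np.asarray(dis)})


class TestConsensusPeaks:
    def test_identical_replicates_return_input(self):
        lst = [iv(0, 100), iv(200, 300)]
        assert consensus_peaks([lst, list(lst), list(lst)]) == lst

    def test_disjoint_replicates_empty(self):
        assert consensus_peaks([[iv(0, 10)], [iv(20, 30)]]) == []

    def test_one_of_three_shared(self):
        r1 = [iv(0, 10), iv(100, 110), iv(200, 210)]
        r2 = [iv(5, 15)]
        r3 = [iv(0, 8), iv(500, 510)]
        assert consensus_peaks([r1, r2, r3]) == [iv(0, 10)]

    def test_min_overlap_threshold(self):
        r1 = [iv(0, 10)]
        r2 = [iv(9, 20)]
        assert consensus_peaks([r1, r2], min_overlap_bp=1) == [iv(0, 10)]
        assert consensus_peaks([r1, r2], min_overlap_bp=2) == []

    def test_empty_replicate_warns(self):
        with pytest.warns(UserWarning):
            assert consensus_peaks([[iv(0, 10)], []]) == []


class TestNormalizeCounts:
    def test_unit_library_is_identity_up_to_log(self):
        counts = np.array([[10**6, 10**6]], dtype=int)  # library total = 1e6
        ps = peakset([iv(0, 100)], counts, counts)
        out = normalize_counts(ps)
        assert out["wt"][0, 0] == pytest.approx(np.log2(10**6 + 1))

    def test_scaling_a_replicate_is_invariant(self):
        wt = np.array([[10, 20], [30, 40], [60, 140]])
        ps1 = peakset([iv(0, 1), iv(2, 3), iv(4, 5)], wt, wt)
        ps2 = peakset([iv(0, 1), iv(2, 3), iv(4, 5)], wt * 2, wt)
        assert np.allclose(normalize_counts(ps1)["wt"], normalize_counts(ps2)["wt"])

    def test_all_zero_replicate_rejected(self):
        wt = np.array([[0, 5], [0, 5]])
        ps = peakset([iv(0, 1), iv(2, 3)], wt, wt + 1)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(ps)


class TestDifferentialPeaks:
    def test_unique_presence_branch(self):
        # ballast peak equalizes library sizes so CPM of the stable peak
        # is identical across conditions
        ps = peakset(
            [iv(0, 100), iv(200, 300), iv(400, 500)],
            [[5, 6, 7], [50, 50, 50], [945, 944, 943]],
            [[0, 0, 0], [50, 50, 50], [950, 950, 950]],
        )
        d = differential_peaks(ps)
        assert d.table.loc[0, "class"] == "lost"
        assert d.table.loc[0, "reason"] == "unique-presence"
        assert d.table.loc[1, "class"] == "unchanged"

    def test_identical_tables_no_differential(self):
        counts = [[50, 60, 55], [40, 45, 42]]
        ps = peakset([iv(0, 1), iv(2, 3)], counts, counts)
        d = differential_peaks(ps)
        assert (d.table["class"] == "unchanged").all()

    def test_every_peak_classified_exactly_once(self):
        cfg = SimulationConfig(seed=3, n_peaks=500)
        ps, _ = simulate_peaksets(cfg)
        d = differential_peaks(ps)
        assert len(d.table) == ps.n_peaks
        assert set(d.table["class"]) <= {"gained", "lost", "unchanged"}

    def test_replicate_column_order_is_irrelevant(self):
        cfg = SimulationConfig(seed=4, n_peaks=300)
        ps, _ = simulate_peaksets(cfg)
        shuffled = PeakSet(
            list(ps.peaks),
            {
                "wt": ps.counts["wt"][:, ::-1],
                "disrupted": ps.counts["disrupted"][:, ::-1],
            },
        )
        d1 = differential_peaks(ps)
        d2 = differential_peaks(shuffled)
        assert (d1.table["class"] == d2.table["class"]).all()

    def test_sensitivity_and_fdr_on_planted_truth(self):
        """Planted log2fc = 2 with 3 replicates: sensitive and FDR-controlled."""
        sens, fdr = [], []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_peaks=500, lfc_range=(2.0, 2.0))
            ps, truth = simulate_peaksets(cfg)
            d = differential_peaks(ps)
            called = d.is_differential
            truth_arr = truth["is_differential"].to_numpy()
            sens.append((called & truth_arr).sum() / max(truth_arr.sum(), 1))
            fdr.append((called & ~truth_arr).sum() / max(called.sum(), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdr) <= 0.1


class TestRepresentationFactor:
    def test_rf_arithmetic(self):
        rf, _ = representation_factor(5, 20, 10, 100)
        assert rf == pytest.approx(2.5)

    def test_rf_one_at_expectation(self):
        rf, _ = representation_factor(2, 20, 10, 100)
        assert rf == pytest.approx(1.0)

    def test_exact_tail_sum_example(self):
        from math import comb

        _, p = representation_factor(5, 20, 10, 100)
        expected = sum(
            comb(10, j) * comb(90, 20 - j) for j in range(5, 11)
        ) / comb(100, 20)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            representation_factor(5, 0, 10, 100)
        with pytest.raises(ValueError):
            representation_factor(11, 20, 10, 100)

    def test_vectorized_tail_matches_scalar(self):
        ks = np.arange(0, 8)
        vec = hypergeom_upper_tail(ks, 50, 10, 20)
        for k in ks[1:]:
            assert vec[k] == pytest.approx(
                representation_factor(int(k), 20, 10, 50)[1]
            )


class TestWindowedEnrichment:
    def test_no_differential_peaks_rejects_nothing(self):
        counts = [[50, 60, 55], [40, 45, 42], [30, 35, 33]]
        ps = peakset(
            [iv(0, 100), iv(5000, 5100), iv(9000, 9100)], counts, counts
        )
        d = differential_peaks(ps)
        res = windowed_enrichment(d, iv(5000, 5100), halfwidths=(1000, 4000))
        for r in res:
            assert r.k == 0 and r.p == 1.0

    def test_whole_chromosome_rf_is_exactly_one(self):
        cfg = SimulationConfig(seed=5, n_peaks=400)
        ps, _ = simulate_peaksets(cfg)
        d = differential_peaks(ps)
        res = windowed_enrichment(d, synthetic_anchor(cfg))
        control = res[-1]
        assert control.halfwidth is None
        assert control.rf == 1.0

    def test_windows_are_monotone_in_n(self):
        cfg = SimulationConfig(seed=6, n_peaks=800)
        ps, _ = simulate_peaksets(cfg)
        d = differential_peaks(ps)
        res = windowed_enrichment(d, synthetic_anchor(cfg))
        ns = [r.n for r in res]
        assert ns == sorted(ns)

    def test_planted_enrichment_recovered(self):
        cfg = SimulationConfig(seed=7)
        ps, _ = simulate_peaksets(cfg)
        d = differential_peaks(ps)
        res = windowed_enrichment(d, synthetic_anchor(cfg))
        innermost = res[0]
        assert innermost.halfwidth == 500_000
        assert 2.4 <= innermost.rf <= 3.6
        assert innermost.p < 0.01


class TestTssDeltaProfiles:
    def genes(self):
        return [
            GeneAnnotation(iv(1000, 3000, strand="+"), "gA", 1000, "5prime"),
            GeneAnnotation(iv(8000, 10000, strand="-"), "gB", 9999, "3prime"),
        ]

    def test_identical_conditions_give_zero_deltas(self):
        peaks = [iv(500, 1500), iv(9500, 10500)]
        counts = [[100, 110, 105], [200, 190, 195]]
        ps = peakset(peaks, counts, counts)
        table, summary = tss_delta_profiles(ps, self.genes())
        assert np.allclose(table.filter(like="bin_").to_numpy(), 0.0)
        assert np.allclose(table["mean_delta"], 0.0)

    def test_gene_without_peaks_flagged_zero(self):
        peaks = [iv(500, 1500)]
        ps = peakset(peaks, [[10, 12, 11]], [[30, 31, 32]])
        table, _ = tss_delta_profiles(ps, self.genes())
        row = table.set_index("gene_id").loc["gB"]
        assert row["mean_delta"] == 0.0
        assert not row["has_peaks"]

    def test_minus_strand_profile_is_reversed(self):
        # peak covers only the left half of the +/- windows
        genes = [
            GeneAnnotation(iv(4000, 6000, strand="+"), "gP", 5000, "5prime"),
            GeneAnnotation(iv(4000, 6000, strand="-"), "gM", 5000, "3prime"),
        ]
        peaks = [iv(3000, 5000)]
        ps = peakset(peaks, [[10, 10, 10]], [[40, 40, 40]])
        table, _ = tss_delta_profiles(ps, genes, flank=2000, n_bins=4)
        bins = [f"bin_{b}" for b in range(4)]
        prof = table.set_index("gene_id")[bins].astype(float)
        assert np.allclose(
            prof.loc["gP"].to_numpy()[::-1], prof.loc["gM"].to_numpy()
        )

    def test_planted_5prime_promoter_gain_detected(self):
        rng = np.random.default_rng(0)
        genes, peaks, wt, dis = [], [], [], []
        for i in range(6):  # 5' genes with gain
            tss = 10_000 + 20_000 * i
            genes.append(
                GeneAnnotation(iv(tss, tss + 2000, strand="+"), f"f{i}", tss, "5prime")
            )
            peaks.append(iv(tss - 500, tss + 500))
            base = rng.poisson(200, 3)
            wt.append(base)
            dis.append(base * 4)
        for i in range(6):  # 3' genes unchanged
            tss = 200_000 + 20_000 * i
            genes.append(
                GeneAnnotation(iv(tss, tss + 2000, strand="+"), f"t{i}", tss, "3prime")
            )
            peaks.append(iv(tss - 500, tss + 500))
            base = rng.poisson(200, 3)
            wt.append(base)
            dis.append(base)
        ps = peakset(peaks, wt, dis)
        _, summary = tss_delta_profiles(ps, genes)
        assert summary["mean_delta_5prime"] > summary["mean_delta_3prime"]
        assert summary["p_value"] < 0.05


class TestAnnotatePeaks:
    def elements(self):
        return [
            ElementAnnotation(iv(0, 100), "promoter"),
            ElementAnnotation(iv(50, 200), "enhancer"),
            ElementAnnotation(iv(300, 400), "insulator"),
        ]

    def make_diff(self, peaks):
        # every query peak is unique-presence lost; ballast keeps the
        # disrupted libraries non-empty
        ballast = iv(900_000, 900_100)
        n = len(peaks)
        wt = np.vstack([np.tile([5, 6, 7], (n, 1)), [[1000, 1000, 1000]]])
        dis = np.vstack([np.zeros((n, 3), int), [[1000, 1000, 1000]]])
        return differential_peaks(peakset(peaks + [ballast], wt, dis))

    def test_promoter_assignment(self):
        d = self.make_diff([iv(10, 40)])
        out = annotate_peaks(d, self.elements())
        assert out.set_index("element_class").loc["promoter", "n_peaks"] == 1

    def test_unmatched_peak_is_other(self):
        d = self.make_diff([iv(1000, 1100)])
        out = annotate_peaks(d, self.elements())
        assert out.set_index("element_class").loc["other", "n_peaks"] == 1

    def test_priority_promoter_over_enhancer(self):
        d = self.make_diff([iv(60, 90)])  # overlaps promoter and enhancer
        out = annotate_peaks(d, self.elements())
        tbl = out.set_index("element_class")["n_peaks"]
        assert tbl["promoter"] == 1 and tbl["enhancer"] == 0


class TestDifferentialPeakClassifier:
    def test_estimator_interface_and_fitted_attributes(self):
        from sklearn.base import clone

        cfg = SimulationConfig(seed=8, n_peaks=300)
        ps, _ = simulate_peaksets(cfg)
        est = DifferentialPeakClassifier(alpha_fdr=0.1)
        assert clone(est).get_params()["alpha_fdr"] == 0.1
        est.fit(ps)
        assert est.labels_.shape == (300,)
        enr = est.enrichment(synthetic_anchor(cfg), halfwidths=(500_000,))
        assert enr[-1].rf == 1.0
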