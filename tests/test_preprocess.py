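"""Calibration, normalization and clustering behavior."""

import numpy as np
import pytest

import pepticlass as pc
from pepticlass.errors import CalibrationError, NormalizationError

from conftest import toy_peaklist
from oracles import single_linkage_partition


def _reference_grid(n=30, lo=900.0, hi=3500.0, t_lo=20.0, t_hi=42.0):
    masses = np.linspace(lo, hi, n)
    times = np.linspace(t_lo, t_hi, n)
    return pc.ReferenceTable(ids=list(range(n)), masses=masses, ce_times=times)


def _sample_from(ref, time_map, extra=()):
    rows = [[m, time_map(t), 10.0] for m, t in zip(ref.masses, ref.ce_times)]
    rows += [list(r) for r in extra]
    return toy_peaklist("s", rows)


class TestCalibration:
    def test_identity_when_times_already_true(self):
        ref = _reference_grid()
        s = _sample_from(ref, lambda t: t)
        out, model = pc.calibrate_ce_time(s, ref)
        np.testing.assert_allclose(out.ce_time, s.ce_time, atol=1e-9)
        assert model.n_matched == 30
        assert model.max_residual < 1e-9

    def test_constant_shift_recovered_exactly(self):
        # local linear fits reproduce affine maps exactly at interior points
        ref = _reference_grid()
        s = _sample_from(ref, lambda t: t + 0.5)
        out, _ = pc.calibrate_ce_time(s, ref)
        np.testing.assert_allclose(out.ce_time, ref.ce_times, atol=1e-6)

    def test_affine_stretch_recovered(self):
        ref = _reference_grid()
        s = _sample_from(ref, lambda t: 1.03 * t - 0.8)
        out, _ = pc.calibrate_ce_time(s, ref)
        np.testing.assert_allclose(out.ce_time, ref.ce_times, atol=1e-6)

    def test_quadratic_drift_residuals_under_bound(self):
        # smooth drift with dense references: QC bound must hold
        ref = _reference_grid(n=60)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a, b, c = rng.normal(0, 0.3), rng.normal(1, 0.01), rng.normal(0, 0.001)
            s = _sample_from(ref, lambda t: a + b * t + c * (t - 30) ** 2)
            _, model = pc.calibrate_ce_time(s, ref)
            assert model.max_residual < 0.35

    def test_too_few_references_flagged(self):
        ref = _reference_grid(n=30)
        s = toy_peaklist("s", [[ref.masses[0], 20.0, 1.0]])
        with pytest.raises(CalibrationError, match="reference"):
            pc.calibrate_ce_time(s, ref)


class TestNormalization:
    def _hk(self, n=6):
        return pc.HousekeepingTable(
            ids=list(range(n)), masses=np.linspace(1000, 2000, n),
            ce_times=np.full(n, 25.0), reference_amplitudes=np.full(n, 10.0))

    def test_uniform_double_intensity_halves_everything(self):
        hk = self._hk()
        rows = [[m, 25.0, 20.0] for m in hk.masses] + [[2500.0, 30.0, 8.0]]
        s = toy_peaklist("s", rows)
        out = pc.normalize_amplitudes(s, hk)
        assert out.metadata["normalization_scale"] == pytest.approx(2.0)
        np.testing.assert_allclose(out.amplitude, np.array([10.0] * 6 + [4.0]))

    def test_median_of_ratios_is_the_scale(self):
        hk = self._hk(3)
        rows = [[hk.masses[0], 25.0, 10.0],   # ratio 1
                [hk.masses[1], 25.0, 20.0],   # ratio 2
                [hk.masses[2], 25.0, 40.0]]   # ratio 4
        s = toy_peaklist("s", rows)
        out = pc.normalize_amplitudes(s, hk)
        assert out.metadata["normalization_scale"] == pytest.approx(2.0)
        np.testing.assert_allclose(out.amplitude, [5.0, 10.0, 20.0])

    def test_unit_ratios_leave_sample_unchanged(self):
        hk = self._hk()
        rows = [[m, 25.0, 10.0] for m in hk.masses]
        s = toy_peaklist("s", rows)
        out = pc.normalize_amplitudes(s, hk)
        np.testing.assert_allclose(out.amplitude, s.amplitude)

    def test_too_few_housekeeping_detections_flagged(self):
        hk = self._hk(6)
        s = toy_peaklist("s", [[hk.masses[0], 25.0, 10.0], [hk.masses[1], 25.0, 10.0]])
        with pytest.raises(NormalizationError):
            pc.normalize_amplitudes(s, hk)

    def test_dilution_removed_on_synthetic_cohort(self, small_cohort):
        _, samples, truth = small_cohort
        for s in samples[:10]:
            cal, _ = pc.calibrate_ce_time(s, truth.reference_table)
            out = pc.normalize_amplitudes(cal, truth.housekeeping_table)
            est = out.metadata["normalization_scale"]
            # median-of-29 estimator error at housekeeping sd 0.1
            assert est == pytest.approx(truth.dilution[s.sample_id], rel=0.12)


class TestClustering:
    def test_within_both_tolerances_merges(self):
        s1 = toy_peaklist("a", [[2000.00, 20.0, 1.0]])
        s2 = toy_peaklist("b", [[2000.05, 20.1, 2.0]])  # 25 ppm, 0.1 min
        mat = pc.match_peptides([s1, s2])
        assert mat.n_peptides == 1
        np.testing.assert_allclose(mat.amplitudes, [[1.0], [2.0]])

    def test_mass_tolerance_exceeded_splits(self):
        s1 = toy_peaklist("a", [[2000.00, 20.0, 1.0]])
        s2 = toy_peaklist("b", [[2000.20, 20.0, 2.0]])  # 100 ppm
        mat = pc.match_peptides([s1, s2])
        assert mat.n_peptides == 2

    def test_ce_tolerance_exceeded_splits(self):
        s1 = toy_peaklist("a", [[2000.00, 20.0, 1.0]])
        s2 = toy_peaklist("b", [[2000.02, 20.5, 2.0]])  # 10 ppm but 0.5 min
        mat = pc.match_peptides([s1, s2])
        assert mat.n_peptides == 2

    def test_chain_diverges_from_single_linkage_as_documented(self):
        # pairwise 40 ppm chain, 80 ppm end to end: single linkage would chain
        # all three; centroid-anchored growth caps the cluster at 50 ppm
        s = [toy_peaklist(c, [[m, 20.0, 1.0]])
             for c, m in zip("abc", [2000.00, 2000.08, 2000.16])]
        mat = pc.match_peptides(s)
        assert mat.n_peptides == 2
        np.testing.assert_allclose(
            mat.amplitudes, [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        sl = single_linkage_partition([(2000.00, 20.0), (2000.08, 20.0), (2000.16, 20.0)],
                                      50.0, 0.35)
        assert sl == {frozenset({0, 1, 2})}  # the documented divergence case

    def test_agrees_with_single_linkage_on_separated_toys(self):
        # when clusters are tight (< half tolerance) and far apart, the greedy
        # partition must equal the connected-components partition
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_clusters = rng.integers(2, 5)
            centers = 1000 + np.cumsum(rng.uniform(5, 50, n_clusters))
            peaks, owner = [], []
            for ci, c in enumerate(centers):
                for si in range(int(rng.integers(1, 4))):
                    peaks.append((c * (1 + rng.uniform(-10e-6, 10e-6)),
                                  20.0 + rng.uniform(-0.1, 0.1)))
                    owner.append(si)
            samples = {}
            for (m, t), si in zip(peaks, owner):
                samples.setdefault(si, []).append([m, t, 1.0])
            pls = [toy_peaklist(f"s{si}", rows) for si, rows in sorted(samples.items())]
            mat = pc.match_peptides(pls)
            sl = single_linkage_partition(peaks, 50.0, 0.35)
            assert mat.n_peptides == len(sl)

    def test_one_peak_per_sample_per_cluster(self):
        # same sample twice near one mass: second peak must seed its own cluster
        s1 = toy_peaklist("a", [[2000.00, 20.0, 1.0], [2000.06, 22.0, 2.0]])
        s2 = toy_peaklist("b", [[2000.01, 20.0, 3.0]])
        mat = pc.match_peptides([s1, s2])
        assert mat.n_peptides == 2
        assert np.count_nonzero(mat.amplitudes[0]) == 2

    def test_empty_input_gives_empty_matrix(self):
        mat = pc.match_peptides([toy_peaklist("a", [])])
        assert mat.n_peptides == 0
        assert mat.amplitudes.shape == (1, 0)

    def test_permuting_sample_order_preserves_partition(self, small_cohort):
        _, samples, _ = small_cohort
        sub = samples[:6]
        m1 = pc.match_peptides(sub)
        m2 = pc.match_peptides(sub[::-1])
        assert m1.n_peptides == m2.n_peptides
        # same partition: amplitudes per sample match after row realignment
        r2 = {sid: m2.amplitudes[i] for i, sid in enumerate(m2.sample_ids)}
        for i, sid in enumerate(m1.sample_ids):
            np.testing.assert_allclose(np.sort(m1.amplitudes[i]), np.sort(r2[sid]))

    def test_recovers_planted_peptide_count(self, preprocessed_matrix):
        mat, truth = preprocessed_matrix
        assert mat.n_peptides == truth.true_mass.size
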