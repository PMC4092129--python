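import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gyrospec.accuracy import (AccuracyReport, ErrorMatrix,
                               apply_detection_threshold, accuracy_metrics,
                               build_error_matrix, cohens_kappa, report_kappa,
                               round_half_up, sample_validation_pixels)
from gyrospec.classification import LabelSet
from gyrospec.spectral_scene import CoverageMap

# the three published 2x2 reference matrices this module is golden-tested on
ACACIA = np.array([[93, 7], [9, 241]])
OXALIS = np.array([[100, 0], [3, 247]])
CARPOBROTUS = np.array([[139, 11], [4, 296]])


class TestDetectionThreshold:
    def test_threshold_area_is_0125(self):
        # 50% of a 0.25 m^2 pixel
        cov = np.array([[0.125]])
        assert apply_detection_threshold(cov, 0.25, 0.5)[0, 0]

    def test_zero_coverage_is_absence(self):
        assert not apply_detection_threshold(np.array([[0.0]]), 0.25, 0.5)[0, 0]

    def test_boundary_inclusive(self):
        cov = np.array([[0.1249999, 0.125, 0.1250001]])
        out = apply_detection_threshold(cov, 0.25, 0.5)[0]
        assert list(out) == [False, True, True]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_fraction_domain(self, bad):
        with pytest.raises(ValueError):
            apply_detection_threshold(np.zeros((2, 2)), 0.25, bad)

    def test_accepts_coverage_map(self):
        cm = CoverageMap(coverage=np.full((3, 3), 0.2), pixel_size=0.5)
        assert np.all(cm.presence(0.5))


class TestSampleValidationPixels:
    def _maps(self, n=40):
        rng = np.random.default_rng(0)
        classified = rng.random((n, n)) < 0.3
        reference = classified ^ (rng.random((n, n)) < 0.05)
        return classified, reference

    def test_counts_and_strata(self):
        classified, reference = self._maps()
        ls = sample_validation_pixels(classified, reference, 100, 250, seed=1)
        assert len(ls) == 350
        picked = classified[ls.rows, ls.cols]
        assert picked.sum() == 100

    def test_deterministic(self):
        classified, reference = self._maps()
        a = sample_validation_pixels(classified, reference, 50, 100, seed=9)
        b = sample_validation_pixels(classified, reference, 50, 100, seed=9)
        np.testing.assert_array_equal(a.rows, b.rows)

    def test_training_exclusion(self):
        classified, reference = self._maps()
        rr, cc = np.nonzero(classified)
        train = LabelSet(rows=rr[:20], cols=cc[:20],
                         labels=np.full(20, "t"), role=np.full(20, "train"))
        ls = sample_validation_pixels(classified, reference, 50, 100,
                                      exclude=train, seed=3)
        assert not (set(zip(ls.rows.tolist(), ls.cols.tolist()))
                    & train.index_set())

    def test_shortfall_when_everything_excluded(self):
        classified, reference = self._maps()
        rr, cc = np.nonzero(classified)
        train = LabelSet(rows=rr, cols=cc, labels=np.full(len(rr), "t"),
                         role=np.full(len(rr), "train"))
        with pytest.raises(ValueError, match="shortfall"):
            sample_validation_pixels(classified, reference, 10, 10,
                                     exclude=train, seed=3)


class TestBuildErrorMatrix:
    def test_all_agree_diagonal(self):
        cls = np.array([[True, False], [True, False]])
        ls = LabelSet(rows=np.array([0, 0, 1, 1]), cols=np.array([0, 1, 0, 1]),
                      labels=np.full(4, "x"), role=np.full(4, "validate"))
        m = build_error_matrix(ls, cls, cls.copy())
        assert m.counts[0, 1] == 0 and m.counts[1, 0] == 0

    def test_constructed_acacia_counts(self):
        # lay out 93 TP, 7 FP, 9 FN, 241 TN on a line of pixels
        n = 350
        cls = np.zeros(n, bool)
        ref = np.zeros(n, bool)
        cls[:100] = True
        ref[:93] = True          # 93 TP, 7 FP
        ref[100:109] = True      # 9 FN
        ls = LabelSet(rows=np.zeros(n, int), cols=np.arange(n),
                      labels=np.full(n, "x"), role=np.full(n, "validate"))
        m = build_error_matrix(ls, cls[None, :], ref[None, :])
        np.testing.assert_array_equal(m.counts, ACACIA)

    def test_empty_rejected(self):
        empty = LabelSet(rows=np.array([], int), cols=np.array([], int),
                         labels=np.array([], str), role=np.array([], str))
        with pytest.raises(ValueError, match="empty"):
            build_error_matrix(empty, np.zeros((2, 2), bool),
                               np.zeros((2, 2), bool))

    def test_missing_value_rejected(self):
        cls = np.array([[None]], dtype=object)
        ls = LabelSet(rows=np.array([0]), cols=np.array([0]),
                      labels=np.array(["x"]), role=np.array(["validate"]))
        with pytest.raises(ValueError, match="missing"):
            build_error_matrix(ls, cls, np.zeros((1, 1), bool))


class TestErrorMatrix:
    def test_marginals_conserve(self):
        m = ErrorMatrix(counts=ACACIA)
        assert m.n == 350
        np.testing.assert_array_equal(m.row_totals, [100, 250])
        np.testing.assert_array_equal(m.col_totals, [102, 248])
        assert m.counts.sum() == m.row_totals.sum() == m.col_totals.sum()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ErrorMatrix(counts=np.array([[1, -1], [0, 0]]))

    def test_shape_enforced(self):
        with pytest.raises(ValueError):
            ErrorMatrix(counts=np.zeros((3, 3)))


class TestGoldenMatrices:
    """The published reference values this module must reproduce exactly."""

    def test_acacia_block(self):
        r = accuracy_metrics(ErrorMatrix(counts=ACACIA)).rounded()
        assert r["users_pct"] == [93.0, 96.4]
        assert r["producers_pct"] == [91.2, 97.2]
        assert r["overall_pct"] == 95.4
        assert r["kappa"] == 0.888

    def test_oxalis_block(self):
        r = accuracy_metrics(ErrorMatrix(counts=OXALIS)).rounded()
        assert r["users_pct"] == [100.0, 98.8]
        assert r["producers_pct"] == [97.1, 100.0]
        assert r["overall_pct"] == 99.1
        assert r["kappa"] == 0.979

    def test_carpobrotus_block(self):
        r = accuracy_metrics(ErrorMatrix(counts=CARPOBROTUS)).rounded()
        assert r["users_pct"] == [92.7, 98.7]
        assert r["producers_pct"] == [97.2, 96.4]
        assert r["overall_pct"] == 96.7
        assert r["kappa"] == 0.924

    def test_carpobrotus_user_producer_gap(self):
        rep = accuracy_metrics(ErrorMatrix(counts=CARPOBROTUS))
        gap = abs(rep.users_pct[0] - rep.producers_pct[0])
        assert round_half_up(gap, 2) == 4.54

    def test_perfect_matrix(self):
        r = accuracy_metrics(ErrorMatrix(counts=np.array([[50, 0], [0, 50]])))
        assert r.overall_pct == 100.0
        assert np.all(r.users_pct == 100.0)
        assert r.kappa == 1.0


class TestKappa:
    def test_kappa_one_iff_diagonal(self):
        assert cohens_kappa(ErrorMatrix(counts=np.array([[5, 0], [0, 7]]))) == 1.0
        assert cohens_kappa(ErrorMatrix(counts=np.array([[5, 1], [0, 7]]))) < 1.0

    def test_degenerate_marginals_nan(self):
        k = cohens_kappa(ErrorMatrix(counts=np.array([[10, 0], [0, 0]])))
        assert np.isnan(k)

    def test_zero_column_producers_undefined_not_zero(self):
        m = ErrorMatrix(counts=np.array([[5, 5], [0, 0]]))
        rep = accuracy_metrics(m)
        assert np.isnan(rep.users_pct[1])
        assert not np.isnan(rep.users_pct[0])

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_permutation_symmetry(self, a, b, c, d):
        m = np.array([[a, b], [c, d]])
        if m.sum() == 0:
            return
        perm = m[::-1, ::-1]        # consistent class relabeling
        r1 = accuracy_metrics(ErrorMatrix(counts=m))
        r2 = accuracy_metrics(ErrorMatrix(counts=perm))
        assert r1.overall_pct == pytest.approx(r2.overall_pct)
        np.testing.assert_allclose(r1.users_pct, r2.users_pct[::-1])
        np.testing.assert_allclose(r1.producers_pct, r2.producers_pct[::-1])
        k1, k2 = cohens_kappa(ErrorMatrix(counts=m)), cohens_kappa(
            ErrorMatrix(counts=perm))
        if np.isnan(k1):
            assert np.isnan(k2)
        else:
            assert k1 == pytest.approx(k2)

    @given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(1, 500))
    @settings(max_examples=60, deadline=None)
    def test_kappa_at_most_overall(self, a, b, c, d):
        m = ErrorMatrix(counts=np.array([[a, b], [c, d]]))
        k = cohens_kappa(m)
        if not np.isnan(k):
            assert k <= np.trace(m.counts) / m.n + 1e-12

    def test_kappa_bounds(self):
        m = ErrorMatrix(counts=np.array([[0, 10], [10, 0]]))
        assert -1.0 <= cohens_kappa(m) <= 1.0


class TestReportConventions:
    def test_overall_is_weighted_producers_mean(self):
        rep = accuracy_metrics(ErrorMatrix(counts=ACACIA))
        m = rep.matrix
        weighted = np.sum(m.col_totals * rep.producers_pct) / m.n
        assert weighted == pytest.approx(rep.overall_pct)

    def test_round_half_up_ties(self):
        assert round_half_up(96.45, 1) == 96.5
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(-0.25, 1) == -0.3

    def test_report_kappa_truncates(self):
        assert report_kappa(0.888672) == 0.888
        assert report_kappa(0.9241) == 0.924

    def test_format_table_layout(self):
        txt = accuracy_metrics(ErrorMatrix(counts=ACACIA)).format_table()
        assert "Column Total" in txt
        assert "95.4" in txt and "0.888" in txt

    def test_to_dict_keeps_unrounded(self):
        d = accuracy_metrics(ErrorMatrix(counts=ACACIA)).to_dict()
        assert d["unrounded"]["overall_pct"] == pytest.approx(95.42857, abs=1e-4)
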