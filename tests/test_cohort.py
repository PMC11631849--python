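import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import lase.cohort as cohort_mod
from lase.cohort import (
    bland_altman,
    cohens_kappa,
    cohort_report,
    load_fixture,
    one_tailed_t,
    roc_auc,
)


@pytest.fixture(scope="module")
def records():
    return load_fixture()


class TestFixture:
    def test_contains_all_27_patients(self, records):
        assert len(records) == 27

    def test_first_patient_values(self, records):
        r = records[0]
        assert r.patient_id == 1
        assert r.lase == pytest.approx(6.693)
        assert (r.af_type, r.basal_rhythm, r.substrate) == (
            "paroxysmal",
            "SR",
            "normal",
        )
        assert not r.recurrence

    def test_recurrence_flags(self, records):
        assert {r.patient_id for r in records if r.recurrence} == {4, 13}

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setattr(cohort_mod, "_FIXTURE_SHA256", "0" * 64)
        with pytest.raises(RuntimeError, match="corrupted"):
            load_fixture()


class TestBlandAltman:
    def test_identical_series(self):
        a = np.arange(10.0)
        res = bland_altman(a, a)
        assert res.mean_difference == 0.0
        assert res.n_outside_loa == 0
        assert res.n_within_band == 10

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=40),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_constant_shift_moves_mean_not_sd(self, values, c):
        a = np.asarray(values)
        b = np.zeros_like(a)
        base = bland_altman(a, b)
        shifted = bland_altman(a + c, b)
        assert shifted.mean_difference == pytest.approx(
            base.mean_difference + c, abs=1e-9
        )
        assert shifted.sd_difference == pytest.approx(base.sd_difference, abs=1e-9)

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            bland_altman([1], [1])


class TestTTest:
    def test_identical_groups_give_half(self):
        res = one_tailed_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 0.5
        assert res.degenerate

    def test_two_pooled_sd_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(2.0, 1.0, size=16)
        b = rng.normal(0.0, 1.0, size=11)
        res = one_tailed_t(a, b, direction="greater")
        assert res.p_value < 0.01

    def test_matches_textbook_pooled_formula(self, records):
        """Closed-form pooled-variance oracle agrees to 1e-10 on the cohort."""
        a = np.array([r.lase for r in records if r.af_type == "paroxysmal"])
        b = np.array([r.lase for r in records if r.af_type == "persistent"])
        res = one_tailed_t(a, b, direction="greater")
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        from scipy.stats import t as tdist

        p = 1.0 - tdist.cdf(t, n1 + n2 - 2)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([True, True, True, False, False, False])
        res = roc_auc(scores, labels, positive_is_low=True)
        assert res.auc == 1.0
        assert 3.0 <= res.youden_cutoff < 10.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.uniform(size=2000) < 0.5
        res = roc_auc(scores, labels)
        assert abs(res.auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pairwise_oracle(self, seed):
        """AUC == exhaustive pairwise comparison count (ties = 1/2)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        res = roc_auc(scores, labels, positive_is_low=True)
        pos, neg = scores[labels], scores[~labels]
        u = sum(
            (1.0 if p < q else 0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert res.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_cross_check_against_sklearn(self, records):
        lase = np.array([r.lase for r in records])
        abnormal = np.array([r.substrate == "abnormal" for r in records])
        res = roc_auc(lase, abnormal, positive_is_low=True)
        assert res.auc == pytest.approx(roc_auc_score(abnormal, -lase), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [True, True])


class TestKappa:
    def test_identical_labelings(self):
        assert cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_chance_level_agreement(self):
        assert cohens_kappa([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_contingency_formula(self, seed):
        rng = np.random.default_rng(seed)
        r1 = rng.integers(0, 2, size=40)
        r2 = rng.integers(0, 2, size=40)
        if np.array_equal(r1, r2):
            r2[0] ^= 1
        po = float((r1 == r2).mean())
        pe = sum(
            float((r1 == k).mean()) * float((r2 == k).mean()) for k in (0, 1)
        )
        expected = (po - pe) / (1 - pe)
        assert cohens_kappa(r1, r2) == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= cohens_kappa(r1, r2) <= 1.0


class TestReport:
    def test_counts_and_blocks(self, records):
        rep = cohort_report(records)
        assert rep["counts"]["patients"] == 27
        assert rep["counts"]["paroxysmal"] == 16
        assert "bland_altman_original_vs_lase" in rep
        assert "roc_substrate" in rep
        assert len(rep["recurrence"]) == 2

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_report([])
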