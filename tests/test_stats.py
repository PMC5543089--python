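import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import eventrsa as er
from helpers import (
    brute_fmri_matrix,
    brute_identity,
    brute_location,
    make_table,
)


def _patterns_for(tt, rng, n_voxels=20, entity_amp=0.0, location_amp=0.0, noise=1.0):
    """Trial patterns assembled directly from entity/location prototypes."""
    ents = sorted(tt.data["entity"].unique())
    locs = sorted(tt.data["location"].unique())
    epat = {e: rng.standard_normal(n_voxels) for e in ents}
    lpat = {l: rng.standard_normal(n_voxels) for l in locs}
    vals = np.vstack(
        [
            entity_amp * epat[row["entity"]]
            + location_amp * lpat[row["location"]]
            + noise * rng.standard_normal(n_voxels)
            for _, row in tt.data.iterrows()
        ]
    )
    return er.ResponsePatternSet(vals, (2.0, 8.0))


class TestFmriSimilarityMatrix:
    def test_identical_patterns_give_ones(self, rng):
        tt = make_table(3, 2, 4, seed=1)
        vals = np.tile(rng.standard_normal(5), (len(tt), 1))
        sm = er.fmri_similarity_matrix(er.ResponsePatternSet(vals, (2, 8)), tt)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(sm.values[off], 1.0)

    def test_matches_brute_force(self, tiny_fixture):
        rps, tt = tiny_fixture
        sm = er.fmri_similarity_matrix(rps, tt)
        labels, expected = brute_fmri_matrix(
            rps.values, list(tt.data["entity"]), list(tt.data["location"])
        )
        assert sm.labels == labels
        assert np.max(np.abs(sm.values - expected)) <= 1e-12

    def test_full_design_pair_counts(self, full_design, rng):
        rps = er.ResponsePatternSet(rng.standard_normal((288, 5)), (2, 8))
        sm = er.fmri_similarity_matrix(rps, full_design)
        counts = sm.meta["pair_counts"]
        off = ~np.eye(24, dtype=bool)
        assert np.all(counts[off] == 108)

    def test_no_admissible_pair_raises(self, rng):
        rows = []
        for r in (1, 2):
            for k, e in enumerate(["a", "b"]):
                rows.append(
                    dict(subject="s", run=r, onset=2.0 + 8.5 * k, entity=e,
                         category="A", location=1, size=1, mirrored=False)
                )
        tt = er.TrialTable(pd.DataFrame(rows))
        rps = er.ResponsePatternSet(rng.standard_normal((4, 5)), (2, 8))
        with pytest.raises(ValueError, match="admissible"):
            er.fmri_similarity_matrix(rps, tt)

    def test_diagonal_is_one(self, tiny_fixture):
        rps, tt = tiny_fixture
        sm = er.fmri_similarity_matrix(rps, tt)
        assert np.allclose(np.diag(sm.values), 1.0)


class TestGroupAverageMatrix:
    def test_single_subject_unchanged(self, rng):
        tt = make_table(3, 2, 4, seed=2)
        rps = _patterns_for(tt, rng)
        sm = er.fmri_similarity_matrix(rps, tt)
        avg = er.group_average_matrix([sm])
        assert np.allclose(avg.values, sm.values)

    def test_cancellation(self):
        labels = ["a", "b"]
        m = er.SimilarityMatrix(labels, np.array([[1.0, 0.4], [0.4, 1.0]]))
        neg = er.SimilarityMatrix(labels, np.array([[1.0, -0.4], [-0.4, 1.0]]))
        avg = er.group_average_matrix([m, neg])
        assert avg.values[0, 1] == pytest.approx(0.0)

    def test_31_matrices_match_mean_oracle(self, rng):
        labels = [f"l{i}" for i in range(5)]
        mats = []
        for _ in range(31):
            x = np.tanh(rng.standard_normal((5, 5)))
            x = (x + x.T) / 2
            np.fill_diagonal(x, 1.0)
            mats.append(er.SimilarityMatrix(labels, x))
        avg = er.group_average_matrix(mats)
        assert np.allclose(avg.values, np.mean([m.values for m in mats], axis=0))

    def test_label_mismatch(self, rng):
        a = er.SimilarityMatrix(["a", "b"], np.eye(2))
        b = er.SimilarityMatrix(["a", "c"], np.eye(2))
        with pytest.raises(ValueError, match="mismatch"):
            er.group_average_matrix([a, b])


class TestRsaTest:
    def test_maximal_statistic(self, small_model):
        res = er.rsa_test(small_model, small_model, n_perm=99, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 100.0)

    def test_determinism(self, small_model, rng):
        x = np.tanh(rng.standard_normal((6, 6)))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 1.0)
        data = er.SimilarityMatrix(small_model.labels, x)
        r1 = er.rsa_test(data, small_model, n_perm=100, seed=5)
        r2 = er.rsa_test(data, small_model, n_perm=100, seed=5)
        assert np.array_equal(r1.null, r2.null)

    def test_nperm_zero_rejected(self, small_model):
        with pytest.raises(ValueError, match="n_perm"):
            er.rsa_test(small_model, small_model, n_perm=0, seed=1)


class TestIdentityStatistic:
    def test_full_design_pair_counts(self, full_design, rng):
        rps = er.ResponsePatternSet(rng.standard_normal((288, 5)), (2, 8))
        res = er.identity_statistic([(rps, full_design)], n_perm=10, seed=0)
        counts = res.meta["admissible_pairs"][0]
        assert len(counts) == 24
        assert all(c == 54 for c in counts.values())

    def test_identical_patterns_give_one(self, rng):
        tt = make_table(3, 2, 4, seed=3)
        vals = np.tile(rng.standard_normal(5), (len(tt), 1))
        res = er.identity_statistic(
            [(er.ResponsePatternSet(vals, (2, 8)), tt)], n_perm=10, seed=0
        )
        assert res.observed == pytest.approx(1.0)

    def test_matches_brute_force(self, tiny_fixture):
        rps, tt = tiny_fixture
        res = er.identity_statistic([(rps, tt)], n_perm=5, seed=0)
        expected = brute_identity(
            rps.values, list(tt.data["entity"]), list(tt.data["location"])
        )
        assert abs(res.observed - expected) <= 1e-12

    def test_noise_patterns_near_zero(self):
        # Monte-Carlo oracle: pure-noise group statistic within 3 SE of zero
        rng = np.random.default_rng(17)
        stats = []
        for i in range(50):
            tt = make_table(4, 4, 4, seed=int(rng.integers(2**31)))
            rps = _patterns_for(tt, rng, n_voxels=30)
            res = er.identity_statistic([(rps, tt)], n_perm=1, seed=i)
            stats.append(res.observed)
        se = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats)) < 3 * se

    def test_no_admissible_pair_raises(self, rng):
        rows = []
        for r in (1, 2):
            rows.append(
                dict(subject="s", run=r, onset=2.0, entity="a",
                     category="A", location=1, size=1, mirrored=False)
            )
            rows.append(
                dict(subject="s", run=r, onset=10.0, entity="b",
                     category="A", location=2 if r == 1 else 3, size=1, mirrored=False)
            )
        tt = er.TrialTable(pd.DataFrame(rows))
        rps = er.ResponsePatternSet(rng.standard_normal((4, 5)), (2, 8))
        with pytest.raises(ValueError, match="'a'"):
            er.identity_statistic([(rps, tt)], n_perm=5, seed=0)

    def test_determinism(self, tiny_fixture):
        rps, tt = tiny_fixture
        r1 = er.identity_statistic([(rps, tt)], n_perm=50, seed=9)
        r2 = er.identity_statistic([(rps, tt)], n_perm=50, seed=9)
        assert np.array_equal(r1.null, r2.null)

    def test_category_restriction(self, rng):
        tt = make_table(4, 4, 4, seed=8)
        rps = _patterns_for(tt, rng, entity_amp=2.0)
        full = er.identity_statistic([(rps, tt)], n_perm=10, seed=0)
        cat_a = er.identity_statistic(
            [(rps, tt)], n_perm=10, seed=0, restrict_to_category="A"
        )
        assert len(cat_a.meta["admissible_pairs"][0]) == 2
        assert len(full.meta["admissible_pairs"][0]) == 4


class TestLocationStatistic:
    def test_full_design_pair_counts(self, full_design, rng):
        rps = er.ResponsePatternSet(rng.standard_normal((288, 5)), (2, 8))
        res = er.location_statistic([(rps, full_design)], n_perm=10, seed=0)
        counts = res.meta["admissible_pairs"][0]
        assert len(counts) == 4
        assert all(c == 2484 for c in counts.values())

    def test_orthogonal_location_patterns(self):
        # noise-free one-hot location patterns: within-location cosine is 1
        tt = make_table(4, 4, 4, seed=4)
        onehot = np.eye(4)
        vals = np.vstack([onehot[row["location"] - 1] for _, row in tt.data.iterrows()])
        res = er.location_statistic(
            [(er.ResponsePatternSet(vals, (2, 8)), tt)], n_perm=10, seed=0
        )
        assert res.observed == pytest.approx(1.0)

    def test_matches_brute_force(self, tiny_fixture):
        rps, tt = tiny_fixture
        res = er.location_statistic([(rps, tt)], n_perm=5, seed=0)
        expected = brute_location(
            rps.values, list(tt.data["entity"]), list(tt.data["location"])
        )
        assert abs(res.observed - expected) <= 1e-12


def _confounded_table(seed, n_entities=6, n_runs=4, subject="sub-01"):
    """Each entity sits at one preferred location for all but the last run,
    so same-entity pairs share a location far more often than random pairs."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, n_runs + 1):
        order = rng.permutation(n_entities)
        for k, e in enumerate(order):
            loc = (e % 4) + 1 if r < n_runs else (e + 1) % 4 + 1
            rows.append(
                dict(subject=subject, run=r, onset=2.0 + k * 8.5,
                     entity=f"e{e:02d}", category="A" if e < n_entities // 2 else "B",
                     location=int(loc), size=1, mirrored=False)
            )
    return er.TrialTable(pd.DataFrame(rows))


class TestExclusionLogic:
    """Location-confounded design, pure location signal: only the
    same-location exclusion keeps the identity statistic at chance."""

    def _subjects(self, seed, n_subjects=5):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n_subjects):
            tt = _confounded_table(seed + 100 + s, subject=f"sub-{s:02d}")
            rps = _patterns_for(tt, rng, n_voxels=50, location_amp=3.0, noise=1.0)
            out.append((rps, tt))
        return out

    def test_exclusion_keeps_identity_at_chance(self):
        data = self._subjects(0)
        res = er.identity_statistic(data, n_perm=200, seed=1)
        assert res.p > 0.05

    def test_removing_exclusion_creates_signal(self):
        data = self._subjects(0)
        res = er.identity_statistic(
            data, n_perm=200, seed=1, exclude_same_location=False
        )
        assert res.p <= 0.01

    def test_role_symmetry(self):
        # swapping which factor carries signal swaps which statistic fires
        rng = np.random.default_rng(5)
        ent_sig, loc_sig = [], []
        for s in range(5):
            tt = make_table(6, 4, 4, seed=300 + s, subject=f"sub-{s:02d}")
            ent_sig.append((_patterns_for(tt, rng, entity_amp=3.0), tt))
            loc_sig.append((_patterns_for(tt, rng, location_amp=3.0), tt))
        assert er.identity_statistic(ent_sig, n_perm=200, seed=2).p <= 0.01
        assert er.location_statistic(ent_sig, n_perm=200, seed=2).p > 0.05
        assert er.location_statistic(loc_sig, n_perm=200, seed=2).p <= 0.01
        assert er.identity_statistic(loc_sig, n_perm=200, seed=2).p > 0.05


class TestSubjectRank:
    def test_above_all_nulls(self, rng):
        nulls = rng.standard_normal((1, 999))
        [r] = er.subject_rank([99.0], nulls)
        assert r.percentile == pytest.approx(1.0)

    def test_below_all_nulls(self, rng):
        nulls = rng.standard_normal((1, 999))
        [r] = er.subject_rank([-99.0], nulls)
        assert r.percentile == pytest.approx(1.0 / 1000.0)

    def test_median_near_half(self, rng):
        nulls = rng.standard_normal((1, 999))
        [r] = er.subject_rank([float(np.median(nulls))], nulls)
        assert abs(r.percentile - 0.5) <= 1.0 / 999.0

    def test_requires_100_nulls(self, rng):
        with pytest.raises(ValueError, match="100"):
            er.subject_rank([0.0], rng.standard_normal((1, 99)))


class TestCompareConditions:
    def test_identical_paired(self):
        ranks = [0.2, 0.5, 0.9, 0.4]
        assert er.compare_conditions(ranks, ranks, paired=True, tail="two") == 1.0

    def test_exact_signed_rank_uniform_order(self):
        a = np.linspace(0.6, 0.99, 10)
        b = a - np.linspace(0.01, 0.2, 10)  # distinct positive differences
        p = er.compare_conditions(a, b, paired=True, tail="one")
        assert p == pytest.approx(1.0 / 1024.0)

    def test_identical_unpaired(self, rng):
        a = rng.random(8)
        p = er.compare_conditions(a, a.copy(), paired=False)
        assert p > 0.9

    def test_bad_tail(self):
        with pytest.raises(ValueError, match="tail"):
            er.compare_conditions([1, 2], [3, 4], tail="both")


class TestSubjectwiseDiagnostics:
    def test_inverse_normal(self, rng):
        rho = rng.standard_normal(5) * 0.1 + 0.2
        pvals = np.full(5, 0.0228)
        pvals[0] = 0.05  # avoid constant-Z degeneracy
        out = er.subjectwise_diagnostics(rho, pvals)
        assert out["z_scores"][1] == pytest.approx(sps.norm.isf(0.0228), abs=1e-9)
        assert out["z_scores"][1] == pytest.approx(2.0, abs=1e-3)

    def test_constant_rho_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            er.subjectwise_diagnostics([0.1, 0.1, 0.1], [0.5, 0.4, 0.3])

    def test_constant_p_rejected(self, rng):
        rho = rng.standard_normal(4) * 0.1
        with pytest.raises(ValueError, match="degenerate"):
            er.subjectwise_diagnostics(rho, [0.5, 0.5, 0.5, 0.5])

    def test_shapiro_calibration_on_normal_draws(self):
        rng = np.random.default_rng(23)
        rejections = sum(
            sps.shapiro(rng.standard_normal(31)).pvalue <= 0.05 for _ in range(1000)
        )
        # oracle check that the diagnostic's building block is calibrated
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_n_below_three_rejected(self):
        with pytest.raises(ValueError, match="3"):
            er.subjectwise_diagnostics([0.1, 0.2], [0.5, 0.4])


class TestRsaSubjectTests:
    def test_observed_matches_matrix_correlation(self, small_model, rng):
        mats = []
        for _ in range(3):
            x = np.tanh(rng.standard_normal((6, 6)))
            x = (x + x.T) / 2
            np.fill_diagonal(x, 1.0)
            mats.append(er.SimilarityMatrix(small_model.labels, x))
        results = er.rsa_subject_tests(mats, small_model, n_perm=50, seed=3)
        for mat, res in zip(mats, results):
            assert res.observed == pytest.approx(
                er.matrix_correlation(mat, small_model)
            )

    def test_restricted_labels(self, small_model, rng):
        x = np.tanh(rng.standard_normal((6, 6)))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 1.0)
        mat = er.SimilarityMatrix(small_model.labels, x)
        keep = small_model.labels[:4]
        [res] = er.rsa_subject_tests(
            [mat], small_model, n_perm=20, seed=3, restrict_labels=keep
        )
        expected = er.matrix_correlation(mat.restrict(keep), small_model.restrict(keep))
        assert res.observed == pytest.approx(expected, abs=1e-12)
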