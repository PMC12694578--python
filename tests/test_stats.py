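"""Group statistics: exclusion, regression, correlation, node scores,
network contrast and clinical associations, each against an independent
oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxsal.stats import (
    CorrelationTable,
    PredictionMissingError,
    exclude_misclassified,
    interfold_regression,
    metric_association,
    metric_pairwise,
    network_contrast,
    node_scores,
    pairwise_kendall,
)
from voxsal.synthetic import make_atlas, make_cohort, recovery_spec
from voxsal.types import CT, PD, SubjectRecord


def _subject(i, cls, pred=None, **kw):
    return SubjectRecord(
        id=f"s{i}", true_class=cls, predicted_class=pred or cls, **kw
    )


# ---------------------------------------------------------------- exclusion

class TestExcludeMisclassified:
    def test_all_correct_keeps_everyone(self):
        subs = [_subject(i, PD) for i in range(3)]
        kept, report = exclude_misclassified(subs)
        assert len(kept) == 3 and report == {PD: 0, CT: 0}

    def test_direct_rule_application(self):
        subs = [
            _subject(0, PD, pred=PD),
            _subject(1, PD, pred=CT),
            _subject(2, CT, pred=CT),
        ]
        kept, report = exclude_misclassified(subs)
        assert [s.id for s in kept] == ["s0", "s2"]
        assert report == {PD: 1, CT: 0}

    def test_all_wrong_excludes_everyone(self):
        subs = [_subject(0, PD, pred=CT), _subject(1, CT, pred=PD)]
        kept, report = exclude_misclassified(subs)
        assert kept == [] and report == {PD: 1, CT: 1}

    def test_unset_predictions_rejected(self):
        s = SubjectRecord(id="x", true_class=PD)
        with pytest.raises(PredictionMissingError):
            exclude_misclassified([s])


# --------------------------------------------------------------- regression

class TestInterfoldRegression:
    def test_identical_folds_give_identity_line(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        fits = interfold_regression({0: v, 1: v.copy()})
        assert fits[0].slope == pytest.approx(1.0)
        assert fits[0].intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_relation_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fits = interfold_regression({0: x, 1: 2 * x + 1})
        assert fits[0].slope == pytest.approx(2.0)
        assert fits[0].intercept == pytest.approx(1.0)

    def test_matches_covariance_over_variance_oracle(self, rng):
        folds = {f: rng.standard_normal(30) for f in range(4)}
        fits = interfold_regression(folds)
        assert len(fits) == 6  # all unordered pairs
        for fit in fits:
            x, y = folds[fit.fold_x], folds[fit.fold_y]
            slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
            intercept = y.mean() - slope * x.mean()
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            interfold_regression({0: np.ones(5), 1: np.arange(5.0)})


# ------------------------------------------------------------------ kendall

def _kendall_oracle(x, y):
    """O(n^2) pair enumeration with tie correction (tau-b)."""
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            conc += s > 0
            disc += s < 0
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    denom = np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (conc - disc) / denom


class TestPairwiseKendall:
    def test_three_point_example(self):
        """x=(1,2,3) vs y=(3,1,2): one concordant, two discordant pairs."""
        m = pd.DataFrame({"x": [1, 2, 3], "y": [3, 1, 2], "z": [1, 2, 3]})
        table = pairwise_kendall(m)
        assert table.tau.loc["x", "y"] == pytest.approx(-1 / 3)
        assert table.tau.loc["x", "z"] == pytest.approx(1.0)

    def test_diagonal_and_symmetry(self, rng):
        m = pd.DataFrame(rng.standard_normal((12, 5)), columns=list("abcde"))
        table = pairwise_kendall(m)
        np.testing.assert_allclose(np.diag(table.tau), 1.0)
        np.testing.assert_allclose(table.tau, table.tau.T, atol=1e-15)
        assert ((table.pvals.to_numpy() >= 0) & (table.pvals.to_numpy() <= 1)).all()

    def test_matches_pair_counting_oracle(self):
        """Every coefficient on a fuzzed 20x30 matrix equals the brute-force
        pair count to 1e-12, including tied columns."""
        rng = np.random.default_rng(17)
        vals = rng.standard_normal((20, 30))
        vals[:, 5] = np.round(vals[:, 5])  # introduce ties
        m = pd.DataFrame(vals, columns=[f"a{i}" for i in range(30)])
        table = pairwise_kendall(m)
        for i in range(0, 30, 7):
            for j in range(i + 1, 30, 5):
                expected = _kendall_oracle(vals[:, i], vals[:, j])
                assert table.tau.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_yields_nan_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4]})
        with pytest.warns(RuntimeWarning):
            table = pairwise_kendall(m)
        assert np.isnan(table.tau.loc["a", "b"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            pairwise_kendall(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


# --------------------------------------------------------------- node score

def _table(names, tau_entries, p_entries):
    n = len(names)
    tau = np.eye(n)
    pv = np.zeros((n, n))
    for (i, j), t in tau_entries.items():
        tau[i, j] = tau[j, i] = t
    for (i, j), p in p_entries.items():
        pv[i, j] = pv[j, i] = p
    return CorrelationTable(
        tau=pd.DataFrame(tau, index=names, columns=names),
        pvals=pd.DataFrame(pv, index=names, columns=names),
        n_subjects=10,
    )


class TestNodeScores:
    def test_no_significant_pairs_means_zero(self):
        t = _table(list("abc"), {(0, 1): 0.5, (0, 2): 0.2, (1, 2): -0.1},
                   {(0, 1): 0.5, (0, 2): 0.9, (1, 2): 0.99})
        assert (node_scores(t) == 0).all()

    def test_saturated_table_hits_upper_bound(self):
        n = 5
        tau = pd.DataFrame(np.ones((n, n)), index=list("abcde"), columns=list("abcde"))
        pv = pd.DataFrame(np.zeros((n, n)), index=list("abcde"), columns=list("abcde"))
        ns = node_scores(CorrelationTable(tau=tau, pvals=pv, n_subjects=9))
        assert (ns == n - 1).all()

    def test_direct_signed_sum_example(self):
        """tau_12=0.5 (p=.01), tau_13=-0.2 (p=.2), tau_23=0.3 (p=.04) gives
        node scores (0.5, 0.8, 0.3)."""
        t = _table(
            list("abc"),
            {(0, 1): 0.5, (0, 2): -0.2, (1, 2): 0.3},
            {(0, 1): 0.01, (0, 2): 0.2, (1, 2): 0.04},
        )
        ns = node_scores(t, alpha=0.05)
        np.testing.assert_allclose(ns.to_numpy(), [0.5, 0.8, 0.3])

    def test_permutation_equivariance(self, rng):
        names = [f"a{i}" for i in range(6)]
        m = pd.DataFrame(rng.standard_normal((15, 6)), columns=names)
        table = pairwise_kendall(m)
        ns = node_scores(table)
        perm = rng.permutation(6)
        m2 = m.iloc[:, perm]
        ns2 = node_scores(pairwise_kendall(m2))
        np.testing.assert_allclose(
            ns2.to_numpy(), ns.to_numpy()[perm], atol=1e-12
        )


# ---------------------------------------------------------------- contrast

class TestNetworkContrast:
    def test_perfectly_concordant_columns_have_zero_contrast(self):
        n = 6
        tau = pd.DataFrame(np.ones((n, n)), index=[f"a{i}" for i in range(n)],
                           columns=[f"a{i}" for i in range(n)])
        pv = tau * 0.0
        table = CorrelationTable(tau=tau, pvals=pv, n_subjects=8)
        nets = {"x": [f"a{i}" for i in range(3)], "y": [f"a{i}" for i in range(3, 6)]}
        out = network_contrast(table, nets)
        assert (out["intra_mean"] == 1).all() and (out["all_mean"] == 1).all()

    def test_planted_two_block_structure_recovered(self):
        """Within-block latent factors produce intra > all with
        non-overlapping intervals; permuting memberships destroys it."""
        rng = np.random.default_rng(4)
        n, per_block = 100, 5
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        cols = {}
        for b, f in enumerate((f1, f2)):
            for j in range(per_block):
                cols[f"b{b}_{j}"] = f + 0.6 * rng.standard_normal(n)
        m = pd.DataFrame(cols)
        table = pairwise_kendall(m)
        nets = {
            "block0": [c for c in m.columns if c.startswith("b0")],
            "block1": [c for c in m.columns if c.startswith("b1")],
        }
        out = network_contrast(table, nets)
        for net in nets:
            lo = out.loc[net, "intra_mean"] - out.loc[net, "intra_halfwidth"]
            hi = out.loc[net, "all_mean"] + out.loc[net, "all_halfwidth"]
            assert lo > hi  # separated 95% intervals
        # permutation control: scrambled memberships erase the contrast
        scrambled = np.array(m.columns)
        rng.shuffle(scrambled)
        nets_perm = {"block0": list(scrambled[:5]), "block1": list(scrambled[5:])}
        out_perm = network_contrast(table, nets_perm)
        for net in nets_perm:
            gap = out_perm.loc[net, "intra_mean"] - out_perm.loc[net, "all_mean"]
            spread = out_perm.loc[net, "intra_halfwidth"] + out_perm.loc[net, "all_halfwidth"]
            assert abs(gap) < max(spread, 0.1)

    def test_singleton_network_rejected(self):
        tau = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        table = CorrelationTable(tau=tau, pvals=tau * 0, n_subjects=5)
        with pytest.raises(ValueError):
            network_contrast(table, {"solo": ["a"]})


# ------------------------------------------------------------- associations

def _pd_cohort_with_matrix(n=40, seed=0, couple=0.0):
    rng = np.random.default_rng(seed)
    subs = []
    sal = {}
    for i in range(n):
        sev = float(np.exp(rng.normal(0, 0.4)))
        subs.append(
            _subject(
                i,
                PD,
                updrs_p3=max(0.0, 15 * sev + rng.normal(0, 4)),
                moca=float(np.clip(28 - 4 * sev - rng.normal(0, 1.5), 0, 30)),
                years_onset=max(0.1, 2.3 * sev + rng.normal(0, 0.8)),
                medicated=bool(rng.uniform() < 0.5),
                ledd=np.nan,
                latent_severity=sev,
            )
        )
        sal[f"s{i}"] = couple * sev + rng.standard_normal(3)
    matrix = pd.DataFrame.from_dict(sal, orient="index", columns=["a", "b", "c"])
    return subs, matrix


class TestMetricAssociation:
    def test_metric_equal_to_saliency_is_perfectly_correlated(self):
        subs, matrix = _pd_cohort_with_matrix(n=12, seed=1)
        matrix["a"] = [s.updrs_p3 for s in subs]
        out = metric_association(matrix, subs, "updrs_p3")
        assert out.loc["a", "pearson_rho"] == pytest.approx(1.0)
        assert out.loc["a", "kendall_tau"] == pytest.approx(1.0)

    def test_pearson_p_uses_t_distribution(self):
        subs, matrix = _pd_cohort_with_matrix(n=20, seed=2)
        out = metric_association(matrix, subs, "updrs_p3")
        for area in matrix.columns:
            x = matrix[area].to_numpy()
            y = np.array([s.updrs_p3 for s in subs])
            r, p = sps.pearsonr(x, y)
            assert out.loc[area, "pearson_p"] == pytest.approx(p, rel=1e-9)

    def test_ledd_restricted_to_medicated(self):
        subs, matrix = _pd_cohort_with_matrix(n=20, seed=3)
        for s in subs:
            if s.medicated:
                s.ledd = 300.0
        out = metric_association(matrix, subs, "ledd")
        assert out["n"].iloc[0] == sum(s.medicated for s in subs)

    def test_planted_coupling_recovered_with_sign_flip_for_cognition(self):
        """Saliency coupled to severity correlates positively with the motor
        score and negatively with cognition (4 of 5 seeds)."""
        hits_updrs = hits_moca = 0
        for seed in range(5):
            subs, matrix = _pd_cohort_with_matrix(n=40, seed=seed, couple=2.0)
            up = metric_association(matrix, subs, "updrs_p3")
            mo = metric_association(matrix, subs, "moca")
            hits_updrs += bool(
                (up["pearson_rho"] > 0).all() and (up["pearson_p"] < 0.05).all()
            )
            hits_moca += bool(
                (mo["pearson_rho"] < 0).all() and (mo["pearson_p"] < 0.05).all()
            )
        assert hits_updrs >= 4 and hits_moca >= 4


class TestMetricPairwise:
    def test_planted_years_cognition_anticorrelation(self, small_atlas):
        """Disease duration scales with severity while cognition declines, so
        their pairwise correlation is negative."""
        spec = recovery_spec(small_atlas, seed=31, n_per_class=100)
        subjects, _ = make_cohort(spec, small_atlas)
        out = metric_pairwise(subjects)
        row = out.loc[("all", "moca", "years_onset")]
        assert row["pearson_rho"] < 0 and row["pearson_p"] < 0.05

    def test_medication_split_present_when_group_large_enough(self, small_atlas):
        spec = recovery_spec(small_atlas, seed=32, n_per_class=60)
        subjects, _ = make_cohort(spec, small_atlas)
        out = metric_pairwise(subjects)
        assert {"all", "medicated", "unmedicated"} <= set(
            out.index.get_level_values("group")
        )

    def test_insufficient_pairs_skipped_with_note(self):
        subs = [
            _subject(0, PD, updrs_p3=10.0, moca=np.nan),
            _subject(1, PD, updrs_p3=12.0, moca=np.nan),
            _subject(2, PD, updrs_p3=14.0, moca=np.nan),
        ]
        out = metric_pairwise(subs)
        note = out.loc[("all", "updrs_p3", "moca"), "note"]
        assert "skipped" in note

    def test_null_metrics_hold_nominal_false_positive_rate(self):
        """Independent metric pairs reject at close to the 5% level across
        1000 replicates."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            hits += sps.pearsonr(x, y)[1] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)
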