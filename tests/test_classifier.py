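import math

import numpy as np
import pytest
from scipy.special import logsumexp

from hypothegon import (
    ClassifierConfig,
    ConfigurationError,
    DataError,
    MalformedJudgmentError,
    STRATEGIES,
    SubjectJudgments,
    bf_bin,
    classify_cohort,
    classify_subject,
    evidence_category,
    kernel_log_likelihood,
)
from hypothegon.classifier import INDETERMINATE

from oracles import brute_force_posterior


def subject_at(predictions, strategy, subject_id="s1", condition="c"):
    """A subject whose judgments sit exactly on one strategy's predictions."""
    return SubjectJudgments(
        subject_id=subject_id,
        condition=condition,
        judgments=tuple(
            (cid, tuple(float(x) for x in preds[strategy]))
            for cid, preds in predictions.items()
        ),
    )


def random_subject(predictions, rng, subject_id="r1", condition="c"):
    return SubjectJudgments(
        subject_id=subject_id,
        condition=condition,
        judgments=tuple(
            (cid, tuple(rng.dirichlet(np.ones(3)))) for cid in predictions
        ),
    )


class TestKernel:
    def test_maximum_at_predicted_position(self):
        assert kernel_log_likelihood((0.4, 0.4, 0.2), (0.4, 0.4, 0.2), 0.1) == 0.0

    def test_density_drops_to_1_over_e_at_squared_distance_d(self):
        d = 0.1
        # displace along one simplex direction by sqrt(d) euclidean distance
        delta = math.sqrt(d / 2.0)
        p = np.array([1 / 3 + delta, 1 / 3 - delta, 1 / 3])
        ll = kernel_log_likelihood(p, np.full(3, 1 / 3), d)
        assert math.exp(ll) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_worked_distance_value(self):
        ll = kernel_log_likelihood((0.6, 0.3, 0.1), (0.4615, 0.2308, 0.3077), 0.1)
        assert ll == pytest.approx(-0.6711018, abs=1e-6)

    def test_radius_mode_squares_the_scale(self):
        p, c = (0.5, 0.3, 0.2), (0.2, 0.5, 0.3)
        sq = float(np.sum((np.array(p) - np.array(c)) ** 2))
        assert kernel_log_likelihood(p, c, 0.1, radius_mode=True) == pytest.approx(
            -sq / 0.01
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            kernel_log_likelihood((1, 0, 0), (0, 1, 0), 0.0)


class TestEvidenceCategories:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (1.0, "weak"),
            (3.139, "moderate"),
            (10.5, "strong"),
            (99.0, "very strong"),
            (150.0, "extreme"),
            (1500.0, "extreme"),
        ],
    )
    def test_bins(self, bf, label):
        assert evidence_category(bf) == label

    @pytest.mark.parametrize(
        "bf,bin_label", [(1.0, ">1"), (2.9, ">1"), (3.01, ">3"), (1500, ">1000")]
    )
    def test_table_columns_keep_the_1000_boundary(self, bf, bin_label):
        assert bf_bin(bf) == bin_label

    def test_bf_below_one_is_a_contract_violation(self):
        with pytest.raises(ConfigurationError):
            evidence_category(0.5)


class TestClassifySubject:
    def test_noiseless_bus_subject(self, design, predictions, clf_cfg):
        res = classify_subject(subject_at(predictions, "BUS"), design, clf_cfg)
        assert res.label == "BUS"
        # closed form: runner-up is CES; log BF = sum of squared BUS-CES
        # distances over the battery divided by d
        sq = sum(
            float(np.sum((p["BUS"] - p["CES"]) ** 2)) for p in predictions.values()
        )
        assert res.bf_1_2 == pytest.approx(math.exp(sq / clf_cfg.d), rel=1e-9)
        assert res.bf_1_2 > 1000
        assert res.evidence_category == "extreme"

    def test_noiseless_ces_subject_certainty(self, design, predictions, clf_cfg):
        # CES and SES predictions are close (squared separation 0.1156 summed
        # over the battery), so even a noiseless CES subject is only
        # moderately certain: BF = exp(1.1556) ~ 3.18, p_post_max ~ 0.76
        res = classify_subject(subject_at(predictions, "CES"), design, clf_cfg)
        assert res.label == "CES"
        oracle_post, _ = brute_force_posterior(
            subject_at(predictions, "CES"), predictions, clf_cfg.d
        )
        assert res.p_post_max == pytest.approx(oracle_post["CES"], abs=1e-9)
        assert res.bf_1_2 == pytest.approx(3.1760, abs=1e-3)
        assert res.p_post_max == pytest.approx(0.7605, abs=1e-3)

    def test_posteriors_match_brute_force_oracle(self, design, predictions, rng):
        cfg = ClassifierConfig()
        for i in range(50):
            subj = random_subject(predictions, rng, subject_id=f"r{i}")
            res = classify_subject(subj, design, cfg)
            oracle_post, _ = brute_force_posterior(subj, predictions, cfg.d)
            for s in STRATEGIES:
                assert res.posterior[s] == pytest.approx(oracle_post[s], abs=1e-9)

    def test_posterior_invariant_to_log_score_offset(self, design, predictions, rng):
        res = classify_subject(random_subject(predictions, rng), design)
        scores = np.array([res.log_scores[s] for s in STRATEGIES])
        for offset in (-1000.0, 17.3, 250.0):
            shifted = scores + offset + np.log(1 / 3)
            post = np.exp(shifted - logsumexp(shifted))
            np.testing.assert_allclose(
                post, [res.posterior[s] for s in STRATEGIES], atol=1e-12
            )

    def test_naive_bayes_chain_property(self, design, predictions, rng):
        # classifying on all cases at once equals feeding per-case posteriors
        # forward as priors
        subj = random_subject(predictions, rng)
        full = classify_subject(subj, design)
        prior = np.full(3, 1 / 3)
        for cid, judgment in subj.judgments:
            one = SubjectJudgments("t", "c", ((cid, judgment),))
            res = classify_subject(
                one, design, ClassifierConfig(strategy_prior=tuple(prior))
            )
            prior = np.array([res.posterior[s] for s in STRATEGIES])
        np.testing.assert_allclose(
            prior, [full.posterior[s] for s in STRATEGIES], atol=1e-9
        )

    def test_equidistant_single_judgment_is_indeterminate(self, design):
        # the centroid is equidistant from all three predictions only on
        # symmetric cases; instead place the judgment at equal distance by
        # using a case and checking exact score ties via a synthetic design
        subj = SubjectJudgments("t", "c", (("case5", (0.19, 0.19, 0.62)),))
        res = classify_subject(subj, design)
        # generic point: not indeterminate; force a tie instead
        assert res.label in STRATEGIES
        # exact tie: judgment equidistant from BUS and CES on the BUS-CES
        # perpendicular bisector cannot be constructed trivially; use equal
        # scores by classifying a subject against duplicated predictions
        preds = {"caseX": {s: np.array([1 / 3, 1 / 3, 1 / 3]) for s in STRATEGIES}}
        tied = SubjectJudgments("t2", "c", (("caseX", (0.5, 0.25, 0.25)),))
        res2 = classify_subject(tied, design, _predictions=preds)
        assert res2.label == INDETERMINATE
        assert res2.bf_1_2 == 1.0
        assert res2.p_post_max == pytest.approx(1 / 3)

    def test_bf_matrix_is_reciprocal(self, design, predictions, rng):
        res = classify_subject(random_subject(predictions, rng), design)
        bf = res.bf.values
        np.testing.assert_allclose(bf * bf.T, np.ones((3, 3)), atol=1e-9)
        assert res.bf_1_2 >= 1.0

    def test_monotone_bf_along_ces_to_bus_line(self, design, predictions):
        ratios = []
        for t in np.linspace(0.0, 1.0, 11):
            judgments = tuple(
                (cid, tuple((1 - t) * p["CES"] + t * p["BUS"]))
                for cid, p in predictions.items()
            )
            res = classify_subject(
                SubjectJudgments("m", "c", judgments), design
            )
            ratios.append(res.bf.loc["BUS", "CES"])
        assert np.all(np.diff(ratios) > 0)

    def test_d_robustness_of_noiseless_labels(self, design, predictions):
        for d in (0.05, 0.1, 0.2):
            cfg = ClassifierConfig(d=d)
            for s in STRATEGIES:
                res = classify_subject(subject_at(predictions, s), design, cfg)
                assert res.label == s

    def test_lattice_mode_close_to_continuum(self, design, predictions, rng):
        subj = random_subject(predictions, rng)
        cont = classify_subject(subj, design, ClassifierConfig())
        latt = classify_subject(
            subj, design, ClassifierConfig(lattice_resolution=48)
        )
        assert latt.label == cont.label
        for s in STRATEGIES:
            assert latt.posterior[s] == pytest.approx(cont.posterior[s], abs=0.05)

    def test_unknown_case_rejected(self, design):
        subj = SubjectJudgments("x", "c", (("nocase", (0.5, 0.3, 0.2)),))
        with pytest.raises(DataError):
            classify_subject(subj, design)

    def test_malformed_judgment_names_subject_and_case(self, design):
        subj = SubjectJudgments("subj7", "c", (("case1", (0.5, 0.3, 0.1)),))
        with pytest.raises(MalformedJudgmentError, match="subj7.*case1"):
            classify_subject(subj, design)


class TestClassifyCohort:
    def test_noiseless_cohort_tables(self, design, predictions):
        subjects = [
            subject_at(predictions, s, subject_id=f"{s}{i}", condition="control")
            for s in STRATEGIES
            for i in range(3)
        ]
        report = classify_cohort(subjects, design)
        counts = report.condition_table.loc["control", list(STRATEGIES)]
        assert counts.tolist() == [3, 3, 3]
        assert report.certainty_table.values.sum() == 9

    def test_condition_margins(self, design, predictions):
        subjects = [
            subject_at(predictions, "BUS", subject_id="a", condition="control"),
            subject_at(predictions, "CES", subject_id="b", condition="instructed"),
        ]
        report = classify_cohort(subjects, design)
        assert list(report.condition_table.index) == ["control", "instructed"]
        assert report.condition_table.values.sum() == 2

    def test_empty_cohort_rejected(self, design):
        with pytest.raises(DataError):
            classify_cohort([], design)
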