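import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy.spatial.distance import pdist, squareform

from faime.differential import DirectionalSignature
from faime.prognosis import (
    CohortAssignment,
    SurvivalTable,
    km_estimate,
    logrank_test,
    pam_partition,
    read_survival_tsv,
    restrict_scores,
    write_survival_tsv,
)
from faime.scoring import MechanismScoreMatrix

from oracles import pam2_brute_force


def _scores(matrix, mech_ids=None, sample_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    mech_ids = mech_ids or [f"m{i}" for i in range(matrix.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(matrix.shape[1])]
    return MechanismScoreMatrix(mech_ids, sample_ids, rescaled=matrix)


def _assignment(labels):
    return CohortAssignment(
        dict(labels), tuple(list(labels)[:2]), 0.0
    )


# ---------------------------------------------------------------------------
# restrict_scores
# ---------------------------------------------------------------------------


def test_restrict_keeps_signature_rows():
    scores = _scores(np.arange(20.0).reshape(5, 4))
    sig = DirectionalSignature("x", 0.05, {"m1": 1, "m3": -1})
    out = restrict_scores(scores, sig)
    assert out.mechanism_ids == ["m1", "m3"]
    np.testing.assert_array_equal(out.rescaled[0], scores.rescaled[1])


def test_restrict_warns_on_absent(caplog):
    scores = _scores(np.zeros((3, 4)))
    sig = DirectionalSignature("x", 0.05, {"m0": 1, "zz": 1})
    with caplog.at_level("WARNING"):
        out = restrict_scores(scores, sig)
    assert out.mechanism_ids == ["m0"]
    assert "zz" in caplog.text


def test_restrict_none_present_errors():
    scores = _scores(np.zeros((2, 4)))
    sig = DirectionalSignature("x", 0.05, {"zz": 1})
    with pytest.raises(ValueError):
        restrict_scores(scores, sig)


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------


def test_pam_collinear_four_points():
    scores = _scores(np.array([[0.0, 1.0, 10.0, 11.0]]))
    out = pam_partition(scores)
    clusters = {c: set(out.samples(c)) for c in (1, 2)}
    assert {frozenset(v) for v in clusters.values()} == {
        frozenset({"s0", "s1"}),
        frozenset({"s2", "s3"}),
    }


def test_pam_two_tight_clouds_exact():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.1, size=(10, 3))
    b = rng.normal(50, 0.1, size=(10, 3))
    x = np.vstack([a, b]).T  # mechanisms x samples
    scores = _scores(x)
    out = pam_partition(scores)
    first = {f"s{j}" for j in range(10)}
    got = {frozenset(out.samples(1)), frozenset(out.samples(2))}
    assert got == {frozenset(first), frozenset(f"s{j}" for j in range(10, 20))}


def test_pam_partition_invariant_under_sample_permutation():
    rng = np.random.default_rng(2)
    x = np.hstack(
        [rng.normal(0, 0.2, size=(4, 8)), rng.normal(5, 0.2, size=(4, 8))]
    )
    ids = [f"s{j}" for j in range(16)]
    base = pam_partition(_scores(x, sample_ids=ids))
    perm = rng.permutation(16)
    permuted = pam_partition(_scores(x[:, perm], sample_ids=[ids[j] for j in perm]))
    part_a = {frozenset(base.samples(1)), frozenset(base.samples(2))}
    part_b = {frozenset(permuted.samples(1)), frozenset(permuted.samples(2))}
    assert part_a == part_b


def test_pam_swap_local_optimality_and_build_improvement():
    rng = np.random.default_rng(3)
    n_global = n_total = 0
    for trial in range(20):
        n = int(rng.integers(4, 13))
        x = rng.normal(size=(3, n))
        scores = _scores(x)
        out = pam_partition(scores)
        dist = squareform(pdist(x.T))
        med = [scores.sample_ids.index(m) for m in out.medoids]
        final = np.minimum(dist[med[0]], dist[med[1]]).sum()
        assert out.total_dissimilarity == pytest.approx(final, abs=1e-9)
        # no single medoid swap improves the final configuration
        for slot in (0, 1):
            other = med[1 - slot]
            for h in range(n):
                if h in med:
                    continue
                assert np.minimum(dist[h], dist[other]).sum() >= final - 1e-9
        # final cost never exceeds the greedy BUILD configuration's cost
        b1 = int(np.argmin(dist.sum(axis=1)))
        gains = np.maximum(dist[:, b1][:, None] - dist, 0.0).sum(axis=0)
        gains[b1] = -np.inf
        b2 = int(np.argmax(gains))
        build_cost = np.minimum(dist[b1], dist[b2]).sum()
        assert final <= build_cost + 1e-9
        best_cost, _ = pam2_brute_force(dist)
        n_total += 1
        n_global += abs(final - best_cost) <= 1e-9
    # descent from BUILD should usually land on the global optimum
    assert n_global / n_total >= 0.8


def test_pam_requires_four_samples():
    with pytest.raises(ValueError):
        pam_partition(_scores(np.zeros((2, 3))))


def test_pam_standardize_flag_runs():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(5, 12))
    out = pam_partition(_scores(x), standardize=True)
    assert set(out.assignment.values()) == {1, 2}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_three_events_no_censoring():
    surv = SurvivalTable(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1])
    asg = _assignment({"a": 1, "b": 1, "c": 1, })
    # need a non-empty cluster 2: add three more subjects
    surv = SurvivalTable(
        ["a", "b", "c", "d", "e", "f"],
        [1.0, 2.0, 3.0, 1.0, 1.0, 1.0],
        [1, 1, 1, 0, 0, 0],
    )
    asg = _assignment({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
    km = km_estimate(surv, asg)
    np.testing.assert_allclose(
        km[1]["survival"].to_numpy(), [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12
    )


def test_km_all_censored_flat_one():
    surv = SurvivalTable(["a", "b", "c", "d"], [5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0])
    asg = _assignment({"a": 1, "b": 1, "c": 2, "d": 2})
    km = km_estimate(surv, asg)
    for c in (1, 2):
        np.testing.assert_array_equal(km[c]["survival"].to_numpy(), [1.0])


def test_km_single_subject_event():
    surv = SurvivalTable(["a", "b"], [5.0, 9.0], [1, 0])
    asg = _assignment({"a": 1, "b": 2})
    km = km_estimate(surv, asg)
    np.testing.assert_allclose(km[1]["survival"].to_numpy(), [1.0, 0.0])
    assert km[1]["time"].tolist() == [0.0, 5.0]


def test_km_monotone_from_one_and_matches_lifelines():
    rng = np.random.default_rng(5)
    n = 40
    times = rng.exponential(10, n).round(2)
    events = rng.integers(0, 2, n)
    ids = [f"s{j}" for j in range(n)]
    surv = SurvivalTable(ids, times, events)
    asg = _assignment({s: (1 if j < 20 else 2) for j, s in enumerate(ids)})
    km = km_estimate(surv, asg)
    for c in (1, 2):
        s = km[c]["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        kmf = KaplanMeierFitter().fit(
            times[(np.arange(n) < 20) == (c == 1)],
            events[(np.arange(n) < 20) == (c == 1)],
        )
        for t, surv_hat in zip(km[c]["time"], s):
            assert surv_hat == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


def test_km_missing_survival_data_errors():
    surv = SurvivalTable(["a"], [1.0], [1])
    asg = _assignment({"a": 1, "b": 2})
    with pytest.raises(ValueError, match="b"):
        km_estimate(surv, asg)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_experience_is_null():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1, 1, 0, 1, 1, 0]
    ids = list("abcdef")
    surv = SurvivalTable(ids, times, events)
    asg = _assignment({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
    res = logrank_test(surv, asg)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_separated_groups_significant():
    ids = [f"s{j}" for j in range(6)]
    surv = SurvivalTable(ids, [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [1] * 6)
    asg = _assignment({s: (1 if j < 3 else 2) for j, s in enumerate(ids)})
    res = logrank_test(surv, asg)
    assert res.chi_square > 3.84  # beyond the 5% chi-square(1) critical value
    assert res.p_value < 0.05


def test_logrank_matches_lifelines_oracle():
    rng = np.random.default_rng(6)
    for trial in range(10):
        n = 50
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        split = rng.integers(10, 40)
        ids = [f"s{j}" for j in range(n)]
        surv = SurvivalTable(ids, times, events)
        asg = _assignment({s: (1 if j < split else 2) for j, s in enumerate(ids)})
        res = logrank_test(surv, asg)
        oracle = ll_logrank(
            times[:split], times[split:], events[:split], events[split:]
        )
        assert res.chi_square == pytest.approx(oracle.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(oracle.p_value, rel=1e-8)


def test_logrank_no_events_warns(caplog):
    surv = SurvivalTable(["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
    asg = _assignment({"a": 1, "b": 1, "c": 2, "d": 2})
    with caplog.at_level("WARNING"):
        res = logrank_test(surv, asg)
    assert res.chi_square == 0.0 and res.p_value == 1.0


# ---------------------------------------------------------------------------
# survival table IO
# ---------------------------------------------------------------------------


def test_survival_tsv_roundtrip(tmp_path):
    surv = SurvivalTable(["a", "b"], [1.5, 2.0], [1, 0])
    p = tmp_path / "surv.tsv"
    write_survival_tsv(surv, p)
    back = read_survival_tsv(p)
    assert back.sample_ids == surv.sample_ids
    np.testing.assert_array_equal(back.time, surv.time)
    np.testing.assert_array_equal(back.event, surv.event)


def test_survival_table_validation():
    with pytest.raises(ValueError):
        SurvivalTable(["a"], [-1.0], [1])
    with pytest.raises(ValueError):
        SurvivalTable(["a"], [1.0], [2])
    with pytest.raises(ValueError):
        SurvivalTable(["a", "a"], [1.0, 2.0], [1, 0])
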