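import numpy as np
import pytest

from etpfam.ensemble import (
    EnsembleCombiner,
    FitMeta,
    ScoreBlock,
    block_from_aggregated,
    ensemble_error,
    fit_combiner,
    lwm_predict,
    make_combiner,
    score_vote,
    select_members,
    simple_vote,
)
from etpfam.errors import NotFittedError
from etpfam.synthetic import (
    SyntheticScoreSpec,
    expert_quarters_spec,
    generate_score_block,
)
from etpfam.window_scoring import AggregatedScore


def random_block(rng, S=None, I=None, K=None):
    S = S or int(rng.integers(1, 30))
    I = I or int(rng.integers(1, 6))
    K = K or int(rng.integers(2, 10))
    t = rng.random((S, I, K)) + 1e-9
    t /= t.sum(axis=2, keepdims=True)
    return ScoreBlock([f"s{j}" for j in range(S)], [f"m{i}" for i in range(I)], t)


class TestVoting:
    def test_simple_majority(self):
        t = np.array([[[0.9, 0.1], [0.8, 0.2], [0.2, 0.8]]])
        block = ScoreBlock(["s0"], ["a", "b", "c"], t)
        assert simple_vote(block)[0] == 0

    def test_simple_single_model_degenerate(self, rng):
        block = random_block(rng, I=1)
        np.testing.assert_array_equal(
            simple_vote(block), block.tensor[:, 0, :].argmax(axis=1)
        )

    def test_simple_tie_resolves_to_lowest_class(self):
        t = np.array([[[0.1, 0.9], [0.9, 0.1]]])  # votes for 1 and 0
        block = ScoreBlock(["s0"], ["a", "b"], t)
        assert simple_vote(block)[0] == 0

    def test_score_vote_hand_sum(self):
        t = np.array([[[0.6, 0.4], [0.1, 0.9]]])  # sums (0.7, 1.3)
        block = ScoreBlock(["s0"], ["a", "b"], t)
        assert score_vote(block)[0] == 1

    def test_one_hot_scores_make_score_vote_equal_simple(self, rng):
        for _ in range(20):
            S, I, K = 10, 3, 5
            winners = rng.integers(0, K, size=(S, I))
            t = np.zeros((S, I, K))
            for s in range(S):
                for i in range(I):
                    t[s, i, winners[s, i]] = 1.0
            block = ScoreBlock(
                [f"s{j}" for j in range(S)], list("abc"), t
            )
            np.testing.assert_array_equal(simple_vote(block), score_vote(block))


class TestLWM:
    def test_unit_weights_reduce_to_score_vote(self, rng):
        for _ in range(20):
            block = random_block(rng)
            np.testing.assert_array_equal(
                lwm_predict(block, np.ones(block.n_models)), score_vote(block)
            )

    def test_one_hot_weight_selects_model(self, rng):
        block = random_block(rng, I=3)
        w = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(
            lwm_predict(block, w), block.tensor[:, 1, :].argmax(axis=1)
        )

    def test_hand_weighted_sum(self):
        t = np.array([[[0.6, 0.4], [0.1, 0.9]]])
        block = ScoreBlock(["s0"], ["a", "b"], t)
        assert lwm_predict(block, np.array([2.0, 1.0]))[0] == 1  # (1.3, 1.7)

    def test_weight_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            lwm_predict(random_block(rng, I=3), np.ones(2))


class TestLWF:
    def test_unit_weights_zero_bias_reduce_to_score_vote(self, rng):
        for _ in range(20):
            block = random_block(rng)
            comb = make_combiner(
                "lwf_perceptron",
                w=np.ones((block.n_models, block.n_classes)),
                b=np.zeros(block.n_classes),
            )
            np.testing.assert_array_equal(comb.predict(block), score_vote(block))

    def test_per_class_expert_selection(self):
        # class-0 column trusts model 0, class-1 column trusts model 1
        t = np.array([[[0.9, 0.1], [0.3, 0.7]],
                      [[0.2, 0.8], [0.6, 0.4]]])
        block = ScoreBlock(["s0", "s1"], ["a", "b"], t)
        w = np.array([[1.0, 0.0], [0.0, 1.0]])
        comb = make_combiner("lwf_perceptron", w=w, b=np.zeros(2))
        scores = comb.class_scores(block)
        np.testing.assert_allclose(scores, [[0.9, 0.7], [0.2, 0.4]])

    def test_dominant_bias_always_wins(self, rng):
        block = random_block(rng, K=4)
        b = np.zeros(4)
        b[2] = 100.0
        comb = make_combiner(
            "lwf_perceptron", w=np.zeros((block.n_models, 4)), b=b
        )
        assert np.all(comb.predict(block) == 2)

    def test_untrained_combiner_refuses_to_predict(self, rng):
        with pytest.raises(NotFittedError):
            EnsembleCombiner("lwf_perceptron").predict(random_block(rng))


class TestStacking:
    def test_own_class_block_weights_reduce_to_score_vote(self, rng):
        for _ in range(20):
            block = random_block(rng)
            I, K = block.n_models, block.n_classes
            w = np.zeros((I, K, K))
            w[:, np.arange(K), np.arange(K)] = 1.0
            comb = make_combiner(
                "stack_perceptron", w=w.reshape(I * K, K), b=np.zeros(K)
            )
            np.testing.assert_array_equal(comb.predict(block), score_vote(block))

    def test_single_model_identity_weights(self, rng):
        block = random_block(rng, I=1)
        K = block.n_classes
        comb = make_combiner(
            "stack_perceptron", w=np.eye(K), b=np.zeros(K)
        )
        np.testing.assert_array_equal(
            comb.predict(block), block.tensor[:, 0, :].argmax(axis=1)
        )

    def test_agrees_with_dense_algebra_oracle(self, rng):
        for _ in range(20):
            block = random_block(rng)
            I, K = block.n_models, block.n_classes
            w = rng.standard_normal((I * K, K))
            b = rng.standard_normal(K)
            comb = make_combiner("stack_perceptron", w=w, b=b)
            S = block.tensor.shape[0]
            # brute force: explicit triple loop over i, l, k
            Z = np.zeros((S, K))
            for s in range(S):
                for k in range(K):
                    acc = b[k]
                    for i in range(I):
                        for l in range(K):
                            acc += w[i * K + l, k] * block.tensor[s, i, l]
                    Z[s, k] = acc
            np.testing.assert_allclose(comb.class_scores(block), Z, atol=1e-9)


class TestSymmetry:
    def test_model_permutation_leaves_voting_unchanged(self, rng):
        for _ in range(20):
            block = random_block(rng, I=4)
            perm = rng.permutation(4)
            shuffled = ScoreBlock(
                list(block.sequence_ids),
                [block.model_ids[i] for i in perm],
                block.tensor[:, perm, :],
            )
            np.testing.assert_array_equal(
                simple_vote(block), simple_vote(shuffled)
            )
            np.testing.assert_array_equal(
                score_vote(block), score_vote(shuffled)
            )


class TestFitCombiner:
    def test_reliable_model_gets_larger_weight(self):
        # model 0 always right, model 1 always wrong
        rng = np.random.default_rng(0)
        K, S = 4, 200
        y = rng.integers(0, K, size=S)
        spec = SyntheticScoreSpec(
            2, np.array([[1.0] * K, [0.0] * K]), seed=1
        )
        block = generate_score_block(spec, y)
        comb = fit_combiner("lwm", block, y, FitMeta(seed=0))
        assert comb.params["w"][0] > comb.params["w"][1]
        err = float((comb.predict(block) != y).mean())
        assert err <= 0.5  # no worse than the bad model

    def test_per_family_specialists_reach_zero_dev_error(self):
        # model 0 is the only model right on families 0..1, model 1 the only
        # one right on families 2..3: LWF resolves it, LWM cannot
        rng = np.random.default_rng(0)
        K, S = 4, 400
        y = rng.integers(0, K, size=S)
        rel = np.array([
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
        ])
        # default confusion targets (k+1 mod K) keep the joint score
        # patterns distinguishable, so the task is exactly solvable
        block = generate_score_block(
            SyntheticScoreSpec(2, rel, seed=1), y
        )
        lwf = fit_combiner(
            "lwf_perceptron", block, y, FitMeta(seed=0, max_iters=1000)
        )
        lwf_err = float((lwf.predict(block) != y).mean())
        single_errs = [
            float((block.tensor[:, i, :].argmax(axis=1) != y).mean())
            for i in range(2)
        ]
        lwm = fit_combiner("lwm", block, y, FitMeta(seed=0))
        lwm_err = float((lwm.predict(block) != y).mean())
        assert lwf_err == 0.0
        assert min(single_errs) > 0.3
        assert lwm_err > lwf_err

    def test_same_seed_identical_parameters(self, rng):
        block = random_block(rng, S=50, I=3, K=5)
        y = rng.integers(0, 5, size=50)
        a = fit_combiner("lwf_perceptron", block, y, FitMeta(seed=4))
        b = fit_combiner("lwf_perceptron", block, y, FitMeta(seed=4))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_unlearned_strategies_refuse_fit(self, rng):
        block = random_block(rng)
        with pytest.raises(ValueError, match="nothing to fit"):
            fit_combiner("simple", block, np.zeros(len(block.sequence_ids), int))

    def test_holdout_loss_never_increases_at_checkpoints(self, rng):
        block = random_block(rng, S=80, I=3, K=4)
        y = rng.integers(0, 4, size=80)
        comb = fit_combiner("lwf_mlp", block, y, FitMeta(seed=2))
        hold = [h["holdout_loss"] for h in comb.history]
        best_so_far = np.minimum.accumulate(hold)
        # the restored checkpoint is the global best
        assert hold.index(min(hold)) + 1 >= 1
        assert np.all(np.diff(best_so_far) <= 0 + 1e-15)

    @pytest.mark.parametrize(
        "strategy", ["lwm", "lwf_perceptron", "lwf_mlp",
                     "stack_perceptron", "stack_mlp"]
    )
    def test_all_learned_strategies_fit_and_predict(self, strategy, rng):
        block = random_block(rng, S=60, I=3, K=4)
        y = rng.integers(0, 4, size=60)
        comb = fit_combiner(strategy, block, y, FitMeta(seed=0, max_iters=50))
        pred = comb.predict(block)
        assert pred.shape == (60,)
        assert set(pred) <= set(range(4))


class TestCombinerIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        block = random_block(rng, S=40, I=2, K=3)
        y = rng.integers(0, 3, size=40)
        comb = fit_combiner("lwf_perceptron", block, y, FitMeta(seed=0))
        p = tmp_path / "comb.npz"
        comb.save(p)
        back = EnsembleCombiner.load(p)
        np.testing.assert_array_equal(back.predict(block), comb.predict(block))


class TestMemberSelection:
    def test_eligibility_filter(self, rng):
        block = random_block(rng, S=30, I=3, K=4)
        y = rng.integers(0, 4, size=30)
        errors = {"m0": 0.10, "m1": 0.25, "m2": 0.15}
        members, curve = select_members(
            errors, block, y, max_members=10, error_threshold=0.20,
            rng=np.random.default_rng(0), strategies=("simple",),
        )
        assert set(members) == {"m0", "m2"}
        assert sorted(curve["size"].unique()) == [1, 2]

    def test_single_member_curve(self, rng):
        block = random_block(rng, S=30, I=2, K=4)
        y = rng.integers(0, 4, size=30)
        errors = {"m0": 0.05, "m1": 0.5}
        members, curve = select_members(
            errors, block, y, max_members=1,
            rng=np.random.default_rng(0), strategies=("simple", "score"),
        )
        assert members == ["m0"]
        expected = float((block.tensor[:, 0, :].argmax(axis=1) != y).mean())
        assert np.allclose(curve["dev_error"], expected)

    def test_no_eligible_model_raises(self, rng):
        block = random_block(rng, S=10, I=2, K=3)
        with pytest.raises(ValueError, match="no model"):
            select_members(
                {"m0": 0.5, "m1": 0.9}, block,
                np.zeros(10, int), error_threshold=0.20,
            )


class TestBlockAssembly:
    def test_from_aggregated_and_missing_entry(self):
        rows = [
            AggregatedScore("s0", "a", "swc", np.array([1.0, 0.0])),
            AggregatedScore("s0", "b", "swc", np.array([0.5, 0.5])),
            AggregatedScore("s1", "a", "swc", np.array([0.0, 1.0])),
        ]
        with pytest.raises(ValueError, match="missing score"):
            block_from_aggregated(rows)
        rows.append(AggregatedScore("s1", "b", "swc", np.array([0.2, 0.8])))
        block = block_from_aggregated(rows)
        assert block.tensor.shape == (2, 2, 2)
        np.testing.assert_allclose(block.tensor[1, 1], [0.2, 0.8])
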