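import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrmil.corpus import ADR, IND
from adrmil.features import FeatureConfig
from adrmil.mil import (
    TrainConfig,
    bag_posterior,
    decide,
    init_unlabeled_posteriors,
    train,
)
from adrmil.simulate import SynthConfig, generate
from adrmil.supervision import filter_ambiguous_seeds, label_corpus


def posteriors(adr_probs):
    p = np.asarray(adr_probs, float)
    return np.column_stack([p, 1 - p])


class TestBagPosterior:
    def test_per_class_max_aggregation(self):
        pred = bag_posterior(posteriors([0.2, 0.9, 0.4]), "b1")
        assert pred.scores == pytest.approx([0.9, 0.8])
        assert pred.label == ADR

    def test_single_instance_bag(self):
        pred = bag_posterior(posteriors([0.3]))
        assert pred.label == IND

    def test_tie_goes_to_adr(self):
        pred = bag_posterior(posteriors([0.5, 0.5]))
        assert pred.label == ADR

    def test_witness_is_argmax_instance(self):
        pred = bag_posterior(posteriors([0.2, 0.9, 0.4]), "b1", ["i0", "i1", "i2"])
        assert pred.witness == "i1"

    def test_empty_bag_errors(self):
        with pytest.raises(ValueError):
            bag_posterior(np.zeros((0, 2)))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_permutation_invariance_and_max_monotonicity(self, probs):
        P = posteriors(probs)
        base = bag_posterior(P)
        rng = np.random.default_rng(0)
        shuffled = bag_posterior(P[rng.permutation(len(probs))])
        assert base.scores == pytest.approx(shuffled.scores)
        assert base.label == shuffled.label
        grown = bag_posterior(np.vstack([P, posteriors([0.5])]))
        assert np.all(grown.scores >= base.scores)


class TestDecide:
    def test_hard_thresholds_to_one_hot(self):
        assert decide(np.array([0.7, 0.3]), "hard", 0.5).tolist() == [1.0, 0.0]

    def test_soft_is_identity(self):
        p = np.array([0.7, 0.3])
        assert decide(p, "soft").tolist() == [0.7, 0.3]

    def test_boundary_goes_to_adr(self):
        assert decide(np.array([0.5, 0.5]), "hard", 0.5).tolist() == [1.0, 0.0]

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.001, 0.999), st.floats(0.05, 0.95))
    def test_hard_equals_soft_thresholded(self, p, cutoff):
        """The hard decision is exactly the soft posterior thresholded
        at the cutoff, instance by instance."""
        soft = decide(np.array([p, 1 - p]), "soft")
        hard = decide(np.array([p, 1 - p]), "hard", cutoff)
        expected = [1.0, 0.0] if soft[0] >= cutoff else [0.0, 1.0]
        assert hard.tolist() == expected


class TestInitPosteriors:
    def test_neutral_mode_is_all_half(self):
        P = init_unlabeled_posteriors(3, "t_p05")
        assert P == pytest.approx(np.full((3, 2), 0.5))

    def test_random_mode_is_seeded(self):
        a = init_unlabeled_posteriors(5, "t_prandom", rng=np.random.default_rng(9))
        b = init_unlabeled_posteriors(5, "t_prandom", rng=np.random.default_rng(9))
        assert np.array_equal(a, b)
        assert a.sum(axis=1) == pytest.approx(np.ones(5))

    def test_warm_start_requires_supervised_model(self):
        with pytest.raises(ValueError):
            init_unlabeled_posteriors(3, "t_pml")

    def test_warm_start_copies_supervised_output(self):
        sup = posteriors([0.9, 0.1])
        P = init_unlabeled_posteriors(2, "t_pml", supervised_posteriors=sup)
        assert np.array_equal(P, sup)
        assert P is not sup


def small_corpus(seed=0, **kw):
    cfg = SynthConfig(
        **{
            "n_bags": 120, "n_drugs": 20, "n_events": 20, "n_patterns": 12,
            "kb_coverage": 0.6, "seed": seed, **kw,
        }
    )
    tuples, seeds, truth = generate(cfg)
    return label_corpus(tuples, filter_ambiguous_seeds(seeds)), truth


class TestTrain:
    @pytest.mark.parametrize("model", ["iem", "dem"])
    def test_supervised_mode_scores_all_unlabeled_bags(self, model):
        corpus, _ = small_corpus()
        result = train(corpus, FeatureConfig("L", "P", "B"), TrainConfig(model=model))
        assert len(result.predictions) == len(corpus.unlabeled_bags)
        assert {p.bag_id for p in result.predictions} == {
            b.bag_id for b in corpus.unlabeled_bags
        }

    def test_transductive_requires_unlabeled_bags(self):
        corpus, _ = small_corpus(kb_coverage=1.0)
        with pytest.raises(ValueError, match="unlabeled"):
            train(corpus, FeatureConfig("L", "P", "B"), TrainConfig(mode="t_pml"))

    @pytest.mark.parametrize("model", ["iem", "dem"])
    def test_random_mode_is_reproducible(self, model):
        corpus, _ = small_corpus()
        cfg = TrainConfig(model=model, mode="t_prandom", seed=7)
        fc = FeatureConfig("L", "P", "B")
        r1, r2 = train(corpus, fc, cfg), train(corpus, fc, cfg)
        assert np.array_equal(r1.posteriors.probs, r2.posteriors.probs)
        assert [(t.iteration, t.log_likelihood) for t in r1.trace] == [
            (t.iteration, t.log_likelihood) for t in r2.trace
        ]
        assert [p.label for p in r1.predictions] == [p.label for p in r2.predictions]

    def test_clamped_labeled_instances_never_move(self):
        corpus, _ = small_corpus()
        result = train(
            corpus, FeatureConfig("L", "P", "B"), TrainConfig(mode="t_p05", max_iter=10)
        )
        clamped = result.posteriors.probs[result.posteriors.clamped]
        assert np.all(np.isin(clamped, [0.0, 1.0]))

    def test_dem_refuses_word_granularity(self):
        corpus, _ = small_corpus()
        with pytest.raises(ValueError, match="phrase"):
            train(corpus, FeatureConfig("L", "W", "B"), TrainConfig(model="dem"))

    def test_warm_start_init_matches_supervised_predictions(self):
        """With max_iter=0 the warm-started transductive posteriors are
        exactly the supervised model's E-step output on D_U."""
        corpus, _ = small_corpus()
        fc = FeatureConfig("L", "P", "B")
        sup = train(corpus, fc, TrainConfig(model="iem", mode="sl"))
        warm = train(corpus, fc, TrainConfig(model="iem", mode="t_pml", max_iter=0))
        n_l = corpus.n_labeled_instances
        sup_scores = np.vstack([
            [p.scores for p in sup.predictions]
        ])
        warm_u = warm.posteriors.probs[n_l:]
        # bag scores from the warm-start table equal the supervised ones
        offset = 0
        for bag, pred in zip(corpus.unlabeled_bags, sup.predictions):
            got = warm_u[offset:offset + len(bag)].max(axis=0)
            assert got == pytest.approx(pred.scores, abs=1e-12)
            offset += len(bag)

    def test_hard_mode_one_hots_free_posteriors(self):
        corpus, _ = small_corpus()
        result = train(
            corpus,
            FeatureConfig("L", "P", "B"),
            TrainConfig(mode="t_p05", decision="hard", max_iter=5),
        )
        free = result.posteriors.probs[~result.posteriors.clamped]
        assert np.all(np.isin(free, [0.0, 1.0]))
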