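import numpy as np
import pytest

from helpers import ALPHABETS, random_chmm, random_instance, sampled_labels
from oracles import enum_log_likelihood, enum_posteriors, logspace_forward

from hnntm.chmm_core import (
    EmissionTable,
    TopologyModel,
    backward,
    baum_welch_labeled,
    cml_loss,
    cml_transition_gradients,
    forward,
    posteriors,
    set_transition_logits,
    transition_logits,
)
from hnntm.seqdata import Alphabet, LabeledSequence


def one_state_model():
    return TopologyModel(
        states=["s"],
        label_set=["a"],
        state_labels=["a"],
        begin=np.array([1.0]),
        trans=np.array([[1.0]]),
        emissions=EmissionTable(np.full((1, 20), 0.05)),
        alphabet=Alphabet(),
    )


class TestForwardBackward:
    def test_one_state_closed_form(self, rng):
        m = one_state_model()
        seq = LabeledSequence("p", rng.integers(0, 20, 10), "a" * 10)
        ll = forward(m, seq).log_likelihood
        assert ll == pytest.approx(10 * np.log(0.05), abs=1e-12)
        assert backward(m, seq).log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_forward_matches_enumeration(self, rng):
        for _ in range(20):
            m = random_chmm(rng, n_states=2, alphabet_size=2)
            seq = random_instance(rng, m, 3)
            E = m.emission_matrix(seq)
            expect = enum_log_likelihood(E, m.begin, m.trans)
            assert forward(m, seq).log_likelihood == pytest.approx(expect, abs=1e-9)
            assert backward(m, seq).log_likelihood == pytest.approx(expect, abs=1e-9)

    def test_zero_emission_symbol_gives_flagged_neg_inf(self):
        probs = np.zeros((1, 20))
        probs[0, 0] = 1.0
        m = one_state_model()
        m.emissions = EmissionTable(probs)
        seq = LabeledSequence("p", np.array([0, 1, 0]), "aaa")
        t = forward(m, seq)
        assert t.log_likelihood == -np.inf and not t.ok and t.blocked_pos == 1

    def test_scaling_agrees_with_logspace_on_long_sequence(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        seq = random_instance(rng, m, 200)
        E = m.emission_matrix(seq)
        direct = logspace_forward(E, m.begin, m.trans)
        assert forward(m, seq).log_likelihood == pytest.approx(direct, abs=1e-8)

    def test_designated_end_states(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        m.end_states = ["s0"]
        seq = random_instance(rng, m, 4)
        E = m.emission_matrix(seq)
        end = np.array([1.0, 0.0, 0.0])
        expect = enum_log_likelihood(E, m.begin, m.trans, end_vec=end)
        assert forward(m, seq).log_likelihood == pytest.approx(expect, abs=1e-9)
        assert backward(m, seq).log_likelihood == pytest.approx(expect, abs=1e-9)


class TestClamped:
    def test_single_label_model_equals_free(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4, n_labels=1)
        seq = random_instance(rng, m, 6)
        free = forward(m, seq).log_likelihood
        clamped = forward(m, seq, labels=seq.labels).log_likelihood
        assert clamped == pytest.approx(free, abs=1e-12)

    def test_clamped_matches_restricted_enumeration(self, rng):
        for _ in range(20):
            m = random_chmm(rng, n_states=3, alphabet_size=3)
            seq = random_instance(rng, m, 4)
            E = m.emission_matrix(seq)
            mask = m.label_mask(seq.labels)
            expect = enum_log_likelihood(E, m.begin, m.trans, mask=mask)
            got = forward(m, seq, labels=seq.labels).log_likelihood
            assert got == pytest.approx(expect, abs=1e-9)

    def test_impossible_labels_flagged(self):
        # two states with a forbidden direct transition a->b at consecutive positions
        m = TopologyModel(
            states=["A", "B"],
            label_set=["a", "b"],
            state_labels=["a", "b"],
            begin=np.array([1.0, 0.0]),
            trans=np.array([[1.0, 0.0], [0.5, 0.5]]),
            emissions=EmissionTable(np.full((2, 20), 0.05)),
        )
        seq = LabeledSequence("p", np.arange(3), "abb")
        t = forward(m, seq, labels=seq.labels)
        assert not t.ok and t.log_likelihood == -np.inf and t.blocked_pos == 1


class TestPosteriors:
    def test_one_state_all_ones(self, rng):
        m = one_state_model()
        seq = LabeledSequence("p", rng.integers(0, 20, 5), "a" * 5)
        g = posteriors(forward(m, seq), backward(m, seq))
        assert np.allclose(g, 1.0)

    def test_columns_sum_to_one_and_match_enumeration(self, rng):
        for _ in range(10):
            m = random_chmm(rng, n_states=3, alphabet_size=3)
            seq = random_instance(rng, m, 5)
            g = posteriors(forward(m, seq), backward(m, seq))
            assert np.allclose(g.sum(axis=0), 1.0, atol=1e-9)
            expect = enum_posteriors(m.emission_matrix(seq), m.begin, m.trans)
            assert np.allclose(g, expect, atol=1e-9)

    def test_clamped_zero_off_label(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        seq = random_instance(rng, m, 6)
        ft = forward(m, seq, labels=seq.labels)
        bt = backward(m, seq, labels=seq.labels)
        g = posteriors(ft, bt)
        off = ~m.label_mask(seq.labels)
        assert np.all(g[off] == 0.0)

    def test_phase_mismatch_errors(self, rng):
        m = random_chmm(rng)
        seq = random_instance(rng, m, 4)
        with pytest.raises(ValueError, match="phase"):
            posteriors(forward(m, seq), backward(m, seq, labels=seq.labels))


class TestBaumWelch:
    def test_single_determined_path_counts(self):
        # toy-style chain where labels fully determine the state path
        m = TopologyModel(
            states=["A", "B"],
            label_set=["a", "b"],
            state_labels=["a", "b"],
            begin=np.array([0.5, 0.5]),
            trans=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emissions=EmissionTable(np.full((2, 4), 0.25), tie_ids=np.array([0, 1])),
            alphabet=Alphabet("ACGT"),
        )
        seq = LabeledSequence("p", np.array([0, 1, 0, 2, 2, 3]), "aabbba",
                              Alphabet("ACGT"))
        fit, _ = baum_welch_labeled(m, [seq], max_iter=1)
        # observed transitions from the unique clamped path a a b b b a:
        # a->a 1, a->b 1 (from 2 a-transitions); b->b 2, b->a 1
        assert np.allclose(fit.trans[0], [0.5, 0.5], atol=1e-9)
        assert np.allclose(fit.trans[1], [1 / 3, 2 / 3], atol=1e-9)
        # state A saw symbols 0,1,3 once each; state B saw 0,2,2
        assert np.allclose(fit.emissions.probs[0], [1 / 3, 1 / 3, 0, 1 / 3], atol=1e-8)
        assert np.allclose(fit.emissions.probs[1], [1 / 3, 0, 2 / 3, 0], atol=1e-8)

    def test_monotone_log_joint(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        data = [random_instance(rng, m, int(rng.integers(10, 30))) for _ in range(10)]
        init = m.copy()
        init.emissions.probs[:] = 1.0 / 4
        _, hist = baum_welch_labeled(init, data, max_iter=20, tol=0.0)
        assert np.all(np.diff(hist) >= -1e-8)

    def test_structural_zeros_preserved(self, toy_model, rng):
        from hnntm.synthetic import GeneratorSpec, sample

        data = sample(GeneratorSpec(kind="chmm", model=toy_model, n=10,
                                    min_len=40, max_len=60, seed=7))
        fit, _ = baum_welch_labeled(toy_model, data, max_iter=5)
        assert np.all(fit.trans[~toy_model.trans_mask] == 0.0)
        assert abs(fit.trans.sum(axis=1) - 1.0).max() < 1e-10


class TestCMLLoss:
    def test_single_label_model_zero(self, rng):
        m = random_chmm(rng, n_labels=1)
        seq = random_instance(rng, m, 8)
        assert cml_loss(m, seq).loss == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_conditional(self, rng):
        for _ in range(10):
            m = random_chmm(rng, n_states=3, alphabet_size=3)
            seq = random_instance(rng, m, 4)
            E = m.emission_matrix(seq)
            lf = enum_log_likelihood(E, m.begin, m.trans)
            lc = enum_log_likelihood(E, m.begin, m.trans, mask=m.label_mask(seq.labels))
            got = cml_loss(m, seq)
            assert got.loss == pytest.approx(lf - lc, abs=1e-9)
            assert got.loss >= -1e-9  # P(x,y) <= P(x)

    def test_impossible_labels_infinite_flagged(self):
        m = TopologyModel(
            states=["A", "B"],
            label_set=["a", "b"],
            state_labels=["a", "b"],
            begin=np.array([1.0, 0.0]),
            trans=np.array([[1.0, 0.0], [0.5, 0.5]]),
            emissions=EmissionTable(np.full((2, 20), 0.05)),
        )
        seq = LabeledSequence("p", np.arange(2), "ab")
        c = cml_loss(m, seq)
        assert c.loss == np.inf and not c.ok


class TestTransitionGradients:
    def test_single_label_model_all_zero(self, rng):
        m = random_chmm(rng, n_labels=1)
        data = [random_instance(rng, m, 6) for _ in range(3)]
        gt, gb = cml_transition_gradients(m, data)
        assert np.allclose(gt, 0.0, atol=1e-10)
        assert np.allclose(gb, 0.0, atol=1e-10)

    def test_central_difference_agreement(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        data = [random_instance(rng, m, int(rng.integers(4, 8))) for _ in range(4)]
        gt, gb = cml_transition_gradients(m, data)

        def total_loss():
            return sum(cml_loss(m, s).loss for s in data)

        h = 1e-5
        zt0, zb0 = transition_logits(m)
        for k in range(m.n_states):
            for l in range(m.n_states):
                zt = zt0.copy()
                zt[k, l] += h
                set_transition_logits(m, zt, zb0)
                lp = total_loss()
                zt[k, l] -= 2 * h
                set_transition_logits(m, zt, zb0)
                lm = total_loss()
                num = (lp - lm) / (2 * h)
                assert gt[k, l] == pytest.approx(num, rel=1e-4, abs=1e-7)
        set_transition_logits(m, zt0, zb0)

    def test_forbidden_transition_gradient_exactly_zero(self, toy_model, rng):
        data = []
        from hnntm.synthetic import GeneratorSpec, sample

        data = sample(GeneratorSpec(kind="chmm", model=toy_model, n=3,
                                    min_len=30, max_len=40, seed=3))
        gt, gb = cml_transition_gradients(toy_model, data)
        assert np.all(gt[~toy_model.trans_mask] == 0.0)
        assert np.all(gb[~toy_model.begin_mask] == 0.0)
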