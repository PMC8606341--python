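import numpy as np
import pytest

from helpers import random_chmm, random_hnn, random_instance

from hnntm.chmm_core import cml_loss, forward
from hnntm.hnn import (
    EmissionNetwork,
    HNNParameters,
    RPROPState,
    TrainConfig,
    attach_networks,
    backprop_gradients,
    batch_loss,
    embed_emission_table,
    error_signal,
    init_networks,
    network_emit,
    rprop_step,
    train_hnn,
)
from hnntm.seqdata import Alphabet, LabeledSequence, WindowSpec
from hnntm.synthetic import GeneratorSpec, sample, toy_topology_model


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestNetworkEmit:
    def test_zero_weights_give_half(self):
        net = EmissionNetwork(np.zeros((3, 8)), np.zeros(3), np.zeros(3), 0.0)
        assert network_emit(net, np.ones(8)) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # 1 input, 1 hidden unit: sigma(2*sigma(1) - 1)
        net = EmissionNetwork(np.array([[1.0]]), np.array([0.0]), np.array([2.0]), -1.0)
        expect = sigmoid(2.0 * sigmoid(1.0) - 1.0)
        assert network_emit(net, np.array([1.0])) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.61351, abs=1e-5)

    def test_monotone_in_output_bias(self, rng):
        net = EmissionNetwork.random(8, 3, rng)
        s = rng.uniform(size=8)
        outs = []
        for b2 in np.linspace(-2, 2, 9):
            net.b2 = b2
            outs.append(network_emit(net, s))
        assert np.all(np.diff(outs) > 0)

    def test_output_clamped_and_finite_log(self):
        net = EmissionNetwork(np.zeros((1, 2)), np.zeros(1), np.array([1e4]), 1e4)
        out = network_emit(net, np.ones(2))
        assert out == 1.0 - 1e-6
        assert np.isfinite(np.log(out)) and np.isfinite(np.log1p(-out))

    def test_dimension_mismatch(self, rng):
        net = EmissionNetwork.random(8, 3, rng)
        with pytest.raises(ValueError, match="dimension"):
            network_emit(net, np.ones(7))

    def test_parameter_count(self, rng):
        net = EmissionNetwork.random(140, 11, rng)
        assert net.n_parameters == 140 * 11 + 11 + 11 + 1

    @pytest.mark.parametrize("activation", ["sigmoid", "tanh", "msigmoid"])
    def test_alternate_hidden_activations_stay_in_unit_interval(self, rng, activation):
        net = EmissionNetwork.random(8, 3, rng, hidden_activation=activation, scale=2.0)
        out = net.batch_output(rng.uniform(size=(20, 8)))
        assert np.all((out > 0) & (out < 1))


class TestHNNLikelihood:
    def test_constant_networks_factorize(self, rng):
        m = random_chmm(rng, n_states=2, alphabet_size=4)
        hm = attach_networks(m, WindowSpec(1, 1), 2, seed=0)
        # freeze every output at c by zeroing inputs and setting b2
        c = 0.3
        for net in hm.emissions.values():
            net.W1[:] = 0.0
            net.b1[:] = 0.0
            net.w2[:] = 0.0
            net.b2 = float(np.log(c / (1 - c)))
        seq = random_instance(rng, m, 7)
        got = forward(hm, seq).log_likelihood
        # log score = L*log(c) + log(total transition path mass = 1)
        assert got == pytest.approx(7 * np.log(c), abs=1e-10)

    def test_embedding_reproduces_chmm(self, rng):
        m = random_chmm(rng, n_states=3, alphabet_size=4)
        hm = embed_emission_table(m)
        for _ in range(5):
            seq = random_instance(rng, m, 6)
            assert forward(hm, seq).log_likelihood == pytest.approx(
                forward(m, seq).log_likelihood, abs=1e-4)
            assert cml_loss(hm, seq).loss == pytest.approx(
                cml_loss(m, seq).loss, abs=2e-4)


class TestErrorSignal:
    def test_single_label_model_zero(self, rng):
        m = random_hnn(rng, n_labels=1)
        seq = random_instance(rng, m, 6)
        eps = error_signal(m, seq)
        assert np.allclose(eps, 0.0, atol=1e-12)

    def test_zero_error_signal_leaves_only_weight_decay(self, rng):
        m = random_hnn(rng, n_labels=1)
        data = [random_instance(rng, m, 6)]
        lam = 0.1
        _, net_grads, gt, gb = backprop_gradients(m, data, weight_decay=lam)
        for (name, net), acc in zip(
            [(n, m.emissions[n]) for n in m.states], net_grads
        ):
            assert np.allclose(acc["W1"], lam * net.W1, atol=1e-10)
            assert np.allclose(acc["b1"], lam * net.b1, atol=1e-10)

    def test_gradient_additivity_over_batch(self, rng):
        m = random_hnn(rng)
        data = [random_instance(rng, m, int(rng.integers(4, 8))) for _ in range(3)]
        params = HNNParameters(m)
        _, ng, gt, gb = backprop_gradients(m, data)
        total = params.pack_gradients(ng, gt, gb)
        acc = np.zeros_like(total)
        for s in data:
            _, ng1, gt1, gb1 = backprop_gradients(m, [s])
            acc += params.pack_gradients(ng1, gt1, gb1)
        assert np.allclose(total, acc, atol=1e-10)

    def test_numerical_gradient_small_instance(self, rng):
        m = random_hnn(rng, n_states=2, alphabet_size=3, hidden=2)
        data = [random_instance(rng, m, 5)]
        params = HNNParameters(m)
        vec = params.pack()
        _, ng, gt, gb = backprop_gradients(m, data)
        grad = params.pack_gradients(ng, gt, gb)
        h = 1e-5
        for i in rng.choice(len(vec), size=min(25, len(vec)), replace=False):
            v = vec.copy()
            v[i] += h
            params.unpack(v)
            lp = batch_loss(m, data)
            v[i] -= 2 * h
            params.unpack(v)
            lm = batch_loss(m, data)
            num = (lp - lm) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-7)
        params.unpack(vec)


class TestRPROP:
    def test_consistent_sign_grows_step(self):
        st = RPROPState.init(1, step0=0.1)
        rprop_step(st, np.array([1.0]))
        rprop_step(st, np.array([1.0]))
        assert st.step[0] == pytest.approx(0.1 * 1.2)

    def test_sign_flip_shrinks_step_and_zeroes_derivative(self):
        st = RPROPState.init(1, step0=0.1)
        rprop_step(st, np.array([1.0]))
        rprop_step(st, np.array([-1.0]))
        assert st.step[0] == pytest.approx(0.1 * 0.5)
        assert st.prev_grad[0] == 0.0

    def test_minimizes_quadratic(self):
        w = np.array([0.0])
        st = RPROPState.init(1)
        for _ in range(100):
            grad = 2 * (w - 3.0)
            w = w + rprop_step(st, grad)
            assert st.step[0] <= st.step_max + 1e-15
            assert st.step[0] >= st.step_min - 1e-15
        assert abs(w[0] - 3.0) < 1e-3

    def test_step_bounds_never_violated(self, rng):
        st = RPROPState.init(50)
        for _ in range(200):
            rprop_step(st, rng.normal(size=50))
            assert np.all(st.step <= st.step_max)
            assert np.all(st.step >= st.step_min)


class TestInitNetworks:
    def _center_determined_data(self, rng, n=12, L=40):
        # label is a deterministic function of the center residue
        alpha = Alphabet("ACGT")
        data = []
        for j in range(n):
            x = rng.integers(0, 4, L)
            labs = "".join("M" if xi < 2 else "i" for xi in x)
            data.append(LabeledSequence(f"c{j}", x, labs, alpha))
        return data, alpha

    def test_separates_center_determined_labels(self, rng):
        data, alpha = self._center_determined_data(rng)
        base = random_chmm(rng, n_states=2, alphabet_size=4)
        base.label_set = ["M", "i"]
        base.state_labels = ["M", "i"]
        hm = attach_networks(base, WindowSpec(1, 1), 4, seed=1)
        cfg = TrainConfig(seed=1, init_epochs=150)
        nets = init_networks(data, hm, cfg)
        from hnntm.seqdata import encode_windows

        outs_pos, outs_neg = [], []
        for s in data:
            X = encode_windows(s, hm.window)
            o = nets[base.states[0]].batch_output(X)
            t = np.array([c == "M" for c in s.labels])
            outs_pos.append(o[t])
            outs_neg.append(o[~t])
        assert np.concatenate(outs_pos).mean() > 0.9
        assert np.concatenate(outs_neg).mean() < 0.1

    def test_seed_reproducibility_bitwise(self, rng):
        data, alpha = self._center_determined_data(rng, n=4, L=20)
        base = random_chmm(np.random.default_rng(5), n_states=2, alphabet_size=4)
        base.label_set = ["M", "i"]
        base.state_labels = ["M", "i"]
        hm = attach_networks(base, WindowSpec(1, 1), 3, seed=2)
        cfg = TrainConfig(seed=9, init_epochs=20)
        n1 = init_networks(data, hm, cfg)
        n2 = init_networks(data, hm, cfg)
        for name in base.states:
            assert np.array_equal(n1[name].W1, n2[name].W1)
            assert n1[name].b2 == n2[name].b2

    def test_absent_label_warns(self, rng):
        alpha = Alphabet("ACGT")
        data = [LabeledSequence("p", rng.integers(0, 4, 20), "M" * 20, alpha)]
        base = random_chmm(rng, n_states=2, alphabet_size=4)
        base.label_set = ["M", "i"]
        base.state_labels = ["M", "i"]
        hm = attach_networks(base, WindowSpec(1, 1), 3, seed=2)
        with pytest.warns(UserWarning, match="absent"):
            init_networks(data, hm, TrainConfig(init_epochs=5))


class TestTrainHNN:
    def _training_setup(self, seed=0, n=12):
        from hnntm.synthetic import default_context_tables

        tables = default_context_tables()
        data = sample(GeneratorSpec(kind="context", context=tables, n=n,
                                    min_len=30, max_len=50, seed=seed))
        from hnntm.chmm_core import EmissionTable, TopologyModel

        base = TopologyModel(
            states=["Si", "Sm"],
            label_set=["i", "M"],
            state_labels=["i", "M"],
            begin=np.array([0.5, 0.5]),
            trans=np.array([[0.88, 0.12], [0.12, 0.88]]),
            emissions=EmissionTable(np.full((2, 4), 0.25)),
            alphabet=tables.alphabet,
        )
        hm = attach_networks(base, WindowSpec(1, 1), 3, seed=seed)
        return hm, data

    def test_loss_decreases_and_early_stop_contract(self):
        hm, data = self._training_setup()
        cfg = TrainConfig(max_epochs=15, seed=0, init_epochs=30)
        hm.emissions = init_networks(data, hm, cfg)
        trained, log = train_hnn(hm, data, cfg)
        holds = [r["holdout_loss"] for r in log]
        trains = [r["train_loss"] for r in log if r["train_loss"] is not None]
        assert trains[-1] < trains[0]
        # returned model is the snapshot at the held-out minimum
        rng = np.random.default_rng(cfg.seed)
        idx = rng.permutation(len(data))
        n_hold = int(round(cfg.holdout_fraction * len(data)))
        hold = [data[i] for i in idx[:n_hold]]
        assert batch_loss(trained, hold or data) == pytest.approx(min(holds), abs=1e-9)

    def test_epoch_cap_respected(self):
        hm, data = self._training_setup(seed=1)
        cfg = TrainConfig(max_epochs=5, seed=1, init_epochs=10, patience=50)
        hm.emissions = init_networks(data, hm, cfg)
        _, log = train_hnn(hm, data, cfg)
        assert log[-1]["epoch"] <= 5

    def test_identical_seed_identical_log(self):
        hm, data = self._training_setup(seed=2)
        cfg = TrainConfig(max_epochs=6, seed=3, init_epochs=10)
        hm.emissions = init_networks(data, hm, cfg)
        t1, log1 = train_hnn(hm, data, cfg)
        t2, log2 = train_hnn(hm, data, cfg)
        assert log1 == log2
        for name in hm.states:
            assert np.array_equal(t1.emissions[name].W1, t2.emissions[name].W1)

    def test_infeasible_sequences_reported(self, rng):
        hm, data = self._training_setup(seed=3)
        alpha = data[0].alphabet
        bad = LabeledSequence("weird", rng.integers(0, 4, 10), "iMiMiMiMiM", alpha)
        # make labels infeasible by forbidding i->M
        hm.trans = np.array([[1.0, 0.0], [0.12, 0.88]])
        hm.trans_mask = hm.trans > 0
        with pytest.raises(ValueError, match="weird"):
            train_hnn(hm, [bad], TrainConfig(max_epochs=2))

    def test_tied_networks_share_object(self):
        model = toy_topology_model()
        data = sample(GeneratorSpec(kind="chmm", model=model, n=6,
                                    min_len=30, max_len=40, seed=5))
        hm = attach_networks(model, WindowSpec(1, 1), 3, seed=5)
        cfg = TrainConfig(tie_networks=True, init_epochs=5, max_epochs=2, seed=5)
        hm.emissions = init_networks(data, hm, cfg)
        assert hm.emissions["M1"] is hm.emissions["M5"]
        assert hm.emissions["I"] is not hm.emissions["O"]
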