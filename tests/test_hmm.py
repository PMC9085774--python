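"""Left-to-right categorical HMM: forward oracle, EM properties, selection."""

import itertools

import numpy as np
import pytest

from ipdinfer import (
    LeftToRightHMM,
    baum_welch,
    forward_loglik,
    prune_for_display,
    sample,
    select_states,
    to_dot,
)


def brute_force_loglik(model: LeftToRightHMM, seq) -> float:
    """Independent oracle: sum path probabilities by full enumeration."""
    S = model.n_states
    total = 0.0
    for path in itertools.product(range(S), repeat=len(seq)):
        p = model.pi[path[0]] * model.B[path[0], seq[0]]
        for prev, cur, obs in zip(path, path[1:], seq[1:]):
            p *= model.A[prev, cur] * model.B[cur, obs]
        total += p
    return np.log(total) if total > 0 else -np.inf


def random_ltr_model(rng: np.random.Generator, S: int, n_symbols: int = 8) -> LeftToRightHMM:
    pi = np.zeros(S)
    pi[0] = 1.0
    A = np.triu(rng.random((S, S)) + 0.05)
    A /= A.sum(axis=1, keepdims=True)
    B = rng.dirichlet(np.ones(n_symbols), size=S)
    return LeftToRightHMM(pi=pi, A=A, B=B)


two_state_delta = LeftToRightHMM(
    pi=[1, 0],
    A=[[0.5, 0.5], [0, 1]],
    B=[[1, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 0, 1]],
)


def test_forward_uniform_one_state():
    model = LeftToRightHMM(pi=[1.0], A=[[1.0]], B=[np.full(8, 1 / 8)])
    seq = [3, 1, 4, 1, 5]
    assert forward_loglik(model, seq) == pytest.approx(5 * np.log(1 / 8))


def test_forward_two_state_enumeration_example():
    # of the 4 hidden paths for [0, 7], only (s1, s2) survives: 1 * 0.5 * 1
    assert np.exp(forward_loglik(two_state_delta, [0, 7])) == pytest.approx(0.5)


def test_forward_impossible_sequence():
    assert forward_loglik(two_state_delta, [7, 0]) == -np.inf


def test_forward_rejects_out_of_alphabet():
    with pytest.raises(ValueError):
        forward_loglik(two_state_delta, [0, 8])


def test_forward_matches_brute_force_enumeration():
    rng = np.random.default_rng(12345)
    for _ in range(100):
        S = int(rng.integers(1, 4))
        L = int(rng.integers(1, 7))
        model = random_ltr_model(rng, S)
        seq = rng.integers(0, 8, size=L)
        assert forward_loglik(model, seq) == pytest.approx(
            brute_force_loglik(model, seq), abs=1e-10
        )


def test_forward_matches_hmmlearn():
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(5)
    model = random_ltr_model(rng, 3)
    ref = hmmlearn.CategoricalHMM(n_components=3)
    ref.startprob_ = model.pi
    ref.transmat_ = model.A
    ref.emissionprob_ = model.B
    seq = rng.integers(0, 8, size=40)
    assert forward_loglik(model, seq) == pytest.approx(
        ref.score(seq.reshape(-1, 1)), abs=1e-8
    )


def test_one_state_fit_is_empirical_frequencies():
    seqs = [np.array([0] * 10 + [7] * 10)]
    model = baum_welch(seqs, 1, seed=0)
    expected = np.zeros(8)
    expected[0] = expected[7] = 0.5
    np.testing.assert_allclose(model.B[0], expected, atol=1e-12)


def test_em_loglik_nondecreasing_and_structure_preserved():
    rng = np.random.default_rng(0)
    seqs = [rng.integers(0, 8, size=60) for _ in range(10)]
    model = baum_welch(seqs, 3, seed=1, n_restarts=2, max_iter=50)
    history = np.array(model.loglik_history)
    assert np.all(np.diff(history) >= -1e-8)
    # structural constraints hold exactly after training
    assert model.pi[0] == 1.0 and np.all(model.pi[1:] == 0.0)
    assert np.all(np.tril(model.A, k=-1) == 0.0)
    np.testing.assert_allclose(model.A.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(model.B.sum(axis=1), 1.0, atol=1e-9)
    model.validate()


def test_two_state_parameter_recovery():
    true = LeftToRightHMM(
        pi=[1, 0],
        A=[[0.95, 0.05], [0, 1]],
        B=[
            [0.7, 0.1, 0.1, 0.1, 0, 0, 0, 0],
            [0, 0, 0, 0, 0.1, 0.1, 0.1, 0.7],
        ],
    )
    rng = np.random.default_rng(7)
    seqs = [sample(true, 100, seed=int(rng.integers(2**31))) for _ in range(50)]
    fit = baum_welch(seqs, 2, seed=3)
    # states are already ordered by the left-to-right topology
    assert np.abs(fit.A - true.A).max() < 0.05
    assert np.abs(fit.B - true.B).max() < 0.05


def test_select_states_iid_prefers_one_state():
    rng = np.random.default_rng(11)
    probs = np.array([0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05])
    seqs = [rng.choice(8, size=80, p=probs) for _ in range(20)]
    for criterion in ("delta", "bic"):
        model = select_states(seqs, s_max=3, criterion=criterion, seed=0, n_restarts=3)
        assert model.n_states == 1


def test_select_states_finds_two_states():
    true = LeftToRightHMM(
        pi=[1, 0],
        A=[[0.95, 0.05], [0, 1]],
        B=[
            [0.7, 0.1, 0.1, 0.1, 0, 0, 0, 0],
            [0, 0, 0, 0, 0.1, 0.1, 0.1, 0.7],
        ],
    )
    rng = np.random.default_rng(21)
    seqs = [sample(true, 100, seed=int(rng.integers(2**31))) for _ in range(50)]
    for criterion in ("delta", "bic"):
        model = select_states(seqs, s_max=4, criterion=criterion, seed=0, n_restarts=3)
        assert model.n_states == 2, criterion


def test_select_states_smax_one():
    seqs = [np.array([0, 1, 2, 3])]
    model = select_states(seqs, s_max=1, seed=0)
    assert model.n_states == 1
    assert len(model.selection_table) == 1


def test_baum_welch_rejects_empty_input():
    with pytest.raises(ValueError):
        baum_welch([np.array([], dtype=int)], 2)


def test_prune_thresholds_are_inclusive():
    model = LeftToRightHMM(
        pi=[1, 0],
        A=[[0.99, 0.01], [0, 1]],
        B=[
            [0.05, 0.051, 0.899, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0.125, 0.875],
        ],
    )
    shown = prune_for_display(model)
    assert shown.B[0, 0] == 0.0  # emission 0.05 exactly -> masked
    assert shown.B[0, 1] == 0.051  # just above threshold -> retained
    assert shown.A[0, 1] == 0.0  # transition 0.01 exactly -> masked
    # rows deliberately not renormalized: display only
    assert shown.B[0].sum() < 1.0


def test_prune_keeps_uniform_emissions():
    model = LeftToRightHMM(pi=[1.0], A=[[1.0]], B=[np.full(8, 0.125)])
    np.testing.assert_array_equal(prune_for_display(model).B, model.B)


def test_sample_delta_emission_constant():
    B = np.zeros((1, 8))
    B[0, 3] = 1.0
    model = LeftToRightHMM(pi=[1.0], A=[[1.0]], B=B)
    assert (sample(model, 20, seed=0) == 3).all()


def test_sample_absorbing_state_constant_suffix():
    B = np.zeros((2, 8))
    B[0] = 1 / 8
    B[1, 5] = 1.0
    model = LeftToRightHMM(pi=[1, 0], A=[[0.5, 0.5], [0, 1]], B=B)
    out = sample(model, 200, seed=1)
    first_five = np.argmax(out == 5)
    assert (out[first_five + 1 :] == 5).all() or first_five == 0


def test_sample_marginals_match_emissions():
    rng = np.random.default_rng(3)
    B = rng.dirichlet(np.ones(8), size=1)
    model = LeftToRightHMM(pi=[1.0], A=[[1.0]], B=B)
    out = sample(model, 10_000, seed=4)
    freqs = np.bincount(out, minlength=8) / len(out)
    assert np.abs(freqs - B[0]).max() < 0.02


def test_generative_roundtrip_marginals():
    """Fit on samples from a known model; re-sampled marginals match source."""
    true = LeftToRightHMM(
        pi=[1, 0],
        A=[[0.9, 0.1], [0, 1]],
        B=[
            [0.8, 0.2, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0.3, 0.7],
        ],
    )
    seqs = [sample(true, 80, seed=s) for s in range(40)]
    fit = baum_welch(seqs, 2, seed=0, n_restarts=3)
    resampled = np.concatenate([sample(fit, 80, seed=1000 + s) for s in range(40)])
    source = np.concatenate(seqs)
    src_freq = np.bincount(source, minlength=8) / len(source)
    fit_freq = np.bincount(resampled, minlength=8) / len(resampled)
    assert np.abs(src_freq - fit_freq).max() < 0.05


def test_dot_single_state_delta():
    B = np.zeros((1, 8))
    B[0, 0] = 1.0
    model = LeftToRightHMM(pi=[1.0], A=[[1.0]], B=B)
    dot = to_dot(model)
    assert "(CC)C 1.00" in dot
    assert "style=bold" in dot


def test_dot_two_state_structure_and_masking():
    model = LeftToRightHMM(
        pi=[1, 0],
        A=[[0.99, 0.01], [0, 1]],
        B=[
            [0.9, 0.1, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0.2, 0.8],
        ],
    )
    full = to_dot(model)
    full_edges = [line for line in full.splitlines() if "->" in line]
    assert len(full_edges) == 3  # one forward edge, two self-loops
    assert full.count("[label=\"s") == 2
    dot = to_dot(prune_for_display(model))
    edges = [line for line in dot.splitlines() if "->" in line]
    # the 0.01 forward edge is masked; both self-loops survive
    assert len(edges) == 2
    assert "s0 -> s1" not in dot


def test_json_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    model = random_ltr_model(rng, 3)
    model.log_likelihood = -12.5
    path = tmp_path / "model.json"
    model.to_json(path)
    back = LeftToRightHMM.from_json(path)
    np.testing.assert_allclose(back.A, model.A)
    np.testing.assert_allclose(back.B, model.B)
    assert back.log_likelihood == -12.5
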