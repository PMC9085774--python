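"""Left-to-right multinomial hidden Markov models over conditional actions.

Each behavioral sub-cluster's pooled symbol sequences are modelled by an HMM
whose hidden states are ordered: the chain starts in state 1 (pi = e1) and
transitions never return to an earlier state (upper-triangular transition
matrix, skips allowed).  Emissions are categorical over the 8-symbol
conditional-action alphabet.  Training is multi-sequence Baum-Welch (EM)
with the structural zeros preserved exactly at every iteration.

The number of hidden states is chosen either by a log-likelihood gain rule
(stop adding states once the relative gain drops below a threshold) or by
BIC.  Both criteria are pragmatic stand-ins for an exact selection rule:
they favour the smallest model that explains the data, which is what the
rendered state machines are meant to be — small and readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .encoding import N_SYMBOLS, SYMBOL_LABELS

_ROW_TOL = 1e-9


@dataclass
class LeftToRightHMM:
    """A fitted (or constructed) left-to-right categorical HMM.

    ``pi`` is always the first basis vector; ``A`` is upper triangular
    (row-stochastic); ``B`` is the S x 8 emission matrix.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    log_likelihood: float = float("nan")
    n_sequences: int = 0
    total_symbols: int = 0
    loglik_history: list[float] = field(default_factory=list)
    selection_table: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        S = self.n_states
        if self.pi.shape != (S,) or self.A.shape != (S, S):
            raise ValueError("inconsistent shapes")
        if abs(self.pi.sum() - 1.0) > _ROW_TOL or self.pi[0] != 1.0:
            raise ValueError("pi must be the first basis vector")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.abs(self.B.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ValueError("emission rows must sum to 1")
        if np.any(np.tril(self.A, k=-1) != 0):
            raise ValueError("transitions must be left-to-right (upper triangular)")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "S": self.n_states,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "loglik": None if np.isnan(self.log_likelihood) else self.log_likelihood,
            "alphabet": list(SYMBOL_LABELS),
            "n_sequences": self.n_sequences,
            "total_symbols": self.total_symbols,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LeftToRightHMM":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            pi=np.array(payload["pi"]),
            A=np.array(payload["A"]),
            B=np.array(payload["B"]),
            log_likelihood=payload.get("loglik") or float("nan"),
            n_sequences=payload.get("n_sequences", 0),
            total_symbols=payload.get("total_symbols", 0),
        )


def _check_symbols(seq: np.ndarray, n_symbols: int) -> np.ndarray:
    seq = np.asarray(seq, dtype=np.int64)
    if seq.size and (seq.min() < 0 or seq.max() >= n_symbols):
        raise ValueError(f"symbols outside alphabet 0..{n_symbols - 1}")
    return seq


def forward_loglik(model: LeftToRightHMM, seq) -> float:
    """Log-likelihood of one sequence via the scaled forward recursion."""
    seq = _check_symbols(seq, model.B.shape[1])
    alpha = model.pi * model.B[:, seq[0]]
    total = alpha.sum()
    if total == 0.0:
        return -np.inf
    loglik = np.log(total)
    alpha /= total
    for obs in seq[1:]:
        alpha = (alpha @ model.A) * model.B[:, obs]
        total = alpha.sum()
        if total == 0.0:
            return -np.inf
        loglik += np.log(total)
        alpha /= total
    return float(loglik)


def _batched_e_step(model: LeftToRightHMM, obs: np.ndarray):
    """Forward-backward for a batch of equal-length sequences.

    ``obs`` has shape (N, T).  Returns (loglik_total, gamma, xi_sum,
    gamma_emit) with gamma shape (N, T, S), xi_sum shape (S, S) summed over
    batch and time, and gamma summed per emitted symbol, shape (S, K).
    """
    N, T = obs.shape
    S = model.n_states
    K = model.B.shape[1]
    Bobs = model.B[:, obs].transpose(1, 2, 0)  # (N, T, S)

    alpha = np.empty((N, T, S))
    scale = np.empty((N, T))
    a = model.pi[None, :] * Bobs[:, 0]
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] == 0.0):
        return -np.inf, None, None, None
    alpha[:, 0] = a / scale[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ model.A) * Bobs[:, t]
        scale[:, t] = a.sum(axis=1)
        if np.any(scale[:, t] == 0.0):
            return -np.inf, None, None, None
        alpha[:, t] = a / scale[:, t, None]
    loglik = float(np.log(scale).sum())

    beta = np.empty((N, T, S))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        nxt = Bobs[:, t + 1] * beta[:, t + 1]  # (N, S)
        beta[:, t] = (nxt @ model.A.T) / scale[:, t + 1, None]
        # xi_t(i,j) = alpha_t(i) A_ij B_j(o_{t+1}) beta_{t+1}(j) / scale_{t+1}
        xi_sum += model.A * (
            alpha[:, t].T @ (nxt / scale[:, t + 1, None])
        )

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma_emit = np.zeros((S, K))
    flat_obs = obs.reshape(-1)
    flat_gamma = gamma.reshape(-1, S)
    np.add.at(gamma_emit.T, flat_obs, flat_gamma)
    return loglik, gamma, xi_sum, gamma_emit


def _initial_model(S: int, n_symbols: int, rng: np.random.Generator) -> LeftToRightHMM:
    """Random emissions (flat Dirichlet), uniform allowed transitions, pi=e1."""
    pi = np.zeros(S)
    pi[0] = 1.0
    A = np.triu(np.ones((S, S)))
    A /= A.sum(axis=1, keepdims=True)
    B = rng.dirichlet(np.ones(n_symbols), size=S)
    return LeftToRightHMM(pi=pi, A=A, B=B)


def _chain_mask(S: int) -> np.ndarray:
    return np.triu(np.ones((S, S))) - np.triu(np.ones((S, S)), k=2)


def baum_welch(
    seqs: list,
    n_states: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_restarts: int = 5,
    chain: bool = False,
    n_symbols: int = N_SYMBOLS,
) -> LeftToRightHMM:
    """Fit a left-to-right categorical HMM by multi-sequence EM.

    The left-to-right zero mask and pi = e1 are structural: they are imposed
    at initialization and preserved exactly by the multiplicative EM updates.
    The best of ``n_restarts`` seeded restarts (by final log-likelihood) is
    returned; its per-iteration log-likelihoods are in ``loglik_history``.

    ``chain`` restricts transitions to self-loops and the immediate
    successor; the default allows skipping states forward.
    """
    seqs = [_check_symbols(s, n_symbols) for s in seqs if len(np.asarray(s))]
    if not seqs:
        raise ValueError("no non-empty sequences to fit")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    # group equal-length sequences into batches for the vectorized E-step
    by_len: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    batches = [np.stack(group) for group in by_len.values()]
    total_symbols = sum(len(s) for s in seqs)

    rng = np.random.default_rng(seed)
    best: LeftToRightHMM | None = None
    for _ in range(max(1, n_restarts)):
        model = _initial_model(n_states, n_symbols, rng)
        if chain and n_states > 1:
            A = model.A * _chain_mask(n_states)
            model.A = A / A.sum(axis=1, keepdims=True)
        history: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            loglik = 0.0
            xi_total = np.zeros((n_states, n_states))
            denom_total = np.zeros(n_states)
            emit_total = np.zeros((n_states, n_symbols))
            occ_total = np.zeros(n_states)
            dead = False
            for obs in batches:
                ll, gamma, xi_sum, gamma_emit = _batched_e_step(model, obs)
                if not np.isfinite(ll):
                    dead = True
                    break
                loglik += ll
                xi_total += xi_sum
                denom_total += gamma[:, :-1].sum(axis=(0, 1))
                emit_total += gamma_emit
                occ_total += gamma.sum(axis=(0, 1))
            if dead:
                break
            history.append(loglik)
            # M-step: rows with no expected visits keep their current values
            A_new = model.A.copy()
            visited = denom_total > 0
            A_new[visited] = xi_total[visited] / denom_total[visited, None]
            B_new = model.B.copy()
            emitted = occ_total > 0
            B_new[emitted] = emit_total[emitted] / occ_total[emitted, None]
            model = replace(model, A=A_new, B=B_new)
            if np.isfinite(prev) and loglik - prev < tol * abs(prev):
                break
            prev = loglik
        if not history:
            continue
        model.log_likelihood = history[-1]
        model.loglik_history = history
        model.n_sequences = len(seqs)
        model.total_symbols = total_symbols
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise RuntimeError("all EM restarts failed (zero-probability data)")
    return best


def _n_free_params(S: int, n_symbols: int = N_SYMBOLS) -> int:
    """Free parameters: upper-triangular transitions minus row constraints,
    plus emissions; pi is fixed."""
    return (S * (S + 1) // 2 - S) + (n_symbols - 1) * S


def select_states(
    seqs: list,
    s_max: int = 4,
    criterion: str = "delta",
    delta: float = 0.01,
    seed: int = 0,
    **fit_kwargs,
) -> LeftToRightHMM:
    """Fit S = 1..s_max and return the selected model.

    ``delta`` criterion: grow the model while each added state improves the
    log-likelihood by at least a relative ``delta``; return the last model
    before the gains fall below it.  ``bic`` criterion: minimize BIC with
    the left-to-right parameter count.  The full score table is attached to
    the returned model as ``selection_table``.
    """
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    if criterion not in ("delta", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    fits: list[LeftToRightHMM] = []
    table: list[dict] = []
    n_obs = None
    for S in range(1, s_max + 1):
        model = baum_welch(seqs, S, seed=seed, **fit_kwargs)
        if n_obs is None:
            n_obs = model.total_symbols
        bic = -2.0 * model.log_likelihood + _n_free_params(S) * np.log(n_obs)
        table.append({"S": S, "loglik": model.log_likelihood, "bic": bic})
        fits.append(model)

    if criterion == "bic":
        chosen = fits[int(np.argmin([row["bic"] for row in table]))]
    else:
        chosen = fits[0]
        for model in fits[1:]:
            gain = model.log_likelihood - chosen.log_likelihood
            # inclusive: a zero gain on a perfectly fit model must stop growth
            if gain <= delta * abs(chosen.log_likelihood):
                break
            chosen = model
    chosen.selection_table = table
    return chosen


def prune_for_display(
    model: LeftToRightHMM,
    emission_threshold: float = 0.05,
    transition_threshold: float = 0.01,
) -> LeftToRightHMM:
    """Copy with small entries zeroed for rendering only.

    Emissions <= 0.05 and transitions <= 0.01 are dropped from the drawing,
    as in the published figures; the rows are deliberately NOT renormalized,
    so the display model is not a probability model.
    """
    B = model.B.copy()
    B[B <= emission_threshold] = 0.0
    A = model.A.copy()
    A[A <= transition_threshold] = 0.0
    return replace(model, A=A, B=B)


def sample(model: LeftToRightHMM, length: int, seed: int = 0) -> np.ndarray:
    """Generate a symbol sequence: start in state 1, walk A, emit per B.

    Rows of A or B that were zeroed for display are renormalized on the fly;
    a state with no outgoing mass self-loops.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    S, K = model.B.shape
    state = 0
    out = np.empty(length, dtype=np.int64)
    for t in range(length):
        b = model.B[state]
        total = b.sum()
        probs = b / total if total > 0 else np.full(K, 1.0 / K)
        out[t] = rng.choice(K, p=probs)
        a = model.A[state]
        total = a.sum()
        if total > 0:
            state = int(rng.choice(S, p=a / total))
    return out


def to_dot(model: LeftToRightHMM, labels: tuple[str, ...] = SYMBOL_LABELS) -> str:
    """Render a (typically pruned) model as GraphViz DOT text.

    One box per state listing the surviving conditional actions with their
    emission probabilities; the initial state is bold; surviving transitions
    (including self-loops) become labelled edges.
    """
    lines = [
        "digraph hmm {",
        "  rankdir=LR;",
        '  node [shape=box, fontname="Helvetica"];',
    ]
    for i in range(model.n_states):
        emissions = [
            f"{labels[k]} {model.B[i, k]:.2f}"
            for k in range(model.B.shape[1])
            if model.B[i, k] > 0
        ]
        label = f"s{i + 1}\\n" + "\\n".join(emissions)
        style = ', style=bold, penwidth=2' if i == 0 else ""
        lines.append(f'  s{i} [label="{label}"{style}];')
    for i in range(model.n_states):
        for j in range(model.n_states):
            if model.A[i, j] > 0:
                lines.append(f'  s{i} -> s{j} [label="{model.A[i, j]:.2f}"];')
    lines.append("}")
    return "\n".join(lines)
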