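"""Conditional-action encoding of IPD play.

The previous round's (own, opponent) action pair is the *context* of the
current decision; combining it with the current action yields one of eight
conditional actions, written e.g. ``(CD)D``.  The fixed integer alphabet is

    (CC)C=0  (CC)D=1  (CD)C=2  (CD)D=3  (DC)C=4  (DC)D=5  (DD)C=6  (DD)D=7

i.e. symbol = 2 * context_index + (0 for C, 1 for D) with contexts ordered
CC, CD, DC, DD.  Round 1 has no context and produces no symbol, so a T-round
game encodes to T - 1 symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .strategies import ACTIONS, CONTEXTS

N_SYMBOLS = 8

#: Human-readable triplet for each symbol, e.g. SYMBOL_LABELS[3] == "(CD)D".
SYMBOL_LABELS: tuple[str, ...] = tuple(
    f"({ctx}){a}" for ctx in CONTEXTS for a in ACTIONS
)


def encode_pair(context: str, action: str) -> int:
    """Map a (context, action) pair to its integer symbol."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    return 2 * CONTEXTS.index(context) + ACTIONS.index(action)


def decode_symbol(symbol: int) -> tuple[str, str]:
    """Invert :func:`encode_pair`: symbol -> (context, action)."""
    if not 0 <= symbol < N_SYMBOLS:
        raise ValueError(f"symbol {symbol!r} outside 0..{N_SYMBOLS - 1}")
    return CONTEXTS[symbol // 2], ACTIONS[symbol % 2]


@dataclass
class ConditionalActionSequence:
    """One player's ordered conditional-action symbols for a round window."""

    player: str
    window: str
    symbols: np.ndarray

    def __len__(self) -> int:
        return len(self.symbols)


def sequence_encode(
    own_actions: Sequence[str], opp_actions: Sequence[str]
) -> np.ndarray:
    """Encode aligned own/opponent action sequences into symbols.

    The symbol at position t-2 combines the context from round t-1 (own and
    opponent executed actions) with the own action at round t, so a T-round
    game yields T-1 symbols.
    """
    if len(own_actions) != len(opp_actions):
        raise ValueError("own and opponent action sequences differ in length")
    if len(own_actions) < 2:
        raise ValueError("need at least 2 rounds to encode a conditional action")
    symbols = np.empty(len(own_actions) - 1, dtype=np.int64)
    for t in range(1, len(own_actions)):
        context = own_actions[t - 1] + opp_actions[t - 1]
        symbols[t - 1] = encode_pair(context, own_actions[t])
    return symbols


@dataclass
class ContextProfile:
    """How often a player experienced each context (CC, CD, DC, DD)."""

    player: str
    counts: np.ndarray  # shape (4,), n_cc, n_cd, n_dc, n_dd


@dataclass
class BehaviorProfile:
    """Cooperative responses per context; probabilities undefined where n=0."""

    player: str
    coop_counts: np.ndarray  # shape (4,), c_cc, c_cd, c_dc, c_dd
    context_counts: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        """p(C | context); NaN flags a context the player never experienced."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.context_counts > 0,
                self.coop_counts / np.maximum(self.context_counts, 1),
                np.nan,
            )


def profiles(seq: ConditionalActionSequence) -> tuple[ContextProfile, BehaviorProfile]:
    """Tally context counts and cooperative-response counts from symbols."""
    symbols = np.asarray(seq.symbols)
    if symbols.size == 0:
        raise ValueError("empty symbol sequence")
    tally = np.bincount(symbols, minlength=N_SYMBOLS)
    context_counts = tally.reshape(4, 2).sum(axis=1)
    coop_counts = tally.reshape(4, 2)[:, 0]
    return (
        ContextProfile(seq.player, context_counts),
        BehaviorProfile(seq.player, coop_counts, context_counts),
    )


def _player_actions(games: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """Per-player (own, opponent) action lists ordered by round."""
    out: dict[str, tuple[list[str], list[str]]] = {}
    for player, group in games.sort_values("round").groupby("player", sort=True):
        out[str(player)] = (list(group["action"]), list(group["opp_action"]))
    return out


def encode_table(
    games: pd.DataFrame, window: tuple[int, int] | None = None, label: str = "full"
) -> list[ConditionalActionSequence]:
    """Encode every player of a game table, optionally restricted to a window.

    ``window`` is an inclusive 1-based round range.  Contexts cross window
    boundaries: the first symbol of rounds 26-50 uses round 25's actions,
    because players saw the previous round regardless of how the analyst
    windows the data.  Only round 1 of the game itself lacks a context, so
    the first window is one symbol shorter than the others.
    """
    if games.empty:
        raise ValueError("empty game table")
    sequences = []
    for player, (own, opp) in _player_actions(games).items():
        full = sequence_encode(own, opp)  # full[t-2] is the symbol of round t
        if window is None:
            symbols = full
        else:
            lo, hi = window
            symbols = full[max(lo, 2) - 2 : hi - 1]
        sequences.append(ConditionalActionSequence(player, label, symbols))
    return sequences


def round_windows(n_rounds: int, window_size: int = 25) -> list[tuple[str, int, int]]:
    """Labelled (W1..Wk) inclusive round ranges covering the game."""
    if n_rounds < 2 * window_size:
        raise ValueError("need at least two full windows of rounds")
    n_windows = n_rounds // window_size
    return [
        (f"W{w + 1}", w * window_size + 1, (w + 1) * window_size)
        for w in range(n_windows)
    ]


def profile_table(sequences: Iterable[ConditionalActionSequence]) -> pd.DataFrame:
    """Per-player context and cooperative-response counts as a DataFrame."""
    rows = []
    for seq in sequences:
        ctx, beh = profiles(seq)
        rows.append(
            (seq.player, *ctx.counts.tolist(), *beh.coop_counts.tolist())
        )
    columns = ["player", "n_cc", "n_cd", "n_dc", "n_dd", "c_cc", "c_cd", "c_dc", "c_dd"]
    return pd.DataFrame(rows, columns=columns).set_index("player")


def treatment_summary(games: pd.DataFrame) -> pd.DataFrame:
    """Pooled context frequencies and per-context cooperation fractions.

    Returns a DataFrame indexed by context with columns ``frequency`` (sums
    to 1 over the four contexts) and ``coop_fraction`` (fraction of symbols
    in that context where the subsequent action was C; NaN if never seen).
    """
    sequences = encode_table(games)
    tally = np.zeros(N_SYMBOLS, dtype=np.int64)
    for seq in sequences:
        tally += np.bincount(seq.symbols, minlength=N_SYMBOLS)
    per_context = tally.reshape(4, 2)
    totals = per_context.sum(axis=1)
    with np.errstate(invalid="ignore"):
        coop = np.where(totals > 0, per_context[:, 0] / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(
        {"frequency": totals / totals.sum(), "coop_fraction": coop},
        index=pd.Index(CONTEXTS, name="context"),
    )
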