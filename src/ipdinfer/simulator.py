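"""Synthetic IPD cohorts with known ground-truth strategies.

Generates long-format game tables that mirror the structure of laboratory
IPD experiments: two treatments (fixed partners ``FP``, shuffled partners
``SP``), 100 rounds by default, and payoffs R=3, S=0, T=4, P=1.  Every player
is driven by a stochastic memory-one strategy with execution noise, and the
ground truth is returned alongside the game table so that downstream
inference can be scored against the planted cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .strategies import ARCHETYPES, StrategySpec, act, archetype

GAME_COLUMNS = [
    "treatment",
    "session",
    "round",
    "player",
    "opponent",
    "action",
    "opp_action",
    "payoff",
]

TRUTH_COLUMNS = [
    "player",
    "strategy_name",
    "p_init",
    "p_cc",
    "p_cd",
    "p_dc",
    "p_dd",
    "noise",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Per-round rewards: reward R, sucker S, temptation T, punishment P.

    The defaults give the dilemma ordering T > R > P > S with 2R > T + S,
    so mutual cooperation beats alternating exploitation.
    """

    R: int = 3
    S: int = 0
    T: int = 4
    P: int = 1

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError("payoffs must satisfy T > R > P > S")
        if not (2 * self.R > self.T + self.S):
            raise ValueError("payoffs must satisfy 2R > T + S")


def payoff(action_a: str, action_b: str, m: PayoffMatrix | None = None) -> tuple[int, int]:
    """Per-round rewards for the focal player and the co-player."""
    m = m or PayoffMatrix()
    table = {
        ("C", "C"): (m.R, m.R),
        ("C", "D"): (m.S, m.T),
        ("D", "C"): (m.T, m.S),
        ("D", "D"): (m.P, m.P),
    }
    try:
        return table[(action_a, action_b)]
    except KeyError:
        raise ValueError(f"invalid actions {(action_a, action_b)!r}") from None


def make_schedule(
    n_players: int,
    n_rounds: int,
    mode: str,
    seed: int | np.random.Generator = 0,
) -> list[list[tuple[int, int]]]:
    """Per-round perfect matchings of player indices 0..n_players-1.

    ``FP`` repeats the adjacent pairing (0,1), (2,3), ... every round, so a
    cohort list ordered in intended pairs keeps those pairs.  ``SP`` draws a
    uniform random perfect matching each round, rejecting any matching in
    which some player keeps the previous round's opponent.
    """
    if n_players < 2 or n_players % 2 != 0:
        raise ValueError("n_players must be an even integer >= 2")
    if mode not in ("FP", "SP"):
        raise ValueError(f"mode must be 'FP' or 'SP', got {mode!r}")
    if mode == "SP" and n_players == 2:
        raise ValueError("SP needs >= 4 players: a single pair must repeat")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if mode == "FP":
        matching = [(i, i + 1) for i in range(0, n_players, 2)]
        return [list(matching) for _ in range(n_rounds)]

    schedule: list[list[tuple[int, int]]] = []
    prev_opp: dict[int, int] = {}
    for _ in range(n_rounds):
        while True:
            order = rng.permutation(n_players)
            matching = [
                (int(order[i]), int(order[i + 1])) for i in range(0, n_players, 2)
            ]
            if all(prev_opp.get(a) != b for a, b in matching):
                break
        schedule.append(matching)
        prev_opp = {}
        for a, b in matching:
            prev_opp[a] = b
            prev_opp[b] = a
    return schedule


@dataclass
class SimulationResult:
    """A simulated treatment: the long-format game table plus ground truth."""

    games: pd.DataFrame
    truth: pd.DataFrame

    @property
    def players(self) -> list[str]:
        return list(self.truth["player"])


def _player_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def simulate(
    cohort: list[StrategySpec],
    n_rounds: int = 100,
    mode: str = "FP",
    m: PayoffMatrix | None = None,
    seed: int = 0,
    session: str = "S1",
) -> SimulationResult:
    """Play a full treatment and return the game table with ground truth.

    Each player carries the executed actions of their previous round (own and
    opponent's) as the context for the next decision — in SP this means the
    context refers to the *previous* partner, exactly as participants saw it.
    """
    if len(cohort) % 2 != 0 or len(cohort) < 2:
        raise ValueError("cohort size must be even and >= 2")
    m = m or PayoffMatrix()
    rng = np.random.default_rng(seed)
    schedule = make_schedule(len(cohort), n_rounds, mode, rng)
    ids = _player_ids(len(cohort))

    # last executed (own, opponent) actions per player; None before round 1
    context: list[tuple[str, str] | None] = [None] * len(cohort)
    rows: list[tuple] = []
    for rnd, matching in enumerate(schedule, start=1):
        actions: dict[int, str] = {}
        for a, b in matching:
            ctx_a = None if context[a] is None else "".join(context[a])
            ctx_b = None if context[b] is None else "".join(context[b])
            actions[a] = act(cohort[a], ctx_a, rng)
            actions[b] = act(cohort[b], ctx_b, rng)
        for a, b in matching:
            pay_a, pay_b = payoff(actions[a], actions[b], m)
            rows.append((mode, session, rnd, ids[a], ids[b], actions[a], actions[b], pay_a))
            rows.append((mode, session, rnd, ids[b], ids[a], actions[b], actions[a], pay_b))
            context[a] = (actions[a], actions[b])
            context[b] = (actions[b], actions[a])

    games = pd.DataFrame(rows, columns=GAME_COLUMNS)
    games = games.sort_values(["round", "player"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "player": ids,
            "strategy_name": [s.name for s in cohort],
            "p_init": [s.p_init for s in cohort],
            "p_cc": [s.p_cc for s in cohort],
            "p_cd": [s.p_cd for s in cohort],
            "p_dc": [s.p_dc for s in cohort],
            "p_dd": [s.p_dd for s in cohort],
            "noise": [s.noise for s in cohort],
        }
    )
    return SimulationResult(games=games, truth=truth)


def validate_game_table(games: pd.DataFrame, m: PayoffMatrix | None = None) -> None:
    """Check the structural invariants of a long-format game table.

    Raises ``ValueError`` on the first violated invariant: schema, one row
    per player per round, symmetric pairing with mirrored actions, and
    payoffs consistent with the payoff matrix.
    """
    m = m or PayoffMatrix()
    missing = [c for c in GAME_COLUMNS if c not in games.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if games.empty:
        raise ValueError("empty game table")
    dup = games.duplicated(subset=["round", "player"])
    if dup.any():
        raise ValueError("a player appears more than once in a round")
    indexed = games.set_index(["round", "player"])
    for (rnd, player), row in indexed.iterrows():
        try:
            mirror = indexed.loc[(rnd, row["opponent"])]
        except KeyError:
            raise ValueError(f"round {rnd}: {row['opponent']} has no row") from None
        if mirror["opponent"] != player:
            raise ValueError(f"round {rnd}: pairing not symmetric for {player}")
        if mirror["action"] != row["opp_action"] or mirror["opp_action"] != row["action"]:
            raise ValueError(f"round {rnd}: actions not mirrored for {player}")
        expected, _ = payoff(row["action"], row["opp_action"], m)
        if int(row["payoff"]) != expected:
            raise ValueError(f"round {rnd}: payoff inconsistent for {player}")


def default_cohort(
    n_players: int, seed: int = 0, noise: float = 0.05
) -> list[StrategySpec]:
    """A heterogeneous cohort drawn from the archetype registry.

    Weights lean toward the conditional strategies that dominate observed
    human play (TFT-like reciprocation, WSLS) while keeping unconditional
    cooperators, defectors and noise players in the mix.
    """
    names = ["AllC", "AllD", "TFT", "GTFT", "WSLS", "Grim", "Random"]
    weights = np.array([0.15, 0.15, 0.20, 0.10, 0.15, 0.10, 0.15])
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(names), size=n_players, p=weights)
    return [archetype(names[i], noise=noise) for i in draws]


def write_game_table(result: SimulationResult, games_path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write the game table CSV and, optionally, the ground-truth sidecar."""
    result.games.to_csv(games_path, index=False)
    if truth_path is not None:
        result.truth.to_csv(truth_path, index=False)


def read_game_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format game table CSV (schema as written by this module)."""
    games = pd.read_csv(path, dtype={"treatment": str, "session": str, "player": str, "opponent": str})
    missing = [c for c in GAME_COLUMNS if c not in games.columns]
    if missing:
        raise ValueError(f"game table at {path} missing columns: {missing}")
    return games


def import_game_table(
    path: str | Path,
    column_map: dict[str, str],
    action_map: dict[str, str] | None = None,
    m: PayoffMatrix | None = None,
) -> pd.DataFrame:
    """Adapt an externally deposited long-format table to the native schema.

    ``column_map`` maps native column names to the source file's column
    names; ``action_map`` translates the source's action labels to C/D.
    The payoff column is recomputed if absent from the map.
    """
    raw = pd.read_csv(path)
    out = pd.DataFrame()
    for native, source in column_map.items():
        if native not in GAME_COLUMNS:
            raise ValueError(f"unknown native column {native!r}")
        if source not in raw.columns:
            raise ValueError(f"source column {source!r} not in {path}")
        out[native] = raw[source]
    if action_map:
        out["action"] = out["action"].map(action_map)
        out["opp_action"] = out["opp_action"].map(action_map)
    if out[["action", "opp_action"]].isna().any().any():
        raise ValueError("unmapped action labels in imported table")
    if "payoff" not in out.columns:
        out["payoff"] = [
            payoff(a, b, m)[0] for a, b in zip(out["action"], out["opp_action"])
        ]
    for col in GAME_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"column map does not produce {col!r}")
    return out[GAME_COLUMNS]
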