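"""Stochastic memory-one strategies for the Iterated Prisoner's Dilemma.

A memory-one strategy is fully described by five probabilities: the chance of
cooperating in the opening round (``p_init``) and the chance of cooperating
after each of the four possible previous-round outcomes, written
player-then-opponent: CC, CD, DC, DD.  An execution-noise parameter flips the
intended action with some probability, modelling trembling-hand errors; the
co-player observes the executed (noisy) action.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: The four memory-one contexts, ordered player-then-opponent.
CONTEXTS: tuple[str, ...] = ("CC", "CD", "DC", "DD")

ACTIONS: tuple[str, str] = ("C", "D")


@dataclass(frozen=True)
class StrategySpec:
    """A stochastic memory-one IPD strategy.

    Parameters
    ----------
    name
        Human-readable label (e.g. ``"TFT"``).
    p_init
        Probability of cooperating in round 1, when no context exists.
    p_cc, p_cd, p_dc, p_dd
        Probability of cooperating after the previous round's outcome was
        CC, CD, DC or DD respectively (own action first).
    noise
        Execution-error probability: the intended action is flipped with this
        probability, independently each round.
    """

    name: str
    p_init: float
    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float
    noise: float = 0.0

    def __post_init__(self) -> None:
        for field in ("p_init", "p_cc", "p_cd", "p_dc", "p_dd", "noise"):
            value = getattr(self, field)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{field}={value!r} outside [0, 1]")

    @property
    def conditional_probs(self) -> np.ndarray:
        """Cooperation probabilities for contexts CC, CD, DC, DD, in order."""
        return np.array([self.p_cc, self.p_cd, self.p_dc, self.p_dd])

    def with_noise(self, noise: float) -> "StrategySpec":
        return replace(self, noise=noise)

    def prob_cooperate(self, context: str | None) -> float:
        """Intended cooperation probability for a context (None = round 1)."""
        if context is None or context == "none":
            return self.p_init
        try:
            return float(self.conditional_probs[CONTEXTS.index(context)])
        except ValueError:
            raise ValueError(f"unknown context {context!r}") from None


#: Canonical archetypes, as (p_init, p_cc, p_cd, p_dc, p_dd).  Grim is the
#: memory-one approximation of the grim trigger; Random is the coin-flipper.
ARCHETYPES: dict[str, StrategySpec] = {
    "AllC": StrategySpec("AllC", 1, 1, 1, 1, 1),
    "AllD": StrategySpec("AllD", 0, 0, 0, 0, 0),
    "TFT": StrategySpec("TFT", 1, 1, 0, 1, 0),
    "GTFT": StrategySpec("GTFT", 1, 1, 1 / 3, 1, 1 / 3),
    "WSLS": StrategySpec("WSLS", 1, 1, 0, 0, 1),
    "Grim": StrategySpec("Grim", 1, 1, 0, 0, 0),
    "Random": StrategySpec("Random", 0.5, 0.5, 0.5, 0.5, 0.5),
}


def archetype(name: str, noise: float = 0.0) -> StrategySpec:
    """Look up a registry archetype, optionally with execution noise."""
    try:
        base = ARCHETYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown archetype {name!r}; known: {', '.join(ARCHETYPES)}"
        ) from None
    return base.with_noise(noise)


def act(strategy: StrategySpec, context: str | None, rng: np.random.Generator) -> str:
    """Sample one executed action.

    The intended action is C with the context-appropriate probability; the
    executed action is the intended one flipped with probability
    ``strategy.noise``.
    """
    p = strategy.prob_cooperate(context)
    intended = "C" if rng.random() < p else "D"
    if strategy.noise > 0 and rng.random() < strategy.noise:
        return "D" if intended == "C" else "C"
    return intended
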