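"""End-to-end strategy inference: encode → cluster → sub-cluster → HMM.

``run_pipeline`` takes one treatment's game table and produces a full
report: contextual clusters (labelled A, B, C, ... from most to least
mutually cooperative), behavioral sub-clusters (A.0, A.1, ...), pooled
conditional-cooperation vectors with binomial standard errors, a fitted
left-to-right HMM per sub-cluster, and nearest-archetype calls.
``window_analysis`` repeats the procedure on 25-round windows to expose
learning effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, encoding, hmm
from .strategies import ARCHETYPES, CONTEXTS, StrategySpec

logger = logging.getLogger("ipdinfer")


@dataclass
class PipelineConfig:
    """Tunable knobs for one pipeline run; defaults match the main analysis."""

    seed: int = 0
    k_max_contextual: int = 8
    k_max_behavioral: int = 6
    kmeans_restarts: int = 10
    normalize: bool = False
    s_max: int = 4
    criterion: str = "delta"
    delta: float = 0.01
    hmm_restarts: int = 5
    hmm_tol: float = 1e-4
    hmm_max_iter: int = 500
    chain: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ArchetypeCall:
    """Nearest memory-one archetype to a conditional-cooperation vector."""

    subcluster: str
    coop_vector: np.ndarray
    archetype: str
    distance: float


@dataclass
class SubClusterReport:
    """Everything inferred for one behavioral sub-cluster."""

    id: str
    players: list[str]
    context_counts: np.ndarray  # pooled n_cc..n_dd
    coop_vector: np.ndarray  # pooled p(C|context), NaN where never seen
    coop_se: np.ndarray  # binomial standard errors, NaN where undefined
    model: hmm.LeftToRightHMM
    display_model: hmm.LeftToRightHMM
    archetype: ArchetypeCall


@dataclass
class PipelineReport:
    """Full output bundle for one treatment (or one round window)."""

    treatment: str
    window: str
    assignments: pd.DataFrame  # player -> context_cluster, behavior_subcluster
    cluster_summary: pd.DataFrame  # Table-2-style rows
    contextual_model: clustering.ClusterModel
    subclusters: list[SubClusterReport] = field(default_factory=list)
    context_composition: pd.DataFrame | None = None

    @property
    def n_subclusters(self) -> int:
        return len(self.subclusters)


def classify_archetype(
    coop_vector: np.ndarray,
    registry: dict[str, StrategySpec] | None = None,
    subcluster: str = "",
) -> ArchetypeCall:
    """Nearest archetype by L1 distance on (p_cc, p_cd, p_dc, p_dd).

    Undefined entries (NaN: the context was never experienced) are excluded
    from the distance together with the matching registry entries.  Ties
    break by registry order.
    """
    registry = registry or ARCHETYPES
    vec = np.asarray(coop_vector, dtype=float)
    defined = ~np.isnan(vec)
    if not defined.any():
        raise ValueError("all conditional-cooperation entries undefined")
    best_name, best_dist = None, np.inf
    for name, spec in registry.items():
        dist = float(np.abs(vec[defined] - spec.conditional_probs[defined]).sum())
        if dist < best_dist:
            best_name, best_dist = name, dist
    return ArchetypeCall(subcluster, vec, best_name, best_dist)


def first_round_cooperation(games: pd.DataFrame, players: list[str] | None = None) -> float:
    """Fraction of players whose round-1 action was C."""
    first = games[games["round"] == games["round"].min()]
    if players is not None:
        first = first[first["player"].isin(players)]
    if first.empty:
        raise ValueError("no players in group")
    return float((first["action"] == "C").mean())


def questionnaire_percentage(n_yes: int, n_total: int) -> float:
    """Share of yes-answers as a percentage, rounded to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_yes <= n_total:
        raise ValueError("need 0 <= n_yes <= n_total")
    return round(100.0 * n_yes / n_total, 2)


def _cluster_names(model: clustering.ClusterModel, offset: int = 0) -> dict[int, str]:
    """Stable letters per contextual cluster, most CC-experienced first."""
    order = np.argsort(-model.centers[:, 0], kind="stable")
    return {int(raw): chr(ord("A") + offset + rank) for rank, raw in enumerate(order)}


def _pooled_behavior(profile_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled context counts, cooperation probabilities and binomial SEs."""
    n = profile_df[clustering.CONTEXT_FEATURES].to_numpy(dtype=float).sum(axis=0)
    c = profile_df[clustering.BEHAVIOR_FEATURES].to_numpy(dtype=float).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, c / np.maximum(n, 1), np.nan)
        se = np.where(n > 0, np.sqrt(p * (1 - p) / np.maximum(n, 1)), np.nan)
    return n, p, se


def run_pipeline(
    games: pd.DataFrame,
    config: PipelineConfig | None = None,
    window: tuple[int, int] | None = None,
    window_label: str = "full",
    cluster_letter_offset: int = 0,
) -> PipelineReport:
    """Run the full inference chain on one treatment's game table."""
    config = config or PipelineConfig()
    if games.empty:
        raise ValueError("empty game table")
    treatments = games["treatment"].unique()
    if len(treatments) != 1:
        raise ValueError("run_pipeline expects a single-treatment table")
    treatment = str(treatments[0])

    sequences = encoding.encode_table(games, window=window, label=window_label)
    seq_by_player = {s.player: s for s in sequences}
    profile_df = encoding.profile_table(sequences)

    ctx_model = clustering.contextual_cluster(
        profile_df,
        k_max=config.k_max_contextual,
        seed=config.seed,
        n_restarts=config.kmeans_restarts,
        normalize=config.normalize,
    )
    names = _cluster_names(ctx_model, cluster_letter_offset)
    logger.info(
        "[%s %s] contextual clustering: k=%d silhouette=%s",
        treatment, window_label, ctx_model.k,
        f"{ctx_model.silhouette:.4f}" if ctx_model.silhouette is not None else "n/a",
    )

    assignments = pd.DataFrame(
        {
            "player": profile_df.index,
            "context_cluster": [names[int(l)] for l in ctx_model.labels],
        }
    ).set_index("player")

    subclusters: list[SubClusterReport] = []
    summary_rows = []
    composition_rows = []
    for raw_label in sorted(names, key=lambda l: names[l]):
        letter = names[raw_label]
        members = profile_df.index[ctx_model.labels == raw_label]
        sub_df = profile_df.loc[members]
        freq = sub_df[clustering.CONTEXT_FEATURES].sum(axis=0).to_numpy(dtype=float)
        composition_rows.append((letter, *(freq / freq.sum()).tolist()))
        beh_model = clustering.behavioral_subcluster(
            sub_df,
            k_max=config.k_max_behavioral,
            seed=config.seed,
            n_restarts=config.kmeans_restarts,
        )
        summary_rows.append(
            (
                treatment,
                letter,
                len(members),
                beh_model.k,
                beh_model.silhouette if beh_model.silhouette is not None else np.nan,
            )
        )
        for sub_id in range(beh_model.k):
            sub_players = [p for p, l in zip(beh_model.players, beh_model.labels) if l == sub_id]
            full_id = f"{letter}.{sub_id}"
            assignments.loc[sub_players, "behavior_subcluster"] = full_id
            n, p, se = _pooled_behavior(profile_df.loc[sub_players])
            seqs = [seq_by_player[p].symbols for p in sub_players]
            model = hmm.select_states(
                seqs,
                s_max=config.s_max,
                criterion=config.criterion,
                delta=config.delta,
                seed=config.seed,
                tol=config.hmm_tol,
                max_iter=config.hmm_max_iter,
                n_restarts=config.hmm_restarts,
                chain=config.chain,
            )
            logger.info(
                "[%s %s] sub-cluster %s: n=%d S=%d loglik=%.2f",
                treatment, window_label, full_id, len(sub_players),
                model.n_states, model.log_likelihood,
            )
            call = classify_archetype(p, subcluster=full_id)
            subclusters.append(
                SubClusterReport(
                    id=full_id,
                    players=sub_players,
                    context_counts=n,
                    coop_vector=p,
                    coop_se=se,
                    model=model,
                    display_model=hmm.prune_for_display(model),
                    archetype=call,
                )
            )

    cluster_summary = pd.DataFrame(
        summary_rows,
        columns=["treatment", "cluster", "n", "n_subclusters", "silhouette"],
    )
    composition = pd.DataFrame(
        composition_rows, columns=["cluster", *[c.lower() for c in CONTEXTS]]
    ).set_index("cluster")
    return PipelineReport(
        treatment=treatment,
        window=window_label,
        assignments=assignments,
        cluster_summary=cluster_summary,
        contextual_model=ctx_model,
        subclusters=subclusters,
        context_composition=composition,
    )


def window_analysis(
    games: pd.DataFrame,
    config: PipelineConfig | None = None,
    window_size: int = 25,
) -> dict[str, PipelineReport]:
    """Re-run the pipeline on consecutive round windows (W1, W2, ...).

    Contexts cross window boundaries, so every window after the first has
    ``window_size`` symbols per player and the first has one fewer.
    """
    n_rounds = int(games["round"].max())
    windows = encoding.round_windows(n_rounds, window_size)
    return {
        label: run_pipeline(games, config, window=(lo, hi), window_label=label)
        for label, lo, hi in windows
    }


def save_report(report: PipelineReport, outdir: str | Path) -> None:
    """Persist a report bundle: CSVs, HMM JSON files and DOT renderings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.assignments.to_csv(outdir / "assignments.csv")
    report.cluster_summary.to_csv(outdir / "cluster_summary.csv", index=False)
    if report.context_composition is not None:
        report.context_composition.to_csv(outdir / "context_composition.csv")
    coop_rows = []
    arch_rows = []
    for sub in report.subclusters:
        coop_rows.append((sub.id, len(sub.players), *sub.coop_vector, *sub.coop_se))
        arch_rows.append((sub.id, sub.archetype.archetype, sub.archetype.distance))
        sub.model.to_json(outdir / f"hmm_{sub.id}.json")
        (outdir / f"hmm_{sub.id}.dot").write_text(hmm.to_dot(sub.display_model))
    pd.DataFrame(
        coop_rows,
        columns=[
            "subcluster", "n",
            "p_cc", "p_cd", "p_dc", "p_dd",
            "se_cc", "se_cd", "se_dc", "se_dd",
        ],
    ).to_csv(outdir / "conditional_cooperation.csv", index=False)
    pd.DataFrame(
        arch_rows, columns=["subcluster", "archetype", "l1_distance"]
    ).to_csv(outdir / "archetypes.csv", index=False)
    meta = {
        "treatment": report.treatment,
        "window": report.window,
        "contextual_k": report.contextual_model.k,
        "contextual_silhouette": report.contextual_model.silhouette,
        "n_subclusters": report.n_subclusters,
    }
    (outdir / "report.json").write_text(json.dumps(meta, indent=2))
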