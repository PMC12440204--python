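"""Classification of learned strategies and Q-value summary statistics.

A run's learned strategy is read off the *realised* action sequence: the
final ``window`` rounds (default 50) are taken, rounds flagged as exploratory
are dropped, and the remaining subsequence is tested for exact periodicity
with period at most 3.  The detected cycle is canonicalised to its
lexicographically smallest rotation under the fixed action orders N < W < S
(beneficiary) and K < G (donor) and looked up in the strategy catalogue:

========  ==============================================  ====
role      strategy                                        label
========  ==============================================  ====
B         Never signal                                    NN
B         Alternate Not signal / Weak signal              NW
B         Always signal weakly                            WW
B         Alternate Not signal / Strong signal            NS
B         Alternate Weak signal / Strong signal           WS
B         Cycle Not signal, Weak signal, Strong signal    NWS
B         Cycle Not signal, Strong signal, Weak signal    NSW
B         Always signal strongly                          SS
D         Always keep                                     KK
D         Alternate Give / Keep                           GK
D         Always give                                     GG
D         Cycle Keep, Keep, Give                          KKG
========  ==============================================  ====

Anything aperiodic (or with a longer period) falls to ``OTHER``.

Two readouts of "the strategy a run learned" are provided:

``policy`` (default)
    Roll out the *converged greedy policies* deterministically from the
    run's final state until the joint dynamics enter a cycle, then classify
    each agent's actions along that cycle.  This reads the strategy off what
    the agents have learned, and is insensitive to residual ε-exploration.
``realised``
    Classify the *played* action sequence in the final ``window`` rounds,
    after dropping rounds flagged as exploratory.  This reads the strategy
    off what the agents actually did; a late exploration that knocks a
    cycle out of phase sends the run to ``OTHER``.

Runs with a static (non-learning) seat are always classified by the
realised readout, since a static seat has no policy table to roll out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import (
    AgentConfig,
    BENEFICIARY_ACTIONS,
    DONOR_ACTIONS,
    Role,
)
from .game import BeneficiaryAction, DonorAction, GameParameters

__all__ = [
    "OTHER",
    "extract_pattern",
    "label_strategy",
    "greedy_policy",
    "policy_cycle",
    "classify_record",
    "strategy_proportions",
    "proportions_from_labels",
    "QSummary",
    "q_summary",
    "SweepResult",
    "sweep_table",
    "planted_action_stream",
]

OTHER = "OTHER"

_ORDER = {a: i for i, a in enumerate(BENEFICIARY_ACTIONS)}
_ORDER.update({a: i for i, a in enumerate(DONOR_ACTIONS)})
_ORDER.update({a.value: i for i, a in enumerate(BENEFICIARY_ACTIONS)})
_ORDER.update({a.value: i for i, a in enumerate(DONOR_ACTIONS)})

_B_CATALOGUE = {
    ("N",): "NN",
    ("W",): "WW",
    ("S",): "SS",
    ("N", "W"): "NW",
    ("N", "S"): "NS",
    ("W", "S"): "WS",
    ("N", "W", "S"): "NWS",
    ("N", "S", "W"): "NSW",
}
_D_CATALOGUE = {
    ("K",): "KK",
    ("G",): "GG",
    ("K", "G"): "GK",
    ("K", "K", "G"): "KKG",
}


def _letter(action) -> str:
    return action.value if hasattr(action, "value") else str(action)


def _canonical_rotation(pattern: tuple) -> tuple:
    """Lexicographically smallest rotation under the fixed action order."""
    rotations = [
        pattern[k:] + pattern[:k] for k in range(len(pattern))
    ]
    return min(rotations, key=lambda rot: tuple(_ORDER[a] for a in rot))


def extract_pattern(
    actions: Sequence,
    explore_flags: Sequence[bool] | None = None,
    window: int = 50,
    max_period: int = 3,
) -> tuple | None:
    """Minimal repeating pattern of the final ``window`` actions, or ``None``.

    Rounds flagged exploratory are dropped before testing for exact
    periodicity; the smallest period ``k <= max_period`` wins and the cycle
    is returned in canonical rotation.  ``None`` stands for no catalogued
    periodicity (the ``OTHER`` class).
    """
    acts = list(actions)[-window:]
    if explore_flags is not None:
        flags = list(explore_flags)[-window:]
        acts = [a for a, f in zip(acts, flags) if not f]
    if not acts:
        raise ValueError("no non-exploratory rounds in the classification window")
    for k in range(1, max_period + 1):
        if len(acts) < k:
            break
        if all(acts[i] == acts[i - k] for i in range(k, len(acts))):
            return _canonical_rotation(tuple(acts[:k]))
    return None


def label_strategy(pattern: tuple | None, role: Role) -> str:
    """Map a canonical pattern to its catalogue label (``OTHER`` fallback)."""
    if pattern is None:
        return OTHER
    key = tuple(_letter(a) for a in pattern)
    catalogue = _B_CATALOGUE if role is Role.BENEFICIARY else _D_CATALOGUE
    return catalogue.get(key, OTHER)


def greedy_policy(qtable) -> dict[str, object]:
    """Greedy action per observation state (ties broken by canonical order)."""
    return {
        state: qtable.actions[int(np.argmax(qtable.values[i]))]
        for i, state in enumerate(qtable.states)
    }


def policy_cycle(record) -> tuple[tuple, tuple]:
    """Attractor cycle of the converged greedy policies of one dyad.

    Starting from the run's final joint action(s), both agents' greedy
    policies are rolled out deterministically.  On the finite state space
    the joint dynamics must enter a cycle; the patterns of beneficiary and
    donor actions along that cycle are returned (canonicalised, ``None``
    where the minimal period exceeds the catalogue's maximum of 3).
    """
    from .agents import BENEFICIARY_ACTIONS as BA, DONOR_ACTIONS as DA

    b_q, d_q = record.b_final, record.d_final
    if b_q is None or d_q is None:
        raise ValueError("policy readout needs Q tables on both seats")
    b_greedy = greedy_policy(b_q)
    d_greedy = greedy_policy(d_q)

    def make_view(states):
        # An agent's table key is the last 2m characters of the engine
        # state, possibly behind a thirst prefix ("T:"/"H:").  Views freeze
        # the prefix at the final round's thirst state.
        key = next(iter(states))
        if ":" in key:
            prefix = ("T:" if record.thirst[-1] else "H:")
            body = len(key) - 2
            return lambda s: prefix + s[-body:]
        body = len(key)
        return lambda s: s[-body:]

    b_view = make_view(b_q.states)
    d_view = make_view(d_q.states)
    widths = [len(next(iter(q.states)).split(":")[-1]) for q in (b_q, d_q)]
    state_width = max(widths)
    m = state_width // 2
    state = "".join(
        BA[bc].value + DA[dc].value
        for bc, dc in zip(record.b_actions[-m:], record.d_actions[-m:])
    )

    seen: dict[str, int] = {}
    trace: list[str] = []
    while state not in seen:
        seen[state] = len(trace)
        trace.append(state)
        b_action = b_greedy[b_view(state)]
        d_action = d_greedy[d_view(state)]
        state = (state + b_action.value + d_action.value)[-state_width:]
    cycle = trace[seen[state]:]
    b_seq = [b_greedy[b_view(s)] for s in cycle] * 3
    d_seq = [d_greedy[d_view(s)] for s in cycle] * 3
    b_pattern = extract_pattern(b_seq, None, window=len(b_seq))
    d_pattern = extract_pattern(d_seq, None, window=len(d_seq))
    return b_pattern, d_pattern


def classify_record(
    record, window: int = 50, readout: str = "policy"
) -> tuple[str, str]:
    """Strategy labels ``(beneficiary, donor)`` of one dyad record.

    ``readout`` is ``"policy"`` (greedy-policy rollout; the default) or
    ``"realised"`` (periodicity of the played tail).  Records with a static
    seat always use the realised readout.
    """
    if readout not in ("policy", "realised"):
        raise ValueError(f"unknown readout {readout!r}")
    if readout == "policy" and record.b_final is not None and record.d_final is not None:
        b_pattern, d_pattern = policy_cycle(record)
    else:
        b_pattern = extract_pattern(
            record.b_action_sequence(), record.b_explored, window=window
        )
        d_pattern = extract_pattern(
            record.d_action_sequence(), record.d_explored, window=window
        )
    return (
        label_strategy(b_pattern, Role.BENEFICIARY),
        label_strategy(d_pattern, Role.DONOR),
    )


def proportions_from_labels(labels: Sequence[str]) -> dict[str, float]:
    """Label distribution (sums to 1), sorted by descending proportion."""
    if len(labels) == 0:
        raise ValueError("no labels to aggregate")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    return dict(
        sorted(((k, v / n) for k, v in counts.items()), key=lambda kv: -kv[1])
    )


def strategy_proportions(
    records: Iterable, window: int = 50, readout: str = "policy"
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-role strategy distributions over a collection of dyad records."""
    b_labels: list[str] = []
    d_labels: list[str] = []
    for rec in records:
        lb, ld = classify_record(rec, window=window, readout=readout)
        b_labels.append(lb)
        d_labels.append(ld)
    return proportions_from_labels(b_labels), proportions_from_labels(d_labels)


@dataclass
class QSummary:
    """Converged Q-value summary: per-state means, grand means, donor gap.

    ``per_state`` frames have one row per observation state and one column
    per action letter; ``grand_mean`` series average the per-state means
    with equal weight.  ``donor_gap`` is grand mean Q(Give) minus grand mean
    Q(Keep) — the statistic that quantifies how sharply the donor has
    discriminated its two actions.
    """

    b_per_state: pd.DataFrame | None
    d_per_state: pd.DataFrame | None
    b_grand_mean: pd.Series | None
    d_grand_mean: pd.Series | None
    donor_gap: float | None


def _window_mean(record_q, snapshot_rounds, rounds, window) -> np.ndarray:
    in_window = snapshot_rounds > rounds - window
    return record_q[in_window].mean(axis=0)


def q_summary(source, window: int = 100) -> QSummary:
    """Converged Q-value statistics averaged over runs.

    ``source`` is either an :class:`~spsgame.engine.ExperimentSummary` (whose
    precomputed window means are used) or an iterable of
    :class:`~spsgame.engine.DyadRecord` with Q snapshots.  "Converged" means
    averaged over the final ``window`` rounds of each run.
    """
    b_states = d_states = None
    if hasattr(source, "window_q_b"):  # ExperimentSummary
        b_win, d_win = source.window_q_b, source.window_q_d
        b_states, d_states = source.b_states, source.d_states
    else:
        records = list(source)
        if not records:
            raise ValueError("no records given")
        b_sum = d_sum = None
        for rec in records:
            if rec.b_q is not None:
                win = _window_mean(rec.b_q, rec.snapshot_rounds, rec.rounds, window)
                b_sum = win if b_sum is None else b_sum + win
                b_states = list(rec.b_final.states)
            if rec.d_q is not None:
                win = _window_mean(rec.d_q, rec.snapshot_rounds, rec.rounds, window)
                d_sum = win if d_sum is None else d_sum + win
                d_states = list(rec.d_final.states)
        n = len(records)
        b_win = None if b_sum is None else b_sum / n
        d_win = None if d_sum is None else d_sum / n
    if b_win is None and d_win is None:
        raise ValueError("source carries no Q snapshots")

    b_frame = d_frame = b_gm = d_gm = None
    gap = None
    if b_win is not None:
        b_frame = pd.DataFrame(
            b_win, index=b_states, columns=[a.value for a in BENEFICIARY_ACTIONS]
        )
        b_gm = b_frame.mean(axis=0)
    if d_win is not None:
        d_frame = pd.DataFrame(
            d_win, index=d_states, columns=[a.value for a in DONOR_ACTIONS]
        )
        d_gm = d_frame.mean(axis=0)
        gap = float(d_gm["G"] - d_gm["K"])
    return QSummary(b_frame, d_frame, b_gm, d_gm, gap)


@dataclass
class SweepResult:
    """Strategy distributions over a learning-rate x discount-rate grid."""

    table: pd.DataFrame
    distributions: dict[tuple[float, float], tuple[dict, dict]]
    predicted_donor_label: str
    #: (lr, dr, proportion) of the grid cell where the donor learns the
    #: predicted strategy least / most often.
    min_combo: tuple[float, float, float]
    best_combo: tuple[float, float, float]

    def donor_proportion(self, label: str) -> pd.DataFrame:
        """Pivot of one donor label's proportion over the grid."""
        sub = self.table[
            (self.table.role == "donor") & (self.table.label == label)
        ]
        return sub.pivot(index="lr", columns="dr", values="proportion")


def sweep_table(
    game: GameParameters,
    learning_rates: Sequence[float] = (0.1, 0.5, 0.9),
    discount_rates: Sequence[float] = (0.1, 0.9),
    rounds: int = 500,
    n_runs: int = 1000,
    base_seed: int = 0,
    thirst_mode: str = "not_thirsty",
    progress=None,
) -> SweepResult:
    """Run one experiment per (learning rate, discount rate) combination.

    All combinations share the game parameters; run seeds are disjoint
    across grid cells (cell ``k`` uses ``base_seed + k * n_runs`` onwards).
    Snapshots are disabled for speed: the sweep summarises strategy labels
    only.
    """
    from .engine import ExperimentConfig, run_experiment
    from .game import predicted_equilibrium

    predicted_label = (
        "GG" if predicted_equilibrium(game)[1] is DonorAction.GIVE else "KK"
    )
    rows = []
    distributions: dict[tuple[float, float], tuple[dict, dict]] = {}
    for k, (lr, dr) in enumerate(
        (lr, dr) for lr in learning_rates for dr in discount_rates
    ):
        config = ExperimentConfig(
            game=game,
            beneficiary=AgentConfig(role=Role.BENEFICIARY, alpha=lr, gamma=dr),
            donor=AgentConfig(role=Role.DONOR, alpha=lr, gamma=dr),
            rounds=rounds,
            n_runs=n_runs,
            base_seed=base_seed + k * n_runs,
            thirst_mode=thirst_mode,
            snapshot_stride=0,
        )
        summary = run_experiment(config)
        distributions[(lr, dr)] = (summary.b_proportions, summary.d_proportions)
        for role, props in (
            ("beneficiary", summary.b_proportions),
            ("donor", summary.d_proportions),
        ):
            for label, prop in props.items():
                rows.append(
                    {"lr": lr, "dr": dr, "role": role, "label": label,
                     "proportion": prop}
                )
        if progress is not None:
            progress(k + 1, len(learning_rates) * len(discount_rates))

    table = pd.DataFrame(rows)
    focal = [
        (lr, dr, d_props.get(predicted_label, 0.0))
        for (lr, dr), (_, d_props) in distributions.items()
    ]
    min_combo = min(focal, key=lambda t: t[2])
    best_combo = max(focal, key=lambda t: t[2])
    return SweepResult(table, distributions, predicted_label, min_combo, best_combo)


def planted_action_stream(
    pattern: Sequence,
    n_rounds: int,
    epsilon: float,
    rng: np.random.Generator,
    actions: Sequence | None = None,
) -> tuple[list, list[bool]]:
    """Synthetic action stream for classifier validation.

    Emits a cyclic ``pattern`` perturbed by ε-exploration: each round, with
    probability ``epsilon`` a uniformly random action is played and flagged
    exploratory (the underlying strategy defers its next scheduled action);
    otherwise the next pattern element is emitted.  Mirrors an agent whose
    policy has converged to a cycle but still explores at rate ε.
    """
    if actions is None:
        actions = (
            BENEFICIARY_ACTIONS
            if isinstance(pattern[0], BeneficiaryAction)
            else DONOR_ACTIONS
        )
    # random starting phase so recovery cannot depend on alignment
    pos = int(rng.integers(len(pattern)))
    stream: list = []
    flags: list[bool] = []
    for _ in range(n_rounds):
        if rng.random() < epsilon:
            stream.append(actions[int(rng.integers(len(actions)))])
            flags.append(True)
        else:
            stream.append(pattern[pos % len(pattern)])
            pos += 1
            flags.append(False)
    return stream, flags
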