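"""Seeded dyadic simulations and batched Monte-Carlo experiments.

A *dyad* is one beneficiary/donor pair playing a fixed number of rounds
(default 500) of the Sir Philip Sidney game while Q-learning from their
inclusive-fitness rewards.  An *experiment* is a batch of independent dyads
(default 1000), each with its own derived seed, summarised by the strategy
labels the agents settle into and by the averaged Q-value trajectories.

Determinism: run ``i`` of an experiment uses seed ``base_seed + i``, split
with :class:`numpy.random.SeedSequence` into three independent streams — one
per agent (exploration, tie-breaks) plus one environment stream (pre-game
history seeding and thirst sampling).  Re-running with the same configuration
reproduces every record exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .agents import (
    AgentConfig,
    BENEFICIARY_ACTIONS,
    DONOR_ACTIONS,
    QLearningAgent,
    Role,
    StaticAgent,
    StaticPolicy,
    joint_label,
)
from .game import (
    BeneficiaryAction,
    DonorAction,
    GameParameters,
    ThirstState,
    predicted_equilibrium,
    round_rewards,
    threshold_satisfied,
)

__all__ = [
    "THIRST_MODES",
    "ExperimentConfig",
    "RoundOutcome",
    "DyadRecord",
    "ExperimentSummary",
    "play_round",
    "run_dyad",
    "run_experiment",
]

#: Valid thirst modes: the beneficiary's state may be pinned for the whole
#: run ("not_thirsty" = p effectively 0, "thirsty" = p effectively 1) or
#: sampled each round with probability ``p`` ("sampled").
THIRST_MODES = ("not_thirsty", "thirsty", "sampled")

_B_CODE = {a: i for i, a in enumerate(BENEFICIARY_ACTIONS)}
_D_CODE = {a: i for i, a in enumerate(DONOR_ACTIONS)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a batch of dyadic runs."""

    game: GameParameters
    beneficiary: AgentConfig | StaticPolicy
    donor: AgentConfig | StaticPolicy
    rounds: int = 500
    n_runs: int = 1000
    base_seed: int = 0
    thirst_mode: str = "not_thirsty"
    snapshot_stride: int = 1
    classify_window: int = 50
    classify_readout: str = "policy"
    q_window: int = 100

    def __post_init__(self) -> None:
        if self.thirst_mode not in THIRST_MODES:
            raise ValueError(
                f"thirst_mode must be one of {THIRST_MODES}, got {self.thirst_mode!r}"
            )
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.rounds < 1:
            raise ValueError("rounds must be at least 1")
        for cfg, role in ((self.beneficiary, Role.BENEFICIARY), (self.donor, Role.DONOR)):
            if isinstance(cfg, AgentConfig):
                if cfg.role is not role:
                    raise ValueError(f"{role.value} seat holds a {cfg.role.value} config")
                if self.rounds <= cfg.explore_rounds:
                    raise ValueError(
                        "rounds must exceed explore_rounds "
                        f"({self.rounds} <= {cfg.explore_rounds})"
                    )
        if self.snapshot_stride < 0:
            raise ValueError("snapshot_stride must be >= 0 (0 disables snapshots)")
        if self.classify_readout not in ("policy", "realised"):
            raise ValueError(
                f"classify_readout must be 'policy' or 'realised', "
                f"got {self.classify_readout!r}"
            )
        if not 1 <= self.classify_window <= self.rounds:
            raise ValueError("classify_window must lie in [1, rounds]")
        if self.q_window < 1:
            raise ValueError("q_window must be at least 1")


class RoundOutcome(NamedTuple):
    """Everything observable about a single round."""

    thirst: ThirstState
    b_action: BeneficiaryAction
    d_action: DonorAction
    b_explored: bool
    d_explored: bool
    reward_b: float
    reward_d: float


@dataclass
class DyadRecord:
    """Trajectory of one dyad: actions, exploration flags, rewards, Q history.

    Actions are stored as integer codes in the canonical orders N<W<S and
    K<G; ``b_q``/``d_q`` hold Q-table snapshots of shape
    ``(n_snapshots, n_states, n_actions)`` taken at ``snapshot_rounds``
    (1-based), or ``None`` for a static agent or when snapshots are
    disabled.
    """

    seed: int
    rounds: int
    thirst: np.ndarray
    b_actions: np.ndarray
    d_actions: np.ndarray
    b_explored: np.ndarray
    d_explored: np.ndarray
    reward_b: np.ndarray
    reward_d: np.ndarray
    snapshot_rounds: np.ndarray
    b_q: np.ndarray | None
    d_q: np.ndarray | None
    b_final: object
    d_final: object

    def b_action_sequence(self) -> list[BeneficiaryAction]:
        return [BENEFICIARY_ACTIONS[c] for c in self.b_actions]

    def d_action_sequence(self) -> list[DonorAction]:
        return [DONOR_ACTIONS[c] for c in self.d_actions]

    def thirst_sequence(self) -> list[ThirstState]:
        return [
            ThirstState.THIRSTY if t else ThirstState.NOT_THIRSTY for t in self.thirst
        ]


@dataclass
class ExperimentSummary:
    """Aggregate of an experiment: labels, proportions, mean Q trajectories."""

    config: ExperimentConfig
    b_labels: list[str]
    d_labels: list[str]
    b_proportions: dict[str, float]
    d_proportions: dict[str, float]
    threshold: object
    predicted: tuple[BeneficiaryAction, DonorAction]
    snapshot_rounds: np.ndarray | None = None
    mean_q_b: np.ndarray | None = None
    mean_q_d: np.ndarray | None = None
    window_q_b: np.ndarray | None = None
    window_q_d: np.ndarray | None = None
    b_states: list[str] = field(default_factory=list)
    d_states: list[str] = field(default_factory=list)
    records: list[DyadRecord] | None = None

    @property
    def seeds(self) -> list[int]:
        return [self.config.base_seed + i for i in range(self.config.n_runs)]

    @property
    def b_top(self) -> tuple[str, float]:
        return max(self.b_proportions.items(), key=lambda kv: kv[1])

    @property
    def d_top(self) -> tuple[str, float]:
        return max(self.d_proportions.items(), key=lambda kv: kv[1])


def _make_agent(cfg, role: Role, rng: np.random.Generator):
    if isinstance(cfg, StaticPolicy):
        return StaticAgent(cfg)
    if isinstance(cfg, AgentConfig):
        return QLearningAgent(cfg, rng)
    raise TypeError(f"expected AgentConfig or StaticPolicy, got {type(cfg)!r}")


def play_round(
    b_agent,
    d_agent,
    state: str,
    thirst: ThirstState,
    params: GameParameters,
    round_number: int,
    next_thirst: ThirstState | None = None,
) -> tuple[RoundOutcome, str]:
    """Play one round and let both agents learn from it.

    ``state`` is the engine state: the fixed-width concatenation of the last
    ``max(memory)`` joint-action labels.  Each agent observes its own view of
    it (its last ``m`` labels, plus thirst if configured).  Rewards are the
    inclusive fitnesses of the realised joint action, and the next engine
    state appends that joint action's label.
    """
    if next_thirst is None:
        next_thirst = thirst
    b_obs = b_agent.observation(state, thirst)
    d_obs = d_agent.observation(state, thirst)
    b_action, b_exp = b_agent.act(b_obs, round_number)
    d_action, d_exp = d_agent.act(d_obs, round_number)
    pay = round_rewards(b_action, d_action, thirst, params)
    next_state = (state + joint_label(b_action, d_action))[-len(state):]
    b_agent.learn(b_obs, b_action, pay.F_B, b_agent.observation(next_state, next_thirst))
    d_agent.learn(d_obs, d_action, pay.F_D, d_agent.observation(next_state, next_thirst))
    outcome = RoundOutcome(
        thirst, b_action, d_action, b_exp, d_exp, pay.F_B, pay.F_D
    )
    return outcome, next_state


def _memory(cfg) -> int:
    return cfg.memory if isinstance(cfg, AgentConfig) else 1


def run_dyad(config: ExperimentConfig, seed: int) -> DyadRecord:
    """Run one seeded dyad of ``config.rounds`` rounds."""
    env_ss, b_ss, d_ss = np.random.SeedSequence(seed).spawn(3)
    env_rng = np.random.default_rng(env_ss)
    b_agent = _make_agent(config.beneficiary, Role.BENEFICIARY, np.random.default_rng(b_ss))
    d_agent = _make_agent(config.donor, Role.DONOR, np.random.default_rng(d_ss))

    rounds = config.rounds
    max_m = max(_memory(config.beneficiary), _memory(config.donor))

    # Pre-game history: m uniformly random joint actions keep the state space
    # at exactly 6**m without a dedicated start state.
    state = "".join(
        joint_label(
            BENEFICIARY_ACTIONS[int(env_rng.integers(3))],
            DONOR_ACTIONS[int(env_rng.integers(2))],
        )
        for _ in range(max_m)
    )

    if config.thirst_mode == "thirsty":
        thirst_codes = np.ones(rounds, dtype=np.uint8)
    elif config.thirst_mode == "not_thirsty":
        thirst_codes = np.zeros(rounds, dtype=np.uint8)
    else:
        thirst_codes = (env_rng.random(rounds) < config.game.p).astype(np.uint8)
    thirst_seq = [
        ThirstState.THIRSTY if t else ThirstState.NOT_THIRSTY for t in thirst_codes
    ]

    b_codes = np.empty(rounds, dtype=np.uint8)
    d_codes = np.empty(rounds, dtype=np.uint8)
    b_exp = np.empty(rounds, dtype=bool)
    d_exp = np.empty(rounds, dtype=bool)
    reward_b = np.empty(rounds)
    reward_d = np.empty(rounds)
    snap_rounds: list[int] = []
    b_snaps: list[np.ndarray] = []
    d_snaps: list[np.ndarray] = []
    stride = config.snapshot_stride

    for n in range(1, rounds + 1):
        i = n - 1
        thirst = thirst_seq[i]
        next_thirst = thirst_seq[i + 1] if n < rounds else thirst
        outcome, state = play_round(
            b_agent, d_agent, state, thirst, config.game, n, next_thirst
        )
        b_codes[i] = _B_CODE[outcome.b_action]
        d_codes[i] = _D_CODE[outcome.d_action]
        b_exp[i] = outcome.b_explored
        d_exp[i] = outcome.d_explored
        reward_b[i] = outcome.reward_b
        reward_d[i] = outcome.reward_d
        if stride and n % stride == 0:
            snap_rounds.append(n)
            if b_agent.is_learning:
                b_snaps.append(b_agent.qtable.values.copy())
            if d_agent.is_learning:
                d_snaps.append(d_agent.qtable.values.copy())

    return DyadRecord(
        seed=seed,
        rounds=rounds,
        thirst=thirst_codes,
        b_actions=b_codes,
        d_actions=d_codes,
        b_explored=b_exp,
        d_explored=d_exp,
        reward_b=reward_b,
        reward_d=reward_d,
        snapshot_rounds=np.asarray(snap_rounds, dtype=int),
        b_q=np.stack(b_snaps) if b_snaps else None,
        d_q=np.stack(d_snaps) if d_snaps else None,
        b_final=b_agent.qtable,
        d_final=d_agent.qtable,
    )


def run_experiment(
    config: ExperimentConfig,
    keep_records: bool = False,
    progress=None,
) -> ExperimentSummary:
    """Run ``config.n_runs`` independent dyads and aggregate them.

    Per role, the summary holds the strategy label of every run, the label
    distribution, mean Q trajectories at the snapshot rounds (averaged over
    runs), and the converged per-(state, action) Q means (averaged over the
    final ``q_window`` rounds and over runs).  ``progress`` may be a callable
    taking ``(done, total)``; it is invoked every 100 runs.
    """
    from .analysis import classify_record, proportions_from_labels

    b_labels: list[str] = []
    d_labels: list[str] = []
    records: list[DyadRecord] = []
    sum_q_b = sum_q_d = None
    sum_win_b = sum_win_d = None
    snap_rounds = None
    b_states: list[str] = []
    d_states: list[str] = []

    for i in range(config.n_runs):
        rec = run_dyad(config, config.base_seed + i)
        lb, ld = classify_record(
            rec, window=config.classify_window, readout=config.classify_readout
        )
        b_labels.append(lb)
        d_labels.append(ld)
        if rec.b_q is not None or rec.d_q is not None:
            if snap_rounds is None:
                snap_rounds = rec.snapshot_rounds
            in_window = rec.snapshot_rounds > config.rounds - config.q_window
        if rec.b_q is not None:
            if sum_q_b is None:
                sum_q_b = np.zeros_like(rec.b_q)
                b_states = list(rec.b_final.states)
            sum_q_b += rec.b_q
            win = rec.b_q[in_window].mean(axis=0)
            sum_win_b = win if sum_win_b is None else sum_win_b + win
        if rec.d_q is not None:
            if sum_q_d is None:
                sum_q_d = np.zeros_like(rec.d_q)
                d_states = list(rec.d_final.states)
            sum_q_d += rec.d_q
            win = rec.d_q[in_window].mean(axis=0)
            sum_win_d = win if sum_win_d is None else sum_win_d + win
        if keep_records:
            records.append(rec)
        if progress is not None and (i + 1) % 100 == 0:
            progress(i + 1, config.n_runs)

    n = config.n_runs
    return ExperimentSummary(
        config=config,
        b_labels=b_labels,
        d_labels=d_labels,
        b_proportions=proportions_from_labels(b_labels),
        d_proportions=proportions_from_labels(d_labels),
        threshold=threshold_satisfied(config.game),
        predicted=predicted_equilibrium(config.game),
        snapshot_rounds=snap_rounds,
        mean_q_b=None if sum_q_b is None else sum_q_b / n,
        mean_q_d=None if sum_q_d is None else sum_q_d / n,
        window_q_b=None if sum_win_b is None else sum_win_b / n,
        window_q_d=None if sum_win_d is None else sum_win_d / n,
        b_states=b_states,
        d_states=d_states,
        records=records if keep_records else None,
    )
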