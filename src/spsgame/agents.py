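"""Tabular Q-learning agents and static-strategy baselines.

Each agent observes the last ``m`` joint actions of the dyad (default
``m = 1``, giving the six states NK, NG, WK, WG, SK, SG), selects an action
ε-greedily, and updates its action-value table with its inclusive-fitness
reward::

    Q_t(s, a) = Q_{t-1}(s, a) + α (R_t(s, a) + γ max_{a'} Q_{t-1}(s', a')
                                   - Q_{t-1}(s, a))

where ``s'`` is the state produced by the joint action just completed.  The
first ``explore_rounds`` rounds are fully exploratory (ε = 1); afterwards ε
decays as 2/N with N the round number.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .game import BeneficiaryAction, DonorAction, ThirstState

__all__ = [
    "Role",
    "AgentConfig",
    "StaticPolicy",
    "QTable",
    "QLearningAgent",
    "StaticAgent",
    "BENEFICIARY_ACTIONS",
    "DONOR_ACTIONS",
    "JOINT_LABELS",
    "epsilon_at",
    "select_action",
    "q_update",
    "encode_state",
    "joint_label",
    "all_states",
]

#: Canonical action orders (also the tie-break / pattern-canonicalisation
#: orders used by the strategy classifier).
BENEFICIARY_ACTIONS: tuple[BeneficiaryAction, ...] = (
    BeneficiaryAction.NOT_SIGNAL,
    BeneficiaryAction.WEAK_SIGNAL,
    BeneficiaryAction.STRONG_SIGNAL,
)
DONOR_ACTIONS: tuple[DonorAction, ...] = (DonorAction.KEEP, DonorAction.GIVE)

#: The six joint-action labels for memory 1, in canonical order.
JOINT_LABELS: tuple[str, ...] = tuple(
    b.value + d.value for b in BENEFICIARY_ACTIONS for d in DONOR_ACTIONS
)


class Role(str, Enum):
    BENEFICIARY = "beneficiary"
    DONOR = "donor"


@dataclass(frozen=True)
class AgentConfig:
    """Hyperparameters of one learning agent.

    ``alpha`` is the learning rate, ``gamma`` the discount rate.  The first
    ``explore_rounds`` rounds are pure exploration; afterwards ε follows
    ``epsilon_decay`` ("2/N", "1/N", or "constant:<value>").  ``memory`` is
    the number of past joint actions in the observation state (state space
    size ``6**memory``).  ``observe_thirst`` optionally appends the current
    thirst state to a beneficiary's observation; the replication presets keep
    it off because they fix the thirst state for a whole run.
    """

    role: Role
    alpha: float = 0.9
    gamma: float = 0.1
    explore_rounds: int = 50
    epsilon_decay: str = "2/N"
    memory: int = 1
    observe_thirst: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if self.explore_rounds < 0:
            raise ValueError("explore_rounds must be non-negative")
        if self.memory < 1:
            raise ValueError("memory must be at least 1")
        _parse_decay(self.epsilon_decay)  # fail fast on unknown rules


@dataclass(frozen=True)
class StaticPolicy:
    """A fixed (possibly cyclic) action sequence; never explores or learns."""

    sequence: tuple

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("static policy needs at least one action")


def _parse_decay(rule: str) -> float | None:
    if rule in ("2/N", "1/N"):
        return None
    if rule.startswith("constant:"):
        value = float(rule.split(":", 1)[1])
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"constant epsilon must lie in [0, 1], got {value}")
        return value
    raise ValueError(f"unknown epsilon decay rule {rule!r}")


def epsilon_at(round_number: int, config: AgentConfig) -> float:
    """Exploration probability for a given 1-based round number."""
    if round_number < 1:
        raise ValueError(f"round_number must be >= 1, got {round_number}")
    if round_number <= config.explore_rounds:
        return 1.0
    rule = config.epsilon_decay
    if rule == "2/N":
        return min(1.0, 2.0 / round_number)
    if rule == "1/N":
        return min(1.0, 1.0 / round_number)
    return float(rule.split(":", 1)[1])


def joint_label(b_action: BeneficiaryAction, d_action: DonorAction) -> str:
    """Two-letter label of a joint action, e.g. 'NG'."""
    return b_action.value + d_action.value


def all_states(memory: int = 1) -> list[str]:
    """All observation states for a given memory length (size ``6**memory``)."""
    return ["".join(combo) for combo in product(JOINT_LABELS, repeat=memory)]


def encode_state(history: Sequence, memory: int = 1) -> str:
    """Encode the last ``memory`` joint actions as an observation state.

    ``history`` holds joint actions, each either an
    ``(BeneficiaryAction, DonorAction)`` pair or a two-letter label.  The
    encoding concatenates the last ``memory`` labels (injective because each
    label has fixed width 2).
    """
    if len(history) < memory:
        raise ValueError(
            f"history of length {len(history)} is shorter than memory {memory}"
        )
    labels = []
    for item in list(history)[-memory:]:
        if isinstance(item, str):
            labels.append(item)
        else:
            b, d = item
            labels.append(joint_label(b, d))
    return "".join(labels)


class QTable:
    """Action-value table mapping (observation state, own action) to Q.

    Values are held in a dense ``(n_states, n_actions)`` float array,
    initialised to zero.
    """

    def __init__(self, states: Iterable[str], actions: Sequence) -> None:
        self.states = list(states)
        self.actions = tuple(actions)
        self._sidx = {s: i for i, s in enumerate(self.states)}
        self._aidx = {a: j for j, a in enumerate(self.actions)}
        self.values = np.zeros((len(self.states), len(self.actions)))

    def value(self, state: str, action) -> float:
        return float(self.values[self._sidx[state], self._aidx[action]])

    def best_value(self, state: str) -> float:
        return float(self.values[self._sidx[state]].max())

    def reset(self) -> None:
        self.values[:] = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Rows = states, columns = action letters."""
        return pd.DataFrame(
            self.values.copy(),
            index=self.states,
            columns=[a.value for a in self.actions],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="state")


def select_action(
    qtable: QTable, state: str, epsilon: float, rng: np.random.Generator
):
    """ε-greedy action selection with uniform random tie-breaking.

    Returns ``(action, explored)`` where ``explored`` marks whether the
    uniform-exploration branch was taken.
    """
    actions = qtable.actions
    if epsilon > 0.0 and rng.random() < epsilon:
        return actions[int(rng.integers(len(actions)))], True
    row = qtable.values[qtable._sidx[state]]
    best = np.flatnonzero(row == row.max())
    if best.size == 1:
        return actions[int(best[0])], False
    return actions[int(best[int(rng.integers(best.size))])], False


def q_update(
    qtable: QTable,
    s: str,
    a,
    reward: float,
    s_next: str,
    config: AgentConfig,
) -> None:
    """One temporal-difference update of entry ``(s, a)`` in place.

    The bootstrap maximum over the next state's actions is taken from the
    pre-update table, so only the single entry ``(s, a)`` changes.
    """
    q = qtable.values
    i = qtable._sidx[s]
    j = qtable._aidx[a]
    target = reward + config.gamma * q[qtable._sidx[s_next]].max()
    q[i, j] += config.alpha * (target - q[i, j])


def _thirst_prefix(thirst: ThirstState) -> str:
    return "T:" if thirst is ThirstState.THIRSTY else "H:"


class QLearningAgent:
    """A learning player: ε-greedy policy over a tabular Q-function."""

    is_learning = True

    def __init__(self, config: AgentConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.actions = (
            BENEFICIARY_ACTIONS if config.role is Role.BENEFICIARY else DONOR_ACTIONS
        )
        states = all_states(config.memory)
        if config.observe_thirst:
            states = [p + s for p in ("T:", "H:") for s in states]
        self.qtable = QTable(states, self.actions)
        self.rng = rng if rng is not None else np.random.default_rng()

    def observation(self, state: str, thirst: ThirstState) -> str:
        """The agent's view of the engine state.

        The engine state is a fixed-width concatenation of two-letter joint
        labels; an agent with memory ``m`` sees only the last ``m`` of them,
        optionally prefixed with its thirst state.
        """
        view = state[-2 * self.config.memory :]
        if self.config.observe_thirst:
            return _thirst_prefix(thirst) + view
        return view

    def act(self, state: str, round_number: int):
        eps = epsilon_at(round_number, self.config)
        return select_action(self.qtable, state, eps, self.rng)

    def learn(self, state: str, action, reward: float, next_state: str) -> None:
        q_update(self.qtable, state, action, reward, next_state, self.config)

    def reset(self) -> None:
        self.qtable.reset()


class StaticAgent:
    """A baseline player that cycles through a fixed action sequence."""

    is_learning = False
    qtable = None

    def __init__(self, policy: StaticPolicy):
        self.policy = policy
        self._pos = 0

    def observation(self, state: str, thirst: ThirstState) -> str:
        return state

    def act(self, state: str, round_number: int):
        action = self.policy.sequence[self._pos % len(self.policy.sequence)]
        self._pos += 1
        return action, False

    def learn(self, state: str, action, reward: float, next_state: str) -> None:
        pass

    def reset(self) -> None:
        self._pos = 0
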