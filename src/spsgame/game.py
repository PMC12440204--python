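"""Core Sir Philip Sidney game: survival payoffs, inclusive fitness, and the
relatedness threshold predicting the donor's equilibrium action.

The game is a dyadic interaction between two related animals.  A beneficiary
(B) may or may not be in need of an indivisible resource (water); a donor (D)
holds the resource.  B may signal need — at a survival cost — and D may give
or keep the resource.  Keeping guarantees D's survival (payoff 1), giving
reduces it to ``U``.  B survives with probability 1 if it receives the
resource, 0 if thirsty without it, and ``V`` if not thirsty without it.
Signal costs scale B's survival multiplicatively: a signal of cost ``c``
leaves B with survival ``s * (1 - c)``.

Because the two players are kin with relatedness ``r``, each player's reward
is its *inclusive fitness* rather than its individual payoff::

    F_i = P_i + r * P_j

Under inclusive fitness the beneficiary never benefits from signalling, and
the donor's equilibrium action flips from Keep to Give once relatedness
exceeds the threshold ``(1 - U) / (1 - V + p V)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import pandas as pd

__all__ = [
    "BeneficiaryAction",
    "DonorAction",
    "ThirstState",
    "GameParameters",
    "PayoffPair",
    "ThresholdResult",
    "individual_payoffs",
    "inclusive_fitness",
    "round_rewards",
    "fitness_matrix",
    "fitness_matrix_csv",
    "threshold_satisfied",
    "predicted_equilibrium",
]


class BeneficiaryAction(Enum):
    """The signaller's three actions, ordered by increasing signal cost."""

    NOT_SIGNAL = "N"
    WEAK_SIGNAL = "W"
    STRONG_SIGNAL = "S"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BeneficiaryAction.{self.name}"


class DonorAction(Enum):
    """The receiver's two actions."""

    KEEP = "K"
    GIVE = "G"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DonorAction.{self.name}"


class ThirstState(Enum):
    """Whether the beneficiary currently needs the resource."""

    THIRSTY = "thirsty"
    NOT_THIRSTY = "not_thirsty"


# Display labels matching the row/column layout of the inclusive-fitness
# matrices (beneficiary rows, donor columns).
_B_LABELS = {
    BeneficiaryAction.NOT_SIGNAL: "Not signal",
    BeneficiaryAction.WEAK_SIGNAL: "Weak signal",
    BeneficiaryAction.STRONG_SIGNAL: "Strong signal",
}
_D_LABELS = {DonorAction.KEEP: "Keep", DonorAction.GIVE: "Give"}


@dataclass(frozen=True)
class GameParameters:
    """Biological constants of one game instance.

    Parameters
    ----------
    p
        Probability the beneficiary is thirsty, in [0, 1].
    U
        Donor survival after giving the resource, in (0, 1).
    V
        Survival of a not-thirsty beneficiary that does not receive the
        resource, in (0, 1).
    r
        Coefficient of relatedness between the players, in [0, 1].
    c_weak, c_strong
        Multiplicative survival costs of the weak and strong signal.  The
        cost of not signalling is always 0.
    """

    p: float
    U: float
    V: float
    r: float
    c_weak: float = 0.25
    c_strong: float = 0.75

    c_none = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not 0.0 < self.U < 1.0:
            raise ValueError(f"U must lie in (0, 1), got {self.U}")
        if not 0.0 < self.V < 1.0:
            raise ValueError(f"V must lie in (0, 1), got {self.V}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if not self.c_none < self.c_weak < self.c_strong <= 1.0:
            raise ValueError(
                "signal costs must satisfy 0 < c_weak < c_strong <= 1, got "
                f"c_weak={self.c_weak}, c_strong={self.c_strong}"
            )

    def signal_cost(self, action: BeneficiaryAction) -> float:
        """Survival cost attached to a beneficiary action."""
        if action is BeneficiaryAction.NOT_SIGNAL:
            return self.c_none
        if action is BeneficiaryAction.WEAK_SIGNAL:
            return self.c_weak
        return self.c_strong


class PayoffPair(NamedTuple):
    """Individual payoffs and inclusive-fitness rewards for one round."""

    P_B: float
    P_D: float
    F_B: float
    F_D: float


class ThresholdResult(NamedTuple):
    """Outcome of the donor's give/keep threshold test.

    ``margin`` is ``r - (1 - U) / (1 - V + p V)``; the threshold is
    satisfied iff the margin is strictly positive.  Near-threshold parameter
    sets (small ``|margin|``) are exactly those where learning is expected to
    discriminate Give from Keep least sharply.
    """

    satisfied: bool
    margin: float
    threshold: float


def individual_payoffs(
    b_action: BeneficiaryAction,
    d_action: DonorAction,
    thirst: ThirstState,
    params: GameParameters,
) -> tuple[float, float]:
    """Individual survival payoffs ``(P_B, P_D)`` for one round.

    The donor survives with probability 1 when keeping and ``U`` when giving.
    The beneficiary's base survival is 1 with the resource, 0 if thirsty
    without it, and ``V`` if not thirsty without it; signal cost ``c`` scales
    this to ``s * (1 - c)``.
    """
    P_D = 1.0 if d_action is DonorAction.KEEP else params.U
    if d_action is DonorAction.GIVE:
        s_B = 1.0
    elif thirst is ThirstState.THIRSTY:
        s_B = 0.0
    else:
        s_B = params.V
    P_B = s_B * (1.0 - params.signal_cost(b_action))
    return P_B, P_D


def inclusive_fitness(P_B: float, P_D: float, r: float) -> tuple[float, float]:
    """Inclusive fitness ``(F_B, F_D)`` with ``F_i = P_i + r * P_j``."""
    return P_B + r * P_D, P_D + r * P_B


def round_rewards(
    b_action: BeneficiaryAction,
    d_action: DonorAction,
    thirst: ThirstState,
    params: GameParameters,
) -> PayoffPair:
    """Payoffs and inclusive-fitness rewards for one joint action."""
    P_B, P_D = individual_payoffs(b_action, d_action, thirst, params)
    F_B, F_D = inclusive_fitness(P_B, P_D, params.r)
    return PayoffPair(P_B, P_D, F_B, F_D)


def fitness_matrix(params: GameParameters, thirst: ThirstState) -> pd.DataFrame:
    """Inclusive-fitness matrix for a fixed thirst state.

    Rows are beneficiary actions (Not signal, Weak signal, Strong signal),
    columns are donor actions (Keep, Give); each cell holds the pair
    ``(F_B, F_D)``.  With a generic cost ``c`` the thirsty matrix is::

                 Keep      Give
        Signal   (r, 1)    (1-c+rU, U+r(1-c))
        Not sig. (r, 1)    (1+rU,   U+r)

    and the not-thirsty matrix replaces the Keep column with
    ``(r+V(1-c), 1+rV(1-c))`` / ``(r+V, 1+rV)``.
    """
    cells: dict[str, dict[str, tuple[float, float]]] = {}
    for d in DonorAction:
        col: dict[str, tuple[float, float]] = {}
        for b in BeneficiaryAction:
            pair = round_rewards(b, d, thirst, params)
            col[_B_LABELS[b]] = (pair.F_B, pair.F_D)
        cells[_D_LABELS[d]] = col
    frame = pd.DataFrame(cells)
    return frame.loc[list(_B_LABELS.values()), list(_D_LABELS.values())]


def fitness_matrix_csv(params: GameParameters, thirst: ThirstState, path) -> None:
    """Write a fitness matrix as CSV with ``F_B, F_D`` formatted cells."""
    frame = fitness_matrix(params, thirst)
    formatted = frame.map(lambda pair: f"{pair[0]:g}, {pair[1]:g}")
    formatted.to_csv(path, index_label="B \\ D")


def threshold_satisfied(params: GameParameters) -> ThresholdResult:
    """Test the donor's give/keep relatedness threshold.

    Against a never-signalling beneficiary, giving is the donor's better
    action iff its expected inclusive fitness exceeds keeping's::

        U + r  >  1 + r (1 - p) V    <=>    r > (1 - U) / (1 - V + p V)

    The denominator is positive because ``V < 1``.
    """
    threshold = (1.0 - params.U) / (1.0 - params.V + params.p * params.V)
    margin = params.r - threshold
    return ThresholdResult(margin > 0.0, margin, threshold)


def predicted_equilibrium(
    params: GameParameters,
) -> tuple[BeneficiaryAction, DonorAction]:
    """Equilibrium strategy pair predicted by the inclusive-fitness analysis.

    The beneficiary never signals (signalling only subtracts survival for any
    positive cost), and the donor gives iff the relatedness threshold is
    satisfied; otherwise it keeps.  Returns the pair, e.g. ``{N, G}``.
    """
    give = threshold_satisfied(params).satisfied
    donor = DonorAction.GIVE if give else DonorAction.KEEP
    return BeneficiaryAction.NOT_SIGNAL, donor
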