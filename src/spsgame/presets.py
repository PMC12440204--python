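"""Replication presets and plain-text experiment configuration.

The three study cases differ only in the game's biological constants:

=====  ====  =====  =====  ====================  ===========
case   r     V      U      threshold satisfied   expectation
=====  ====  =====  =====  ====================  ===========
case1  0.5   0.2    0.2    no                    {N, K}
case2  0.8   0.1    0.9    yes                   {N, G}
case3  0.9   0.75   0.95   yes (near limit)      {N, G}
=====  ====  =====  =====  ====================  ===========

Default learning settings: learning rate 0.9, discount rate 0.1, 500 rounds
per dyad, 50 exploratory rounds, ε = 2/N decay, 1000 runs.
"""

from __future__ import annotations

from typing import Any

import yaml

from .agents import AgentConfig, Role, StaticPolicy
from .engine import THIRST_MODES, ExperimentConfig
from .game import BeneficiaryAction, DonorAction, GameParameters

__all__ = [
    "CASES",
    "case_parameters",
    "make_case_config",
    "validate_config",
    "ConfigError",
]

CASES: dict[str, dict[str, float]] = {
    "case1": {"r": 0.5, "V": 0.2, "U": 0.2},
    "case2": {"r": 0.8, "V": 0.1, "U": 0.9},
    "case3": {"r": 0.9, "V": 0.75, "U": 0.95},
}


def _case_key(case) -> str:
    key = f"case{case}" if isinstance(case, int) else str(case)
    if key not in CASES:
        raise ValueError(f"unknown preset {case!r}; choose from {sorted(CASES)}")
    return key


def case_parameters(case, thirst_mode: str = "not_thirsty", p: float | None = None,
                    ) -> GameParameters:
    """Game parameters of a named case; ``p`` follows the thirst mode."""
    values = CASES[_case_key(case)]
    if p is None:
        p = 1.0 if thirst_mode == "thirsty" else 0.0
    return GameParameters(p=p, **values)


def make_case_config(
    case,
    lr: float = 0.9,
    dr: float = 0.1,
    rounds: int = 500,
    n_runs: int = 1000,
    base_seed: int = 0,
    thirst_mode: str = "not_thirsty",
    snapshot_stride: int = 1,
    explore_rounds: int = 50,
    memory: int = 1,
    epsilon_decay: str = "2/N",
) -> ExperimentConfig:
    """Fully bound experiment configuration for one replication case."""
    return ExperimentConfig(
        game=case_parameters(case, thirst_mode),
        beneficiary=AgentConfig(
            role=Role.BENEFICIARY, alpha=lr, gamma=dr,
            explore_rounds=explore_rounds, memory=memory,
            epsilon_decay=epsilon_decay,
        ),
        donor=AgentConfig(
            role=Role.DONOR, alpha=lr, gamma=dr,
            explore_rounds=explore_rounds, memory=memory,
            epsilon_decay=epsilon_decay,
        ),
        rounds=rounds,
        n_runs=n_runs,
        base_seed=base_seed,
        thirst_mode=thirst_mode,
        snapshot_stride=snapshot_stride,
    )


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


def _check_range(d, key, lo, hi, errors, prefix, lo_open=False, hi_open=False,
                 default=None):
    if key not in d:
        if default is None:
            errors.append(f"{prefix}{key}: missing")
            return None
        return default
    try:
        value = float(d[key])
    except (TypeError, ValueError):
        errors.append(f"{prefix}{key}: not a number ({d[key]!r})")
        return None
    lo_ok = value > lo if lo_open else value >= lo
    hi_ok = value < hi if hi_open else value <= hi
    if not (lo_ok and hi_ok):
        lob = "(" if lo_open else "["
        hib = ")" if hi_open else "]"
        errors.append(f"{prefix}{key}: {value} outside {lob}{lo}, {hi}{hib}")
        return None
    return value


def _parse_game(d: dict, errors: list[str]) -> GameParameters | None:
    prefix = "game."
    p = _check_range(d, "p", 0, 1, errors, prefix, default=0.0)
    U = _check_range(d, "U", 0, 1, errors, prefix, lo_open=True, hi_open=True)
    V = _check_range(d, "V", 0, 1, errors, prefix, lo_open=True, hi_open=True)
    r = _check_range(d, "r", 0, 1, errors, prefix)
    c_weak = _check_range(d, "c_weak", 0, 1, errors, prefix, lo_open=True,
                          default=0.25)
    c_strong = _check_range(d, "c_strong", 0, 1, errors, prefix, lo_open=True,
                            default=0.75)
    if None in (p, U, V, r, c_weak, c_strong):
        return None
    if not c_weak < c_strong:
        errors.append(f"game.c_weak: {c_weak} must be below c_strong ({c_strong})")
        return None
    return GameParameters(p=p, U=U, V=V, r=r, c_weak=c_weak, c_strong=c_strong)


_B_BY_LETTER = {a.value: a for a in BeneficiaryAction}
_D_BY_LETTER = {a.value: a for a in DonorAction}


def _parse_agent(d: dict, role: Role, errors: list[str]):
    prefix = role.value + "."
    if "static" in d:
        lookup = _B_BY_LETTER if role is Role.BENEFICIARY else _D_BY_LETTER
        seq = []
        for letter in d["static"]:
            if str(letter) not in lookup:
                errors.append(
                    f"{prefix}static: unknown action {letter!r} "
                    f"(choose from {sorted(lookup)})"
                )
                return None
            seq.append(lookup[str(letter)])
        if not seq:
            errors.append(f"{prefix}static: empty action sequence")
            return None
        return StaticPolicy(tuple(seq))
    alpha = _check_range(d, "alpha", 0, 1, errors, prefix, lo_open=True, default=0.9)
    gamma = _check_range(d, "gamma", 0, 1, errors, prefix, hi_open=True, default=0.1)
    explore = d.get("explore_rounds", 50)
    if not (isinstance(explore, int) and explore >= 0):
        errors.append(f"{prefix}explore_rounds: must be a non-negative integer")
        explore = None
    memory = d.get("memory", 1)
    if not (isinstance(memory, int) and memory >= 1):
        errors.append(f"{prefix}memory: must be an integer >= 1")
        memory = None
    decay = str(d.get("epsilon_decay", "2/N"))
    try:
        AgentConfig(role=role, alpha=0.5, gamma=0.5, epsilon_decay=decay)
    except ValueError:
        errors.append(f"{prefix}epsilon_decay: unknown rule {decay!r}")
        return None
    if None in (alpha, gamma, explore, memory):
        return None
    return AgentConfig(
        role=role, alpha=alpha, gamma=gamma, explore_rounds=explore,
        memory=memory, epsilon_decay=decay,
        observe_thirst=bool(d.get("observe_thirst", False)),
    )


def validate_config(text: str) -> ExperimentConfig:
    """Parse and validate a YAML experiment configuration.

    All invariant violations are collected and reported together in a
    :class:`ConfigError`; on success a fully bound
    :class:`~spsgame.engine.ExperimentConfig` is returned.
    """
    raw: Any = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["top level: expected a mapping of configuration keys"])
    errors: list[str] = []

    game = _parse_game(raw.get("game", {}) or {}, errors)
    beneficiary = _parse_agent(
        raw.get("beneficiary", {}) or {}, Role.BENEFICIARY, errors
    )
    donor = _parse_agent(raw.get("donor", {}) or {}, Role.DONOR, errors)

    rounds = raw.get("rounds", 500)
    if not (isinstance(rounds, int) and rounds >= 1):
        errors.append("rounds: must be a positive integer")
        rounds = None
    n_runs = raw.get("n_runs", 1000)
    if not (isinstance(n_runs, int) and n_runs >= 1):
        errors.append("n_runs: must be a positive integer")
        n_runs = None
    base_seed = raw.get("base_seed", 0)
    if not isinstance(base_seed, int):
        errors.append("base_seed: must be an integer")
        base_seed = None
    thirst_mode = raw.get("thirst_mode", "not_thirsty")
    if thirst_mode not in THIRST_MODES:
        errors.append(f"thirst_mode: {thirst_mode!r} not one of {THIRST_MODES}")
        thirst_mode = None
    if rounds is not None:
        for cfg, name in ((beneficiary, "beneficiary"), (donor, "donor")):
            if isinstance(cfg, AgentConfig) and rounds <= cfg.explore_rounds:
                errors.append(
                    f"rounds: {rounds} must exceed {name}.explore_rounds "
                    f"({cfg.explore_rounds})"
                )
    if errors:
        raise ConfigError(errors)
    return ExperimentConfig(
        game=game,
        beneficiary=beneficiary,
        donor=donor,
        rounds=rounds,
        n_runs=n_runs,
        base_seed=base_seed,
        thirst_mode=thirst_mode,
        snapshot_stride=int(raw.get("snapshot_stride", 1)),
    )
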