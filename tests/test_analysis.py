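"""Pattern extraction, strategy labelling, Q summaries, the sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spsgame as sg
from spsgame import (
    BeneficiaryAction as B,
    DonorAction as D,
    QTable,
    Role,
    extract_pattern,
    label_strategy,
    planted_action_stream,
    q_summary,
)
from spsgame.analysis import (
    OTHER,
    _B_CATALOGUE,
    _D_CATALOGUE,
    greedy_policy,
    policy_cycle,
    proportions_from_labels,
)

N, W, S = B.NOT_SIGNAL, B.WEAK_SIGNAL, B.STRONG_SIGNAL
K, G = D.KEEP, D.GIVE


class TestExtractPattern:
    def test_constant_sequence(self):
        assert extract_pattern([N] * 50) == (N,)

    def test_alternation_canonicalised(self):
        assert extract_pattern([G, K] * 25) == (K, G)
        assert extract_pattern([K, G] * 25) == (K, G)

    def test_period_three(self):
        assert extract_pattern([K, K, G] * 20) == (K, K, G)
        assert extract_pattern([G, K, K] * 20) == (K, K, G)

    def test_exploratory_rounds_dropped(self):
        actions = [K] * 50
        actions[13] = G
        flags = [False] * 50
        flags[13] = True
        assert extract_pattern(actions, flags) == (K,)
        # without the flag the lone Give breaks periodicity
        assert extract_pattern(actions, None) is None

    def test_aperiodic_is_other(self):
        rng = np.random.default_rng(0)
        actions = [list((N, W, S))[i] for i in rng.integers(0, 3, 50)]
        assert extract_pattern(actions) is None

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            extract_pattern([K] * 10, [True] * 10)


class TestLabelStrategy:
    @pytest.mark.parametrize("pattern,label", list(_B_CATALOGUE.items()))
    def test_beneficiary_catalogue(self, pattern, label):
        acts = {a.value: a for a in B}
        assert label_strategy(tuple(acts[x] for x in pattern), Role.BENEFICIARY) == label

    @pytest.mark.parametrize("pattern,label", list(_D_CATALOGUE.items()))
    def test_donor_catalogue(self, pattern, label):
        acts = {a.value: a for a in D}
        assert label_strategy(tuple(acts[x] for x in pattern), Role.DONOR) == label

    def test_cycle_direction_distinguished(self):
        assert label_strategy((N, W, S), Role.BENEFICIARY) == "NWS"
        assert label_strategy((N, S, W), Role.BENEFICIARY) == "NSW"

    def test_other(self):
        assert label_strategy(None, Role.DONOR) == OTHER
        assert label_strategy((W, W, S), Role.BENEFICIARY) == OTHER


@settings(derandomize=True, max_examples=200)
@given(
    pattern=st.sampled_from(sorted(_B_CATALOGUE) + sorted(_D_CATALOGUE)),
    phase=st.integers(0, 2),
    reps=st.integers(5, 20),
)
def test_classification_invariant_to_phase(pattern, phase, reps):
    """Rotations of a periodic tail map to the same label."""
    role = Role.BENEFICIARY if pattern in _B_CATALOGUE else Role.DONOR
    acts = {a.value: a for a in (B if role is Role.BENEFICIARY else D)}
    cycle = [acts[x] for x in pattern]
    phase %= len(cycle)
    rotated = cycle[phase:] + cycle[:phase]
    seq = (rotated * reps)[: len(cycle) * reps]
    expect = (_B_CATALOGUE if role is Role.BENEFICIARY else _D_CATALOGUE)[pattern]
    assert label_strategy(extract_pattern(seq, window=len(seq)), role) == expect


def test_classifier_recovers_planted_patterns_under_noise():
    """>= 99% recovery of every catalogue pattern at the converged
    exploration rate (epsilon = 0.004, 50-round window)."""
    rng = np.random.default_rng(2024)
    for catalogue, role, acts in (
        (_B_CATALOGUE, Role.BENEFICIARY, {a.value: a for a in B}),
        (_D_CATALOGUE, Role.DONOR, {a.value: a for a in D}),
    ):
        for pattern, expected in catalogue.items():
            cycle = tuple(acts[x] for x in pattern)
            hits = 0
            n_trials = 300
            for _ in range(n_trials):
                stream, flags = planted_action_stream(cycle, 50, 0.004, rng)
                got = label_strategy(extract_pattern(stream, flags), role)
                hits += got == expected
            assert hits / n_trials >= 0.99, (pattern, hits / n_trials)


def test_planted_stream_noise_rate():
    rng = np.random.default_rng(5)
    _, flags = planted_action_stream((K, G), 20_000, 0.1, rng)
    assert abs(np.mean(flags) - 0.1) < 0.01
    stream, flags = planted_action_stream((K, G), 100, 0.0, rng)
    assert not any(flags)
    assert extract_pattern(stream, flags, window=100) == (K, G)


class TestPolicyReadout:
    def _record_stub(self, b_values, d_values, last=("N", "K")):
        """Minimal record-like object with hand-set final Q tables."""
        states = sg.all_states(1)
        b_q = QTable(states, (N, W, S))
        d_q = QTable(states, (K, G))
        b_q.values[:] = b_values
        d_q.values[:] = d_values

        class Stub:
            b_final = b_q
            d_final = d_q
            thirst = np.zeros(10, dtype=np.uint8)
            b_actions = np.array([{"N": 0, "W": 1, "S": 2}[last[0]]])
            d_actions = np.array([{"K": 0, "G": 1}[last[1]]])

        return Stub()

    def test_constant_policies(self):
        b_values = np.tile([1.0, 0.0, 0.0], (6, 1))  # N everywhere
        d_values = np.tile([1.0, 0.0], (6, 1))       # K everywhere
        rec = self._record_stub(b_values, d_values)
        assert sg.classify_record(rec) == ("NN", "KK")

    def test_alternating_donor_policy(self):
        states = sg.all_states(1)
        b_values = np.tile([1.0, 0.0, 0.0], (6, 1))
        d_values = np.zeros((6, 2))
        for i, state in enumerate(states):
            # give after a Keep round, keep after a Give round -> GK cycle
            d_values[i, 1 if state.endswith("K") else 0] = 1.0
        rec = self._record_stub(b_values, d_values)
        assert sg.classify_record(rec) == ("NN", "GK")

    def test_greedy_policy_ties_break_canonically(self):
        table = QTable(["NK"], (K, G))
        assert greedy_policy(table)["NK"] is K


def test_proportions_sum_to_one_and_cover_all_runs(small_case1_summary):
    s = small_case1_summary
    assert len(s.b_labels) == s.config.n_runs
    assert sum(s.b_proportions.values()) == pytest.approx(1.0)
    assert sum(s.d_proportions.values()) == pytest.approx(1.0)
    b_props, d_props = sg.strategy_proportions(s.records)
    assert b_props == s.b_proportions
    assert d_props == s.d_proportions


def test_empty_label_collection_rejected():
    with pytest.raises(ValueError):
        proportions_from_labels([])


def test_q_summary_grand_mean_is_unweighted_state_mean(small_case1_summary):
    qs = q_summary(small_case1_summary)
    assert qs.d_grand_mean["G"] == pytest.approx(qs.d_per_state["G"].mean())
    assert qs.b_grand_mean["N"] == pytest.approx(qs.b_per_state["N"].mean())
    assert qs.donor_gap == pytest.approx(
        qs.d_per_state["G"].mean() - qs.d_per_state["K"].mean()
    )
    # from records agrees with the precomputed summary aggregates
    from_records = q_summary(small_case1_summary.records)
    assert from_records.donor_gap == pytest.approx(qs.donor_gap)


def test_case1_donor_gap_is_negative(small_case1_summary):
    """Below the relatedness threshold, keeping is worth more than giving."""
    assert q_summary(small_case1_summary).donor_gap < 0


def test_sweep_single_cell_matches_experiment(case1_params):
    result = sg.sweep_table(
        case1_params, learning_rates=(0.9,), discount_rates=(0.1,),
        rounds=150, n_runs=10, base_seed=200,
    )
    config = sg.make_case_config("case1", rounds=150, n_runs=10, base_seed=200,
                                 snapshot_stride=0)
    summary = sg.run_experiment(config)
    b_props, d_props = result.distributions[(0.9, 0.1)]
    assert b_props == summary.b_proportions
    assert d_props == summary.d_proportions
    assert result.predicted_donor_label == "KK"
    assert result.min_combo == result.best_combo
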