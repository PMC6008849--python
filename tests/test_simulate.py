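"""Synchronous dynamics: net effect, stepping, termination, batch mode."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_run
from pathdyn.fixtures import random_network, toy_feedback_network
from pathdyn.model import (
    BlockingRule,
    EdgeSpec,
    Network,
    NetworkError,
    NodeSpec,
)
from pathdyn.simulate import (
    DynamicalState,
    _initial_dynamical_state,
    batch_simulate,
    net_effect,
    simulate,
    step,
)


def _single(state: int) -> Network:
    return Network(nodes=[NodeSpec("A", initial_state=state)]).finalize(-1)


def _dyn(net: Network) -> DynamicalState:
    return _initial_dynamical_state(net, net.initial_configuration())


class TestNetEffect:
    def test_sum_of_state_times_weight(self):
        net = Network(
            nodes=[NodeSpec("i", initial_state=3), NodeSpec("j", initial_state=5)],
            edges=[EdgeSpec("i", "j", "activation", 2)],
        ).finalize(-1)
        assert net_effect(net, _dyn(net), "j", 0) == 3 * 2 + 5 * (-1)

    def test_zero_sources_zero_effect(self):
        net = Network(
            nodes=[NodeSpec("i", initial_state=0), NodeSpec("j", initial_state=0)],
            edges=[EdgeSpec("i", "j", "activation", 2)],
        ).finalize(-1)
        assert net_effect(net, _dyn(net), "j", 0) == 0

    def test_unknown_node_errors(self):
        net = _single(1)
        with pytest.raises(NetworkError):
            net_effect(net, _dyn(net), "nope", 0)

    def test_delayed_edge_reads_padded_history(self):
        """With delay 2, early steps read the t=0 source state."""
        net = Network(
            nodes=[NodeSpec("i", kind="signal",
                            signal_pattern=(0, 5, 5, 5, 5, 5)),
                   NodeSpec("j", initial_state=4)],
            edges=[EdgeSpec("i", "j", "activation", 2, delay=2)],
        )
        d = _dyn(net)
        # at t=1 the edge reads s_i(-1) = s_i(0) = 0
        assert net_effect(net, d, "j", 1) == 0
        traj = simulate(net, max_steps=5)
        # j first rises at t=4, driven by s_i(2) = 5 two steps earlier
        assert traj.series("j")[:5] == (4, 4, 4, 4, 5)


class TestBlocking:
    def _net(self):
        net = Network(
            nodes=[NodeSpec("Y", initial_state=5), NodeSpec("Z", initial_state=0),
                   NodeSpec("X1", initial_state=0), NodeSpec("X2", initial_state=0)],
            edges=[EdgeSpec("Y", "Z", "activation", 2)],
        )
        return net

    def test_all_mode_needs_every_blocker(self):
        net = self._net()
        net.add_blocking_rule(
            BlockingRule(frozenset({"X1", "X2"}), ("Y", "Z"), mode="all")
        )
        # X1 active, X2 not: rule inactive, edge contributes
        net.set_initial_state("X1", 3)
        assert net_effect(net, _dyn(net), "Z", 0) == 10
        net.set_initial_state("X2", 1)
        assert net_effect(net, _dyn(net), "Z", 0) == 0

    def test_any_mode_needs_one_blocker(self):
        net = self._net()
        net.add_blocking_rule(
            BlockingRule(frozenset({"X1", "X2"}), ("Y", "Z"), mode="any")
        )
        net.set_initial_state("X2", 1)
        assert net_effect(net, _dyn(net), "Z", 0) == 0

    def test_active_steps_restricts_blocking(self):
        net = self._net()
        net.add_blocking_rule(
            BlockingRule(frozenset({"X1"}), ("Y", "Z"), active_steps=frozenset({0}))
        )
        net.set_initial_state("X1", 9)
        d = _dyn(net)
        assert net_effect(net, d, "Z", 0) == 0     # blocked at step 0
        assert net_effect(net, d, "Z", 1) == 10    # free afterwards

    def test_rule_on_absent_edge_rejected(self):
        net = self._net()
        with pytest.raises(NetworkError):
            net.add_blocking_rule(BlockingRule(frozenset({"X1"}), ("Z", "Y")))


class TestStep:
    def test_descent_by_one(self):
        net = _single(5)
        nxt = step(net, _dyn(net), 0)
        assert nxt.states["A"] == 4

    def test_clamp_at_nine(self):
        net = Network(
            nodes=[NodeSpec("i", initial_state=9), NodeSpec("j", initial_state=9)],
            edges=[EdgeSpec("i", "j", "activation", 7)],
        ).finalize(-1)
        assert step(net, _dyn(net), 0).states["j"] == 9

    def test_constant_signal_pattern(self):
        net = Network(nodes=[NodeSpec("S", kind="signal", signal_pattern=(9,))])
        traj = simulate(net, max_steps=5)
        assert set(traj.series("S")) == {9}


class TestSimulate:
    def test_all_zero_fixed_point_immediately(self):
        net = Network(nodes=[NodeSpec("A"), NodeSpec("B")]).finalize(-1)
        traj = simulate(net)
        assert traj.termination == "steady_state"
        assert len(traj) == 2
        assert traj.configurations[0].states == traj.configurations[1].states

    @pytest.mark.parametrize("s", range(10))
    def test_forced_descent_reaches_zero_in_s_steps(self, s):
        traj = simulate(_single(s))
        assert traj.termination == "steady_state"
        assert traj.series("A") == tuple(range(s, -1, -1)) + (0,) * (1 if s else 1)

    def test_toy_feedback_cycles_with_constant_signal(self):
        traj = simulate(toy_feedback_network())
        assert traj.termination == "cycle"
        assert len(set(traj.series("signal"))) == 1
        for n in "ABC":
            cyc = traj.series(n)[traj.cycle_start:-1]
            assert len(set(cyc)) >= 2

    def test_unfinalized_network_warns_not_errors(self, caplog):
        net = Network(nodes=[NodeSpec("A", initial_state=2)])
        with caplog.at_level("WARNING"):
            traj = simulate(net)
        assert any("not finalized" in r.message for r in caplog.records)
        assert traj.termination == "steady_state"

    def test_max_steps_respected(self):
        traj = simulate(toy_feedback_network(), max_steps=3)
        assert traj.termination in ("cycle", "max_steps")
        assert len(traj) - 1 <= 3

    def test_determinism(self):
        net = random_network(6, seed=42, max_delay=2, with_signal=True)
        t1 = simulate(net, max_steps=None)
        t2 = simulate(net, max_steps=None)
        assert [c.states for c in t1.configurations] == [
            c.states for c in t2.configurations
        ]
        assert (t1.termination, t1.cycle_start) == (t2.termination, t2.cycle_start)

    def test_non_constant_signal_never_steady(self):
        net = Network(nodes=[
            NodeSpec("S", kind="signal", signal_pattern=(0, 9)),
            NodeSpec("A"),
        ])
        net.add_edge(EdgeSpec("S", "A", "activation", 1)).finalize(-1)
        traj = simulate(net, max_steps=None)
        assert traj.termination == "cycle"

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_agreement_no_delays(self, seed):
        """Step-by-step agreement with the literal transition-rule oracle."""
        net = random_network(seed % 7 + 2, seed, with_signal=bool(seed % 3))
        traj = simulate(net, max_steps=30)
        expected = naive_run(net, len(traj) - 1)
        assert [c.states for c in traj.configurations] == expected

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_termination_soundness_with_delays(self, seed):
        """Unbounded runs end in steady state or cycle; fixed points verify;
        cycles replay."""
        net = random_network(seed % 5 + 2, seed, max_delay=2,
                             with_signal=bool(seed % 2))
        traj = simulate(net, max_steps=None)
        assert traj.termination in ("steady_state", "cycle")
        for c in traj.configurations:
            assert all(0 <= s <= 9 for s in c.states.values())
        if traj.termination == "steady_state":
            # re-stepping the fixed point leaves it unchanged
            tail = simulate(net, max_steps=None, initial=traj.final.states)
            assert tail.configurations[1].states == traj.final.states
        else:
            period = len(traj) - 1 - traj.cycle_start
            assert period >= 1
            # states at cycle_start recur at the end
            assert (traj.configurations[traj.cycle_start].states
                    == traj.final.states)


class TestBatch:
    def test_forced_descent_batch_statistics(self):
        summary = batch_simulate(_single(0), exhaustive_nodes=["A"])
        assert summary.total_runs == 10
        assert len(summary.attractors) == 1
        a = summary.attractors[0]
        assert a["kind"] == "steady_state"
        assert a["representative"] == [{"A": 0}]
        assert a["frequency"] == 10
        assert a["mean_steps"] == pytest.approx(4.5)

    def test_explicit_single_condition_matches_simulate(self):
        net = _single(0)
        summary = batch_simulate(net, initial_conditions=[{"A": 7}])
        assert summary.total_runs == 1
        assert summary.attractors[0]["mean_steps"] == 7

    def test_mutual_activation_matches_brute_force(self):
        net = Network(
            nodes=[NodeSpec("A"), NodeSpec("B")],
            edges=[EdgeSpec("A", "B", "activation", 2),
                   EdgeSpec("B", "A", "activation", 2)],
        ).finalize(-1)
        summary = batch_simulate(net, exhaustive_nodes=["A", "B"])
        assert summary.total_runs == 100
        # brute force: run the naive oracle per condition, find the first
        # recurring configuration, and canonicalize the attractor it opens
        expected = {}
        for a in range(10):
            for b in range(10):
                probe = net.copy().set_initial_state("A", a).set_initial_state("B", b)
                run = naive_run(probe, 300)
                seen = {}
                for t, cfg in enumerate(run):
                    key = tuple(sorted(cfg.items()))
                    if key in seen:
                        period = [
                            tuple(sorted(c.items())) for c in run[seen[key]:t]
                        ]
                        break
                    seen[key] = t
                if len(period) == 1:
                    rep = ("steady_state", tuple(period))
                else:
                    rep = ("cycle", min(
                        tuple(period[i:] + period[:i]) for i in range(len(period))
                    ))
                expected[rep] = expected.get(rep, 0) + 1
        got = {}
        for att in summary.attractors:
            reps = tuple(
                tuple(sorted(s.items())) for s in att["representative"]
            )
            got[(att["kind"], reps)] = att["frequency"]
        assert got == expected

    def test_random_mode_requires_seed(self):
        with pytest.raises(NetworkError):
            batch_simulate(_single(1), n_random=5)

    def test_empty_conditions_rejected(self):
        with pytest.raises(NetworkError):
            batch_simulate(_single(1), initial_conditions=[])

    def test_random_mode_reproducible(self):
        net = random_network(4, seed=9)
        s1 = batch_simulate(net, n_random=20, seed=5)
        s2 = batch_simulate(net, n_random=20, seed=5)
        assert s1.to_dict() == s2.to_dict()
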