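import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actnet import engine, fixtures
from actnet.model import (
    EdgeSpec,
    FateClassifier,
    NetworkModel,
    NodeSpec,
    apply_clamps,
)
from actnet.simulate import (
    SimState,
    classify_fate,
    edge_rate,
    find_attractor,
    net_rate,
    simulate,
    step,
)


class TestEdgeRate:
    def test_scenario1_full_activity(self, ras_motif):
        state = SimState.from_model(ras_motif, {"Wnt": 100})
        edge = ras_motif.edges[0]  # Wnt -> Ras, k=0.444
        assert edge_rate(edge, state) == pytest.approx(0.444)

    def test_scenario3_zero_regulator_gives_zero(self):
        m = fixtures.motif("and_gate")
        for init in ({"A": 0, "B": 100}, {"A": 100, "B": 0}):
            state = SimState.from_model(m, init)
            (e3,) = [e for e in m.edges if e.scenario == 3]
            assert edge_rate(e3, state) == 0.0

    def test_scenario2_activation_saturated_target(self):
        m = NetworkModel(
            nodes=[NodeSpec("E", initial=100), NodeSpec("S", initial=100)],
            edges=[EdgeSpec(("E",), "S", "activation", 2, 1.0)],
        )
        state = SimState.from_model(m)
        assert edge_rate(m.edges[0], state) == 0.0

    def test_scenario2_inhibition_uses_active_fraction(self):
        m = NetworkModel(
            nodes=[NodeSpec("E", initial=100), NodeSpec("S", initial=40)],
            edges=[EdgeSpec(("E",), "S", "inhibition", 2, 1.0)],
        )
        state = SimState.from_model(m)
        assert edge_rate(m.edges[0], state) == pytest.approx(0.4)

    def test_nonnegative(self, mini_chondro):
        state = SimState.from_model(
            mini_chondro, {n: 50 for n in mini_chondro.node_names()}
        )
        for e in mini_chondro.edges:
            assert edge_rate(e, state) >= 0.0


class TestNetRate:
    def test_competing_edges(self, abc_example):
        state = SimState.from_model(abc_example)
        assert net_rate(abc_example, "B", state) == pytest.approx(0.1)

    def test_ras_at_44(self, ras_motif):
        state = SimState.from_model(ras_motif, {"Wnt": 100, "Ras": 44})
        assert net_rate(ras_motif, "Ras", state) == pytest.approx(0.444 - 0.44)

    def test_no_incoming_edges(self, abc_example):
        state = SimState.from_model(abc_example)
        assert net_rate(abc_example, "A", state) == 0.0


class TestStep:
    def test_single_decay_step(self, single_decay):
        state = SimState.from_model(single_decay, {"A": 1})
        out = step(single_decay, state)
        assert out["A"] == 0 and out.event_count == 1

    def test_tie_break_lower_index_first(self):
        m = NetworkModel(
            nodes=[NodeSpec("P", initial=50), NodeSpec("Q", initial=50)],
            edges=[
                EdgeSpec(("P",), "P", "inhibition", 1, 1.0),
                EdgeSpec(("Q",), "Q", "inhibition", 1, 1.0),
            ],
        )
        out = step(m, SimState.from_model(m))
        assert out["P"] == 49 and out["Q"] == 50

    def test_ras_rises_from_44(self, ras_motif):
        m = apply_clamps(ras_motif, {"Wnt": 100})
        state = SimState.from_model(m, {"Ras": 44})
        assert step(m, state)["Ras"] == 45

    def test_quiescent_raises(self, single_decay):
        state = SimState.from_model(single_decay, {"A": 0})
        with pytest.raises(RuntimeError):
            step(single_decay, state)


class TestSimulate:
    def test_all_zero_is_quiescent(self, mini_chondro):
        tr = simulate(
            mini_chondro, init={n: 0 for n in mini_chondro.node_names()}
        )
        assert tr.events == [] and not tr.truncated

    def test_abc_b_monotone_to_bound(self, abc_example):
        tr = simulate(abc_example)
        levels = [lv for _, node, lv in tr.events if node == "B"]
        assert levels == list(range(1, 101))
        assert tr.final["B"] == 100

    def test_deterministic_bit_identical(self, mini_chondro):
        init = {n: 37 for n in mini_chondro.node_names()}
        t1 = simulate(mini_chondro, init=init)
        t2 = simulate(mini_chondro, init=init)
        assert t1.events == t2.events

    def test_truncation_recorded(self, ras_motif):
        m = apply_clamps(ras_motif, {"Wnt": 100})
        tr = simulate(m, max_events=10)
        assert tr.truncated and len(tr.events) == 10

    def test_time_strictly_increasing_on_distinct_rates(self, abc_example):
        tr = simulate(abc_example)
        times = [t for t, _, _ in tr.events]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_events_change_one_node_by_one(self, mini_chondro):
        init = {n: 61 for n in mini_chondro.node_names()}
        tr = simulate(mini_chondro, init=init)
        current = dict(zip(tr.initial.node_names, map(int, tr.initial.activities)))
        for _, node, level in tr.events:
            assert abs(level - current[node]) == 1
            current[node] = level

    def test_trajectory_frame_columns(self, abc_example):
        frame = simulate(abc_example).to_frame()
        assert list(frame.columns) == ["time", "node", "level"]


class TestFindAttractor:
    def test_ras_cycle_reports_44(self, ras_motif):
        att = find_attractor(apply_clamps(ras_motif, {"Wnt": 100}))
        assert att.kind == "limit_cycle"
        assert att.period == 2
        assert att.reported_levels["Ras"] == 44

    def test_all_zero_is_null(self, mini_chondro):
        att = find_attractor(
            mini_chondro, init={n: 0 for n in mini_chondro.node_names()}
        )
        assert att.kind == "null"
        assert all(v == 0 for v in att.reported_levels.values())

    def test_pure_decay_fixed_point(self, single_decay):
        att = find_attractor(single_decay)
        assert att.kind in ("fixed_point", "null")
        assert att.reported_levels["A"] == 0
        # exactly one event per level of decay
        assert att.events_to_reach == 100

    def test_unresolved_on_tiny_budget(self, mini_chondro):
        att = find_attractor(
            mini_chondro,
            init={n: 50 for n in mini_chondro.node_names()},
            max_events=3,
        )
        assert att.kind == "unresolved"


class TestClassifyFate:
    def test_table_rows(self):
        cls = FateClassifier.two_fate()
        from actnet.simulate import Attractor

        sox = Attractor("fixed_point", {"SOX9": 88, "RUNX2": 0}, 1, 10)
        runx = Attractor("fixed_point", {"SOX9": 0, "RUNX2": 100}, 1, 10)
        null = Attractor("null", {"SOX9": 0, "RUNX2": 0}, 1, 0)
        assert classify_fate(sox, cls) == "SOX9+"
        assert classify_fate(runx, cls) == "RUNX2+"
        assert classify_fate(null, cls) == "Null"

    def test_unresolved_label(self):
        from actnet.simulate import Attractor

        att = Attractor("unresolved", {"SOX9": 88, "RUNX2": 0}, 0, 99)
        assert classify_fate(att, FateClassifier.two_fate()) == "unresolved"


# --- invariants -----------------------------------------------------------

@given(seed=st.integers(0, 10_000), init_seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_boundedness_on_random_networks(seed, init_seed):
    params = fixtures.GeneratorParams(
        n_nodes=5, edge_density=0.4, frac_slow=0.3, frac_and=0.2, seed=seed
    )
    m = fixtures.random_network(params)
    rng = np.random.default_rng(init_seed)
    init = {nd.name: int(rng.integers(0, 101)) for nd in m.nodes}
    tr = simulate(m, init=init, max_events=2000)
    current = dict(zip(tr.initial.node_names, map(int, tr.initial.activities)))
    for _, node, level in tr.events:
        assert 0 <= level <= 100
        current[node] = level


def test_null_absorbing_without_positive_clamps(mini_chondro):
    tr = simulate(mini_chondro, init={n: 0 for n in mini_chondro.node_names()})
    assert tr.events == []


@pytest.mark.parametrize("start", [1, 17, 100])
def test_decay_exact_event_count(start):
    m = NetworkModel(
        nodes=[NodeSpec("A", initial=start)],
        edges=[EdgeSpec(("A",), "A", "inhibition", 1, 0.7)],
    )
    tr = simulate(m)
    assert len(tr.events) == start
    assert tr.final["A"] == 0


@pytest.mark.parametrize("level_lo,level_hi", [(20, 80), (0, 100), (50, 51)])
def test_net_rate_monotone_in_activator(level_lo, level_hi):
    m = NetworkModel(
        nodes=[NodeSpec("E"), NodeSpec("S", initial=30)],
        edges=[EdgeSpec(("E",), "S", "activation", 1, 0.8)],
    )
    lo = net_rate(m, "S", SimState.from_model(m, {"E": level_lo}))
    hi = net_rate(m, "S", SimState.from_model(m, {"E": level_hi}))
    assert hi >= lo


def test_kernel_matches_pure_python(ras_motif):
    """The numba-compiled kernel and its pure-Python source must agree."""
    if not engine.HAVE_NUMBA:
        pytest.skip("numba not available; single code path")
    m = apply_clamps(ras_motif, {"Wnt": 100})
    cm = engine.CompiledModel(m)
    a0 = cm.make_init()

    compiled = cm.run(a0, record=True)
    original = engine._kernel
    try:
        engine._kernel = original.py_func
        interpreted = cm.run(a0, record=True)
    finally:
        engine._kernel = original
    assert compiled.status == interpreted.status
    assert compiled.n_events == interpreted.n_events
    np.testing.assert_array_equal(compiled.ev_node, interpreted.ev_node)
    np.testing.assert_allclose(compiled.ev_time, interpreted.ev_time)
    np.testing.assert_allclose(compiled.mean_levels, interpreted.mean_levels)
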