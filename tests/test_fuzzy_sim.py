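"""Fuzzy-logic evaluation, synchronous simulation, attractors, expansion."""

import numpy as np
import pytest
from conftest import boolean_step
from hypothesis import given, settings
from hypothesis import strategies as st

from boolpath.boolean_builder import (
    ASSIGN,
    BooleanNetwork,
    BooleanRelation,
    BooleanVariable,
    Literal,
    build_network,
)
from boolpath.errors import AttractorError, ValidationError
from boolpath.fixtures import make_random_pathway
from boolpath.fuzzy_sim import (
    SimulationConfig,
    SimulationTrace,
    TransferFunction,
    default_initial_values,
    detect_attractor,
    eval_relation,
    expand_trace,
    simulate,
    step,
)


def _ring(names, init_hot=None):
    """A rotation ring a0 -> a1 -> ... -> a0 built directly as a network."""
    variables = {n: BooleanVariable(n) for n in names}
    relations = tuple(
        BooleanRelation(names[(i + 1) % len(names)], ASSIGN, (Literal(names[i]),))
        for i in range(len(names))
    )
    return BooleanNetwork(variables, relations)


AND_REL = BooleanRelation("o", "AND", (Literal("a"), Literal("b")))
OR_REL = BooleanRelation("o", "OR", (Literal("a"), Literal("b")))


def test_eval_relation_min_max_semantics():
    state = {"a": 0.7, "b": 0.4}
    assert eval_relation(AND_REL, state) == pytest.approx(0.4)
    assert eval_relation(OR_REL, state) == pytest.approx(0.7)


def test_eval_relation_negation_and_corners():
    rel = BooleanRelation("o", "AND", (Literal("a"), Literal("b", negated=True)))
    assert eval_relation(rel, {"a": 1.0, "b": 1.0}) == 0.0
    # Boolean corners match two-state logic
    for a in (0.0, 1.0):
        for b in (0.0, 1.0):
            assert eval_relation(AND_REL, {"a": a, "b": b}) == float(bool(a) and bool(b))
            assert eval_relation(OR_REL, {"a": a, "b": b}) == float(bool(a) or bool(b))


def test_eval_relation_missing_variable_raises():
    with pytest.raises(KeyError):
        eval_relation(AND_REL, {"a": 1.0})


def test_step_holds_unrelated_variables():
    net = BooleanNetwork(
        {"a": BooleanVariable("a"), "b": BooleanVariable("b")},
        (BooleanRelation("b", ASSIGN, (Literal("a"),)),),
    )
    new = step(net, {"a": 1.0, "b": 0.0})
    assert new == {"a": 1.0, "b": 1.0}
    empty = BooleanNetwork({"a": BooleanVariable("a")}, ())
    assert step(empty, {"a": 0.3}) == {"a": 0.3}


@pytest.mark.parametrize("seed", range(25))
def test_step_matches_boolean_simulator_on_binary_states(seed):
    net = build_network(make_random_pathway(seed))
    rng = np.random.default_rng(seed)
    state = {v: float(rng.integers(0, 2)) for v in net.variables}
    bool_state = {v: int(x) for v, x in state.items()}
    for _ in range(12):
        state = step(net, state)
        bool_state = boolean_step(net, bool_state)
        assert state == {v: float(x) for v, x in bool_state.items()}


def test_constant_network_converges_in_two_rows():
    net = BooleanNetwork({"a": BooleanVariable("a")}, ())
    trace = simulate(net, SimulationConfig(initial_values={"a": 0.4}))
    assert trace.terminated_by == "converged"
    assert len(trace) == 2
    assert trace.attractor == (1, 1)


def test_three_cycle_hits_iteration_cap_with_period_three():
    net = _ring(["a", "b", "c"])
    trace = simulate(net, SimulationConfig(initial_values={"a": 1.0}))
    assert trace.terminated_by == "iteration_cap"
    assert len(trace) == 101  # cap = max(100, ceil(1.2 * 3)) = 100 updates
    assert trace.attractor is not None and trace.attractor[1] == 3


def test_iteration_cap_scales_with_variable_count():
    names = [f"v{i:03d}" for i in range(100)]
    net = _ring(names)
    assert net.iteration_cap() == 120
    trace = simulate(net, SimulationConfig(initial_values={names[0]: 1.0}))
    assert trace.terminated_by == "iteration_cap"
    assert len(trace) == 121


def test_loop_fixture_output_is_periodic(loop_network):
    trace = simulate(loop_network)
    assert trace.terminated_by == "iteration_cap"
    start, period = trace.attractor
    assert period > 1
    out = trace.column("OUT")[start:]
    assert out.max() == 1.0 and out.min() == 0.0  # oscillating output complex


def test_convergence_threshold_honored(loop_network):
    trace = simulate(loop_network, SimulationConfig(initial_values={"PKC": 0.5}))
    assert trace.terminated_by == "converged"
    assert np.max(np.abs(trace.values[-1] - trace.values[-2])) < 1e-6
    assert trace.column("OUT")[-1] == pytest.approx(0.5)


def test_detect_attractor_fixed_point_and_cycle():
    const = SimulationTrace(("a",), np.full((5, 1), 0.3), "converged")
    assert detect_attractor(const) == (0, 1)
    rng = np.random.default_rng(7)
    cycle = rng.uniform(size=(6, 3))
    values = np.vstack([rng.uniform(size=(4, 3)), np.tile(cycle, (5, 1))])
    trace = SimulationTrace(("x", "y", "z"), values, "iteration_cap")
    assert detect_attractor(trace) == (4, 6)


def test_detect_attractor_none_for_monotone_trace():
    values = np.linspace(0, 1, 12).reshape(-1, 1)
    trace = SimulationTrace(("a",), values, "iteration_cap")
    assert detect_attractor(trace) is None


def test_expand_fixed_point_stops_after_first_comparison():
    trace = SimulationTrace(("a",), np.full((7, 1), 0.6), "converged", attractor=(0, 1))
    expanded = expand_trace(trace)
    assert len(expanded) == 7 + 20  # one expansion block, then stop
    assert np.all(expanded.values == 0.6)


def test_expand_reaches_cap_exactly():
    rng = np.random.default_rng(3)
    cycle = rng.uniform(size=(6, 2))
    trace = SimulationTrace(("a", "b"), np.tile(cycle, (3, 1)), "iteration_cap", attractor=(0, 6))
    config = SimulationConfig(expansion_tol=1e-15)
    expanded = expand_trace(trace, config)
    assert len(expanded) == config.expansion_cap  # 1000 rows exactly
    # the extension replays the cycle in phase
    assert np.allclose(expanded.values[996], cycle[996 % 6])


def test_expand_without_attractor_raises():
    values = np.linspace(0, 1, 12).reshape(-1, 1)
    trace = SimulationTrace(("a",), values, "iteration_cap", attractor=None)
    with pytest.raises(AttractorError, match="iteration cap"):
        expand_trace(trace)


def test_hill_transfer_normalized():
    tf = TransferFunction("hill", hill_n=3, hill_k=0.5)
    assert tf(0.0) == 0.0
    assert tf(1.0) == pytest.approx(1.0)
    xs = np.linspace(0, 1, 200)
    ys = [tf(x) for x in xs]
    assert all(0 <= y <= 1 for y in ys)
    assert all(b >= a for a, b in zip(ys, ys[1:]))  # monotone increasing
    with pytest.raises(ValidationError):
        TransferFunction("hill", hill_n=-1)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000), data=st.data())
def test_values_stay_in_unit_interval(seed, data):
    """min/max/1-x and normalized transfers preserve [0,1] for any initial
    state in [0,1], including under Hill transfers."""
    net = build_network(make_random_pathway(seed % 50, n_entities=6, n_reactions=4))
    init = {
        v: data.draw(st.floats(0, 1, allow_nan=False), label=v) for v in net.variables
    }
    transfers = {rel.output: TransferFunction("hill") for rel in net.relations}
    trace = simulate(
        net, SimulationConfig(max_iterations=15, initial_values=init), transfers
    )
    assert trace.values.min() >= 0.0 and trace.values.max() <= 1.0


def test_default_initial_values_follow_root_rule(loop_network):
    init = default_initial_values(loop_network)
    hot = {v for v, x in init.items() if x == 1.0}
    assert hot == loop_network.root_inputs | loop_network.root_components
    assert init["OUT"] == 0.0


def test_trace_tsv_roundtrip(tmp_path, loop_network):
    trace = simulate(loop_network)
    path = tmp_path / "trace.tsv"
    trace.to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[0] == "step"
    assert len(lines) == len(trace) + 1


def test_simulation_is_deterministic(loop_network):
    a = simulate(loop_network)
    b = simulate(loop_network)
    assert np.array_equal(a.values, b.values)
    assert a.attractor == b.attractor
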