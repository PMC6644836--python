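"""Affinity-to-strength mapping, drug application and impact scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolpath.boolean_builder import (
    ASSIGN,
    BooleanNetwork,
    BooleanRelation,
    BooleanVariable,
    Literal,
)
from boolpath.drug_perturbation import (
    DrugAction,
    apply_drug,
    expand_pair,
    min_assay,
    relative_impact,
    run_perturbation_study,
    strength_from_assay,
    write_scores,
)
from boolpath.errors import ContractError, EmptyTargetError, ResolutionError
from boolpath.evidence import DrugTargetInteraction
from boolpath.fuzzy_sim import SimulationConfig, SimulationTrace, simulate


class TestStrengthFromAssay:
    def test_branch_values(self):
        assert strength_from_assay(0.5) == 0.999
        assert strength_from_assay(5) == 0.99
        assert strength_from_assay(16) == pytest.approx(
            0.99 - 0.196 * (math.log10(16) - 1), abs=1e-12
        )
        assert strength_from_assay(16) == pytest.approx(0.9500, abs=5e-5)
        assert strength_from_assay(1e6) == 0.0
        assert strength_from_assay(5e7) == 0.0

    def test_continuous_at_10_nM_under_log10(self):
        assert strength_from_assay(10) == pytest.approx(0.99, abs=1e-12)
        assert strength_from_assay(10 - 1e-9) == pytest.approx(0.99, abs=1e-6)

    def test_monotone_non_increasing(self):
        grid = np.logspace(-2, 7, 10_000)
        vals = [strength_from_assay(v) for v in grid]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            strength_from_assay(0.0)
        with pytest.raises(ValueError):
            strength_from_assay(-5)


def _rec(drug, target, atype, val):
    return DrugTargetInteraction(drug, target, atype, val)


def test_min_assay_across_types(kinase_table):
    assert min_assay(kinase_table, "KINI", "KIT") == 16.0
    assert min_assay(kinase_table, "KINI", "GHOST") is None
    assert min_assay([], "KINI", "KIT") is None
    assert min_assay([_rec("d", "T", "KD", 7.0)], "d", "T") == 7.0


def _driven_network():
    """r (clamped source) drives t through an ASSIGN relation."""
    return BooleanNetwork(
        {"r": BooleanVariable("r"), "t": BooleanVariable("t")},
        (BooleanRelation("t", ASSIGN, (Literal("r"),)),),
        root_inputs=frozenset({"r"}),
    )


def test_inhibition_gates_steady_state():
    net = _driven_network()
    action = DrugAction("d", ("t",), "inhibition", 0.999)
    transfers = apply_drug(net, None, action)
    trace = simulate(net, transfers=transfers)
    assert trace.column("t")[-1] == pytest.approx(0.001)


def test_activation_lifts_silent_variable():
    net = _driven_network()
    action = DrugAction("d", ("t",), "activation", 0.99)
    transfers = apply_drug(net, None, action)
    trace = simulate(
        net, SimulationConfig(initial_values={"r": 0.0}), transfers=transfers
    )
    assert trace.column("t")[-1] == pytest.approx(0.99)


def test_zero_strength_is_noop():
    net = _driven_network()
    transfers = apply_drug(net, None, DrugAction("d", ("t",), "inhibition", 0.0))
    ref = simulate(net)
    per = simulate(net, transfers=transfers)
    assert np.array_equal(ref.values, per.values)


def test_apply_drug_unknown_target():
    with pytest.raises(ResolutionError):
        apply_drug(_driven_network(), None, DrugAction("d", ("ghost",), "inhibition", 0.5))


def _trace(values, terminated="iteration_cap", attractor=None):
    values = np.asarray(values, dtype=float)
    return SimulationTrace(
        tuple(f"v{i}" for i in range(values.shape[1])), values, terminated, attractor
    )


def test_relative_impact_identical_is_zero():
    t = _trace(np.random.default_rng(0).uniform(size=(10, 3)))
    assert all(s.score == 0.0 for s in relative_impact(t, t))


def test_relative_impact_zero_reference_is_one():
    ref = _trace(np.zeros((5, 2)))
    per = _trace(np.full((5, 2), 0.5))
    assert all(s.score == 1.0 for s in relative_impact(ref, per))
    # both zero -> defined as 0
    assert all(s.score == 0.0 for s in relative_impact(ref, ref))


def test_relative_impact_contract_errors():
    a, b = _trace(np.zeros((4, 2))), _trace(np.zeros((5, 2)))
    with pytest.raises(ContractError):
        relative_impact(a, b)
    c = SimulationTrace(("x", "y"), np.zeros((4, 2)), "converged")
    with pytest.raises(ContractError):
        relative_impact(a, c)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_relative_impact_antisymmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    ref = _trace(rng.uniform(size=(8, 4)))
    per = _trace(rng.uniform(size=(8, 4)))
    fwd = relative_impact(ref, per)
    rev = relative_impact(per, ref)
    for f, r in zip(fwd, rev):
        assert -1.0 <= f.score <= 1.0
        assert f.score == pytest.approx(-r.score, abs=1e-12)


def test_expand_pair_lockstep_equal_lengths():
    rng = np.random.default_rng(1)
    cycle = rng.uniform(size=(3, 2))
    ref = _trace(np.tile(cycle, (4, 1)), attractor=(0, 3))
    per = _trace(np.full((5, 2), 0.25), "converged", attractor=(4, 1))
    ref2, per2, scores = expand_pair(ref, per)
    assert len(ref2) == len(per2)
    assert len(scores) == 2


def test_study_zero_strength_drug_scores_zero(loop_pathway, kinase_table):
    study = run_perturbation_study(loop_pathway, kinase_table, "NOOP01")
    assert all(s.score == 0.0 for s in study.scores)


def test_study_inhibitor_lowers_output_attractor(loop_pathway, kinase_table):
    """With the kinase regulator at half activity the output complex cycles
    with floor 0.5; the 16 nM kinase inhibitor (strength ~0.95) collapses it
    toward 1 - strength."""
    study = run_perturbation_study(
        loop_pathway, kinase_table, "KINI", initial_overrides={"PKC": 0.5}
    )
    s_ref, p_ref = study.reference.attractor
    s_per, p_per = study.perturbed.attractor
    ref_min = study.reference.column("OUT")[s_ref:].min()
    per_min = study.perturbed.column("OUT")[s_per:].min()
    assert per_min < ref_min
    assert ref_min == pytest.approx(0.5)
    assert per_min == pytest.approx(1 - study.actions[0].strength, abs=1e-3)
    assert study.score_for("OUT").score < 0


def test_study_reference_shift_changes_loop_attractor(loop_pathway):
    """Reducing one clamped regulator input from 1.0 to 0.5 without any drug
    changes the attractor values of downstream loop members."""
    table = [_rec("x", "KIT", "KD", 1e6)]  # strength-0 placeholder drug
    base = run_perturbation_study(loop_pathway, table, "x")
    shifted = run_perturbation_study(
        loop_pathway, table, "x", initial_overrides={"PKC": 0.5}
    )
    for var in ("LOOP_1", "OUT"):
        s0, p0 = base.reference.attractor
        s1, p1 = shifted.reference.attractor
        a = base.reference.column(var)[s0 : s0 + p0]
        b = shifted.reference.column(var)[s1 : s1 + p1]
        assert sorted(set(np.round(a, 9))) != sorted(set(np.round(b, 9)))


def test_study_without_mapped_target_errors(loop_pathway):
    with pytest.raises(EmptyTargetError):
        run_perturbation_study(loop_pathway, [_rec("d", "NOTHERE", "KD", 5.0)], "d")


def test_study_deterministic_and_exportable(tmp_path, loop_pathway, kinase_table):
    a = run_perturbation_study(loop_pathway, kinase_table, "KINI")
    b = run_perturbation_study(loop_pathway, kinase_table, "KINI")
    assert [s.score for s in a.scores] == [s.score for s in b.scores]
    path = tmp_path / "scores.tsv"
    assert write_scores(a.scores, path) == len(a.scores)
    assert path.read_text().startswith("variable\treference_auc")
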