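"""The py-substitution engine: partition validation, linearization,
null-space solution, independent selection, constraints, composition."""

import itertools
import random

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from pysubst import (concentration_symbol, fixture, parse_model,
                     solve_steady_state)
from pysubst.fixtures import random_linear_model
from pysubst.substitution import (PartitionError, PartitionMap,
                                  TrivialSteadyStateError, VerificationError,
                                  coefficient_matrix, compose_and_verify,
                                  count_admissible_partitions, dependency_map,
                                  introduce_pseudospecies, resolve_constraints,
                                  select_independent, validate_partition)


def conc_partition(model):
    """All concentrations to Y (P = rate constants): for first-order models."""
    return PartitionMap.from_sets(model, Y=list(model.species_names))


class TestValidatePartition:
    def test_omm_homogeneous_ok(self, omm1):
        model, pm = omm1
        report = validate_partition(model, pm)
        assert report.ok
        assert set(report.degrees.values()) == {1}

    def test_bilinear_velocity_flagged_degree_two(self, fum1):
        model, _ = fum1
        pm = PartitionMap.from_sets(model, Y=["E", "F"])
        report = validate_partition(model, pm)
        assert not report.ok
        flagged = {rate: (deg, off) for rate, deg, off in report.violations}
        assert flagged["k1f"][0] == 2          # k1f * x_E * x_F
        assert set(flagged["k1f"][1]) == {"E", "F"}

    def test_zero_order_velocity_flagged_degree_zero(self):
        model = fixture("omm1")[0]
        pm = PartitionMap.from_sets(model, Y=["k1", "k2", "k3", "k5"])
        report = validate_partition(model, pm)
        assert not report.ok
        assert ("k4", 0, []) in report.violations

    def test_non_bijective_partition_rejected(self, omm1):
        model, _ = omm1
        with pytest.raises(PartitionError, match="bijection"):
            PartitionMap(model, p_order=["E", "S", "ES", "P"],
                         y_order=["k1", "k2", "k3", "k4"])  # k5 unassigned
        with pytest.raises(PartitionError, match="twice"):
            PartitionMap(model, p_order=["E", "S", "ES", "P", "k1"],
                         y_order=["k1", "k2", "k3", "k4", "k5"])


class TestPseudospecies:
    def test_sublinear_constraint_is_unity(self):
        model = fixture("omm1")[0]
        pm = PartitionMap.from_sets(model, Y=["k1", "k2", "k3", "k5"])
        model2, pm2 = introduce_pseudospecies(model, pm, "k4")
        assert validate_partition(model2, pm2).ok
        (ps,) = pm2.pseudospecies
        assert ps.target == 1
        assert pm2.y_order[-1] == ps.name

    def test_superlinear_constraint_is_displaced_monomial(self):
        model, pm = fixture("omm4")
        (ps,) = pm.pseudospecies
        assert ps.target == concentration_symbol("ES") ** 2
        assert pm.y_order[1] == ps.name

    def test_superlinear_with_rate_constant_in_y_refused(self):
        model = parse_model("species: E S ES P\nE + S -> ES ; k1\n"
                            "ES -> E + S ; k2\nES -> E + P ; k3 order(ES)=2\n"
                            "0 -> S ; k4\nP -> 0 ; k5")
        pm = PartitionMap.from_sets(model, Y=["ES", "k3", "k1", "k4", "k5"])
        with pytest.raises(PartitionError, match="reassign"):
            introduce_pseudospecies(model, pm, "k3")


class TestCoefficientSystem:
    def test_omm_homogeneous_shape_rank_free_columns(self, omm1_system):
        sys = omm1_system
        assert sys.C.shape == (4, 5)
        assert sys.rank == 3
        assert [j + 1 for j in sys.free_columns] == [2, 5]

    def test_rank_nullity_holds_everywhere(self, omm1_system, fum2_system):
        for sys in (omm1_system, fum2_system,
                    coefficient_matrix(*fixture("omm3")),
                    coefficient_matrix(*fixture("omm4"))):
            assert sys.q + sys.rank == sys.C.cols
            # independent rank check: exact random rational evaluation
            rng = random.Random(0)
            subs = {s: sp.Rational(rng.randint(1, 997), rng.randint(1, 997))
                    for s in sys.C.free_symbols}
            assert sys.C.xreplace(subs).rank() == sys.rank

    def test_null_space_basis_annihilates_c(self, fum2_system):
        prod = (fum2_system.C * fum2_system.B).applyfunc(sp.cancel)
        assert prod == sp.zeros(*prod.shape)

    def test_special_solution_normalization(self, fum2_system):
        B, free = fum2_system.B, fum2_system.free_columns
        for col, j in enumerate(free):
            for col2, j2 in enumerate(free):
                assert B[j, col2] == (1 if col == col2 else 0)

    def test_trivial_steady_state_error_for_full_column_rank(self):
        # closed irreversible chain: stoichiometric matrix has full column
        # rank (no cycles), so the homogeneous strategy admits only the
        # trivial steady state and every concentration pins a unique rate
        model = parse_model("A -> B ; k1\nB -> C ; k2")
        with pytest.raises(TrivialSteadyStateError):
            coefficient_matrix(model, PartitionMap.homogeneous(model))

    def test_reversible_pair_breaks_uniqueness(self, omm1_system):
        # any reversible pair is a cycle: the rate constants are then never
        # uniquely determined by the concentrations (q >= 1)
        assert omm1_system.q >= 1

    def test_p_cone_recovery_on_omm(self, omm1, omm1_system):
        """P = X, Y = R reduces to the classical left-null-space construction
        with C = N @ diag(velocity monomials)."""
        model, pm = omm1
        phi = pm.phi
        monomials = [(r.velocity() / r.k).subs(phi) for r in model.reactions]
        expected = model.stoichiometric_matrix() * sp.diag(*monomials)
        assert sp.simplify(omm1_system.C - expected) == sp.zeros(4, 5)


class TestDependencyMap:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_psi_matches_independent_linear_solve(self, seed):
        """Oracle: solve C y = 0 for the pivot variables by sympy's equation
        solver and compare with the basis construction."""
        model = random_linear_model(5, 8, seed=seed)
        sys = coefficient_matrix(model, conc_partition(model))
        dmap = dependency_map(sys)
        y = sp.Matrix(sys.partition.y_aliases)
        pivot_syms = [y[j] for j in sys.pivots]
        solset = sp.linsolve(list(sys.C * y), pivot_syms)
        assert len(solset) == 1
        sol = dict(zip(pivot_syms, next(iter(solset))))
        free_sub = {dmap.free_map[j]: y[j] for j in sys.free_columns}
        for j in range(sys.C.cols):
            got = dmap.ybar[j].subs(free_sub)
            want = sol.get(y[j], y[j])
            assert sp.cancel(got - want) == 0

    def test_zero_matrix_edge_case_identity_relabeling(self):
        # a single reversible isomerization with both species frozen-free:
        # concentrations in P, rate constants in Y, nothing constrained
        # except one balance; a 1x1-rank system keeps psi minimal
        model = parse_model("A <-> B ; k")
        sys = coefficient_matrix(model, PartitionMap.homogeneous(model))
        dmap = dependency_map(sys)
        # free column maps to its own u; pivot column to an expression
        assert dmap.ybar[sys.free_columns[0]] == dmap.u_symbols[0]


class TestSelectIndependent:
    def test_fum2_printed_row_set_accepted(self, fum2_system):
        pm = fum2_system.partition
        targets = [pm.y_order[i] for i in (2, 4, 5, 6, 9)]  # rows 3,5,6,7,10
        sel = select_independent(fum2_system, targets)
        assert sel.accepted
        # the induced ybar fixes each target to its own symbol
        for t in targets:
            i = pm.y_index(t)
            assert sp.cancel(sel.ybar[i] - pm.quantity_symbol(t)) == 0

    def test_dependent_rows_rejected_not_raised(self, fum2_system):
        sel = select_independent(fum2_system, ["F", "H", "OH", "M", "k5r"])
        assert not sel.accepted
        assert sel.u_exprs is None

    def test_q_one_acceptance_iff_nonzero_basis_entry(self, fum1):
        model, pm = fum1
        sys = coefficient_matrix(model, pm)
        assert sys.q == 1
        for name in pm.y_order:
            sel = select_independent(sys, [name])
            entry = sys.B[pm.y_index(name), 0]
            assert sel.accepted == (sp.cancel(entry) != 0)
            if sel.accepted:
                # u = w_i / B_i for a 1x1 inversion
                expected = pm.quantity_symbol(name) / entry
                assert sp.cancel(sel.u_exprs[0] - expected) == 0

    def test_wrong_cardinality_raises(self, fum2_system):
        with pytest.raises(ValueError, match="q = 5"):
            select_independent(fum2_system, ["F", "H"])


class TestCountAdmissible:
    def test_all_ones_column(self):
        # q = 1 and B = all-ones: every 1x1 submatrix is invertible
        model = parse_model("A <-> B ; k")
        pm = PartitionMap.from_sets(model, Y=["A", "B"])
        sys = coefficient_matrix(model, pm)
        assert sys.q == 1
        assert count_admissible_partitions(sys) == sum(
            1 for i in range(2) if sys.B[i, 0] != 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(-3, 3), min_size=3, max_size=3),
                    min_size=4, max_size=6))
    def test_matches_brute_force_enumeration(self, rows):
        """Row-matroid count equals exhaustive determinant enumeration."""
        B = sp.Matrix(rows)

        class FakeSystem:
            pass

        sys = FakeSystem()
        sys.B, sys.q = B, 3
        expected = sum(
            1 for combo in itertools.combinations(range(B.rows), 3)
            if B[list(combo), :].det() != 0)
        assert count_admissible_partitions(sys) == expected


class TestConstraintsAndComposition:
    def test_omm3_single_linear_branch_pins_one_u(self):
        model, pm = fixture("omm3")
        sys = coefficient_matrix(model, pm)
        assert sys.q == 2
        dmap = dependency_map(sys)
        branches = resolve_constraints(sys, dmap)
        assert len(branches) == 1
        (sub,) = [branches[0].u_subs]
        assert len(sub) == 1
        sol = compose_and_verify(model, pm, dmap, branches[0])
        # the synthesis rate constant stays independent, as intended
        assert sp.Symbol("k4", positive=True) in sol.independents
        assert sol.verified

    def test_omm4_product_constraint_two_verified_branches(self):
        model, pm = fixture("omm4")
        sys = coefficient_matrix(model, pm)
        dmap = dependency_map(sys)
        branches = resolve_constraints(sys, dmap)
        assert len(branches) == 2
        for b in branches:
            sol = compose_and_verify(model, pm, dmap, b)
            assert sol.verified
            assert sol.n_dependent == 3
            # pseudospecies never appear among the reported quantities
            for name in (ps.name for ps in pm.pseudospecies):
                assert concentration_symbol(name) not in sol.dependents

    def test_corrupted_psi_detected(self, omm1):
        """Negative control: a single sign flip in psi must not verify."""
        model, pm = omm1
        sys = coefficient_matrix(model, pm)
        dmap = dependency_map(sys)
        j = sys.pivots[0]
        dmap.ybar[j] = -dmap.ybar[j]
        from pysubst.substitution import Branch
        with pytest.raises(VerificationError, match="residual"):
            compose_and_verify(model, pm, dmap, Branch(0, {}))

    def test_strategy_invariance_three_dependents(self):
        """Homogeneous, heterogeneous, sublinear and superlinear strategies
        all leave exactly rank(N) = 3 dependent quantities."""
        for name in ("omm1", "omm2", "omm3", "omm4"):
            for sol in solve_steady_state(*fixture(name)):
                assert sol.n_dependent == 3, name

    @pytest.mark.parametrize("name,n_x,n_r", [
        ("omm1", 4, 5), ("omm2", 4, 5), ("omm3", 4, 5), ("omm4", 4, 5),
        ("fum2", 9, 12), ("toy_switch", 3, 8)])
    def test_total_parameter_count(self, name, n_x, n_r):
        """|independents| = |X| + |R| - rank(N): pseudospecies net out."""
        model, pm = fixture(name)
        rank_N = sp.Matrix(
            [row for i, row in enumerate(
                model.stoichiometric_matrix().tolist())
             if not model.species[i].is_pseudo]).rank()
        for sol in solve_steady_state(model, pm):
            assert sol.n_independent == n_x + n_r - rank_N
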