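"""FBA engine: LP correctness, loopless flux patterns, lexicographic
source minimization."""

import numpy as np
import pytest
from scipy import optimize

from conftest import enumerate_vertices_optimum, random_bounded_model

from nitroyield.fba import (
    max_circulation,
    minimize_sources,
    solve_fba,
    solve_loopless,
)
from nitroyield.stoich import MetabolicModel, Reaction, Species
from nitroyield.synth import ToySpec, make_loop_fixture, make_toy_autotroph


def _steady_state_violation(model, fluxes):
    S = model.stoichiometric_matrix()
    keep = [model.species_index[s] for s in model.balanced_species_ids()]
    v = np.array([fluxes[r.id] for r in model.reactions])
    return np.max(np.abs(S[keep] @ v)) if keep else 0.0


class TestSolveFBA:
    def test_chain_toy_optimum_is_uptake_bound(self, chain_toy):
        sol = solve_fba(chain_toy, "GROW", "max")
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)

    def test_blocked_feed_kills_growth(self, chain_toy):
        sol = solve_fba(chain_toy, "GROW", "max", blocked={"UP"})
        assert sol.objective_value == pytest.approx(0.0)

    def test_branched_toy_matches_vertex_enumeration(self):
        # branch with a 2:1 stoichiometric step competing with a 1:1 step
        model = MetabolicModel(
            species=[Species("a_c"), Species("b_c"),
                     Species("x_e", compartment="boundary")],
            reactions=[
                Reaction("UP", {"a_c": 1}, 0, 10),
                Reaction("R2TO1", {"a_c": -2, "b_c": 1}, 0, 1000),
                Reaction("R1TO1", {"a_c": -1, "b_c": 1}, 0, 3),
                Reaction("OUT", {"b_c": -1, "x_e": 1}, 0, 1000),
            ],
        )
        sol = solve_fba(model, "OUT", "max")
        expected = enumerate_vertices_optimum(model, "OUT", "max")
        assert sol.objective_value == pytest.approx(expected)
        assert sol.objective_value == pytest.approx(6.5)  # 3 + (10-3)/2

    def test_random_networks_match_vertex_enumeration(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(25):
            model = random_bounded_model(rng)
            sol = solve_fba(model, "sink", "max")
            if not sol.optimal:
                continue
            expected = enumerate_vertices_optimum(model, "sink", "max")
            assert expected is not None
            assert sol.objective_value == pytest.approx(expected, abs=1e-6)
            checked += 1
        assert checked >= 15

    def test_steady_state_and_bounds_respected(self, toy_autotroph):
        model = toy_autotroph.copy()
        model.reactions.append(
            Reaction("SRC_ATP", {"adp_c": -1, "pi_c": -1, "h_c": -1,
                                 "atp_c": 1, "h2o_c": 1}, 0, 1e6))
        model.reactions.append(
            Reaction("SRC_NADH", {"nad_c": -1, "h_c": -1, "nadh_c": 1},
                     0, 1e6))
        sol = solve_fba(model, "BIOMASS", "max", fixed={"BIOMASS": 1.0})
        assert sol.optimal
        assert _steady_state_violation(model, sol.fluxes) < 1e-6
        for r in model.reactions:
            assert r.lower_bound - 1e-8 <= sol.fluxes[r.id] <= r.upper_bound + 1e-8

    def test_infeasible_reported_not_raised(self, chain_toy):
        sol = solve_fba(chain_toy, "GROW", "max", fixed={"GROW": 20.0})
        assert sol.status == "infeasible"

    def test_duality_gap_is_zero_on_toys(self):
        """Strong duality: the hand-built dual LP gives the same optimum."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            model = random_bounded_model(rng)
            sol = solve_fba(model, "sink", "max")
            if not sol.optimal:
                continue
            n = len(model.reactions)
            keep = [model.species_index[s] for s in model.balanced_species_ids()]
            S = model.stoichiometric_matrix()[keep]
            lb = np.array([r.lower_bound for r in model.reactions])
            ub = np.array([r.upper_bound for r in model.reactions])
            c = np.zeros(n)
            c[model.reaction_index["sink"]] = 1.0
            # dual of max{c v : S v = 0, lb <= v <= ub}:
            # min ub.u - lb.w  s.t.  S^T y + u - w = c, u, w >= 0
            m = S.shape[0]
            cd = np.concatenate([np.zeros(m), ub, -lb])
            A_eq = np.hstack([S.T, np.eye(n), -np.eye(n)])
            bounds = [(None, None)] * m + [(0, None)] * (2 * n)
            dual = optimize.linprog(cd, A_eq=A_eq, b_eq=c, bounds=bounds,
                                    method="highs")
            assert dual.status == 0
            assert dual.fun == pytest.approx(sol.objective_value, abs=1e-6)


class TestLoopless:
    def test_neutral_circulation_removed_objective_unchanged(self):
        lf = make_loop_fixture(corrected=True)
        plain = solve_fba(lf, "ATPM", "max")
        loopless = solve_loopless(lf, "ATPM", "max")
        assert plain.objective_value == pytest.approx(20.0)
        assert loopless.objective_value == pytest.approx(20.0, abs=1e-6)
        assert max_circulation(lf, loopless.fluxes) == pytest.approx(0.0, abs=1e-6)

    def test_atp_from_nothing_blocked(self, loop_fixture):
        plain = solve_fba(loop_fixture, "ATPM", "max", blocked={"EX_glc"})
        loopless = solve_loopless(loop_fixture, "ATPM", "max",
                                  blocked={"EX_glc"})
        assert plain.objective_value > 0  # the uncorrected-model mistake
        assert loopless.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_irreversibility_correction_equivalent_fix(self):
        lf = make_loop_fixture(corrected=True)
        sol = solve_fba(lf, "ATPM", "max", blocked={"EX_glc"})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_cycle_support_detected_by_null_space(self, loop_fixture):
        """The planted 3-cycle is a null-space vector of the internal S."""
        from scipy.linalg import null_space

        model = loop_fixture
        keep = [model.species_index[s] for s in model.balanced_species_ids()]
        internal = [i for i, r in enumerate(model.reactions)
                    if r.id not in model.exchange_ids]
        N = null_space(model.stoichiometric_matrix()[keep][:, internal])
        ids = [model.reactions[i].id for i in internal]
        loop_rows = [ids.index(x) for x in ("LOOP1", "LOOP2", "LOOP3")]
        # the unit circulation on the 3-cycle lies in the null space:
        # projecting it onto span(N) must return it unchanged
        target = np.zeros(len(ids))
        for x in loop_rows:
            target[x] = 1.0
        proj = N @ (N.T @ target)
        assert np.allclose(proj, target, atol=1e-8)

    def test_random_networks_loopless_vs_plain(self):
        """Loopless never beats plain FBA, its solutions carry zero
        circulation, and it matches plain FBA whenever the plain optimum is
        already loop-free."""
        rng = np.random.default_rng(23)
        for _ in range(15):
            model = random_bounded_model(rng)
            plain = solve_fba(model, "sink", "max")
            if not plain.optimal:
                continue
            loopless = solve_loopless(model, "sink", "max")
            assert loopless.optimal
            assert loopless.objective_value <= plain.objective_value + 1e-6
            if max_circulation(model, plain.fluxes) < 1e-6:
                assert loopless.objective_value == pytest.approx(
                    plain.objective_value, abs=1e-6)
            assert max_circulation(model, loopless.fluxes) < 1e-6

    def test_acyclic_networks_loopless_equals_plain(self):
        """On feed-forward (cycle-free) networks every optimum is loop-free,
        so the loopless optimum must equal the plain one."""
        rng = np.random.default_rng(29)
        checked = 0
        for _ in range(15):
            n_sp = 5
            species = [Species(f"s{i}_c") for i in range(n_sp)]
            species.append(Species("out_e", compartment="boundary"))
            reactions = [Reaction("feed", {"s0_c": 1}, 0, 10)]
            # edges only from lower to higher species index: no directed cycle
            for j in range(6):
                i = int(rng.integers(0, n_sp - 1))
                k = int(rng.integers(i + 1, n_sp))
                coef = float(rng.integers(1, 3))
                reactions.append(
                    Reaction(f"r{j}", {f"s{i}_c": -1.0, f"s{k}_c": coef},
                             0, float(rng.choice([5.0, 10.0, 1000.0]))))
            reactions.append(
                Reaction("sink", {f"s{n_sp-1}_c": -1, "out_e": 1}, 0, 1000))
            model = MetabolicModel(species=species, reactions=reactions)
            plain = solve_fba(model, "sink", "max")
            loopless = solve_loopless(model, "sink", "max")
            assert plain.optimal and loopless.optimal
            assert loopless.objective_value == pytest.approx(
                plain.objective_value, abs=1e-6)
            checked += 1
        assert checked == 15


class TestMinimizeSources:
    @staticmethod
    def _with_sources(model):
        work = model.copy()
        work.reactions.append(
            Reaction("SRC_ATP", {"adp_c": -1, "pi_c": -1, "h_c": -1,
                                 "atp_c": 1, "h2o_c": 1}, 0, 1e6))
        work.reactions.append(
            Reaction("SRC_NADH", {"nad_c": -1, "h_c": -1, "nadh_c": 1},
                     0, 1e6))
        return work

    def test_recovers_planted_costs(self):
        model = self._with_sources(
            make_toy_autotroph(ToySpec(atp_cost=0.10, nadh_cost=0.05, gam=0.0)))
        sol = minimize_sources(model, ["SRC_ATP", "SRC_NADH"],
                               fixed={"BIOMASS": 1.0})
        assert sol.optimal
        assert sol.source_minima["SRC_ATP"] == pytest.approx(100.0, abs=1e-7)
        assert sol.source_minima["SRC_NADH"] == pytest.approx(50.0, abs=1e-7)

    def test_order_dependence_documented(self):
        """With a free NADH->ATP conversion the pair is non-unique; the
        first-minimized source wins (ATP-first is the canonical order)."""
        model = self._with_sources(
            make_toy_autotroph(ToySpec(atp_cost=0.10, nadh_cost=0.05, gam=0.0)))
        # conversion that lets NADH substitute for ATP 1:1
        model.reactions.append(Reaction(
            "NADH_TO_ATP",
            {"nadh_c": -1, "adp_c": -1, "pi_c": -1, "h_c": -1,
             "nad_c": 1, "atp_c": 1, "h2o_c": 1}, 0, 1e6))
        atp_first = minimize_sources(model, ["SRC_ATP", "SRC_NADH"],
                                     fixed={"BIOMASS": 1.0})
        nadh_first = minimize_sources(model, ["SRC_NADH", "SRC_ATP"],
                                      fixed={"BIOMASS": 1.0})
        assert atp_first.source_minima["SRC_ATP"] == pytest.approx(0.0, abs=1e-7)
        assert atp_first.source_minima["SRC_NADH"] == pytest.approx(150.0, abs=1e-6)
        assert nadh_first.source_minima["SRC_NADH"] == pytest.approx(50.0, abs=1e-6)
        assert nadh_first.source_minima["SRC_ATP"] == pytest.approx(100.0, abs=1e-6)

    def test_unused_source_minimizes_to_zero(self):
        model = self._with_sources(
            make_toy_autotroph(ToySpec(atp_cost=0.10, nadh_cost=0.0, gam=0.0)))
        sol = minimize_sources(model, ["SRC_ATP", "SRC_NADH"],
                               fixed={"BIOMASS": 1.0})
        assert sol.source_minima["SRC_NADH"] == pytest.approx(0.0, abs=1e-8)

    def test_infeasible_stage_reports_status(self, chain_toy):
        sol = minimize_sources(chain_toy, ["UP"], fixed={"GROW": 20.0})
        assert sol.status == "infeasible"
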