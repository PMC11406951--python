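import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from commgem import fluxcore
from commgem.draftgem import ModelReaction, OrganismModel
from commgem.fluxcore import FluxProblem, build_flux_problem, fba, fva, gapfill
from commgem.netgen import Compound, Reaction, UniversalNetwork


def transport(rid, cid):
    return ModelReaction(
        id=rid, stoichiometry={(cid, "e"): -1.0, (cid, "c"): 1.0},
        lower=-1000.0, upper=1000.0, transport=True,
    )


def rxn(rid, stoich, lower=0.0, upper=1000.0):
    return ModelReaction(id=rid, stoichiometry=stoich, lower=lower, upper=upper)


def chain_model(intermediate_upper=1000.0):
    """uptake -> A, A -> B, B -> biomass."""
    return OrganismModel(
        model_id="chain", member_label="chain",
        reactions={
            "tA": transport("tA", "A"),
            "r1": rxn("r1", {("A", "c"): -1.0, ("B", "c"): 1.0}, upper=intermediate_upper),
            "bio1": rxn("bio1", {("B", "c"): -1.0}),
        },
        biomass_reaction="bio1", objective="bio1",
    )


def random_problem(rng, n_compounds=8, n_reactions=12):
    S = np.zeros((n_compounds, n_reactions))
    for j in range(n_reactions):
        picked = rng.choice(n_compounds, size=3, replace=False)
        S[picked[0], j] = -1.0
        S[picked[1], j] = 1.0
        if rng.random() < 0.5:
            S[picked[2], j] = rng.choice([-1.0, 1.0])
    lower = np.where(rng.random(n_reactions) < 0.4, -10.0, 0.0)
    upper = np.full(n_reactions, 10.0)
    objective = np.zeros(n_reactions)
    objective[int(rng.integers(n_reactions))] = 1.0
    return FluxProblem(
        reaction_ids=[f"v{j}" for j in range(n_reactions)],
        compound_instances=[(f"c{i}", "c") for i in range(n_compounds)],
        S=S, lower=lower, upper=upper, objective=objective,
    )


class TestFba:
    def test_chain_bottleneck_is_uptake_bound(self):
        problem = build_flux_problem(chain_model(), medium={"A"}, uptake_limit=10.0)
        result = fba(problem)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_chain_intermediate_bound(self):
        problem = build_flux_problem(chain_model(intermediate_upper=4.0), medium={"A"},
                                     uptake_limit=10.0)
        assert fba(problem).objective_value == pytest.approx(4.0, abs=1e-8)

    def test_no_medium_no_growth(self):
        problem = build_flux_problem(chain_model(), medium=set())
        assert fba(problem).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_residual_small(self):
        problem = build_flux_problem(chain_model(), medium={"A"})
        result = fba(problem)
        v = np.array([result.fluxes[r] for r in problem.reaction_ids])
        assert np.abs(problem.S @ v).max() <= 1e-6

    def test_unbounded_status_reported(self):
        problem = FluxProblem(
            reaction_ids=["a", "b"],
            compound_instances=[("x", "c")],
            S=np.array([[1.0, -1.0]]),
            lower=np.array([-np.inf, -np.inf]),
            upper=np.array([np.inf, np.inf]),
            objective=np.array([1.0, 0.0]),
        )
        assert fba(problem).status == "unbounded"

    def test_infeasible_status_reported(self):
        # forced flux into a dead-end compound cannot satisfy steady state
        problem = FluxProblem(
            reaction_ids=["a"],
            compound_instances=[("x", "c")],
            S=np.array([[1.0]]),
            lower=np.array([1.0]),
            upper=np.array([2.0]),
            objective=np.array([1.0]),
        )
        assert fba(problem).status == "infeasible"

    def test_dual_solver_cross_check(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            problem = random_problem(rng)
            mine = fba(problem)
            # independent formulation solved with a different method
            res = linprog(
                -problem.objective,
                A_eq=problem.S, b_eq=np.zeros(problem.S.shape[0]),
                bounds=list(zip(problem.lower, problem.upper)),
                method="highs-ipm",
            )
            assert mine.status == "optimal" and res.success
            assert mine.objective_value == pytest.approx(-res.fun, abs=1e-6)


def brute_force_blocked(problem, tol=1e-9):
    """Per-reaction two-LP enumeration oracle, independent of fluxcore.fva."""
    blocked = set()
    ranges = {}
    for j, rid in enumerate(problem.reaction_ids):
        c = np.zeros(len(problem.reaction_ids))
        c[j] = 1.0
        lo = linprog(c, A_eq=problem.S, b_eq=np.zeros(problem.S.shape[0]),
                     bounds=list(zip(problem.lower, problem.upper)), method="highs")
        hi = linprog(-c, A_eq=problem.S, b_eq=np.zeros(problem.S.shape[0]),
                     bounds=list(zip(problem.lower, problem.upper)), method="highs")
        vmin, vmax = lo.fun, -hi.fun
        ranges[rid] = (vmin, vmax)
        if abs(vmin) <= tol and abs(vmax) <= tol:
            blocked.add(rid)
    return blocked, ranges


class TestFva:
    def test_dead_end_reaction_blocked(self):
        model = OrganismModel(
            model_id="m", member_label="m",
            reactions={
                "tA": transport("tA", "A"),
                "r1": rxn("r1", {("A", "c"): -1.0, ("B", "c"): 1.0}),  # B is a dead end
                "bio1": rxn("bio1", {("A", "c"): -1.0}),
            },
            biomass_reaction="bio1", objective="bio1",
        )
        problem = build_flux_problem(model, medium={"A"})
        result = fva(problem)
        assert "r1" in result.blocked

    def test_open_chain_zero_blocked(self):
        problem = build_flux_problem(chain_model(), medium={"A"})
        result = fva(problem)
        assert result.blocked_percentage == 0.0

    def test_blocked_set_equals_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            problem = random_problem(rng, n_compounds=7, n_reactions=10)
            mine = fva(problem)
            oracle_blocked, oracle_ranges = brute_force_blocked(problem)
            assert mine.blocked == oracle_blocked
            for rid in problem.reaction_ids:
                assert mine.ranges[rid][0] == pytest.approx(oracle_ranges[rid][0], abs=1e-7)
                assert mine.ranges[rid][1] == pytest.approx(oracle_ranges[rid][1], abs=1e-7)

    def test_fva_brackets_fba_solution(self):
        problem = build_flux_problem(chain_model(), medium={"A"})
        solution = fba(problem)
        result = fva(problem)
        for rid, (lo, hi) in result.ranges.items():
            assert lo - 1e-7 <= solution.fluxes[rid] <= hi + 1e-7

    def test_objective_fraction_constrains_region(self):
        problem = build_flux_problem(chain_model(), medium={"A"})
        result = fva(problem, fix_objective_fraction=1.0)
        lo, hi = result.ranges["bio1"]
        assert lo == pytest.approx(10.0, abs=1e-6)

    def test_blocked_percentage_invariant_under_reordering(self):
        model = chain_model()
        problem = build_flux_problem(model, medium={"A"})
        pct1 = fva(problem).blocked_percentage
        reordered = OrganismModel(
            model_id=model.model_id, member_label=model.member_label,
            reactions={k: model.reactions[k] for k in reversed(sorted(model.reactions))},
            biomass_reaction="bio1", objective="bio1",
        )
        pct2 = fva(build_flux_problem(reordered, medium={"A"})).blocked_percentage
        assert pct1 == pct2


def tiny_universal():
    """Catalog: A (seed) -> B -> C; biomass needs C; plus a parallel A -> C."""
    compounds = {c: Compound(id=c, name=c) for c in "ABC"}
    reactions = {
        "tA": Reaction(id="tA", stoichiometry=(("A", 1),), reversible=True, transport=True),
        "r1": Reaction(id="r1", stoichiometry=(("A", -1), ("B", 1)), reversible=False),
        "r2": Reaction(id="r2", stoichiometry=(("B", -1), ("C", 1)), reversible=False),
        "r3": Reaction(id="r3", stoichiometry=(("A", -1), ("C", 1)), reversible=False),
    }
    return UniversalNetwork(
        compounds=compounds, reactions=reactions,
        biomass_precursors=["C"], seed_compounds=["A"],
    )


def model_from(universal, rids, biomass_cpd="C"):
    from commgem.draftgem import _instantiate

    reactions = {rid: _instantiate(universal.reactions[rid]) for rid in rids}
    reactions["bio1"] = rxn("bio1", {(biomass_cpd, "c"): -1.0})
    return OrganismModel(
        model_id="m", member_label="m", reactions=reactions,
        biomass_reaction="bio1", objective="bio1",
    )


class TestGapfill:
    def test_already_growing_returns_empty(self):
        net = tiny_universal()
        model = model_from(net, ["tA", "r1", "r2"])
        result = gapfill(model, net, medium={"A"})
        assert result.status == "already_feasible"
        assert result.added == set()

    def test_single_missing_reaction_found(self):
        net = tiny_universal()
        model = model_from(net, ["tA", "r1"])  # missing r2 (or r3)
        result = gapfill(model, net, medium={"A"})
        assert result.status == "filled"
        assert len(result.added) == 1
        assert result.added <= {"r2", "r3"}
        assert result.minimal

    def test_unfillable_reported(self):
        net = tiny_universal()
        model = model_from(net, ["r1"], biomass_cpd="C")
        # remove the transporter from the catalog: no uptake path can exist
        crippled = UniversalNetwork(
            compounds=net.compounds,
            reactions={k: v for k, v in net.reactions.items() if k != "tA"},
            biomass_precursors=["C"], seed_compounds=["A"],
        )
        result = gapfill(model, crippled, medium={"A"})
        assert result.status == "unfillable"

    def test_cardinality_equals_power_set_search(self):
        net = tiny_universal()
        model = model_from(net, ["tA"])  # needs either {r3} or {r1, r2}
        result = gapfill(model, net, medium={"A"})

        # independent power-set enumeration oracle
        candidates = sorted(set(net.reactions) - set(model.reactions))
        best = None
        for size in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                trial = model_from(net, ["tA", *combo])
                problem = build_flux_problem(trial, medium={"A"})
                if fba(problem).objective_value > 1e-9:
                    best = size
                    break
            if best is not None:
                break
        assert best == 1
        assert len(result.added) == best
        assert result.added == {"r3"}

    def test_greedy_inclusion_minimal(self):
        net = tiny_universal()
        model = model_from(net, ["tA"])
        result = gapfill(model, net, medium={"A"}, method="greedy")
        assert result.status == "filled"
        # inclusion-minimality: removing any kept reaction breaks growth
        for rid in result.added:
            remaining = result.added - {rid}
            trial = model_from(net, ["tA", *sorted(remaining)])
            problem = build_flux_problem(trial, medium={"A"})
            assert fba(problem).objective_value <= 1e-9

    def test_gapfill_never_removes_reactions(self):
        net = tiny_universal()
        model = model_from(net, ["tA", "r1"])
        result = gapfill(model, net, medium={"A"})
        filled = fluxcore.apply_gapfill(model, net, result.added)
        assert set(model.reactions) <= set(filled.reactions)
        assert model.compounds <= filled.compounds

    def test_draft_models_grow_after_gapfill(self, universal):
        from commgem.draftgem import build_draft_model
        from commgem.netgen import sample_organism_genome, simulate_mag

        g = sample_organism_genome(universal, 2, seed=31, organism_id="spG")
        mag = simulate_mag(g, 55, 0, [], seed=32)
        model = build_draft_model(mag.genome, universal, "spG", provenance="mag")
        medium = fluxcore.default_medium(universal)
        core = set(universal.modules["core"])
        result = gapfill(model, universal, medium,
                         candidates=sorted(core - set(model.reactions)))
        if result.status == "filled":
            filled = fluxcore.apply_gapfill(model, universal, result.added)
            problem = build_flux_problem(filled, medium)
            assert fba(problem).objective_value > 1e-9
        else:
            assert result.status == "already_feasible"


class TestFoldChangeAccounting:
    def test_post_gapfill_counts_non_decreasing(self, universal):
        from commgem.community import census, merge_models
        from commgem.draftgem import build_draft_model
        from commgem.netgen import sample_organism_genome, simulate_mag

        medium = fluxcore.default_medium(universal)
        core = set(universal.modules["core"])
        models, filled_models = [], []
        for i in range(4):
            g = sample_organism_genome(universal, 2, seed=400 + i, organism_id=f"sp{i}")
            mag = simulate_mag(g, 60, 0, [], seed=500 + i)
            model = build_draft_model(mag.genome, universal, f"sp{i}", provenance="mag")
            models.append(model)
            result = gapfill(model, universal, medium,
                             candidates=sorted(core - set(model.reactions)))
            filled_models.append(fluxcore.apply_gapfill(model, universal, result.added))
        pre = census(merge_models(models))
        post = census(merge_models(filled_models))
        assert post.total_predicted >= pre.total_predicted
        assert post.unique_metabolites >= pre.unique_metabolites
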