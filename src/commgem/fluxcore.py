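"""Linear-programming core: FBA, FVA blocked-reaction classification, and
parsimonious gapfilling against the universal network.

Problems are standard steady-state LPs: maximize the objective flux subject
to S v = 0 and per-reaction bounds.  Exchange reactions are synthesized for
every extracellular compound instance; compounds in the medium may be taken
up (bounded), everything extracellular may be secreted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog

from .community import CommunityModel
from .draftgem import DEFAULT_UPPER, ModelReaction, OrganismModel
from .netgen import UniversalNetwork

__all__ = [
    "FluxProblem",
    "FbaResult",
    "FvaResult",
    "GapfillResult",
    "build_flux_problem",
    "fba",
    "fva",
    "gapfill",
    "default_medium",
    "BLOCKED_TOL",
]

BLOCKED_TOL = 1e-9  # |flux| below this is zero
DEFAULT_UPTAKE = 10.0


@dataclass
class FluxProblem:
    reaction_ids: list
    compound_instances: list  # (cid, compartment) rows
    S: np.ndarray  # compounds x reactions
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray  # coefficients, maximized

    def __post_init__(self):
        n_c, n_r = self.S.shape
        if n_r != len(self.reaction_ids) or n_c != len(self.compound_instances):
            raise ValueError("stoichiometric matrix shape mismatch")
        if (self.lower > self.upper).any():
            raise ValueError("lower bound exceeds upper bound")

    def index_of(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def model_reaction_ids(self) -> list:
        """Reactions of the model itself (excluding synthesized exchanges)."""
        return [r for r in self.reaction_ids if not r.startswith("EX_")]


@dataclass
class FbaResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float]
    fluxes: dict

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    ranges: dict  # reaction id -> (min flux, max flux)
    blocked: set
    blocked_percentage: float  # over model reactions (exchanges excluded)
    tol: float = BLOCKED_TOL


@dataclass
class GapfillResult:
    added: set
    status: str  # "already_feasible" | "filled" | "unfillable"
    method: str  # "exact" | "greedy"
    minimal: bool  # True when cardinality-minimality is guaranteed


def default_medium(universal: UniversalNetwork) -> set:
    """All universal seed compounds open for uptake."""
    return set(universal.seed_compounds)


def _gather_reactions(model: Union[OrganismModel, CommunityModel]):
    if isinstance(model, CommunityModel):
        reactions = model.reactions
        objective_ids = list(model.objective_reactions)
        shared = model.shared_compartment
    else:
        reactions = model.reactions
        objective_ids = [model.objective]
        shared = "e"
    return reactions, objective_ids, shared


def build_flux_problem(
    model: Union[OrganismModel, CommunityModel],
    medium: Optional[Iterable[str]] = None,
    *,
    uptake_limit: float = DEFAULT_UPTAKE,
) -> FluxProblem:
    """Assemble the steady-state LP for a model or community.

    An exchange reaction ``EX_<cid>_<comp>`` is added for every compound
    instance in the extracellular compartment; uptake (negative flux) is
    allowed only for compounds in the medium, up to ``uptake_limit``;
    secretion is open for all extracellular compounds.  The community
    objective is the unweighted sum of member biomass fluxes.
    """
    medium = set(medium) if medium is not None else set()
    reactions, objective_ids, shared = _gather_reactions(model)

    rids = sorted(reactions)
    instances = sorted({k for r in reactions.values() for k in r.stoichiometry})
    ex_rows = [(cid, comp) for cid, comp in instances if comp == shared]

    all_ids = list(rids) + [f"EX_{cid}_{comp}" for cid, comp in ex_rows]
    row_index = {k: i for i, k in enumerate(instances)}
    S = np.zeros((len(instances), len(all_ids)))
    lower = np.zeros(len(all_ids))
    upper = np.zeros(len(all_ids))

    for j, rid in enumerate(rids):
        r = reactions[rid]
        for key, coeff in r.stoichiometry.items():
            S[row_index[key], j] += coeff
        lower[j], upper[j] = r.lower, r.upper
    for k, (cid, comp) in enumerate(ex_rows):
        j = len(rids) + k
        S[row_index[(cid, comp)], j] = -1.0
        lower[j] = -uptake_limit if cid in medium else 0.0
        upper[j] = DEFAULT_UPPER

    objective = np.zeros(len(all_ids))
    for rid in objective_ids:
        objective[all_ids.index(rid)] = 1.0
    return FluxProblem(
        reaction_ids=all_ids,
        compound_instances=instances,
        S=S,
        lower=lower,
        upper=upper,
        objective=objective,
    )


_LP_OPTIONS = {"presolve": True}


def _solve(c, problem: FluxProblem, extra_A_ub=None, extra_b_ub=None, method="highs"):
    res = linprog(
        c,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        bounds=list(zip(problem.lower, problem.upper)),
        method=method,
    )
    return res


def fba(problem: FluxProblem, *, method: str = "highs") -> FbaResult:
    """Maximize the objective flux at steady state.

    Unboundedness is reported as a distinct status (it indicates missing
    bounds), never silently.
    """
    res = _solve(-problem.objective, problem, method=method)
    if res.status == 2:
        return FbaResult(status="infeasible", objective_value=None, fluxes={})
    if res.status == 3:
        return FbaResult(status="unbounded", objective_value=None, fluxes={})
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    v = res.x
    residual = np.abs(problem.S @ v).max() if v.size else 0.0
    if residual > 1e-6:
        raise RuntimeError(f"steady-state residual too large: {residual}")
    fluxes = dict(zip(problem.reaction_ids, (float(x) for x in v)))
    return FbaResult(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def fva(
    problem: FluxProblem,
    fix_objective_fraction: float = 0.0,
    *,
    tol: float = BLOCKED_TOL,
) -> FvaResult:
    """Per-reaction flux minimum/maximum over the feasible region.

    With ``fix_objective_fraction > 0`` the region is additionally
    constrained to objective >= fraction * optimum.  Blocked classification
    uses fraction 0 (a blocked reaction cannot carry flux under *any*
    feasible state): a reaction is blocked iff |min| <= tol and |max| <= tol.
    """
    if not 0.0 <= fix_objective_fraction <= 1.0:
        raise ValueError("fix_objective_fraction must be in [0, 1]")
    A_ub = b_ub = None
    if fix_objective_fraction > 0.0:
        base = fba(problem)
        if not base.ok:
            raise RuntimeError(f"base problem not optimal: {base.status}")
        A_ub = -problem.objective.reshape(1, -1)
        b_ub = np.array([-fix_objective_fraction * base.objective_value])

    n = len(problem.reaction_ids)
    ranges = {}
    blocked = set()
    for j, rid in enumerate(problem.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(c, problem, A_ub, b_ub)
        hi = _solve(-c, problem, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise RuntimeError(f"FVA LP failed for {rid}: {lo.message} / {hi.message}")
        vmin, vmax = float(lo.fun), float(-hi.fun)
        ranges[rid] = (vmin, vmax)
        if abs(vmin) <= tol and abs(vmax) <= tol:
            blocked.add(rid)

    model_rids = problem.model_reaction_ids()
    n_model_blocked = sum(1 for r in model_rids if r in blocked)
    pct = 100.0 * n_model_blocked / len(model_rids) if model_rids else 0.0
    return FvaResult(ranges=ranges, blocked=blocked, blocked_percentage=pct, tol=tol)


def fva_to_tsv(result: FvaResult, path) -> None:
    import pandas as pd

    rows = [
        {"reaction": rid, "min": lo, "max": hi, "blocked": rid in result.blocked}
        for rid, (lo, hi) in sorted(result.ranges.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gapfilling
# ---------------------------------------------------------------------------


def _grows(model: OrganismModel, medium: set, uptake_limit: float, tol: float) -> bool:
    problem = build_flux_problem(model, medium, uptake_limit=uptake_limit)
    result = fba(problem)
    return result.ok and result.objective_value > tol


def _augment(model: OrganismModel, universal: UniversalNetwork, rids: Iterable[str]) -> OrganismModel:
    from .draftgem import _instantiate

    augmented = model.copy()
    for rid in rids:
        augmented.reactions[rid] = _instantiate(universal.reactions[rid])
    return augmented


def gapfill(
    model: OrganismModel,
    universal: UniversalNetwork,
    medium: Iterable[str],
    *,
    candidates: Optional[Iterable[str]] = None,
    method: str = "auto",
    max_exact: int = 12,
    uptake_limit: float = DEFAULT_UPTAKE,
    tol: float = BLOCKED_TOL,
) -> GapfillResult:
    """Find a small set of catalog reactions whose addition enables growth.

    Returns the empty set when the model already grows on the medium.  For
    candidate pools of at most ``max_exact`` reactions the search is
    exhaustive over subset cardinality (guaranteed minimal); larger pools
    use a deterministic greedy add-all-then-prune that yields an
    inclusion-minimal (near-minimal cardinality) set, flagged as such.
    Gapfilling only ever adds reactions.
    """
    medium = set(medium)
    if method not in ("auto", "exact", "greedy"):
        raise ValueError("method must be auto, exact or greedy")
    if candidates is None:
        candidates = set(universal.reactions) - set(model.reactions)
    candidates = sorted(set(candidates) - set(model.reactions))

    if _grows(model, medium, uptake_limit, tol):
        return GapfillResult(added=set(), status="already_feasible", method="exact", minimal=True)

    if not _grows(_augment(model, universal, candidates), medium, uptake_limit, tol):
        return GapfillResult(added=set(), status="unfillable", method="exact", minimal=True)

    use_exact = method == "exact" or (method == "auto" and len(candidates) <= max_exact)
    if use_exact:
        for size in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, size):
                if _grows(_augment(model, universal, combo), medium, uptake_limit, tol):
                    return GapfillResult(
                        added=set(combo), status="filled", method="exact", minimal=True
                    )
        raise RuntimeError("exhaustive search inconsistent with full-pool feasibility")

    # greedy: start from the full candidate pool and prune deterministically
    keep = list(candidates)
    for rid in sorted(candidates):
        trial = [r for r in keep if r != rid]
        if _grows(_augment(model, universal, trial), medium, uptake_limit, tol):
            keep = trial
    return GapfillResult(added=set(keep), status="filled", method="greedy", minimal=False)


def apply_gapfill(model: OrganismModel, universal: UniversalNetwork, added: Iterable[str]) -> OrganismModel:
    """Return a copy of the model with the gapfill reactions added."""
    return _augment(model, universal, sorted(added))
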