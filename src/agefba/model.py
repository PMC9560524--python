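"""Enzyme-constrained metabolic models and the underlying linear program.

The model couples a stoichiometric network (steady-state mass balance
``S v = 0`` with flux bounds) to enzyme capacity constraints: each enzyme
``i`` catalysing reaction ``j`` with turnover number ``kcat_ij`` [1/h] and
subunit stoichiometry ``n_ij`` requires a usage
``e_i = sum_j (n_ij / kcat_ij) v_j`` [mmol/gDW], and the total enzyme mass
``e_pool = sum_i MW_i e_i`` [g/gDW] is capped by the available pool
``sigma * f * P_tot`` (average saturation x modelled mass fraction x total
protein content).

Models are stored and solved in irreversible (split) form: reactions with a
negative lower bound are split into a forward and a backward column at load
time, with ``reversible_parent`` recording the original id, so that
"reactions producing metabolite X" has a fixed sign per column.
"""
from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

INF = math.inf

#: default feasibility / optimality tolerance handed to the LP solver
FEASIBILITY_TOL = 1e-9

#: HiGHS dual simplex: deterministic vertex selection for a fixed column
#: ordering, which makes the non-parsimonious solution reproducible.
_LP_METHOD = "highs-ds"
_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


class ModelIntegrityError(ValueError):
    """A reaction, enzyme or named role references an unknown entity."""


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


# ---------------------------------------------------------------------------
# data classes
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A (possibly split) reaction column.

    ``stoich`` maps metabolite id to signed coefficient (products positive).
    Bounds are fluxes in mmol/gDW/h. ``pathway`` is a free-text label used by
    the flux analytics; ``reversible_parent`` / ``isoenzyme_group`` drive the
    collapse step when comparing flux distributions.
    """

    id: str
    stoich: dict[str, float] = field(default_factory=dict)
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = INF
    pathway: str = ""
    reversible_parent: str | None = None
    isoenzyme_group: str | None = None

    @property
    def is_exchange(self) -> bool:
        """Exchange/sink pseudo-reactions touch at most one metabolite."""
        return len(self.stoich) <= 1


@dataclass
class Enzyme:
    id: str
    MW: float  # kDa == g/mmol
    kcat: dict[str, float] = field(default_factory=dict)  # reaction id -> 1/h
    n: dict[str, float] = field(default_factory=dict)  # subunit stoichiometry
    lower_bound: float = 0.0
    upper_bound: float = INF

    def subunits(self, rid: str) -> float:
        return self.n.get(rid, 1.0)


@dataclass
class FluxSolution:
    """Result of one or more chained LP solves over the same problem."""

    v: dict[str, float]
    e: dict[str, float]
    e_pool: float
    stage_values: list[float]
    status: str  # optimal | infeasible | unbounded
    objective_labels: list[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    enzymes: list[Enzyme]
    sigma: float = 1.0
    f: float = 1.0
    P_tot: float = 1.0
    named_reactions: dict[str, str] = field(default_factory=dict)
    reaction_sets: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._enz_index = {e.id: i for i, e in enumerate(self.enzymes)}

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def enzyme(self, eid: str) -> Enzyme:
        return self.enzymes[self._enz_index[eid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    @property
    def pool_bound(self) -> float:
        return self.sigma * self.f * self.P_tot

    def named(self, role: str) -> str:
        try:
            return self.named_reactions[role]
        except KeyError as exc:
            raise ModelIntegrityError(f"no reaction registered for role {role!r}") from exc

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with one row per metabolite, one column per reaction."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                if met not in self._met_index:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
                S[self._met_index[met], j] = coef
        return S

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def _num(x: float):
            return None if x in (INF, -INF) else x

        return {
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoich": dict(r.stoich),
                    "lower_bound": _num(r.lower_bound),
                    "upper_bound": _num(r.upper_bound),
                    "pathway": r.pathway,
                    "reversible_parent": r.reversible_parent,
                    "isoenzyme_group": r.isoenzyme_group,
                }
                for r in self.reactions
            ],
            "enzymes": [
                {
                    "id": e.id,
                    "MW": e.MW,
                    "kcat": dict(e.kcat),
                    "n": dict(e.n),
                    "lower_bound": _num(e.lower_bound),
                    "upper_bound": _num(e.upper_bound),
                }
                for e in self.enzymes
            ],
            "pool": {"sigma": self.sigma, "f": self.f, "P_tot": self.P_tot},
            "named_reactions": dict(self.named_reactions),
            "reaction_sets": {k: list(v) for k, v in self.reaction_sets.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetabolicModel":
        def _lb(x):
            return 0.0 if x is None else x

        def _ub(x):
            return INF if x is None else x

        mets = [Metabolite(**m) for m in data["metabolites"]]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=_lb(r.get("lower_bound")),
                upper_bound=_ub(r.get("upper_bound")),
                pathway=r.get("pathway", ""),
                reversible_parent=r.get("reversible_parent"),
                isoenzyme_group=r.get("isoenzyme_group"),
            )
            for r in data["reactions"]
        ]
        enzs = [
            Enzyme(
                id=e["id"],
                MW=float(e["MW"]),
                kcat={k: float(v) for k, v in e["kcat"].items()},
                n={k: float(v) for k, v in e.get("n", {}).items()},
                lower_bound=_lb(e.get("lower_bound")),
                upper_bound=_ub(e.get("upper_bound")),
            )
            for e in data["enzymes"]
        ]
        pool = data.get("pool", {})
        model = cls(
            metabolites=mets,
            reactions=rxns,
            enzymes=enzs,
            sigma=float(pool.get("sigma", 1.0)),
            f=float(pool.get("f", 1.0)),
            P_tot=float(pool.get("P_tot", 1.0)),
            named_reactions=dict(data.get("named_reactions", {})),
            reaction_sets={k: list(v) for k, v in data.get("reaction_sets", {}).items()},
        )
        return split_reversible(model)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MetabolicModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls.from_dict(data)


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction into forward/backward columns.

    The forward column keeps the original stoichiometry with bounds
    ``[0, ub]``; the backward column is negated with bounds ``[0, -lb]``.
    Enzyme kcat/n entries are duplicated onto both directions.
    """
    new_rxns: list[Reaction] = []
    renames: dict[str, list[str]] = {}
    for r in model.reactions:
        if r.lower_bound < 0.0:
            fwd = Reaction(
                id=f"{r.id}__fwd",
                name=r.name,
                stoich=dict(r.stoich),
                lower_bound=0.0,
                upper_bound=r.upper_bound,
                pathway=r.pathway,
                reversible_parent=r.id,
                isoenzyme_group=r.isoenzyme_group,
            )
            bwd = Reaction(
                id=f"{r.id}__bwd",
                name=r.name,
                stoich={k: -v for k, v in r.stoich.items()},
                lower_bound=0.0,
                upper_bound=-r.lower_bound,
                pathway=r.pathway,
                reversible_parent=r.id,
                isoenzyme_group=r.isoenzyme_group,
            )
            new_rxns.extend([fwd, bwd])
            renames[r.id] = [fwd.id, bwd.id]
        else:
            new_rxns.append(r)
    if not renames:
        return model
    new_enzs = []
    for e in model.enzymes:
        kcat, n = {}, {}
        for rid, k in e.kcat.items():
            for target in renames.get(rid, [rid]):
                kcat[target] = k
                if rid in e.n:
                    n[target] = e.n[rid]
        new_enzs.append(
            Enzyme(id=e.id, MW=e.MW, kcat=kcat, n=n,
                   lower_bound=e.lower_bound, upper_bound=e.upper_bound)
        )
    named = {
        role: renames[rid][0] if rid in renames else rid
        for role, rid in model.named_reactions.items()
    }
    sets = {
        name: [t for rid in rids for t in renames.get(rid, [rid])]
        for name, rids in model.reaction_sets.items()
    }
    return MetabolicModel(
        metabolites=model.metabolites,
        reactions=new_rxns,
        enzymes=new_enzs,
        sigma=model.sigma,
        f=model.f,
        P_tot=model.P_tot,
        named_reactions=named,
        reaction_sets=sets,
    )


# ---------------------------------------------------------------------------
# linear problem
# ---------------------------------------------------------------------------

@dataclass
class LinearProblem:
    """An LP over variables (v_1..v_m, e_1..e_k, e_pool).

    Equality rows: mass balance per metabolite, usage coupling per enzyme and
    the pool coupling. Inequality rows hold locked-stage constraints appended
    by the lexicographic optimiser.
    """

    var_names: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    n_reactions: int
    n_enzymes: int
    A_ub: np.ndarray = None  # type: ignore[assignment]
    b_ub: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.var_names)
        if self.A_ub is None:
            self.A_ub = np.zeros((0, n))
            self.b_ub = np.zeros(0)
        self.index = {name: i for i, name in enumerate(self.var_names)}

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def copy(self) -> "LinearProblem":
        return LinearProblem(
            var_names=self.var_names,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            n_reactions=self.n_reactions,
            n_enzymes=self.n_enzymes,
            A_ub=self.A_ub.copy(),
            b_ub=self.b_ub.copy(),
        )

    def set_bounds(self, name: str, lower: float | None = None,
                   upper: float | None = None) -> None:
        i = self.index[name]
        if lower is not None:
            self.lb[i] = lower
        if upper is not None:
            self.ub[i] = upper

    def add_inequality(self, coefficients: dict[str, float], rhs: float) -> None:
        """Append a row  sum_i a_i x_i <= rhs."""
        row = np.zeros(self.n_vars)
        for name, w in coefficients.items():
            row[self.index[name]] += w
        self.A_ub = np.vstack([self.A_ub, row])
        self.b_ub = np.append(self.b_ub, rhs)

    def dense_objective(self, coefficients: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for name, w in coefficients.items():
            try:
                c[self.index[name]] += w
            except KeyError as exc:
                raise ModelIntegrityError(f"unknown variable {name!r} in objective") from exc
        return c


def build_lp(model: MetabolicModel) -> LinearProblem:
    """Assemble the enzyme-constrained LP (no objective attached).

    Rows: ``S v = 0`` per metabolite; per enzyme ``i``
    ``-sum_j (n_ij/kcat_ij) v_j + e_i = 0`` over reactions with a kcat entry;
    pool coupling ``-sum_i MW_i e_i + e_pool = 0``. Box bounds come from the
    reaction/enzyme bounds and ``0 <= e_pool <= sigma f P_tot``.
    """
    m_rxn, m_enz = len(model.reactions), len(model.enzymes)
    var_names = (
        [r.id for r in model.reactions]
        + [e.id for e in model.enzymes]
        + ["e_pool"]
    )
    n = m_rxn + m_enz + 1
    rows = len(model.metabolites) + m_enz + 1
    A = np.zeros((rows, n))
    # mass balance
    A[: len(model.metabolites), :m_rxn] = model.stoichiometric_matrix()
    # enzyme coupling
    for i, enz in enumerate(model.enzymes):
        row = len(model.metabolites) + i
        for rid, kcat in enz.kcat.items():
            if not model.has_reaction(rid):
                raise ModelIntegrityError(
                    f"enzyme {enz.id!r} references unknown reaction {rid!r}"
                )
            if kcat <= 0:
                raise ModelIntegrityError(
                    f"enzyme {enz.id!r} has non-positive kcat for {rid!r}"
                )
            A[row, model._rxn_index[rid]] = -enz.subunits(rid) / kcat
        A[row, m_rxn + i] = 1.0
    # pool coupling
    pool_row = len(model.metabolites) + m_enz
    for i, enz in enumerate(model.enzymes):
        A[pool_row, m_rxn + i] = -enz.MW
    A[pool_row, n - 1] = 1.0

    lb = np.zeros(n)
    ub = np.full(n, INF)
    for j, r in enumerate(model.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
    for i, e in enumerate(model.enzymes):
        lb[m_rxn + i], ub[m_rxn + i] = e.lower_bound, e.upper_bound
    lb[n - 1], ub[n - 1] = 0.0, model.pool_bound

    return LinearProblem(
        var_names=var_names, A_eq=A, b_eq=np.zeros(rows),
        lb=lb, ub=ub, n_reactions=m_rxn, n_enzymes=m_enz,
    )


def solve_lp(problem: LinearProblem, objective) -> FluxSolution:
    """Solve the LP for one objective (an ``optimize.Objective`` or a
    ``(coefficients, direction)`` pair) and report the achieved value."""
    if isinstance(objective, tuple):
        coefficients, direction = objective
        label = "custom"
    else:
        coefficients, direction, label = (
            objective.coefficients, objective.direction, objective.label
        )
    sign = -1.0 if direction == "max" else 1.0
    c = problem.dense_objective(coefficients)
    res = linprog(
        sign * c,
        A_ub=problem.A_ub if len(problem.b_ub) else None,
        b_ub=problem.b_ub if len(problem.b_ub) else None,
        A_eq=problem.A_eq,
        b_eq=problem.b_eq,
        bounds=np.column_stack([problem.lb, problem.ub]),
        method=_LP_METHOD,
        options=_LP_OPTIONS,
    )
    if res.status == 0:
        status = "optimal"
    elif res.status == 2:
        status = "infeasible"
    elif res.status == 3:
        status = "unbounded"
    else:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
    if status != "optimal":
        return FluxSolution(v={}, e={}, e_pool=float("nan"), stage_values=[],
                            status=status, objective_labels=[label])
    x = res.x
    m = problem.n_reactions
    v = {problem.var_names[j]: float(x[j]) for j in range(m)}
    e = {problem.var_names[m + i]: float(x[m + i]) for i in range(problem.n_enzymes)}
    z = float(c @ x)
    return FluxSolution(v=v, e=e, e_pool=float(x[-1]), stage_values=[z],
                        status="optimal", objective_labels=[label])


def total_production_flux(model: MetabolicModel, metabolite: str,
                          solution: FluxSolution, weighted: bool = True,
                          reactions: list[str] | None = None) -> float:
    """Total production rate of ``metabolite``: sum of ``max(S_mj, 0) * v_j``.

    With ``weighted=False`` every producing reaction contributes its raw flux
    (sensitivity variant; the stoichiometry-weighted sum is the default since
    it is a true production rate, invariant to reaction scaling).
    """
    if metabolite not in model._met_index:
        raise ModelIntegrityError(f"unknown metabolite {metabolite!r}")
    rids = reactions if reactions is not None else [r.id for r in model.reactions]
    total = 0.0
    for rid in rids:
        coef = model.reaction(rid).stoich.get(metabolite, 0.0)
        if coef > 0:
            total += (coef if weighted else 1.0) * solution.v.get(rid, 0.0)
    return total


def total_consumption_flux(model: MetabolicModel, metabolite: str,
                           solution: FluxSolution,
                           reactions: list[str] | None = None) -> float:
    """Stoichiometry-weighted consumption rate of ``metabolite``."""
    if metabolite not in model._met_index:
        raise ModelIntegrityError(f"unknown metabolite {metabolite!r}")
    rids = reactions if reactions is not None else [r.id for r in model.reactions]
    total = 0.0
    for rid in rids:
        coef = model.reaction(rid).stoich.get(metabolite, 0.0)
        if coef < 0:
            total += -coef * solution.v.get(rid, 0.0)
    return total


def validate_model(model: MetabolicModel) -> list[str]:
    """Diagnostics report; empty iff all model invariants hold."""
    issues: list[str] = []
    met_ids = {m.id for m in model.metabolites}
    rxn_ids = {r.id for r in model.reactions}
    catalysed = {rid for e in model.enzymes for rid in e.kcat}
    used_mets: set[str] = set()
    for r in model.reactions:
        for met in r.stoich:
            if met not in met_ids:
                issues.append(f"reaction {r.id}: unknown metabolite {met}")
            used_mets.add(met)
        if r.lower_bound > r.upper_bound:
            issues.append(f"reaction {r.id}: lower bound exceeds upper bound")
        if not r.stoich and not r.is_exchange:
            issues.append(f"reaction {r.id}: empty stoichiometry")
        if not r.is_exchange and r.id not in catalysed:
            issues.append(f"reaction {r.id}: internal reaction without enzyme")
    for met in met_ids - used_mets:
        issues.append(f"metabolite {met}: not used by any reaction")
    for e in model.enzymes:
        if e.MW <= 0:
            issues.append(f"enzyme {e.id}: non-positive molecular weight")
        if e.lower_bound > e.upper_bound:
            issues.append(f"enzyme {e.id}: lower bound exceeds upper bound")
        for rid, kcat in e.kcat.items():
            if rid not in rxn_ids:
                issues.append(f"enzyme {e.id}: unknown reaction {rid}")
            if kcat <= 0:
                issues.append(f"enzyme {e.id}: non-positive kcat for {rid}")
        for rid, nn in e.n.items():
            if nn < 1:
                issues.append(f"enzyme {e.id}: subunit stoichiometry < 1 for {rid}")
    for role, rid in model.named_reactions.items():
        if rid not in rxn_ids:
            issues.append(f"named role {role}: unknown reaction {rid}")
    for name, rids in model.reaction_sets.items():
        for rid in rids:
            if rid not in rxn_ids:
                issues.append(f"reaction set {name}: unknown reaction {rid}")
    if model.pool_bound <= 0:
        issues.append("enzyme pool sigma*f*P_tot is not positive")
    return issues
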