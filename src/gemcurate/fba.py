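"""Flux balance analysis, gene-rule evaluation, and gene-knockout screens.

FBA solves the LP  max/min c·v  s.t.  S·v = 0,  lb ≤ v ≤ ub,  where S is
the stoichiometric matrix.  A medium constrains uptake through exchange
reactions (negative flux = uptake).  Single-gene knockouts disable every
reaction whose gene rule evaluates false with that gene removed and call
the gene essential when the biomass optimum falls below a flux threshold
(default 1e-6 hr⁻¹; calls are insensitive to the exact value over several
orders of magnitude).
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csc_matrix

from .errors import GeneRuleError, SolverError
from .model import Medium, MetabolicModel

# LP tolerances recorded in result metadata; fixed for reproducibility
# across solver builds.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7

_LINPROG_OPTIONS = {
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": OPTIMALITY_TOL,
}

DEFAULT_ESSENTIALITY_THRESHOLD = 1e-6


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            if rule[pos:].strip():
                raise GeneRuleError(
                    f"gene rule: unexpected character {rule[pos]!r} at position {pos}"
                )
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


@functools.lru_cache(maxsize=4096)
def _parse(rule: str):
    """Parse a gene rule into a nested tuple AST.

    Grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    factor := GENE | '(' expr ')'.  Keywords are case-insensitive.
    """
    tokens = _tokenize(rule)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def expect_factor():
        nonlocal idx
        tok = peek()
        if tok is None:
            where = tokens[idx - 1][1] if tokens else 0
            raise GeneRuleError(f"gene rule {rule!r}: expected gene or '(' after position {where}")
        if tok == "(":
            idx += 1
            node = expr()
            if peek() != ")":
                raise GeneRuleError(f"gene rule {rule!r}: unbalanced parenthesis")
            idx += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GeneRuleError(
                f"gene rule {rule!r}: unexpected {tok!r} at position {tokens[idx][1]}"
            )
        idx += 1
        return ("gene", tok)

    def term():
        nonlocal idx
        node = expect_factor()
        parts = [node]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            parts.append(expect_factor())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def expr():
        nonlocal idx
        parts = [term()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    if not tokens:
        return None
    node = expr()
    if idx != len(tokens):
        raise GeneRuleError(
            f"gene rule {rule!r}: trailing tokens at position {tokens[idx][1]}"
        )
    return node


def _eval(node, knocked_out: frozenset[str]) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in knocked_out
    if kind == "and":
        return all(_eval(c, knocked_out) for c in node[1])
    return any(_eval(c, knocked_out) for c in node[1])


def gene_rule_active(rule: str, knocked_out: set[str] | frozenset[str]) -> bool:
    """Evaluate a gene rule with the given genes set to false.

    Empty rules are always active (spontaneous/orphan reactions).
    """
    node = _parse(rule.strip())
    if node is None:
        return True
    return _eval(node, frozenset(knocked_out))


def gene_rule_genes(rule: str) -> frozenset[str]:
    """The set of gene identifiers appearing in a rule."""
    node = _parse(rule.strip())
    out: set[str] = set()

    def walk(n):
        if n[0] == "gene":
            out.add(n[1])
        else:
            for c in n[1]:
                walk(c)

    if node is not None:
        walk(node)
    return frozenset(out)


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

@dataclass
class FluxDistribution:
    """Solution of one FBA problem."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"


class LinearSystem:
    """Reusable LP representation of S·v = 0 with per-solve bound overrides.

    Building the sparse stoichiometric matrix once and varying only bounds
    makes repeated solves (knockout screens) cheap.
    """

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.reaction_ids = [r.id for r in model.reactions]
        self._rxn_pos = {rid: i for i, rid in enumerate(self.reaction_ids)}
        met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(coef)
        self.S = csc_matrix(
            (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
        )
        self.base_lb = np.array([r.lower_bound for r in model.reactions], float)
        self.base_ub = np.array([r.upper_bound for r in model.reactions], float)
        # gene -> positions of reactions whose rule mentions it
        self._gene_rxns: dict[str, list[int]] = {}
        for j, r in enumerate(model.reactions):
            for g in r.genes():
                self._gene_rxns.setdefault(g, []).append(j)

    def medium_bounds(self, medium: Medium | None) -> tuple[np.ndarray, np.ndarray]:
        lb = self.base_lb.copy()
        ub = self.base_ub.copy()
        if medium is not None:
            medium.validate()
            for r in self.model.reactions:
                if r.is_exchange:
                    j = self._rxn_pos[r.id]
                    lb[j] = -float(medium.uptake_limits.get(r.id, 0.0))
        return lb, ub

    def knockout_positions(self, knocked_out: set[str]) -> list[int]:
        """Reaction positions disabled by knocking out the given genes."""
        ko = frozenset(knocked_out)
        candidates: set[int] = set()
        for g in ko:
            candidates.update(self._gene_rxns.get(g, ()))
        return [
            j for j in sorted(candidates)
            if not gene_rule_active(self.model.reactions[j].gene_rule, ko)
        ]

    def solve(
        self,
        objective: dict[str, float],
        sense: str = "max",
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
    ) -> FluxDistribution:
        if lb is None:
            lb = self.base_lb
        if ub is None:
            ub = self.base_ub
        c = np.zeros(len(self.reaction_ids))
        for rid, coef in objective.items():
            c[self._rxn_pos[rid]] = coef
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options=_LINPROG_OPTIONS,
        )
        if res.status == 0:
            fluxes = dict(zip(self.reaction_ids, res.x.tolist()))
            return FluxDistribution(fluxes, float(sign * res.fun), "optimal")
        if res.status == 2:
            return FluxDistribution({}, float("nan"), "infeasible")
        if res.status == 3:
            return FluxDistribution({}, float("nan"), "unbounded")
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")


def solve_fba(
    model: MetabolicModel,
    medium: Medium | None = None,
    objective_reaction_id: str | None = None,
    sense: str = "max",
    knocked_out: set[str] | None = None,
) -> FluxDistribution:
    """Maximize (or minimize) flux through one reaction at steady state."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    obj = objective_reaction_id or model.biomass_reaction_id
    if not model.has_reaction(obj):
        raise ValueError(f"objective reaction {obj!r} not in model")
    sys = LinearSystem(model)
    lb, ub = sys.medium_bounds(medium)
    if knocked_out:
        for j in sys.knockout_positions(knocked_out):
            lb[j] = 0.0
            ub[j] = 0.0
    return sys.solve({obj: 1.0}, sense=sense, lb=lb, ub=ub)


# ---------------------------------------------------------------------------
# Knockout screens
# ---------------------------------------------------------------------------

@dataclass
class EssentialityCall:
    gene: str
    essential: bool
    biomass_flux: float
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD


def single_gene_knockouts(
    model: MetabolicModel,
    medium: Medium | None = None,
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD,
    genes: list[str] | None = None,
) -> list[EssentialityCall]:
    """Simulate every single-gene knockout and call essentiality.

    Reactions whose gene rule evaluates false under the knockout are
    constrained to zero flux (bounds set to 0, matrix shape preserved);
    biomass is then maximized.  Infeasible knockouts count as zero biomass.
    ``genes`` extends/overrides the screened set (genes absent from every
    rule are trivially nonessential).
    """
    sys = LinearSystem(model)
    lb0, ub0 = sys.medium_bounds(medium)
    universe = sorted(model.genes) if genes is None else list(genes)
    biomass = model.biomass_reaction_id
    calls: list[EssentialityCall] = []
    for g in universe:
        lb, ub = lb0, ub0
        positions = sys.knockout_positions({g})
        if positions:
            lb = lb0.copy()
            ub = ub0.copy()
            for j in positions:
                lb[j] = 0.0
                ub[j] = 0.0
        sol = sys.solve({biomass: 1.0}, sense="max", lb=lb, ub=ub)
        flux = sol.objective_value if sol.status == "optimal" else 0.0
        calls.append(EssentialityCall(g, flux < threshold, flux, threshold))
    return calls


def write_essentiality_tsv(calls: list[EssentialityCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(c.gene, int(c.essential), c.biomass_flux) for c in calls],
        columns=["gene", "essential", "biomass_flux"],
    ).to_csv(path, sep="\t", index=False)
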