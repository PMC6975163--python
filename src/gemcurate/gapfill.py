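"""Parsimonious gap filling and media-shuffled ensemble generation.

Gap filling selects reactions from a universal bag U whose addition lets
the draft model produce biomass in a medium.  The LP is

    min Σ_{j penalized} |y_j|
    s.t.  S·v + U·y = 0,  v_biomass ≥ biomass_floor,  bounds on v and y,

i.e. parsimonious FBA repurposed: only fluxes through universal reactions
are penalized, and biomass is required only to clear a small floor
(default 0.05 hr⁻¹) representing a binary growth call.  |y_j| is
linearized by splitting each universal flux into nonnegative y⁺, y⁻ with
y = y⁺ − y⁻ and objective Σ(y⁺ + y⁻).

An ensemble member is built by shuffling the media conditions and
gap-filling them sequentially: reactions activated in one condition lose
their penalty for all later conditions of that member, so different
orders can yield different reaction sets.  Repeating with fresh shuffles
and deduplicating yields an ensemble of alternative gap-filled models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csc_matrix

from .ensemble import Ensemble, build_ensemble
from .errors import DegenerateEnsembleError, GapfillInfeasibleError, SolverError
from .fba import _LINPROG_OPTIONS, LinearSystem
from .model import Medium, MetabolicModel, UniversalReactionBag

DEFAULT_BIOMASS_FLOOR = 0.05
DEFAULT_ACTIVATION_CUTOFF = 1e-11


@dataclass
class GapfillProblem:
    """One gap-fill LP: draft model + universal bag under one medium.

    ``penalty`` maps each universal reaction id to True (penalized, the
    default) or False (free); only penalized fluxes enter the objective.
    """

    model: MetabolicModel
    universal: UniversalReactionBag
    medium: Medium
    penalty: dict[str, bool] = field(default_factory=dict)
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR
    activation_cutoff: float = DEFAULT_ACTIVATION_CUTOFF

    def __post_init__(self) -> None:
        if self.biomass_floor <= 0:
            raise ValueError("biomass_floor must be positive")
        if self.activation_cutoff <= 0:
            raise ValueError("activation_cutoff must be positive")
        full = {r.id: True for r in self.universal.reactions}
        extra = set(self.penalty) - set(full)
        if extra:
            raise ValueError(f"penalty keys not in universal bag: {sorted(extra)}")
        full.update(self.penalty)
        self.penalty = full


@dataclass
class GapfillSolution:
    """Reactions activated by one gap-fill solve."""

    activated: frozenset[str]
    objective: float
    condition: str


@dataclass
class MemberRecipe:
    """One ensemble member: a media ordering and the union of activated
    reactions across its conditions."""

    media_order: list[str]
    gapfilled_reactions: frozenset[str]


class _GapfillSystem:
    """Combined LP over model fluxes v and split universal fluxes y⁺, y⁻.

    Variable layout: [v (n_model) | y⁺ (n_univ) | y⁻ (n_univ)].  Built once
    per (model, universal) pair; medium and penalties vary per solve.
    """

    def __init__(self, model: MetabolicModel, universal: UniversalReactionBag):
        universal.validate(model)
        self.model = model
        self.universal = universal
        self.model_sys = LinearSystem(model)
        self.univ_ids = [r.id for r in universal.reactions]
        met_ids = list(dict.fromkeys(
            [m.id for m in model.metabolites]
            + [mid for r in universal.reactions for mid in r.stoichiometry]
        ))
        met_pos = {mid: i for i, mid in enumerate(met_ids)}
        n_model = len(model.reactions)
        n_univ = len(universal.reactions)
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(coef)
        for j, r in enumerate(universal.reactions):
            for mid, coef in r.stoichiometry.items():
                i = met_pos[mid]
                rows.append(i)
                cols.append(n_model + j)          # y⁺
                vals.append(coef)
                rows.append(i)
                cols.append(n_model + n_univ + j)  # y⁻
                vals.append(-coef)
        self.A = csc_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), n_model + 2 * n_univ)
        )
        self.n_model = n_model
        self.n_univ = n_univ
        self.yplus_ub = np.array(
            [max(r.upper_bound, 0.0) for r in universal.reactions], float
        )
        self.yminus_ub = np.array(
            [max(-r.lower_bound, 0.0) for r in universal.reactions], float
        )
        self._biomass_pos = self.model_sys._rxn_pos[model.biomass_reaction_id]

    def solve(self, problem: GapfillProblem) -> GapfillSolution:
        lb_v, ub_v = self.model_sys.medium_bounds(problem.medium)
        lb_v = lb_v.copy()
        lb_v[self._biomass_pos] = max(
            lb_v[self._biomass_pos], problem.biomass_floor
        )
        lb = np.concatenate([lb_v, np.zeros(2 * self.n_univ)])
        ub = np.concatenate([ub_v, self.yplus_ub, self.yminus_ub])
        pen = np.array(
            [1.0 if problem.penalty[rid] else 0.0 for rid in self.univ_ids]
        )
        c = np.concatenate([np.zeros(self.n_model), pen, pen])
        res = linprog(
            c,
            A_eq=self.A,
            b_eq=np.zeros(self.A.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options=_LINPROG_OPTIONS,
        )
        if res.status == 2:
            raise GapfillInfeasibleError(
                f"no gap-fill solution exists for medium {problem.medium.name!r}: "
                "biomass floor unreachable even with the full universal bag"
            )
        if res.status != 0:
            raise SolverError(
                f"gap-fill LP failed (status {res.status}): {res.message}"
            )
        y = res.x[self.n_model:self.n_model + self.n_univ] - \
            res.x[self.n_model + self.n_univ:]
        activated = frozenset(
            rid
            for rid, flux in zip(self.univ_ids, y)
            if problem.penalty[rid] and abs(flux) > problem.activation_cutoff
        )
        return GapfillSolution(activated, float(res.fun), problem.medium.name)


def gapfill_condition(problem: GapfillProblem) -> GapfillSolution:
    """Solve one gap-fill LP and report activated penalized reactions.

    A universal reaction is activated when its optimal flux magnitude
    exceeds ``activation_cutoff`` (default 1e-11) and it was penalized.
    """
    return _GapfillSystem(problem.model, problem.universal).solve(problem)


def build_member(
    model: MetabolicModel,
    universal: UniversalReactionBag,
    media: list[Medium],
    rng: np.random.Generator,
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR,
    activation_cutoff: float = DEFAULT_ACTIVATION_CUTOFF,
    _system: "_GapfillSystem | None" = None,
    verify: bool = True,
) -> MemberRecipe:
    """Gap-fill all media in a random order, freeing penalties as it goes.

    Returns the union of activated reactions; the draft plus that union
    must grow (biomass ≥ floor) in every input medium, which is checked
    when ``verify`` is true.
    """
    if not media:
        raise ValueError("at least one medium is required")
    sys_ = _system or _GapfillSystem(model, universal)
    order = [media[i] for i in rng.permutation(len(media))]
    penalty = {rid: True for rid in sys_.univ_ids}
    union: set[str] = set()
    for medium in order:
        sol = sys_.solve(
            GapfillProblem(
                model, universal, medium,
                penalty=dict(penalty),
                biomass_floor=biomass_floor,
                activation_cutoff=activation_cutoff,
            )
        )
        union |= sol.activated
        for rid in sol.activated:
            penalty[rid] = False
    recipe = MemberRecipe([m.name for m in order], frozenset(union))
    if verify:
        _verify_member(model, universal, recipe, media, biomass_floor)
    return recipe


def _verify_member(
    model: MetabolicModel,
    universal: UniversalReactionBag,
    recipe: MemberRecipe,
    media: list[Medium],
    biomass_floor: float,
) -> None:
    from .fba import solve_fba

    filled = model.copy()
    mets = universal.metabolite_map()
    for rid in sorted(recipe.gapfilled_reactions):
        filled.add_reaction(universal.get_reaction(rid).copy(), mets)
    for medium in media:
        sol = solve_fba(filled, medium)
        if sol.status != "optimal" or sol.objective_value < biomass_floor - 1e-9:
            raise SolverError(
                f"gap-filled member fails to grow in medium {medium.name!r} "
                f"(status {sol.status}, biomass {sol.objective_value!r})"
            )


def generate_ensemble(
    model: MetabolicModel,
    universal: UniversalReactionBag,
    media: list[Medium],
    n: int = 1000,
    seed: int = 0,
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR,
    activation_cutoff: float = DEFAULT_ACTIVATION_CUTOFF,
    min_unique: int = 3,
) -> Ensemble:
    """Build ``n`` members with fresh media shuffles; deduplicate.

    Penalties reset to the original state at the start of each member.
    Duplicate recipes (identical reaction sets, media order ignored) are
    removed.  Fewer than ``min_unique`` unique members raises a
    degenerate-ensemble error.  Per-member RNG streams derive from
    ``(seed, member index)`` so results are order-independent and
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    system = _GapfillSystem(model, universal)
    recipes: list[MemberRecipe] = []
    seen: set[frozenset[str]] = set()
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        recipe = build_member(
            model, universal, media, rng,
            biomass_floor=biomass_floor,
            activation_cutoff=activation_cutoff,
            _system=system,
            verify=False,
        )
        if recipe.gapfilled_reactions not in seen:
            seen.add(recipe.gapfilled_reactions)
            recipes.append(recipe)
    if len(recipes) < min_unique:
        raise DegenerateEnsembleError(
            f"only {len(recipes)} unique gap-fill solution(s) found "
            f"(minimum {min_unique})"
        )
    for recipe in recipes:
        _verify_member(model, universal, recipe, media, biomass_floor)
    metadata = {
        "seed": seed,
        "n_requested": n,
        "n_unique": len(recipes),
        "biomass_floor": biomass_floor,
        "activation_cutoff": activation_cutoff,
        "media": [m.name for m in media],
        "media_order_per_member": [r.media_order for r in recipes],
    }
    return build_ensemble(model, universal, recipes, metadata)


def enumerate_minimal_gapfills(
    model: MetabolicModel,
    universal: UniversalReactionBag,
    medium: Medium,
    biomass_floor: float = DEFAULT_BIOMASS_FLOOR,
    activation_cutoff: float = DEFAULT_ACTIVATION_CUTOFF,
    max_universe: int = 12,
) -> tuple[float, list[frozenset[str]]]:
    """Exhaustively enumerate minimal-flux-sum gap-fill solutions.

    For every subset of the universal bag, solve the restricted LP (all
    subset reactions penalized) and keep subsets whose optimum equals the
    global minimum with every subset reaction active.  Intended for small
    universes (hard cap ``max_universe``); used to verify fixture ground
    truth and as an independent oracle for :func:`gapfill_condition`.
    """
    from itertools import combinations

    ids = universal.reaction_ids
    if len(ids) > max_universe:
        raise ValueError(f"universe too large to enumerate ({len(ids)} reactions)")
    best = np.inf
    solutions: list[tuple[float, frozenset[str]]] = []
    for size in range(len(ids) + 1):
        for combo in combinations(ids, size):
            sub = UniversalReactionBag(
                reactions=[universal.get_reaction(r).copy() for r in combo],
                metabolites=list(universal.metabolites),
            )
            try:
                sol = gapfill_condition(
                    GapfillProblem(
                        model, sub, medium,
                        biomass_floor=biomass_floor,
                        activation_cutoff=activation_cutoff,
                    )
                )
            except GapfillInfeasibleError:
                continue
            if sol.activated == frozenset(combo):
                solutions.append((sol.objective, frozenset(combo)))
                best = min(best, sol.objective)
    if not np.isfinite(best):
        raise GapfillInfeasibleError(
            f"no gap-fill solution exists for medium {medium.name!r}"
        )
    minimal = sorted(
        {s for obj, s in solutions if obj <= best + 1e-7}, key=sorted
    )
    return float(best), minimal
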