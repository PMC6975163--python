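"""Domain types and I/O for constraint-based metabolic models.

A model is a stoichiometric network: metabolites, reactions with flux
bounds (mmol·gDW⁻¹·hr⁻¹) and boolean gene rules, and a designated biomass
reaction whose flux proxies growth rate.  The canonical on-disk format is
a small JSON dialect (see ``docs/model_schema.md``); SBML Level 3 FBC is
supported for reading through cobrapy's parser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species localized to a compartment (e.g. ``"c"``, ``"e"``)."""

    id: str
    name: str = ""
    compartment: str = "c"

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be nonempty")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional gene rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    means consumed.  ``gene_rule`` is a boolean expression over gene ids
    using ``and``/``or`` and parentheses (case-insensitive); an empty rule
    marks a spontaneous or orphan reaction.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    subsystems: list[str] = field(default_factory=list)

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction has exactly one stoichiometric entry."""
        return len(self.stoichiometry) == 1

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry must be nonempty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    def genes(self) -> frozenset[str]:
        from .fba import gene_rule_genes

        return gene_rule_genes(self.gene_rule)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_rule=self.gene_rule,
            subsystems=list(self.subsystems),
        )


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic network with a biomass objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return frozenset(out)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def get_reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def get_metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def add_reaction(self, reaction: Reaction,
                     metabolites: Mapping[str, Metabolite] | None = None) -> None:
        """Add a reaction, creating any missing metabolites.

        Unknown metabolite ids are looked up in ``metabolites`` when given;
        otherwise a bare metabolite is created with the compartment guessed
        from a trailing ``_<tag>`` in the id.
        """
        if self.has_reaction(reaction.id):
            raise ValidationError(f"duplicate reaction id {reaction.id!r}")
        for mid in reaction.stoichiometry:
            if mid not in self._met_index:
                if metabolites and mid in metabolites:
                    met = metabolites[mid]
                    met = Metabolite(met.id, met.name, met.compartment)
                else:
                    tag = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                    met = Metabolite(mid, compartment=tag)
                self.metabolites.append(met)
                self._met_index[mid] = met
        self.reactions.append(reaction)
        self._rxn_index[reaction.id] = reaction

    def copy(self, new_id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            metabolites=[Metabolite(m.id, m.name, m.compartment) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def validate(self) -> None:
        dups = _duplicates(m.id for m in self.metabolites)
        if dups:
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        dups = _duplicates(r.id for r in self.reactions)
        if dups:
            raise ValidationError(f"duplicate reaction ids: {dups}")
        for m in self.metabolites:
            m.validate()
        for r in self.reactions:
            r.validate()
            missing = [mid for mid in r.stoichiometry if mid not in self._met_index]
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {missing}"
                )
        if self.biomass_reaction_id not in self._rxn_index:
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )


@dataclass
class UniversalReactionBag:
    """Candidate reactions for gap filling (gene rules not required).

    Ids must be disjoint from any model the bag is used to gap-fill.
    """

    reactions: list[Reaction]
    metabolites: list[Metabolite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: r for r in self.reactions}
        self._met_index = {m.id: m for m in self.metabolites}

    def get_reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_map(self) -> dict[str, Metabolite]:
        return dict(self._met_index)

    def validate(self, model: MetabolicModel | None = None) -> None:
        dups = _duplicates(r.id for r in self.reactions)
        if dups:
            raise ValidationError(f"duplicate universal reaction ids: {dups}")
        for r in self.reactions:
            r.validate()
            if not (abs(r.lower_bound) < float("inf") and abs(r.upper_bound) < float("inf")):
                raise ValidationError(f"universal reaction {r.id!r}: bounds must be finite")
        if model is not None:
            clash = [r.id for r in self.reactions if model.has_reaction(r.id)]
            if clash:
                raise ValidationError(
                    f"universal reaction ids overlap the model: {clash}"
                )


@dataclass
class Medium:
    """Named growth condition: exchange reaction id → max uptake rate (≥ 0).

    Applying a medium sets each listed exchange reaction's lower bound to
    −limit (negative flux = uptake) and zeroes uptake for unlisted
    exchanges; upper bounds (secretion) are untouched.
    """

    name: str
    uptake_limits: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        bad = {k: v for k, v in self.uptake_limits.items() if v < 0}
        if bad:
            raise ValidationError(f"medium {self.name!r}: negative uptake limits {bad}")


SubsystemAnnotation = dict[str, list[str]]


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystems": r.subsystems,
            }
            for r in model.reactions
        ],
    }


def _reaction_from_dict(d: dict) -> Reaction:
    return Reaction(
        id=d["id"],
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        lower_bound=float(d.get("lower_bound", -DEFAULT_BOUND)),
        upper_bound=float(d.get("upper_bound", DEFAULT_BOUND)),
        gene_rule=d.get("gene_rule", ""),
        subsystems=list(d.get("subsystems", [])),
    )


def _model_from_dict(d: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=d["id"],
        metabolites=[
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d["metabolites"]
        ],
        reactions=[_reaction_from_dict(r) for r in d["reactions"]],
        biomass_reaction_id=d["biomass_reaction_id"],
    )
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the canonical JSON dialect (sorted keys, indent 1)."""
    Path(path).write_text(
        json.dumps(_model_to_dict(model), sort_keys=True, indent=1) + "\n"
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (canonical dialect) or SBML Level 3 FBC.

    The format is inferred from the suffix when not given (``.json`` vs
    ``.xml``/``.sbml``).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(
                f"{path}: JSON parse failure at line {exc.lineno}: {exc.msg}"
            ) from exc
        return _model_from_dict(d)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    biomass = None
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            biomass = rxn.id
            break
    if biomass is None:
        for rxn in cm.reactions:
            if "biomass" in rxn.id.lower():
                biomass = rxn.id
                break
    if biomass is None:
        raise ValidationError(f"{path}: no objective/biomass reaction found in SBML")
    model = MetabolicModel(
        id=cm.id or path.stem,
        metabolites=[
            Metabolite(m.id, m.name or "", m.compartment or "c") for m in cm.metabolites
        ],
        reactions=[
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_rule=r.gene_reaction_rule or "",
                subsystems=[r.subsystem] if r.subsystem else [],
            )
            for r in cm.reactions
        ],
        biomass_reaction_id=biomass,
    )
    model.validate()
    return model


def write_universal(bag: UniversalReactionBag, path: str | Path) -> None:
    d = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in bag.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystems": r.subsystems,
            }
            for r in bag.reactions
        ],
    }
    Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n")


def read_universal(path: str | Path) -> UniversalReactionBag:
    d = json.loads(Path(path).read_text())
    bag = UniversalReactionBag(
        reactions=[_reaction_from_dict(r) for r in d["reactions"]],
        metabolites=[
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d.get("metabolites", [])
        ],
    )
    bag.validate()
    return bag


# ---------------------------------------------------------------------------
# Media and annotation tables
# ---------------------------------------------------------------------------

def read_media(path: str | Path) -> list[Medium]:
    """Read a media TSV: rows = exchange reaction ids, columns = conditions.

    Missing cells are zero uptake; zero-uptake entries are omitted from the
    returned maps.  Column order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    media: list[Medium] = []
    for cond in df.columns:
        col = df[cond].fillna(0.0)
        if (col < 0).any():
            bad = col[col < 0]
            raise ValidationError(
                f"medium {cond!r}: negative uptake values for {list(bad.index)}"
            )
        limits = {rid: float(v) for rid, v in col.items() if v > 0}
        media.append(Medium(str(cond), limits))
    return media


def write_media(media: list[Medium], path: str | Path) -> None:
    all_rids = sorted({rid for m in media for rid in m.uptake_limits})
    df = pd.DataFrame(
        {m.name: [m.uptake_limits.get(rid, 0.0) for rid in all_rids] for m in media},
        index=pd.Index(all_rids, name="exchange"),
    )
    df.to_csv(path, sep="\t")


def complete_medium(model: MetabolicModel, limit: float = 1000.0) -> Medium:
    """Rich ("complete") medium: every exchange open at ``limit`` uptake."""
    return Medium(
        "complete", {r.id: float(limit) for r in model.exchange_reactions}
    )


def read_subsystem_annotation(path: str | Path) -> SubsystemAnnotation:
    """Read a two-column TSV (reaction_id, subsystem); repeats accumulate."""
    df = pd.read_csv(path, sep="\t")
    ann: SubsystemAnnotation = {}
    for rid, sub in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ann.setdefault(str(rid), []).append(str(sub))
    return ann


def write_subsystem_annotation(ann: SubsystemAnnotation, path: str | Path) -> None:
    rows = [(rid, s) for rid in sorted(ann) for s in ann[rid]]
    pd.DataFrame(rows, columns=["reaction_id", "subsystem"]).to_csv(
        path, sep="\t", index=False
    )
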