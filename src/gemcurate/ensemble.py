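"""Ensembles of gap-filled models and ensemble-wide simulations.

An ensemble is a base model plus a boolean member × variable-reaction
feature matrix; a variable reaction is one present in some members and
absent from others.  Gap-filled reactions shared by every member are
absorbed into the base model so the matrix holds only genuine variation.
Ensemble simulations (gene-essentiality screens, growth rates) run on
materialized members; subsampling curves quantify how ensemble size
saturates the space of variable features and non-consensus predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fba import DEFAULT_ESSENTIALITY_THRESHOLD, LinearSystem, single_gene_knockouts
from .model import (
    Medium,
    MetabolicModel,
    UniversalReactionBag,
    complete_medium,
    read_model,
    read_universal,
    write_model,
    write_universal,
)

if TYPE_CHECKING:
    from .gapfill import MemberRecipe


@dataclass
class Ensemble:
    """Base model + member × variable-reaction presence matrix."""

    base_model: MetabolicModel
    universal: UniversalReactionBag
    feature_matrix: np.ndarray  # bool, members × variable reactions
    variable_reactions: list[str]
    member_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=bool)
        if self.feature_matrix.shape != (len(self.member_ids), len(self.variable_reactions)):
            raise ValidationError("feature matrix shape does not match labels")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def validate(self) -> None:
        self.base_model.validate()
        if self.variable_reactions:
            present = self.feature_matrix.any(axis=0)
            absent = (~self.feature_matrix).any(axis=0)
            bad = [
                rid
                for rid, p, a in zip(self.variable_reactions, present, absent)
                if not (p and a)
            ]
            if bad:
                raise ValidationError(
                    f"reactions not variable across members: {bad}"
                )
        rows = {tuple(row) for row in self.feature_matrix}
        if len(rows) != self.n_members:
            raise ValidationError("duplicate member rows in feature matrix")

    def member_index(self, member_id: str) -> int:
        try:
            return self.member_ids.index(member_id)
        except ValueError:
            raise KeyError(f"unknown member id {member_id!r}") from None

    # -- serialization ----------------------------------------------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_model(self.base_model, directory / "base_model.json")
        write_universal(self.universal, directory / "universal.json")
        pd.DataFrame(
            self.feature_matrix.astype(int),
            index=pd.Index(self.member_ids, name="member"),
            columns=self.variable_reactions,
        ).to_csv(directory / "features.tsv", sep="\t")
        (directory / "metadata.json").write_text(
            json.dumps(self.metadata, indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        df = pd.read_csv(directory / "features.tsv", sep="\t", index_col=0)
        meta_path = directory / "metadata.json"
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            base_model=read_model(directory / "base_model.json"),
            universal=read_universal(directory / "universal.json"),
            feature_matrix=df.to_numpy(dtype=bool),
            variable_reactions=[str(c) for c in df.columns],
            member_ids=[str(i) for i in df.index],
            metadata=metadata,
        )


def build_ensemble(
    model: MetabolicModel,
    universal: UniversalReactionBag,
    recipes: "list[MemberRecipe]",
    metadata: dict | None = None,
) -> Ensemble:
    """Assemble an ensemble from unique member recipes.

    Reactions present in every recipe (consensus gap fills) are added to
    the base model; the feature matrix covers only variable reactions.
    """
    sets = [r.gapfilled_reactions for r in recipes]
    union = frozenset().union(*sets) if sets else frozenset()
    consensus = frozenset.intersection(*sets) if sets else frozenset()
    variable = sorted(union - consensus)
    base = model.copy()
    mets = universal.metabolite_map()
    for rid in sorted(consensus):
        base.add_reaction(universal.get_reaction(rid).copy(), mets)
    matrix = np.array(
        [[rid in s for rid in variable] for s in sets], dtype=bool
    ).reshape(len(sets), len(variable))
    meta = dict(metadata or {})
    meta["consensus_reactions"] = sorted(consensus)
    ens = Ensemble(
        base_model=base,
        universal=universal,
        feature_matrix=matrix,
        variable_reactions=variable,
        member_ids=[f"m{i:04d}" for i in range(len(sets))],
        metadata=meta,
    )
    ens.validate()
    return ens


def materialize_member(ensemble: Ensemble, member_id: str) -> MetabolicModel:
    """The base model plus the member's present variable reactions."""
    i = ensemble.member_index(member_id)
    model = ensemble.base_model.copy(new_id=f"{ensemble.base_model.id}__{member_id}")
    mets = ensemble.universal.metabolite_map()
    for rid, present in zip(ensemble.variable_reactions, ensemble.feature_matrix[i]):
        if present:
            model.add_reaction(ensemble.universal.get_reaction(rid).copy(), mets)
    return model


@dataclass
class EssentialityMatrix:
    """Boolean member × gene knockout outcomes at a biomass threshold."""

    values: np.ndarray  # bool, members × genes
    genes: list[str]
    member_ids: list[str]
    threshold: float
    medium_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.member_ids), len(self.genes)):
            raise ValidationError("essentiality matrix shape does not match labels")

    def non_consensus_genes(self) -> list[str]:
        """Genes whose call differs between at least two members."""
        varied = self.values.any(axis=0) & (~self.values).any(axis=0)
        return [g for g, v in zip(self.genes, varied) if v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=pd.Index(self.member_ids, name="member"),
            columns=self.genes,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD,
                 medium_name: str = "complete") -> "EssentialityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=bool),
            genes=[str(c) for c in df.columns],
            member_ids=[str(i) for i in df.index],
            threshold=threshold,
            medium_name=medium_name,
        )


def ensemble_essentiality(
    ensemble: Ensemble,
    medium: Medium | None = None,
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD,
) -> EssentialityMatrix:
    """Single-gene knockout screen on every member.

    Default medium is the complete (rich) medium of the base model.  The
    gene universe is the union over members; since universal reactions
    carry no gene rules, in practice this equals the base model's gene
    set.  Genes absent from a member's rules are nonessential for it.
    """
    genes = sorted(
        set(ensemble.base_model.genes).union(
            *(r.genes() for r in ensemble.universal.reactions)
        )
    )
    rows = []
    for member_id in ensemble.member_ids:
        model = materialize_member(ensemble, member_id)
        med = medium if medium is not None else complete_medium(model)
        calls = single_gene_knockouts(model, med, threshold=threshold, genes=genes)
        rows.append([c.essential for c in calls])
    return EssentialityMatrix(
        values=np.array(rows, dtype=bool).reshape(len(rows), len(genes)),
        genes=genes,
        member_ids=list(ensemble.member_ids),
        threshold=threshold,
        medium_name=medium.name if medium is not None else "complete",
    )


def ensemble_growth_rates(
    ensemble: Ensemble, medium: Medium | None = None
) -> pd.Series:
    """Plain FBA biomass maximum per member (for growth-rate statistics)."""
    rates = {}
    for member_id in ensemble.member_ids:
        model = materialize_member(ensemble, member_id)
        med = medium if medium is not None else complete_medium(model)
        sys = LinearSystem(model)
        lb, ub = sys.medium_bounds(med)
        sol = sys.solve({model.biomass_reaction_id: 1.0}, "max", lb, ub)
        rates[member_id] = sol.objective_value if sol.status == "optimal" else 0.0
    return pd.Series(rates, name="growth_rate")


VALID_STATISTICS = ("variable_reactions", "non_consensus_genes", "growth_rate_variance")


@dataclass
class SubsampleCurve:
    """Saturation statistic vs subsample size (draws with replacement)."""

    sizes: list[int]
    means: list[float]
    stds: list[float]
    statistic: str
    draws: int = 1000

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mean": self.means, "std": self.stds,
             "statistic": self.statistic}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _count_variable_columns(matrix: np.ndarray, idx: np.ndarray) -> int:
    sub = matrix[idx]
    return int((sub.any(axis=0) & (~sub).any(axis=0)).sum())


def subsample_curve(
    data: np.ndarray | EssentialityMatrix | "Ensemble" | pd.Series,
    statistic: str,
    step: int = 20,
    draws: int = 1000,
    seed: int = 0,
) -> SubsampleCurve:
    """Bootstrap saturation curve over subsample sizes step, 2·step, ….

    ``statistic``: ``variable_reactions`` counts feature-matrix columns
    that vary within the draw; ``non_consensus_genes`` does the same on an
    essentiality matrix; ``growth_rate_variance`` is the variance of a
    per-member growth-rate vector within the draw.  At each size, ``draws``
    random member draws with replacement are made and the statistic's mean
    and standard deviation over draws reported.
    """
    if statistic not in VALID_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; expected one of {VALID_STATISTICS}"
        )
    if statistic == "growth_rate_variance":
        values = np.asarray(
            data.to_numpy() if isinstance(data, pd.Series) else data, dtype=float
        )
        n = values.shape[0]
    else:
        if isinstance(data, Ensemble):
            matrix = data.feature_matrix
        elif isinstance(data, EssentialityMatrix):
            matrix = data.values
        else:
            matrix = np.asarray(data, dtype=bool)
        n = matrix.shape[0]
    if n < step:
        raise ValueError(f"need at least step={step} members, got {n}")
    sizes = list(range(step, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    rng = np.random.default_rng(seed)
    means, stds = [], []
    for size in sizes:
        idx = rng.integers(0, n, size=(draws, size))
        if statistic == "growth_rate_variance":
            stats = values[idx].var(axis=1)
        else:
            drawn = matrix[idx]  # draws × size × features
            stats = (drawn.any(axis=1) & (~drawn).any(axis=1)).sum(axis=1)
        means.append(float(np.mean(stats)))
        stds.append(float(np.std(stats)))
    return SubsampleCurve(sizes, means, stds, statistic, draws)
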