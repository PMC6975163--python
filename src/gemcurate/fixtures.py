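"""Synthetic toy universes with known gap-fill and essentiality ground truth.

Every pipeline stage is testable offline against these generators.  The
networks are linear-pathway scaffolds with branch decoys — no
thermodynamic or biomass realism is attempted; the unit under test is the
algorithmics.

Two generators:

* :func:`make_toy_universe` — a gapped draft, a universal bag, media, and
  exhaustively verified minimal gap-fill solutions per medium.  Each
  carbon source Cᵢ has its own medium; the draft lacks the Cᵢ_c → P_c
  conversion, which sits in the universal bag alongside a cheaper
  cross-feeding converter (Cᵢ_c → 2·C1_c) that only pays off once the
  pathway-1 conversion is penalty-free — so media order genuinely changes
  the selected reaction set and ensembles are non-degenerate.

* :func:`make_split_ensemble` — a synthetic ensemble with one engineered
  phenotype-splitting bypass reaction plus independent coin-flip decoy
  reactions.  Member composition is sampled directly (a deterministic LP
  cannot sample alternate optima), but the essentiality flip the splitter
  causes is real network behavior, computed by FBA knockouts downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import Ensemble
from .errors import ValidationError
from .fba import DEFAULT_ESSENTIALITY_THRESHOLD, single_gene_knockouts
from .model import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    UniversalReactionBag,
    complete_medium,
)

UPTAKE_LIMIT = 10.0


@dataclass
class FixtureSpec:
    """Parameters of a generated toy universe."""

    n_pathways: int = 2
    n_decoy_reactions: int = 2
    n_media: int = 2
    n_split_reactions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.n_decoy_reactions, self.n_split_reactions) < 0:
            raise ValidationError("fixture counts must be ≥ 0")
        if self.n_media < 1:
            raise ValidationError("n_media must be ≥ 1")
        if self.n_media > self.n_pathways:
            raise ValidationError("each medium needs its own pathway carbon source")


def _exchange(mid: str, rid: str) -> Reaction:
    return Reaction(rid, {mid: -1.0}, lower_bound=0.0, upper_bound=1000.0)


def make_toy_universe(
    spec: FixtureSpec,
) -> tuple[MetabolicModel, UniversalReactionBag, list[Medium], dict]:
    """Build a gapped draft model, universal bag, media, and ground truth.

    Topology: every carbon route converges on a precursor ``P_pre_c``
    that the gene-gated draft step ``D_P`` (gene ``gP``) converts to the
    biomass substrate ``P_c``.  The conversion Cᵢ_c → P_pre_c is missing
    from the draft (the gap); the universal bag holds it (``U_Rᵢ``) plus,
    for i ≥ 2, a 2:1 cross-feeding converter into C1 that only pays off
    once ``U_R1`` is penalty-free — so media order changes the selection.

    Each split reaction adds a carbon whose universal bypass
    ``U_SPLITk`` lands directly on ``P_c``, skipping ``D_P``: members
    that gap-filled the bypass call ``gP`` nonessential in rich medium,
    members that took the converter route call it essential — the
    engineered essentiality bimodality.

    The draft cannot reach the biomass floor in any medium until the
    known universal reactions are added.  Ground truth records, per
    medium, the minimal-flux-sum gap-fill solutions, verified by
    exhaustive subset enumeration when the universe has ≤ 8 reactions.
    """
    mets = [Metabolite("P_pre_c", "precursor (pre)", "c"),
            Metabolite("P_c", "biomass precursor", "c"),
            Metabolite("biomass_e", "biomass", "e")]
    reactions = [
        Reaction("D_P", {"P_pre_c": -1.0, "P_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, gene_rule="gP"),
        Reaction("BIOMASS", {"P_c": -1.0, "biomass_e": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        _exchange("biomass_e", "EX_biomass"),
    ]
    universal_rxns: list[Reaction] = []
    universal_mets: list[Metabolite] = []
    media: list[Medium] = []
    n_carbons = spec.n_pathways + spec.n_split_reactions

    def add_carbon(i: int) -> None:
        mets.extend([Metabolite(f"C{i}_e", f"carbon {i}", "e"),
                     Metabolite(f"C{i}_c", f"carbon {i}", "c")])
        reactions.extend([
            _exchange(f"C{i}_e", f"EX_C{i}"),
            Reaction(f"T_C{i}", {f"C{i}_e": -1.0, f"C{i}_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gene_rule=f"gT{i}"),
        ])

    for i in range(1, spec.n_pathways + 1):
        add_carbon(i)
        # the gap: the conversion to precursor lives in the universal bag
        universal_rxns.append(
            Reaction(f"U_R{i}", {f"C{i}_c": -1.0, "P_pre_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0)
        )
        if i > 1:
            # cross-feeding converter with 2:1 gain: cheaper than U_Ri once
            # U_R1 is penalty-free, dearer otherwise → order-dependent picks
            universal_rxns.append(
                Reaction(f"U_CONV{i}", {f"C{i}_c": -1.0, "C1_c": 2.0},
                         lower_bound=0.0, upper_bound=1000.0)
            )
    for k in range(1, spec.n_split_reactions + 1):
        j = spec.n_pathways + k
        add_carbon(j)
        # bypass straight to P_c: skips the gene-gated D_P step
        universal_rxns.append(
            Reaction(f"U_SPLIT{k}", {f"C{j}_c": -1.0, "P_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0)
        )
        universal_rxns.append(
            Reaction(f"U_SCONV{k}", {f"C{j}_c": -1.0, "C1_c": 2.0},
                     lower_bound=0.0, upper_bound=1000.0)
        )
    for i in range(1, spec.n_media + 1):
        media.append(Medium(f"carbon_{i}", {f"EX_C{i}": UPTAKE_LIMIT}))
    for k in range(1, spec.n_split_reactions + 1):
        media.append(
            Medium(f"split_{k}", {f"EX_C{spec.n_pathways + k}": UPTAKE_LIMIT})
        )
    for k in range(1, spec.n_decoy_reactions + 1):
        universal_mets += [Metabolite(f"Z{k}a_c", compartment="c"),
                           Metabolite(f"Z{k}b_c", compartment="c")]
        universal_rxns.append(
            Reaction(f"U_DECOY{k}", {f"Z{k}a_c": -1.0, f"Z{k}b_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0)
        )
    draft = MetabolicModel("toy_draft", mets, reactions, "BIOMASS")
    draft.validate()
    universal = UniversalReactionBag(universal_rxns, universal_mets)
    universal.validate(draft)
    ground_truth = _ground_truth(draft, universal, media, spec)
    return draft, universal, media, ground_truth


def _ground_truth(draft, universal, media, spec) -> dict:
    from .gapfill import enumerate_minimal_gapfills

    per_medium: dict[str, list[frozenset[str]]] = {}
    if len(universal.reactions) <= 8:
        for medium in media:
            try:
                _, minimal = enumerate_minimal_gapfills(draft, universal, medium)
            except Exception as exc:  # pragma: no cover - degenerate spec
                raise ValidationError(
                    f"fixture admits no gap-fill solution for {medium.name!r}: {exc}"
                ) from exc
            per_medium[medium.name] = minimal
    else:
        # enumeration is exponential; record the designed solutions instead
        for medium in media:
            if medium.name.startswith("split_"):
                k = int(medium.name.split("_")[1])
                per_medium[medium.name] = [frozenset({f"U_SPLIT{k}"})]
            else:
                i = int(medium.name.split("_")[1])
                per_medium[medium.name] = [frozenset({f"U_R{i}"})]
    expected_recipes = _expected_recipes(spec)
    return {
        "per_medium": per_medium,
        "expected_recipes": expected_recipes,
        "uptake_limit": UPTAKE_LIMIT,
        "splitters": [f"U_SPLIT{k}" for k in range(1, spec.n_split_reactions + 1)],
        "flip_gene": "gP" if spec.n_split_reactions else None,
    }


def _expected_recipes(spec: FixtureSpec) -> list[frozenset[str]] | None:
    """Designed set of reachable member recipes for the 2-media fixture.

    Order (carbon_1, carbon_2) picks U_R1 then the cheap converter;
    order (carbon_2, carbon_1) picks U_R2 then U_R1.
    """
    if spec.n_media != 2 or spec.n_split_reactions != 0:
        return None
    return [frozenset({"U_R1", "U_CONV2"}), frozenset({"U_R2", "U_R1"})]


# ---------------------------------------------------------------------------
# Split ensemble (phenotype-splitting fixture)
# ---------------------------------------------------------------------------

def make_split_ensemble(
    n_members: int = 200,
    n_decoys: int = 20,
    seed: int = 0,
    splitter_presence: float = 0.5,
) -> tuple[Ensemble, dict]:
    """Synthetic ensemble with one engineered phenotype-splitting reaction.

    Base network: carbon A reaches the biomass precursor only through the
    gene-gated chain T_A (gene gA) → D_A (gene gD); carbon B is imported
    (T_B, gene gB) but is a dead end in the base model.  The splitter
    ``U_BYPASS`` (B_c → P_c) rescues knockouts of gA and gD, so members
    carrying it call both genes nonessential while members lacking it call
    them essential — a deterministic essentiality flip.  Decoy variable
    reactions operate on disconnected metabolites (never carry flux) and
    are assigned to members as independent fair coin flips.

    The member composition matrix is sampled directly rather than via
    gap-filling (synthetic stand-in for the post-gap-fill state); rows are
    deduplicated to satisfy ensemble invariants.  Returns the ensemble and
    a ground-truth dict (splitter id, flipped genes, splitter presence per
    member).
    """
    if not 0 < splitter_presence < 1:
        raise ValidationError("splitter_presence must be in (0, 1)")
    mets = [
        Metabolite("A_e", compartment="e"), Metabolite("A_c", compartment="c"),
        Metabolite("B_e", compartment="e"), Metabolite("B_c", compartment="c"),
        Metabolite("P_c", compartment="c"), Metabolite("biomass_e", compartment="e"),
    ]
    reactions = [
        _exchange("A_e", "EX_A"),
        _exchange("B_e", "EX_B"),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, gene_rule="gA"),
        Reaction("T_B", {"B_e": -1.0, "B_c": 1.0}, 0.0, 1000.0, gene_rule="gB"),
        Reaction("D_A", {"A_c": -1.0, "P_c": 1.0}, 0.0, 1000.0, gene_rule="gD"),
        Reaction("BIOMASS", {"P_c": -1.0, "biomass_e": 1.0}, 0.0, 1000.0),
        _exchange("biomass_e", "EX_biomass"),
    ]
    base = MetabolicModel("split_base", mets, reactions, "BIOMASS")
    base.validate()
    universal_mets: list[Metabolite] = []
    universal_rxns = [
        Reaction("U_BYPASS", {"B_c": -1.0, "P_c": 1.0}, 0.0, 1000.0),
    ]
    for k in range(1, n_decoys + 1):
        universal_mets += [Metabolite(f"D{k}a_c", compartment="c"),
                           Metabolite(f"D{k}b_c", compartment="c")]
        universal_rxns.append(
            Reaction(f"U_DECOY{k}", {f"D{k}a_c": -1.0, f"D{k}b_c": 1.0}, 0.0, 1000.0)
        )
    universal = UniversalReactionBag(universal_rxns, universal_mets)
    universal.validate(base)

    rng = np.random.default_rng(seed)
    n_features = 1 + n_decoys
    rows: list[tuple[bool, ...]] = []
    seen: set[tuple[bool, ...]] = set()
    attempts = 0
    while len(rows) < n_members:
        attempts += 1
        if attempts > 100 * n_members:
            raise ValidationError(
                "could not sample enough unique members; increase n_decoys"
            )
        row = tuple(
            np.concatenate([
                rng.random(1) < splitter_presence,
                rng.random(n_decoys) < 0.5,
            ]).tolist()
        )
        if row not in seen:
            seen.add(row)
            rows.append(row)
    matrix = np.array(rows, dtype=bool)
    # guarantee both splitter states occur
    if matrix[:, 0].all() or not matrix[:, 0].any():
        matrix[0, 0] = not matrix[0, 0]
    variable = ["U_BYPASS"] + [f"U_DECOY{k}" for k in range(1, n_decoys + 1)]
    ensemble = Ensemble(
        base_model=base,
        universal=universal,
        feature_matrix=matrix,
        variable_reactions=variable,
        member_ids=[f"m{i:04d}" for i in range(n_members)],
        metadata={
            "generator": "make_split_ensemble",
            "synthetic_member_composition": True,
            "seed": seed,
            "n_decoys": n_decoys,
        },
    )
    ensemble.validate()
    ground_truth = {
        "splitter": "U_BYPASS",
        "flipped_genes": ["gA", "gD"],
        "constant_genes": ["gB"],
        "splitter_present": matrix[:, 0].copy(),
    }
    return ensemble, ground_truth


def make_synthetic_essentiality(
    model: MetabolicModel,
    flip_fraction: float,
    seed: int = 0,
    medium: Medium | None = None,
    threshold: float = DEFAULT_ESSENTIALITY_THRESHOLD,
) -> dict[str, bool]:
    """Simulated-truth experimental essentiality table with assay noise.

    Runs a single-gene knockout screen on ``model`` (complete medium by
    default) and flips each call independently with probability
    ``flip_fraction``, emulating the technical noise of real screens.
    """
    if not 0 <= flip_fraction <= 1:
        raise ValidationError("flip_fraction must be within [0, 1]")
    med = medium if medium is not None else complete_medium(model)
    calls = single_gene_knockouts(model, med, threshold=threshold)
    rng = np.random.default_rng(seed)
    flips = rng.random(len(calls)) < flip_fraction
    return {
        c.gene: (not c.essential) if flip else c.essential
        for c, flip in zip(calls, flips)
    }


def write_experimental_essentiality(table: dict[str, bool], path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted((g, int(v)) for g, v in table.items()),
        columns=["gene", "essential"],
    ).to_csv(path, sep="\t", index=False)


def read_experimental_essentiality(path) -> dict[str, bool]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(g): bool(int(v)) for g, v in zip(df["gene"], df["essential"])}
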