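# File formats

## Model JSON (canonical dialect)

A model file is a single JSON object; `write_model` emits it with sorted
keys and indent 1, so read → write is a byte-level fixed point.

```json
{
 "id": "example",
 "biomass_reaction_id": "BIOMASS",
 "metabolites": [
  {"id": "A_e", "name": "A", "compartment": "e"},
  {"id": "A_c", "name": "A", "compartment": "c"}
 ],
 "reactions": [
  {
   "id": "EX_A",
   "stoichiometry": {"A_e": -1.0},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_rule": "",
   "subsystems": []
  },
  {
   "id": "T_A",
   "stoichiometry": {"A_e": -1.0, "A_c": 1.0},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_rule": "g1 or (g2 and g3)",
   "subsystems": ["transport"]
  }
 ]
}
```

Constraints enforced on read:

- metabolite and reaction ids nonempty and unique;
- every metabolite id referenced by a reaction is declared;
- `lower_bound ≤ upper_bound`; stoichiometry nonempty (negative = consumed);
- `biomass_reaction_id` names an existing reaction;
- `gene_rule` grammar: identifiers, `and`, `or`, parentheses
  (keywords case-insensitive); an empty rule marks a spontaneous/orphan
  reaction;
- a reaction is an *exchange* iff it has exactly one stoichiometric entry.

Flux units are mmol·gDW⁻¹·hr⁻¹ throughout. Exchange reactions are written
`A_e ⇌ ∅` with negative flux = uptake.

A universal reaction bag uses the same dialect without
`biomass_reaction_id` (top-level keys `metabolites`, `reactions`); bag
bounds must be finite (default ±1000) and bag reaction ids must be disjoint
from any model the bag gap-fills.

SBML Level 3 FBC files are read through cobrapy's parser (`read_model(path,
format="sbml")`, or by suffix); SBML writing is not supported — the JSON
dialect is canonical.

## Media TSV

One row per exchange reaction, one column per condition; the first column
holds exchange reaction ids. Cell = maximum uptake rate (≥ 0); empty cells
mean zero uptake. Condition (column) order is preserved.

```
exchange	glcA	glcB
EX_A	10	
EX_B		5
```

Medium application sets each listed exchange's lower bound to −limit and
zeroes uptake for unlisted exchanges; upper (secretion) bounds are
untouched. Data-specific supplements (e.g. adding a cofactor such as heme
to every condition) are expressed by adding the corresponding exchange row
to the media table — this is configuration, not package logic.

## Subsystem annotation TSV

Two columns, `reaction_id` and `subsystem`; repeat a reaction id on several
rows to assign multiple subsystems (each contributes an independent
observation in subsystem statistics).

## Experimental essentiality TSV

Two columns, `gene` and `essential` (0/1).

## Ensemble directory

`base_model.json` (model JSON, with consensus gap-filled reactions already
added), `universal.json` (the bag, for materializing members),
`features.tsv` (member × variable-reaction 0/1 matrix, first column
`member`), `metadata.json` (seed, parameters, media orders, consensus
reaction list).
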