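# mpdiag

Molecular process diagrams for rule-based models.

`mpdiag` parses rule-based models written in a BNGL dialect, analyses each
reaction rule at site level, and renders the model as a **molecular process
diagram (MPD)**: a bipartite graph whose nodes are *molecular complexes*
(grouping all patterns with the same molecular composition, regardless of
states or bonding) and *processes* (one per reaction rule). Diagrams are
available at three resolution levels:

1. **Level 1** — complexes, processes, consumption/production arcs with
   stoichiometry.
2. **Level 2** — plus labels for every site *modified* by a rule
   (state changes such as `U→P@Y1`, bond changes such as `bond@site–ecd`).
3. **Level 3** — plus *context* labels for sites that are required in a
   specific state but left unchanged (e.g. `unbound@tmd`).

Diagrams export to GraphML (round-trippable), SBGN-ML 0.2 process
description (with all MPD-specific content in strippable `extension`
elements and annotation glyphs, so removing them yields a plain SBGN-PD
map), and Graphviz DOT.

## Layout

| module               | purpose                                                              |
| -------------------- | -------------------------------------------------------------------- |
| `mpdiag.bngl`        | model types, BNGL parser/writer, canonical pattern labels            |
| `mpdiag.semantics`   | reactant/product molecule correspondence, per-site classification    |
| `mpdiag.builder`     | MPD construction (`build_mpd`, `composition_key`, `mpd_stats`)       |
| `mpdiag.matching`    | brute-force pattern matching, rule expansion, state enumeration      |
| `mpdiag.export`      | deterministic layout, GraphML / SBGN-ML / DOT writers                |
| `mpdiag.fixtures`    | built-in EGFR example (`egfr_model`), seeded random-model generator  |

## Supported BNGL dialect

Molecule types with `~`-separated states; patterns with bonds `!n`, `!+`,
`!?`; `~?` state wildcards; `0` as an empty reactant/product side;
`@compartment:` prefixes (carried, not topology-checked); `parameters`,
`molecule types`, `seed species`/`species`, `reaction rules`,
`observables`/`functions` (retained opaquely) and `compartments` blocks;
`#` comments and `\` line continuations. `DeleteMolecules`,
`include_reactants`/`exclude_reactants`, fixed species `$` and unknown
blocks raise an "unsupported construct" error naming the construct.

## CLI

```sh
mpd demo -o egfr.bngl                 # write the built-in EGFR example
mpd stats egfr.bngl                   # node/arc counts
mpd stats egfr.bngl --sites           # per-site classification as TSV
mpd build egfr.bngl --level 3 --format sbgnml -o egfr.sbgn
mpd build egfr.bngl --format graphml -o egfr.graphml
mpd expand egfr.bngl --rule R1        # concrete reactions from the seed species
```

Exit codes: `0` success, `2` parse/validation error, `3` unsupported construct.

## Example

```python
from mpdiag import egfr_model, build_mpd, mpd_stats
from mpdiag.export import layout, to_sbgnml

model = egfr_model()
graph = build_mpd(model, level=3)
print(mpd_stats(graph))          # 6 processes, 4 complexes
print(to_sbgnml(graph, layout(graph)))
```
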