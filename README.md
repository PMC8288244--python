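# rgroupnet

Mining R-group replacement knowledge from compound collections.

During hit-to-lead and lead optimization, medicinal chemists grow analogue
series (AS): sets of compounds sharing a core structure and differing only in
the substituents (R-groups) placed at its substitution sites. Which R-group
to try next at a given site is largely experience-driven. `rgroupnet` turns a
plain table of SMILES structures into a data-driven answer:

1. **Compound standardization & filtering** — canonicalize structures (largest
   organic fragment), keep compounds with molecular weight ≤ 1000 Da.
2. **Generalized compound–core fragmentation** — exhaustively cut single
   exocyclic bonds (never ring or multiple bonds) to split each compound into
   a candidate core with indexed substitution sites plus one R-group per
   site. A split is kept only if the core holds at least half of the
   compound's heavy atoms (`2·core ≥ compound`, integer comparison), every
   R-group is peripheral (touches exactly one cut) and no R-group exceeds 13
   heavy atoms. Heavy atoms carrying hydrogen may additionally be marked as
   virtual hydrogen-cut sites, so hydrogen itself participates as an R-group.
3. **Analogue-series extraction** — compounds sharing a canonical core, at
   least three per core (by default each compound belongs to one series).
4. **Replacement network** — for every substitution site with *k* distinct
   R-groups, all C(*k*, 2) unordered pairs are counted as bidirectional
   replacements. Nodes are unique R-groups; the **edge weight** EW(a, b) is
   the number of sites at which a and b interchange; the **node degree** ND
   is the number of distinct replacement partners. Removing the three generic
   groups — hydrogen, methyl, phenyl — and any orphaned nodes yields the
   *final* network.
5. **Replacement hierarchies** — for each top-ranked R-group, the top-5
   first-layer replacements by EW, each with its top-2 onward replacements
   (at most 10 root→first→second sequences), serialized as a searchable XML
   database, with the network exported as a Cytoscape-ready
   `source,target,weight` CSV.

Because public bioactivity databases are not bundled, the package ships a
first-class synthetic-library generator (`rgroupnet.synthetic`) that builds
seeded combinatorial analogue libraries with exact ground truth (series
membership, site tables, edge weights), used throughout the test suite.

## Worked example

One rigid benzofuran scaffold with one substitution site and the pool
{H, F, Cl, Br}:

```python
from rgroupnet import LibrarySpec, ScaffoldSpec, generate_library, run_pipeline, RunConfig

spec = LibrarySpec(
    scaffolds=(ScaffoldSpec("[*:1]c1cc2ccccc2o1", (("H", "*F", "*Cl", "*Br"),)),),
    seed=7,
)
records, truth = generate_library(spec)
result = run_pipeline(records, RunConfig())
print(result.manifest["counters"])
```

prints

```
{'compounds_in': 4, 'compounds_kept': 4, 'decompositions': 78, 'series': 1,
 'substitution_sites': 1, 'unique_rgroups': 4, 'global_nodes': 4,
 'global_edges': 6, 'final_nodes': 3, 'final_edges': 3, 'hierarchies': 3}
```

All four compounds (including the unsubstituted parent, which carries the
hydrogen R-group) form one series on one site; the four R-groups at that site
yield exactly C(4, 2) = 6 pairwise replacements, each observed at one site
(weight 1). Removing hydrogen for the final network leaves the halogen
triangle. The same chain is available from the shell:

```bash
rgroupnet simulate spec.yaml -o sim/
rgroupnet run sim/compounds.csv --mw-column mol_weight -o out/
rgroupnet search out/database.xml "F[*]"
```

The search prints the `*F` hierarchy as an indented tree with EW values.

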