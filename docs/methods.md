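# Methods

## The model

`rgroupnet` treats substituent choice as a frequency problem over observed
analogue series. An analogue series is a set of at least three compounds
sharing a common core and differing only at the core's indexed substitution
sites. Within one series, two distinct R-groups observed at the same site
constitute one unordered, bidirectional replacement: the site provides the
chemical context in which the two groups are known to interchange. Pooling
these site-specific replacements over all series yields a weighted,
undirected network on unique R-groups. The edge weight EW(a, b) counts the
number of substitution sites (not member pairs) at which a and b co-occur:
a site with many members but only two distinct R-groups contributes exactly
one to that edge, so the weight measures breadth of context, not library
size. A node's degree ND counts its distinct replacement partners and ranks
R-groups by breadth of use. Potency changes associated with individual
replacements are deliberately out of scope: the counts aggregate across all
series and targets.

## Fragmentation

Cores and R-groups are produced by cutting single exocyclic bonds — every
acyclic single bond between two heavy atoms is a legal cut, with no
retrosynthetic rule restriction. The enumeration is exhaustive over cut
subsets up to `max_sites` rather than randomized: exhaustion is a
deterministic superset of any random sample of cuts and is affordable at
desk scale. A per-compound budget (default 500,000 evaluated combinations)
skips hyper-flexible molecules with a warning rather than stalling the run.

A candidate split is accepted when:

- exactly one fragment, the core, is incident to every cut and each other
  fragment (an R-group) is incident to exactly one. For a single cut both
  orientations are evaluated, since either side may serve as the core;
- the core contains at least half of the compound's heavy atoms, compared
  in integers (`2·core_heavy ≥ compound_heavy`) so the boundary is exact
  and inclusive;
- no R-group exceeds `rgroup_max_heavy` (default 13) heavy atoms.

Hydrogen is a first-class R-group. Any core heavy atom bearing a hydrogen
may be marked as a virtual hydrogen-cut site, which adds an attachment
point carrying the fixed hydrogen fragment `*[H]` (zero heavy atoms). At
least one real (heavy) cut is required per decomposition, so cores are
never enumerated from a molecule's hydrogens alone. The one case this
excludes — the fully unsubstituted parent, which is identical to the
hydrogen-saturated core — is handled at the series level: while grouping,
each candidate core is saturated with hydrogens and looked up in the
compound table, and an exact match joins the group with the all-hydrogen
assignment. This keeps hydrogen "present at each site prior to
replacement" without exploding the per-compound enumeration.

### Canonical cores and symmetric sites

A core's identity is its canonical SMILES with attachment points numbered
`[1*]..[k*]` along the canonical atom ranks of the label-free core, so the
same chemical core reached from different compounds produces the identical
string. On symmetric cores (e.g. para-disubstituted benzene) several site
assignments describe the same decomposition; assignments are collapsed to
one orbit representative using the site permutations induced by graph
automorphisms of the core (computed with a VF2 search over the molecular
graph, node-matched on element, charge, aromaticity and hydrogen count,
edge-matched on bond order; the enumeration is capped at 5000
isomorphisms, and because permutations are always derived from the
canonical core string the collapse is consistent across compounds). The
lexicographically smallest per-site R-group tuple is the representative.

## Series assembly

Decompositions are grouped by canonical core; a compound with several
assignments on one core keeps the canonically smallest. Two membership
modes exist. `overlapping` keeps every core with enough candidates.
`unique` (default) assigns each compound to at most one series by a greedy
pass: cores ordered by candidate count descending, core heavy atoms
descending, site count ascending, core string ascending; each core claims
its unclaimed candidates and survives only if at least `min_members`
(default 3, inclusive) remain. The site-count tie-break is a parsimony
rule of this package: cores that differ only by additional always-hydrogen
sites tie on both candidate count and heavy atoms, and preferring the
fewest sites makes the selected core the most parsimonious description of
the same compound set (and the selection independent of SMILES string
accidents).

## Network, refinement and hierarchies

The global network collects all distinct R-groups over all sites as nodes
(R-groups from single-R-group sites remain as isolated nodes) and sums
site contributions into edge weights; by construction the total edge
weight equals Σ_s C(k_s, 2) over sites with k_s distinct R-groups. The
final network removes hydrogen, methyl and phenyl — the three groups so
generic that they would dominate every ranking — and drops nodes left
isolated. Surviving weights are untouched.

A 5×2 replacement hierarchy for a root R-group takes the root's top
`n_first` = 5 neighbors by EW (first layer) and, per first-layer group,
its top `n_second` = 2 neighbors by EW excluding the root and the group
itself (second layer), each layer shorter when neighbors run out — at most
10 root→first→second sequences. The exclusion of back-edges to the root
and parent is a design choice for decision support: a hierarchy that
suggests undoing the previous replacement carries no information. All EW
ties break by ascending canonical SMILES, making every selection
deterministic. Hierarchies for the `top_k` = 500 highest-ND R-groups form
the database, serialized as XML (`rgroup` / `first` / `second` elements
with `smiles`, `ew`, `rank`, `nd` attributes, document order = rank
order). The writer is a deterministic hand serializer so that
write∘read∘write is byte-identical; the reader validates structure and
ordering. Since methyl and phenyl are absent from the final network, they
can be read as implicit generic replacements applicable to any hierarchy;
the search command surfaces this as a static note.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mw_max` | 1000 Da | inclusive molecular-weight ceiling for input compounds |
| `rgroup_max_heavy` | 13 | maximum heavy atoms per R-group |
| `min_members` | 3 | minimum compounds per analogue series (inclusive) |
| `max_sites` | 4 | maximum cuts (heavy + hydrogen) per decomposition |
| `assignment_mode` | `unique` | series membership: disjoint vs overlapping |
| `remove_set` | H, methyl, phenyl | nodes removed for the final network |
| `drop_isolated` | true | also drop nodes orphaned by the removal |
| `top_k` | 500 | number of hierarchy roots |
| `n_first`, `n_second` | 5, 2 | hierarchy layer widths |
| `cut_budget` | 500,000 | per-compound cut-combination ceiling |

`max_sites` = 4 reflects that analogue series overwhelmingly vary few
positions at a time; larger values grow the enumeration combinatorially
without adding series of practical size.

## The synthetic generator and what passing tests show

`rgroupnet.synthetic` emulates exactly the regularity the pipeline
assumes: rigid ring scaffolds (8–13 heavy atoms, no cuttable internal
bond) with 1–2 indexed sites, combinatorial substituent pools (hydrogen
allowed), optional seeded subsampling (`fill`) and structurally unrelated
decoy singletons. Ground truth — series membership, per-site R-group sets
and the full weighted edge list — is computed by construction, and an
independent double-loop oracle rebuilds the expected network without
touching the pipeline's code path.

Ground truth is exact only under validated recoverability conditions:
every substituent within the 13-atom cap, worst-case substituent sums
within the half rule, scaffolds with pairwise distinct parent ring
systems, and — for any scaffold reaching series size — at least two
distinct substituents per site, none of the pools collapsible into an
enlarged core (guaranteed when hydrogen or a one-atom substituent is
present, or attachment elements differ). A `validate=False` mode emits
deliberately violating libraries to exercise the rejection paths; its
ground truth is not used for equality checks.

These libraries do **not** mimic real collections in other respects: no
activity data, no property or scaffold-frequency distributions, no salts
or stereo-rich structures, and molecule sizes far below the 1000 Da
ceiling. Passing tests therefore demonstrate correctness of the counting
and graph machinery under the method's structural assumptions, not the
chemical composition of networks derived from real screening collections,
whose scale (tens of thousands of series, millions of edges) is outside
desk scope.

Library and test problem sizes (tens of compounds per library, 20 seeded
libraries for oracle equivalence, 14-node saturated networks for
hierarchy bounds) were chosen as the smallest sizes that exercise every
rule, including multi-site cores, symmetry collapse and hydrogen
membership.

## Numerical and degenerate-input choices

- All identity comparisons are string comparisons on canonical SMILES;
  stereochemistry is preserved in identities by default, with an optional
  strip flag at input time.
- Multi-fragment inputs (salts) keep the largest organic fragment; the
  supplied molecular-weight column, if any, overrides the computed value.
- Boundary cases are inclusive throughout (MW = 1000 kept, series of
  exactly 3 kept, R-group of exactly 13 kept, core of exactly half kept).
- Empty results (no series, empty network) are legal and propagate
  cleanly; an empty hierarchy database is refused only at XML write time.
- A single heavy cut that splits a molecule into two half-rule-compatible
  parts yields both orientations; deduplication on (core, canonical
  assignment) collapses symmetric duplicates.

## Known limitations

- Automorphism search is capped; pathological highly symmetric cores
  beyond the cap collapse with a partial permutation group (consistently,
  but possibly keeping more than one orbit representative).
- Canonical site numbering relies on RDKit's canonical ranking; exotic
  resonance/tautomer pairs that canonicalize differently are treated as
  different cores, mirroring the underlying toolkit.
- The cut budget skips (not truncates) over-flexible compounds, so a
  single macromolecule-like record cannot silently bias the network.
- Hierarchies are derived from whatever network they are given; building
  them from the unrefined global network will be dominated by hydrogen,
  methyl and phenyl, which is why the refined network is the default
  source.
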