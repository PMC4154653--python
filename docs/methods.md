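# Methods

## Origin counting on an unresolved backbone

The deep branching order of prokaryotic lineages is not resolved, so the
primary counting path deliberately avoids a resolved species tree: it
treats the backbone as a star over *origin units*.  A unit is a lineage,
or a group of lineages declared to share a single origin of a trait by a
merge rule.  For a mode present in *k* units the minimal explanations are
*k* independent origins, or one origin plus *k − 1* horizontal transfers;
a mode declared *ancient* contributes exactly one origin (its patchiness
is read as secondary loss) and hence zero transfers.  Per mode,
`hgt = max(origins − 1, 0)`, so summing over modes gives
`total_hgt = total_origins − (number of modes present)` — on the packaged
census, 26 − 9 = 17.

Grouping assumptions are data, not code (`groupings_table1.yaml`):
ancient modes `[He, Me]`; one all-mode merge of the five proteobacterial
subgroups sampled in the census; one FO-scoped merge of the archaeoglobi,
thermoplasmata and the unclassified euryarchaeon.  Merge rules may share a
lineage only when their mode scopes are disjoint, and every merged lineage
must exist in the matrix being collapsed.  A crenarchaeal ancient-origin
assumption is sometimes also entertained for this census; the default
config omits it, since the shipped rules already reproduce the published
totals — edit the YAML to explore alternatives.

## Sankoff small parsimony

For resolved trees (and for synthetic studies) a binary-state Sankoff
dynamic program is provided: edge costs `gain_cost` (absent→present) and
`loss_cost` (present→absent), either possibly infinite (a Dollo-style
"no reversals" model uses `loss_cost = ∞`), and a root-state prior
(`absent`, `present`, `free`).  Infinite costs propagate through the
min-plus recursion as IEEE `inf`, which is safe under addition and `min`.
Backtracing prefers `absent` at ties in a fixed preorder, so the reported
optimal labeling — and its gain/loss tally — is reproducible.
Multifurcations are handled natively.  On a star tree with losses
forbidden and an absent root, the gain count equals the unit count, which
ties the two counting paths together (tested).

## Duplication-call rules

Calls are rule-based readings of a gene tree against a species backbone,
not a reconciliation optimization.  Two support levels follow common
publication practice: *robust* (posterior ≥ 0.95 and bootstrap ≥ 80) and
*shown* (≥ 0.80 and ≥ 50).  When a node carries both annotations both
must pass; a single annotation decides alone; an unannotated node fails.
Rules, in order:

* **SSD** — the copy's sister group at a `shown`-supported parent consists
  only of same-species copies.
* **LSD** — the smallest `shown`-supported clade containing the copy holds
  extra copies of ≥ 2 species that form a clade in the backbone (species
  are mapped to their own leaf if present, else to their lineage's leaf;
  the backbone may be a lineage-level polytomy).
* **paralog_clade** — the copy belongs to the largest robustly supported
  clade consisting entirely of extra copies and spanning ≥ `min_lineages`
  lineages.  This check precedes the transfer check: an ancient paralog
  clade always nests among foreign lineages by construction, and its
  members must not be mistaken for recent transfers.  The family tree may
  be re-rooted at this clade; rooting never changes copy counts.
* **HGT_candidate** — the copy nests, at `robust` support, in a clade
  whose other members all belong to foreign lineages; the donor is the
  majority lineage among them, and a tie leaves the copy unresolved —
  deliberately cautious, matching how such placements are hedged in
  practice.

Terminal-extension flagging (`flag_overhangs`) takes measured leading and
trailing overhangs against the orthogroup alignment as input and flags
N/C extensions at a configurable threshold (default 100 aa; known
signature extensions range from 80 aa upward).

## Locus architecture

Coordinates are 0-based serial ORF indices per replicon — the literature
counts "intervening ORFs", not base pairs; bp distances are optional
metadata.  A block boundary falls where the gap between consecutive ATP
genes exceeds `max_intervening` (default 3: single hypothetical ORFs are
routinely drawn inside intact loci, while a 4-ORF separation is drawn as
split) or where the replicon changes.  `X` (hypothetical) genes never
anchor a block edge; `?` (unassignable ATPI-family) genes ride along in
blocks and pattern strings but, like `X`, contribute no adjacency
characters.  A block's reading direction is its majority strand, so
patterns come out in transcription order; adjacencies are therefore
directed.

Split junctions are named against a reference order (default the
canonical `I-sI-0A-0C-0B-ID-IA-IG-IB-IE`): a reference-adjacent label
pair whose members never co-occur in a block is a junction — only block
co-membership matters, since split loci are read against the intact
order.  Duplicate placement: the *main* block is the one with the most
distinct core labels (a tie raises, prompting a `max_intervening`
review); same-label copies sharing a block are `in_locus`, copies outside
the main block `ectopic`.  When exactly two 0B copies share a block the
upstream one is renamed 0B′ — inputs never contain the prime; three or
more copies are flagged for manual review and left unchanged.

The N-ATPase detector requires atpR present (switchable off, because
degenerate N-loci missing atpR exist), the δ subunit (ID) absent, and the
block's label sequence to be a subsequence of `IB-IE-I-R-0A-0C-0B-IA-IG`
in either reading direction, tolerating absences from splits or partial
loci.

### Ancestral gene order

Each directed core-label adjacency observed within a block is a binary
character per genome (0B′ folds into 0B; consecutive duplicates
collapse).  Ancestral presence is inferred by k-ary Fitch parsimony over
the backbone (a star over the input genomes when none is given):
root set {present} scores 1, {absent} 0, ambiguous 0.5.  Edge weight is
`2 × ancestral + frequency`, so parsimony dominates and observed
frequency breaks ties; the ancestral order is the maximum-weight
Hamiltonian path over all observed labels, found by exact bitmask dynamic
programming (capped at 16 labels; locus alphabets are ~10).  A label
missing from some genomes is never vetoed — its place is decided by the
genomes that retain it.  If no single path covers every label the best
partial chains are concatenated with a warning.

## Synthetic data

The simulators emulate the generative assumptions of the analyses: a
pure-birth species-tree topology with unit branch lengths (rates are
per-branch); Poisson gains/losses and transfers for a binary trait, with
transfer donors drawn from lineages currently bearing the trait at the
traversal frontier — a discrete stand-in for contemporaneity, adequate
for counting but not for timing; gene families grown inside the species
tree with per-branch duplication (supports set to maximal values unless
degraded); and locus evolution by per-branch split (uniform junction),
adjacent in-locus duplication, and single-gene loss.

Defaults: 20 leaves; gain 0.1, loss 0.05, transfer 0.05 per branch;
duplication probability 0.1, split probability 0.2, gene-loss probability
0.05 per branch.  The trait rates give sparse, patchy tip distributions
(a handful of gains on a ~38-branch tree); the locus probabilities
scatter several splits and duplications across the tree while leaving the
canonical adjacencies in the majority, the regime the architecture
analyses target.  Event logs are complete: replaying them from the root
reproduces every leaf state and locus exactly (tested), and all
generators are bit-reproducible under a fixed seed.

What the simulators do *not* emulate: sequence evolution (no alignments
or substitution models), within-species processes, branch-length
heterogeneity, biased transfer partners, or annotation error.  Passing
recovery tests therefore show the inference machinery is correct under
its own model assumptions, not that real genomes satisfy them.

Two recovery caveats are inherent to parsimony, not defects: true gains
are recovered exactly only when independent — a gain nested under
another, or two sibling gains, are indistinguishable from fewer, deeper
events, and the recovery test excludes such replicates; and the true
history bounds the parsimony minimum only through its *total* event count
(gains + losses + transfers), since parsimony may happily trade a true
loss for an extra gain at equal cost.

## Numerical and format choices

* Lineage keys are lower-cased and whitespace-normalized; census tables
  mix styles.
* Abbreviations follow first-2 + "_" + first-3 + mode-code; tokens of
  6–9 characters ending in the record's mode code are accepted as
  well-formed, covering short epithets and condensed variants, and a
  per-record override column is honored (collision resolution for
  congeneric species is the caller's, via overrides).
* The packaged census is transcribed at lineage-count resolution: counts,
  lineages, domains and exemplar species are faithful; unnamed slots are
  filled with clearly synthetic placeholder binomials so that the table
  has one row per species.
* The per-lineage locus fixture reconstructs one representative canonical
  locus per lineage from the published split-junction and duplication
  descriptions; N-ATPase example loci live in a separate file because
  they are *additional* loci in real genomes and would otherwise
  contaminate canonical ancestral-order inference.

## Limitations

* Origin counts are conditional on the supplied grouping config; the tool
  reports counts under stated assumptions and does not search over
  alternative defensible groupings.
* The duplication classifier reports per-tree calls; reconciling
  conflicting placements across trees built by different methods is left
  to the user.
* Aggregate duplicate tallies over a full multi-genome dataset (and any
  statistic requiring the underlying sequence data) are out of scope.
* Adjacency parsimony assumes within-block gene order is preserved
  relative to the intact reference; rearrangements inside blocks are not
  modeled.
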