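# Methods

## Orthology model

Presence calls are gene-level bidirectional best hits. For a human gene *g*
with representative protein *p* (by convention the longest isoform, supplied
by the `GeneMap`), and a target genome *s*:

* the forward best hit is the subject in *s* with maximal bit score among
  hits with E ≤ `e_threshold`;
* the call is 1 iff the reverse best hit of that subject, against the human
  proteome, maps to any isoform of *g*.

`e_threshold` defaults to **0.1**, deliberately permissive: divergent
centriolar components (SAS-4/SAS-5 class proteins in nematodes) drop below
conventional significance cutoffs, and the reciprocal test — not the E-value
— carries the specificity. "Above the threshold" is interpreted as E ≤ 0.1
(admissible), the only reading under which a *low* cutoff is permissive.
Ties in bit score break by lower E-value, then lexicographically smaller
subject id — an arbitrary but fixed policy that makes calls invariant to
hit-file row order. Only one representative
protein is queried per gene; reverse hits may land on any isoform because
matching is by gene id. Whether the original analysis queried every isoform
is not determinable; the representative-protein choice is this package's
and is configurable through the `GeneMap`.

## Distances and clustering

Genes and genomes are clustered by unweighted average linkage
(scipy's NN-chain implementation; deterministic for a given input).
Two metrics are offered:

* `euclidean` (default): √Hamming between binary profiles;
* `mean_squared`: Hamming/n — what classic desktop clustering tools
  actually compute when asked for "Euclidean". The monotone transform does
  not change the distance *ranking* of pairs, but average linkage takes
  means over member pairs, so the two dialects can disagree on topology;
  both are first-class and tested.

Merge heights under average linkage are monotone nondecreasing toward the
root; the `Dendrogram` container asserts this. When two candidate merges tie
exactly, the library's deterministic internal order decides; on binary data
ties are common, so cluster *membership* at a cut is stable but the merge
trace within a tie block is implementation-defined.

## Ciliated-left leaf ordering

For display, genome leaves are ordered so ciliated genomes sit as far left
as the dendrogram topology allows: at every internal node the child subtree
with the higher fraction of ciliated leaves is placed first (ties keep the
input order). By a pairwise-exchange argument this greedy rule minimizes the
summed positions of ciliated leaves over all 2^(n−1) orderings reachable by
flipping children; the test suite verifies exhaustive optimality on trees up
to 8 leaves.

## Seed-anchored cluster extraction

The ciliary cluster is the clade around a seed gene. Three stopping rules:

* `fixed_height` — largest seed clade with merge height ≤ the given cut;
* `target_size` — smallest seed clade with ≥ k leaves, for pinning a known
  cluster size;
* `elbow` (default) — walk the seed-to-root path and cut just below the
  largest relative jump (h₊ − h)/h between consecutive merge heights; a
  zero-height base with a positive jump counts as infinite, so in noise-free
  data the maximal identical-profile clade is returned exactly.

The elbow rule operationalizes "grow the cluster until loosening the
similarity constraint stops adding genes gradually". It is deliberately
simple and is brittle in two known ways: a small clade of coincidentally
identical noisy profiles below the seed creates an infinite gap and truncates
the cluster, and a large height jump near the root (between profile
super-classes) can occasionally out-compete the module boundary. At the
benchmark noise level this affects a minority of replicates — the recovery
contract is therefore stated on the median over replicates — and
`target_size`/`fixed_height` are the right tools when the expected size or
scale is known. Every extraction returns its full growth trace
(height, size per step) so the cut can be audited.

## Robustness subsampling

Cluster stability is probed by removing a fraction of genomes — stratified:
each major group loses `round(fraction × size)` members uniformly at random
— re-clustering, re-extracting around the same seed, and reporting the
overlap with the full-matrix cluster. Removing an entire group is an error
by design: the exercise thins the tree evenly rather than pruning whole
branches. An explicit genome list is accepted instead of a fraction, for
reproducing published reduced panels.

## Dollo loss inference

Cilia are modeled as a Dollo character: present at the eukaryotic root,
gained once, never regained. Under this model the minimal explanation of the
leaf states is unique: a loss sits on every edge whose entire subtree lacks
the trait while the parent clade still contains a carrier. The count equals
the exhaustive minimal-edge-cover optimum (verified against enumeration on
trees ≤ 10 leaves) and is invariant to child rotation. Losses are attributed
to the major group of the species below the edge. Prokaryote outgroups never
enter the trait analysis. When no resolved species tree is supplied, a
rank-level tree (major groups as polytomous clades, flat within groups) is
built from the annotations; any Newick tree can be substituted, and loss
counts on the rank-level tree are an upper bound on those from a resolved
tree because within-group clade losses splinter into per-species events.

## Loss patterns and function prediction

Per genome and functional category, the fraction of the category's genes
retained is discretized with strict inequalities: high iff > 2/3,
mid iff > 1/3, low otherwise (the boundary points 2/3 and 1/3 fall to mid
and low respectively). Genomes sharing a discretized vector share a loss
pattern; the distinct-pattern count is bounded by both 3^#categories and the
genome count.

Function prediction uses only the conservation footprint. With conservation
= fraction of ciliated genomes carrying the gene:

* conservation < 0.5 → `no_prediction` (too patchy to call);
* else `motility` iff the gene is absent from **all** ciliated genomes whose
  cilia are immotile (the nematode/tick class) and present in ≥ 0.5 of
  motile-ciliated genomes;
* else `biogenesis`.

Both 0.5 cutoffs are parameters; the published analysis chose its tiers
manually, so the defaults here are this package's operating point, not a
claim about the original cutoffs. The `reduced_complement` annotation flag
is carried through for custom rules but does not enter the default rule.
If the annotation panel contains no immotile-ciliated genomes the motility
footprint is unobservable and everything conserved enough is called
biogenesis.

"Universally conserved" genes are those present in every ciliated genome and
absent from every nonciliated eukaryote; prokaryote columns are ignored.
Note that under the simulator's i.i.d. false-negative noise the probability
that a gene survives this strict test across ~140 ciliated genomes is
(1 − fn)^140 ≈ 0 at fn = 0.05 — real core ciliary genes are detected
essentially without false negatives, so this is a known feature of the noise
model, not of the statistic (noise-free simulations recover planted
universal genes exactly).

## Screen-scoring rubrics

All assays map to 0 (no phenotype) – 4 (strong). Bins printed to one decimal
leave small numeric gaps (e.g. amphid 10.9–11.0); bins here are half-open
with each gap attached to the worse (higher) score, making every in-range
value scoreable while reproducing every printed example. The overall
dye-fill phenotype is the numeric maximum of the amphid and phasmid scores.
Fertility bins on pupae counts: ≥ 90 → 0, 60–89 → 1, 30–59 → 2, 10–29 → 3,
< 10 → 4. The scolopidia call is binary: abnormal iff strictly more than 20%
of scolopidia are defective.

Rubrics with verbal category edges ("several individuals", "strong lethality
with a few survivors") are operationalized as documented fraction
thresholds: viability 4 at fraction dead = 1, 3 at ≥ 0.9, 2 at ≥ 0.5, 1 at
≥ 0.1; wing posture 4 at 1.0, 3 above 0.5, 2 at 0.5, 1 at ≥ 0.15; flight 2
at ≥ 0.5 non-fliers (so "half unable to fly" scores 2), 1 at ≥ 0.15. The
0.15 floor encodes "several individuals" against the ≥ 20-animal counting
convention. Categorical rubrics (uncoordination strong classes,
spermiogenesis stages) are direct lookups. In significance aggregation a
gene counts as significant when any assay score exceeds 1 (strictly);
missing assays are skipped, never imputed as 0, and percentages are reported
as integers.

## Synthetic data generator

The generator emulates the study conditions: 147 eukaryotic genomes across
eight major groups plus 12 prokaryote outgroups (group sizes roughly
proportional to real sampling of the eukaryotic tree), a ciliary gene
complement of 300 genes split into biogenesis (240), motility (40) and
BBSome (20) modules, 4,700 conserved background genes, 13 independent cilium
losses and 2 additional motility-only losses, background per-branch loss
probability 0.005, false-negative rate 0.05 (sequence-divergence misses) and
false-positive rate 0.001 (spurious reciprocal hits). Within-group
topologies are random binary trees; loss edges are drawn uniformly among
edges strictly inside eukaryotic group clades, subject to the constraint
that every chosen edge remains a *maximal* absent clade (no nesting, and no
ancestor left without an unaffected descendant) — exactly the condition
under which Dollo counting returns the configured number of losses, and
which also guarantees every group keeps a ciliated genome. Module genes
track their trait deterministically before noise; only background genes
undergo sporadic per-branch Dollo loss. All randomness flows from the single
mandatory `rng_seed`.

What the generator does **not** emulate: correlated detection failure (real
false negatives concentrate in fast-evolving lineages — a per-species
multiplier knob exists but defaults to off), partial module retention
(real genomes keep fragments of lost machines), gene duplication and gene
trees, and any sequence-level realism. Passing recovery tests therefore
demonstrate the pipeline's correctness under the stated generative model,
not its performance on real proteomes.

Fabricated hit tables invert the orthology layer: present cells get an
admissible forward hit (E = 10^(−U(5,50))) whose reverse best lands on an
isoform of the same gene; absent cells get, with equal probability, no hit,
an inadmissible hit (E > threshold), or an admissible decoy whose reverse
best maps to a dedicated decoy gene — the three failure modes of a
reciprocal test. The round-trip through `build_matrix` is exact by
construction and verified property-wise.

## Benchmark problem sizes

The planted-cluster recovery benchmark runs 50 replicates of 5,000 genes ×
120 genomes (112 eukaryotes + 8 outgroups), one 300-gene ciliary module, 10
independent losses, false-negative rate 0.05, and asserts median Jaccard
≥ 0.9 between recovered and planted module. The study-shaped simulation
(5,000 × 159) is used for the end-to-end pipeline runs. Exhaustive oracles
run on instances ≤ 10 items (linkage, Dollo) and ≤ 8 leaves (leaf
ordering), the sizes at which enumeration is exact and instant.

## Known limitations

* The elbow extraction heuristic is the weakest link at high noise (see
  above); prefer `target_size` when an expected size exists.
* Rank-level trees inflate loss counts relative to resolved topologies;
  supply a resolved Newick tree for publication-grade counts.
* The BBH caller assumes one representative protein per gene and gene-level
  reverse matching; proteome-specific isoform pathologies are out of scope.
* Screen rubrics with verbal edges embed this package's documented numeric
  choices; override the registry for alternative operationalizations.
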