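# Methods

## Clade branch-length statistics

All statistics operate on a rooted phylogram with nonnegative branch
lengths (polytomies allowed; unique tip labels enforced). For a clade
with tip set *C* and MRCA *v*:

* **CBL** — sum of every terminal and internal branch strictly below
  *v*. The stem branch subtending *v* is *not* "within" the clade and is
  excluded; a single-tip clade therefore has CBL = 0.
* **normalized CBL** — CBL/|*C*|, removing the mechanical dependence of
  CBL on clade size.
* **CPD (cumulative patristic distance)** — CBL plus the branch length
  on the path from the root to *v*. Whether "the node supporting the
  clade" is reached through its stem branch is a genuine ambiguity; the
  default *includes* the stem (the node is reached via its stem), and
  `include_stem=False` / `--cpd-exclusive-stem` gives the exclusive
  convention. When *v* is the root both conventions coincide with CBL.

Non-monophyletic tip sets raise by default; `force_mrca` computes over
the full MRCA subtree and flags the record `monophyletic=False`, which
is the right behaviour for published trees where a rogue sequence breaks
a clade. Missing branch lengths parse as 0 with a warning (or raise with
`missing_length="error"`). Reports round to 3 decimals; computation is
at full double precision.

## Stability and Dollo reconstruction

A clade is **stable** iff every species in the matrix has ≥ 1 functional
copy. Pseudogenes do not establish presence by default
(`count_pseudogenes` overrides): a genome whose only copy is
pseudogenized has functionally lost the gene, which is exactly the
situation the classification is meant to flag.

**Dollo reconstruction** assumes a single origin and irreversible loss.
The origin is placed at the species-tree MRCA of the carriers — the most
parsimonious single origin. Below the origin, the minimal loss set is
the set of *maximal all-absent subtrees*, found in one post-order pass.
This decomposition is unique on a rooted tree (no tie-breaking is ever
needed, which the test suite asserts by exhaustive enumeration on all
patterns over small random trees). An all-absent child of a polytomy
receives its own loss. A per-clade `origin_at_root` override supports
the deeper-origin reading used when outgroup or synteny evidence places
a clade's birth above its extant distribution; forcing the root origin
can only add losses.

The **ancestral repertoire** at a node counts clades whose presence flag
is true there. The **lower bound** n_clades − n_lineage_specific_duplicates
reproduces the duplication-corrected arithmetic: each duplication
confined to one species group adds one clade that the genus ancestor
cannot have carried. Note the two conventions can disagree: in the
packaged fixture the strict MRCA-origin repertoire at the root is 14,
while the arithmetic bound is 15, because one ancestral lineage
(CG13091/CG10097) is counted at the genus root despite being absent from
an entire subgenus; the package computes both and leaves the choice
explicit.

## Packaged fixture

`data/far_clades.tsv` + `data/drosophila12.nwk` encode the FAR
repertoire statements for the 12 *Drosophila* genomes: 12 clades with a
functional copy everywhere (with the 8-copy *D. virilis* expansion of
CG10096), GJ13738 restricted to subgenus Drosophila + *D. willistoni*,
CG13091 absent from the ananassae group and subgenus Drosophila, CG10097
confined to the melanogaster subgroup with the *D. sechellia* copy
pseudogenized, the CG14893 lineage reaching *D. virilis* with two
independent terminal losses (*D. mojavensis*, *D. grimshawi*) and a
3-copy *D. ananassae* expansion, CG17560/CG17562 melanogaster-group
only, three clades flagged as lineage-specific duplicates, and the
per-clade RNAi-lethality phenotypes (9/12 stable and 1/5 tested unstable
clades lethal). Per-species totals are *not* calibrated to genome-wide
counts — those require genome-scale homology searches outside this
package's scope. The species-tree branch lengths are approximate
literature divergence times (root ≈ 63 My); every discrete result
(stability, Dollo, repertoires) depends only on the topology.

## Selection-test post-processing

−2Δln L = 2(ln L_alt − ln L_null) is referred to the χ²(df) upper tail
(df = 1 for the branch-site test). A negative statistic — possible when
the alternative optimum was not found — is clamped to 0 and flagged
rather than rejected, for robustness to real optimizer output.
Holm–Bonferroni applies the step-down rule p\_(i) × (m − i + 1) with a
running maximum over the sorted order (the lift matters: the largest raw
value is *not* simply multiplied by 1), capped at 1, mapped back to
input order; the family of hypotheses is the input table. Branch-site
parameter columns (p0, p1, p2a, p2b, ω0–ω2) are validated for range
(proportions in [0,1], ω ≥ 0) and carried through untouched.

The stable-vs-unstable comparison uses a two-sided two-sample t-test,
pooled-variance Student by default (consistent with df = n₁ + n₂ − 2
style reporting); Welch–Satterthwaite is available by flag. Group
membership comes from the stability calls, values from any of
cbl/normalized_cbl/cpd.

## Simulator

Each clade starts as one lineage at the species-tree root. Along an edge
of duration T every lineage independently follows a linear birth–death
process (duplication λ, loss μ per unit time) simulated event-by-event
(Gillespie), so the exact per-edge event counts are logged as ground
truth; at each speciation every surviving lineage enters both daughter
edges. Gene-tree branch lengths are elapsed time × r, the per-class
substitution-rate multiplier. Surviving unifurcations are collapsed at
emission.

Defaults are the *Drosophila*-like study conditions: the packaged
12-species tree (depth ≈ 63 time units), 12 stable clades (λ = μ = 0,
r = 1) and 6 unstable clades (λ = μ = 0.05 per unit time, r = 2).
`pseudogene_prob` (default 0.1, a modest value reflecting that most
losses leave no recognizable relic) applies only to losses on terminal
edges: such copies are emitted as pseudogene tips truncated at the loss
time, emulating recognizable recent pseudogenes, while internal-edge
losses are pruned — ancient pseudogenes decay beyond recognition and
real surveys only annotate recent ones. Randomness derives from one
`numpy` SeedSequence spawned into one child stream per clade, so results
are bit-reproducible and adding clades never perturbs existing ones.

What the simulator does **not** emulate: sequence-level evolution (no
alignments; branch lengths are deterministic multiples of time, so
within-class rate variation among stable clades is absent), gene
conversion/concerted evolution, regain (Dollo world), and
pseudogene persistence across speciations. Consequently, passing
simulation-based tests demonstrates correctness of the bookkeeping and
the statistical machinery under the model, not that real gene families
satisfy the model.

### A note on the power of the group comparison

Under the default conditions the stable group is degenerate (every
stable clade has the identical normalized CBL = total tree length/12 ≈
30.2) while λ = μ = 0.05 over a 63-unit-deep tree produces extreme
turnover in the unstable class (surviving clades average ~19 copies).
Duplications add many recent tips that dilute CBL per sequence, so the
unstable normalized CBL (empirically mean ≈ 34, sd ≈ 18) sits only
slightly above the stable constant despite the doubled substitution
rate, and the two-sided t-test at α = 0.05 rejects in roughly half the
replicates rather than the large majority one might expect from r = 2
alone. The acceptance suite asserts the stronger power figure and
documents the shortfall rather than altering the study conditions;
analyses relying on the normalized-CBL contrast should expect high power
only at milder turnover (λ, μ ≲ 0.01 per unit time at this depth), where
gene trees stay close to scaled copies of the species tree.

## Numerical and interface conventions

χ² tails via `scipy.stats.chi2.sf` (cross-checked against
erfc(√(x/2)) for df = 1 at 10⁻¹² relative tolerance), Holm via
`statsmodels`, t-tests via `scipy.stats.ttest_ind`; Newick I/O via
`dendropy` with underscores preserved verbatim and `[...]` comments
skipped. All tables are UTF-8 TSV with a header; `report.json` carries
full-precision floats, `report.pretty.txt` the rounded presentation.
Pipeline exit codes: 0 success, 2 validation failure, 1 runtime error;
a `report.json.partial` marker is left behind on abort.

## Known limitations

* Dollo minimality is per-clade; no cross-clade rate model (no
  birth–death likelihood on counts, by design).
* `repertoire_lower_bound` trusts the `lineage_specific_duplicate`
  annotation; it does not infer duplication nodes from tree shape.
* The t-test assumes approximate normality of the chosen metric across
  clades; with very few unstable clades the comparison is fragile, and a
  zero-variance group makes the pooled statistic degenerate.
* The published genome-wide comparison on the full 200-sequence FAR
  phylogram requires the externally deposited tree (Dryad
  doi:10.5061/dryad.s31rc70); an optional integration test runs when
  that file is supplied locally.
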