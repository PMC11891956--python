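# Methods

## Distances

Uncorrected p-distance with **pairwise deletion**: a site contributes
to a pair only when both sequences carry a canonical base; gaps, Ns
and IUPAC ambiguity codes are treated as missing data, never as
mismatches. On 313-site minibarcodes with sporadic Ns this keeps the
maximum usable signal; complete deletion would discard whole columns
for a single degraded sequence. Mismatch and compared-site counts are
kept as integers, so a threshold test `distance ≤ t` is evaluated as
`mismatches ≤ t · compared + 1e-12` — exact fractions with a small
absolute slack so that a pair at exactly 3.0% links at the 3%
threshold despite binary-float representation.

Pairs sharing fewer than `min_overlap` sites (default **100** of 313)
carry essentially no information about a 1–5% divergence and are
flagged invalid: they appear as NaN in exports and never create
cluster links (conservative against chaining on noise). In strict
mode they abort instead.

## Clustering

MOTUs are the connected components of the graph linking pairs at
`distance ≤ threshold` (single linkage with transitive closure). This
rule is what threshold-based barcode clustering tools implement in
practice, and it is the only linkage under which partitions at
increasing thresholds are guaranteed **nested** — the property the
stability classification depends on. MOTU ids are canonical (named
after the lexicographically smallest member), making partitions
invariant under input reordering and output files byte-reproducible.

## Stability classes and the examination plan

Base threshold 3%; stability grid **{1, 1.5, 2, 2.5, 3}%**
(configurable — the 0.5% step is this package's choice; what matters
is that the grid spans 1% to the base). A base MOTU is
composition-stable when its exact specimen set occurs as one whole
cluster at every grid threshold. Classification:

* singleton — one member;
* instable — composition changes over the grid **or** maximum
  internal p-distance > 1.5%;
* stable — otherwise.

A continuous stability index (fraction of grid thresholds with
unchanged composition) is reported as a diagnostic; classification is
binary as above.

Haplotypes are zero-distance single-linkage groups ("identical on all
mutually compared sites"); with missing data this relation is closed
transitively, which can merge sequences that differ only at sites one
of them lacks — the conservative reading for planning purposes.

Examination plan: singletons contribute their specimen; stable MOTUs
the most distant specimen pair (ties broken lexicographically), or a
single specimen when only one haplotype exists; instable MOTUs the
most distant pair plus one representative (smallest id) of every
*main* haplotype not already covered. "Main" is not standardized in
the field; the default here is every haplotype with ≥ 2 members plus
always the largest, configurable by count or frequency.

## Congruence and conflict resolution

Congruence is judged on examined specimens only; unexamined specimens
inherit the species of their MOTU after resolution (the subsampling
semantics of LIT). MOTUs with no examined specimen are *untested* and
retained as putative species under their MOTU id; by default they stay
inside the match-ratio cluster counts.

The match ratio `2·Nc/(N_a+N_b)` is computed on the shared specimen
set of the two partitions; it is symmetric and equals 1 iff the
partitions coincide.

Resolution searches the threshold grid nearest-first (minimal
perturbation of the base partition): fused MOTUs are re-split using
finer partitions restricted to the MOTU's members (valid only when
every contained morphospecies lies entirely inside the MOTU); split
morphospecies are re-fused using coarser partitions, accepting the
first cluster that contains all of the label's examined specimens and
nothing labelled otherwise — such a fusion may absorb neighbouring
untested MOTUs, which is intended (they are the "neighbouring
clusters"). A morphospecies that is simultaneously split and fused at
the base threshold is marked *conflict* outright: neither remedy alone
can fix it, and the examined-specimen sets it would need are not
produced by any single-threshold partition. Conflict specimens remain
unassigned to species; conflicts are data, not errors. Resolution is
local: MOTUs outside the affected clusters are never touched.

## Completeness

Coverage is computed on the **combined** clustering of both batches
(batch labels do not affect distances): a MOTU is shared when it holds
specimens of both batches, new when it holds only batch-2 specimens.
MOTU coverage = shared / batch-2-occupied; specimen coverage = batch-2
specimens in shared MOTUs / batch-2 total. The randomization null
redraws pseudo-batch-1 uniformly without replacement at the observed
batch sizes and recomputes both coverages on the fixed partition, 100
replicates by default, reporting mean ± sample sd (n−1; the
denominator convention is this package's documented choice). Only
batch sizes are preserved — not site or habitat structure. All
replicates flow through one seeded integer RNG, so a fixed seed
reproduces the per-replicate vectors exactly across platforms.

## Simulator

`simulate_community` emulates a Malaise-trap minibarcode sample:

* **Abundances** — geometric rank-abundance by default with
  p = 0.05, allocated by largest remainder with a floor of one
  specimen per species. At the package's reference scale (140
  species, 2947 specimens) this yields ≈ 20% singleton species,
  matching the rare-species tail such inventories show; log-series
  and uniform curves are available.
* **Sequences** — ancestors are drawn as sense codons of the
  invertebrate mitochondrial code (frame 0 stop-free by
  construction), substitutions only, no indels, so simulated data are
  aligned by construction and pass the stop-codon QC. An optional
  flag injects pseudogene-like sequences with stops in all three
  frames to exercise the filter.
* **Divergences** — species ancestors are rejection-sampled to ≥ 5%
  from all others; specimens deviate from their lineage ancestor by at
  most `max_intra/2` sites (star topology), bounding intraspecific
  pairs by 1%. Cryptic pairs are planted at 1.8% (splittable at 1%,
  fused at 3%); divergent conspecific lineages at 4% (split at 3%,
  fused at 5%).
* **Batches** — a uniform random split at the requested fraction;
  morphospecies labels equal the true species, with an optional
  mislabelling rate.

What the simulator does **not** emulate: coalescent genealogies and
skewed haplotype frequency spectra, indels and alignment error,
contamination and chimeras, geographic structure between batches, and
morphospecies only being observable on a subsample or one sex. Tests
passing on simulated data therefore demonstrate the correctness of
the clustering/stability/congruence/coverage machinery under a clean
barcode gap with known truth — not the field behaviour of any
particular empirical dataset.

## Problem sizes and numerics

The test suite works on communities of 60–180 specimens; the
acceptance script runs the package's reference scenario of 2947
specimens (distance matrix of ~4.3M pairs, vectorized over encoded
uint8 sequences), which completes in seconds. Determinism everywhere:
canonical MOTU ids, lexicographic tie-breaks for most-distant pairs,
size-then-id ordering of haplotypes, and a single seeded RNG per
simulation or randomization run.

## Known limitations

* Single-linkage chaining can connect species through intermediate
  haplotypes at high thresholds; this is inherent to the method being
  implemented, and the stability classes exist precisely to flag it.
* The conflict-resolution search considers single-threshold remedies
  (one split or one fuse), not mixed recombinations of clusters across
  thresholds.
* Translation-based QC checks forward frames only; reverse-complement
  orientation is assumed fixed upstream.
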