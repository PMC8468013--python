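# Methods

## Problem and model

Closely related bacterial species — the motivating case is
*Lacticaseibacillus zeae* against its neighbours in the *L. casei* group
and other lactic acid bacteria — can be indistinguishable by 16S rRNA
sequencing.  A pan-genome route sidesteps this: cluster every annotated
gene from a cohort of genomes into ortholog families, find a family
carried by *every* genome of the target species and by *no* other genome,
confirm that its closest homolog anywhere else is far below the clustering
threshold, and design a qPCR assay inside that gene.  `panmarker`
implements this discovery pipeline end to end, plus the standard-curve
mathematics that turns the assay into a quantification method.

## Ortholog clustering

Genes are clustered with a deterministic greedy centroid scheme
(UCLUST-style): genes sorted by length (descending, ties broken by
genome and gene id) either join the first earlier cluster whose
representative they match at ≥ the identity cutoff (default 0.50) or
found a new cluster.  Identity is matches / alignment columns of a global
alignment with match +1, mismatch −1, gap open −2, gap extend −1
(Biopython's `PairwiseAligner`).

Clustering operates on **amino-acid sequence by default** (CDS translated
with the standard code; nucleotide mode is available).  The reason is
empirical and worth stating: under this scoring, two *unrelated* random
DNA sequences align at ≈ 0.49–0.52 identity, i.e. exactly at the
conventional 50% cutoff, so nucleotide clustering at 0.5 cannot separate
gene families from noise.  Unrelated proteins align at ≈ 0.22, leaving a
wide margin below 0.50 while cross-species homologs (≈ 0.75 at the
default between-species divergence) stay safely above it.  Nucleotide
clustering remains sensible at tighter cutoffs (≥ ~0.7) and is exercised
in the tests.

A shared-k-mer prefilter (k = 5 for amino acids, k = 11 for nucleotides)
preselects candidate representatives through an inverted index.  The
provable bound (an alignment with at most (1−cutoff)·L edits destroys at
most k k-mers each) is applied when it is informative; at permissive
cutoffs it is vacuous and the filter degrades to requiring ≥ 1 shared
k-mer.  That heuristic can in principle drop a pair whose mismatches are
spaced more regularly than point mutation produces; `use_prefilter=False`
gives the exact quadratic behaviour.

## Pan-genome partition

The clusters × genomes copy-number matrix (paralogs counted, presence =
count ≥ 1) is partitioned into **core** (present in all genomes),
**unique** (present in exactly one genome — the singleton sense of
"unique gene") and **accessory** (everything else).  A clade-specific
marker — present in all genomes of one species only — is a different
notion and lives in the screen.  With a single genome in the cohort every
cluster would be both core and unique; it is classed core.

## Phylogenies

Two distance substrates feed classical neighbor-joining (Saitou–Nei):
Jaccard (or Hamming) distances on the presence/absence matrix, and
p-distances on the concatenation of 20 randomly sampled (seeded)
single-copy core clusters, each member projected onto its cluster
representative (equal-length pairs column-for-column, otherwise via
global alignment; gap columns excluded pairwise).  NJ is implemented
in-package so tie-breaking is deterministic (lexicographic on the
smallest leaf label of each node) and negative branch-length estimates
are clamped to zero and counted; scikit-bio's NJ acts as an independent
oracle in the tests.  NJ is exact on additive matrices, which the tests
exploit.

## Marker screen

Stage 1 keeps clusters whose genome set is exactly the target clade and
whose members all match the cluster representative at ≥ 94% **nucleotide**
identity — the scale on which strain-level variants of one gene differ
(amino-acid identity at the same strain divergence dips to ≈ 0.91 and
would spuriously reject).  Stage 2 aligns each survivor's representative
(amino acid — the scale on which distant homologs are compared) against
every non-target gene and discards the candidate if any hit reaches the
cross-identity ceiling (default 0.50, the clustering cutoff).  Best hits
below a 30% report floor are flagged "below floor" rather than attributed
to a specific gene, since identities there are alignment noise.
Survivors are ranked by rank_score = w_gc·gc_penalty + w_len·len_penalty
(distance of GC from [0.40, 0.60]; distance of length from
[300, 2000] nt normalized by the interval width; both weights 1), ties on
cluster id.  The ranking formula is this package's own quantification of
the informal "suitability for primer design by GC content and length"
criterion; the weights are config-exposed.

## Primer design and in-silico PCR

All primer windows of 18–24 nt with GC in [0.40, 0.60], Wallace Tm
(2·(A+T) + 4·(G+C)) in [55, 65] °C and no homopolymer ≥ 5 are enumerated;
pairs must give a product of 80–200 bp with |ΔTm| ≤ 3 °C.  Windows are
additionally restricted to positions conserved across every target-clade
copy of the marker (computed by projecting members onto the
representative), so the pair binds every strain exactly — designing on a
single copy would place primers on strain SNPs and miss part of the
clade.  Ranking is deterministic: |ΔTm|, then closeness of the product to
130 bp, then a soft preference for G/C 3' ends, then leftmost
coordinates.  Product length uses the synthesis convention — the
inclusive span between the two primers' 5' ends — so two 20-mers with an
88 nt insert give 128 bp.

In-silico PCR scans every sequence and its reverse complement for primer
sites within a mismatch tolerance (default 2) with the 3'-terminal 3 nt
required exact (extension launches from the 3' end), and reports every
inward-facing opposite-strand pair up to 3 kb.  Amplicon Tm is predicted
with the salt-adjusted empirical formula 81.5 + 0.41·GC% − 675/N +
16.6·log10[Na⁺] (default 0.05 M), reported to 0.5 °C and never used as a
pass/fail criterion.  Primer-level Tm uses the Wallace rule; both
formulas are deliberate simplifications — no nearest-neighbour
thermodynamics, dimer or hairpin ΔG.

## qPCR standard curve

Ct is modelled as linear in log10 concentration (x in log10 CFU/mL, so a
10³–10⁹ dilution series maps to x ∈ [3, 9]).  Ordinary least squares
gives slope and intercept; r² is the squared Pearson correlation;
efficiency = (10^(−1/slope) − 1)·100 (slope −3.3219 ⇔ 100%, exact
doubling); an assay is high-efficiency when r² ≥ 0.98 and the slope lies
in [−3.6, −3.1], boundaries inclusive.  Quantification inverts the line.
Efficiencies are displayed to one decimal; unrounded values are retained.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with full ground truth.  Defaults: 9 species, 5 genomes of the target
species + 3 of each other species (29 genomes); 120 core and 80 accessory
gene families; genes 300–900 nt (codon-multiple lengths), GC 0.47; one
planted marker in every target genome only; one homolog of the marker at
36% amino-acid identity in the first non-target species.

Divergence parameters are expected **pairwise** nucleotide divergences
(each lineage is substituted at half the rate from the shared ancestor):
within-species 0.02 (nucleotide identities ≈ 0.94–1.0, the band the
screen's default threshold assumes) and between-species 0.12 (amino-acid
identities ≈ 0.75 between species' homologs — above the 0.50 clustering
cutoff, so shared families cluster across species and a core genome
exists, and far below the within-species band, so species remain
separable).  A between-species divergence high enough to push homologs
below the clustering cutoff (≈ 0.45 pairwise) would empty the core genome
and make every target-species family "clade-exclusive"; that regime is
instead represented by the planted distant homolog, whose substitution
rate is derived from the requested amino-acid identity by inverting a
codon model ((1−q)³ + 3q(1−q)²·0.24 synonymous recovery) with a small
Monte-Carlo-calibrated correction (+0.016 at 36%) for the identity
inflation global alignment achieves by gapping.

Accessory families are assigned to random species subsets of size 2 to
n−1, never to the target species alone — clade exclusivity is controlled
solely by the planted markers, so ground truth is unambiguous.
Substitution-only by default (an optional indel rate exists to stress the
aligner); no operon structure, synteny, intergenic sequence or sequencing
error is modelled.  Passing tests on these communities therefore
demonstrate the pipeline's logic under clean divergence structure, not
robustness to annotation errors, horizontal transfer of the marker, or
assembly artifacts.

## Problem sizes and numerical choices

Replicated checks (the 100-seed marker-recovery acceptance test, the
25-community acceptance script sweep) use a scaled community — 40 core +
30 accessory families, genes 300–600 nt, cohort structure unchanged — so
a replicate runs in ~2 s; single-run analyses use the full defaults.
Trees are skipped inside the recovery loop (the claim under test concerns
selection and specificity).  Alignment scoring is fixed (+1/−1/−2/−1);
identity ties between co-optimal alignments follow Biopython's first
reported alignment.  All randomness flows from explicit integer seeds
(numpy `default_rng`); reruns are byte-identical.

## Known limitations

- The cross-homology scan is limited to the supplied genome set; a real
  deployment would also search a comprehensive protein database.
- Greedy centroid clustering depends on the length-sorted insertion
  order; it is deterministic but, like UCLUST, not an optimal partition.
- The k-mer prefilter is heuristic at permissive cutoffs (see above).
- Wallace/empirical Tm formulas are coarse; primer pairs passing here
  should still be checked with a thermodynamic model before synthesis.
- COG/functional annotation of candidates is out of scope (requires
  external databases), as is melting-curve signal processing.
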