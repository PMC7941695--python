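# Methods

## Haplogroup model and marker panels

The haplogroup hierarchy is a rooted tree whose root ("Y-Adam") is the
ancestral Y chromosome without derived mutations. Panels are 7/8-column
TSVs (haplogroup, parent, marker, position — or position_hg19/position_hg38
pairs — ancestral, derived, key flag, optional reference base). The
reference base defaults to the ancestral allele; a separate column exists
because a marker's derived allele sometimes *is* the reference-genome base,
which is exactly the case the hidden-reference rule must handle. No genome
FASTA is required: the panel is self-contained.

*Resolution* r of a haplogroup is its depth (edge count from the root) —
the only monotone, tree-intrinsic definition available. Haplogroup
simplification for frequency analyses returns the ancestor at a requested
depth; it is idempotent and the identity for nodes at or above that depth.
Simplification is by ancestor walking, not name-string truncation, so
panels with arbitrary haplogroup names work; ISOGG-style name truncation
would be a presentation-layer convenience only.

Markers may recur at several haplogroups (recurrent mutations); each
occurrence scores only its own haplogroup. No global consistency solve is
attempted for back-mutations.

## Classification

Scoring: per haplogroup, m counts scorable markers, n those observed
derived. A marker is scorable when its position has a haploid call, or — in
sequencing mode — when the position is absent from the variant table
entirely, in which case the sample is taken to carry the reference base
(sites where all samples equal the reference are not emitted in
sequencing-derived VCFs). In array mode absent positions are unscorable.
Heterozygous diploid chrY calls (pseudo-autosomal leakage, errors) are
unscorable rather than ancestral; missing calls ('.') are unscorable in
both modes. Pileup input uses the majority base among reads passing depth
(default ≥ 2), base-quality (≥ 13) and mapping-quality (≥ 20) thresholds;
ties are unscorable.

Candidate terminals are cutoff-passing haplogroups supported by at least
one derived key marker; when none exists (typical for array data), the same
procedure runs over all cutoff-passing haplogroups. For each candidate the
tracking rate t = (Σ Rᵢ)/r is computed over **all** r levels of its
root path — a level with no scorable markers contributes Rᵢ = 0, a
deliberate conservative choice (the alternative, summing only scorable
levels, would let sparsely covered deep tracks look fully supported).
Selection maximizes t with deterministic tie-breaks: greater r, more
key-derived levels, lexicographically smallest terminal. The cutoff U
defaults to 0.7: it tolerates one miss among small marker sets while
rejecting single-coincidence matches. "Most markers derived" in the
candidate-collection step is implemented as the same cutoff U.

Terminal refinement descends from the selected key terminal through
children whose (ordinary-marker) rate passes U, choosing the
highest-rate child (then lexicographic) at each step; supporting derived
markers are recorded in the output's mutation column.

A consequence of max-t selection worth knowing: a deep track is capped by
its weakest level, so a single badly genotyped internal level can make the
classifier stop above it (the all-passing prefix track has t = 1.0). With
realistic marker densities (~10 markers per haplogroup, as on recent
ISOGG trees) and 5% per-site error this is rare (per-level failure
~0.1%); with very sparse panels (≤ 5 markers per node) terminal recovery
degrades to roughly 90% at the same error rate.

## Y-STR genotyping

The extension loop counts motif repeats greedily, in composition order,
over a window of current length |L| + s·(k+1) after k extensions; it
returns q as soon as q ≤ p, incrementing p otherwise. p strictly increases,
so termination is guaranteed; the iteration cap (default 30, above any
plausible human allele) converts pathological windows into no-calls.
No-call reasons are explicit: "truncated" (window shorter than the
reference span), "ambiguous" (non-ACGT inside the reference span),
"iteration-cap".

Compound loci ((TCTG)₃(TCTA)₉ and similar): the extension unit s is the
length of the **last** motif and extension effectively grows the terminal
block; which block the original procedure extends is unspecified, so the
choice is isolated in one function and documented here.

Read-based consensus: only reads spanning the locus ± 5 bp flank are used;
the call is the modal per-read repeat number, requiring ≥ 2 spanning calls
and modal fraction ≥ 0.6 — chosen to favour no-call over wrong call.
Indel-based genotyping shifts the reference p by (net indel length)/s for
in-frame nets, after trimming shared allele prefixes/suffixes; off-frame
nets and mutually overlapping indels are no-calls. DYS385a/b are genotyped
and reported as two independent columns.

The packaged locus table (`data/str_panel_synthetic.tsv`) carries the
standard locus names and motif compositions of the nested commercial kits
but **synthetic** coordinates; deriving real hg19/hg38 coordinates is out
of scope, and user panels with real coordinates are accepted via the same
schema.

## Population statistics

Fst/G_ST on haplogroup frequencies treats haplogroup identity as one
multi-allelic locus: H = 1 − Σpᵢ², H_S the unweighted mean within-population
H, H_T from the unweighted mean frequency vector, Fst = (H_T − H_S)/H_T,
negative estimates clamped to 0 (required for MDS distances). A
sample-size-corrected variant (n/(n−1) on within-H) is available behind a
flag. PCA operates at the population level on the column-centred frequency
matrix via SVD; eigenvalues are axis variances and sum to the total
variance. MDS is classical (Torgerson): double-centred −D²/2,
eigendecomposition, deterministic, no seed; on exact Euclidean input it
reproduces distances up to rigid motion.

Y-STR statistics: HD = n/(n−1)(1 − Σpᵢ²) over distinct complete
haplotypes; MPD with locus-mismatch (default) or squared-difference
metric; per-locus G_ST averaged over polymorphic loci. AMOVA is one level
(among/within populations), computed from the pairwise distance matrix via
the standard sums-of-squares identities (distances play the role of
squared differences, the usual convention for molecular data);
Phi_ST = σ²_a/(σ²_a + σ²_w) and its p-value comes from label permutations
under a caller-supplied seed. Hierarchical (region/population) designs are
out of scope.

Bayesian haplogroup prediction multiplies, over shared loci, the smoothed
reference frequency of the observed allele under each haplogroup, times a
prior (uniform by default). Smoothing adds a pseudocount (default 0.5) to
every allele bin at a locus (bins = alleles seen anywhere at that locus,
plus the queried allele), so alleles unseen under one haplogroup retain
non-zero likelihood. The packaged reference is a hand-built synthetic toy;
user references use the same TSV schema (haplogroup, locus, allele, count).

## Phylogeny and dating scaffold

Step one hangs samples as leaves under their haplogroup node, prunes
haplogroup nodes without sample descendants and collapses unary chains
(keeping the most derived label). Step two resolves each polytomy in post
order into a bifurcating subtree over its child units, each represented by
its lexicographically first leaf's sequence: UPGMA (scipy average-linkage)
or neighbor-joining (scikit-bio) on IBS mismatch distances, or Fitch
parsimony (exhaustive over rooted shapes up to 8 units, stepwise addition
beyond). Replacement preserves the backbone: preliminary-tree clades remain
clades. Without an alignment, polytomies break into a deterministic
caterpillar by sample-id order (with a warning). Sequence pairs with no
overlapping called sites get IBS distance 1 plus a warning. NJ's
trifurcating root is binarized deterministically by pairing the last two
subtrees in sorted order — root placement within a replaced polytomy is
arbitrary by construction.

Divergence-time estimation itself is delegated to an external Bayesian MCMC
program; this package generates its input bundle (PHYLIP-style alignment,
newick tree without branch lengths carrying '>lower<upper' calibration
annotations, control file) and parses its node-time summary (lines
`t_n<k> mean (low, high)`, node numbering: leaves 1..s in newick order,
internal nodes s+1.. in preorder). Built-in main-trunk calibration bounds
ship as configuration data (kyr, scaled by a configurable time unit); user
calibrations override them. Test fixtures for the parser are synthetic
stand-ins, labelled as such.

## Networks and TMRCA

Haplotype distance is Σ|Δrepeat| (stepwise-mutation-consistent; Hamming is
not used). The median-joining construction keeps, at tolerance ε, every
edge whose endpoints cannot be connected by edges lighter than w − ε;
candidate medians are locus-wise medians of connected triplets, added one
at a time (strict spanning-length improvement, deterministic sorted order)
until a fixed point, then obsolete medians are pruned. Total spanning
length never increases when a median is accepted, and the greedy result
matches the exhaustive Steiner-augmented-MST optimum on the small instances
where that optimum is computable. fdi export (taxon records with
multiplicities and population composition, link records with weights,
deterministic circular layout) is byte-stable and round-trips through the
package's own parser.

rho = multiplicity-weighted mean shortest-path mutational distance from a
designated root node; T = rho/μ with μ per haplotype per generation;
SE = √(rho·Σwᵢ²)/μ (wᵢ = multiplicity shares), stated in the output.
ASD = mean squared repeat difference from the ancestral haplotype over
samples and loci; T = ASD/μ with μ per locus per generation. Both report
generations and years (generation time default 30, configurable). ASD is
unbiased for star genealogies under symmetric single-step mutation; rho is
biased low by back-mutation cancellation once the per-locus mutation load
λ = μ_locus·T approaches ~0.4 (E|net displacement| ≈ λ(1−λ/2)), which is
why the rho recovery simulation uses a low load (20 loci, μ = 5·10⁻⁴,
depth 200, λ = 0.1, bias ≈ 5%) while the ASD simulation uses the standard
forensic-scale setting (17 loci, μ = 0.002, depth 200).

## Synthetic data: what it emulates, what it does not

Generators produce balanced marker trees with per-node key/ordinary
markers (default 10 markers per haplogroup, matching the marker density of
recent ISOGG trees; a fraction with derived = reference to exercise the
hidden-reference rule), multi-sample haploid VCFs with per-call error and
missingness and correct hidden-reference omission, STR-spanning reads with
the true allele embedded in random flanks (all-match CIGARs), and
star-genealogy STR tables (Poisson(μ·depth) symmetric ±1 steps per locus).
All are deterministic under a fixed seed.

Not emulated: alignment artifacts (soft-clips, indet CIGARs, stutter
noise), population structure beyond the star genealogy, linkage between
markers, contamination, or female samples. Passing tests therefore
demonstrate algorithmic correctness on clean, in-model data — error rates
on real sequencing data depend on upstream calling/alignment quality and
panel accuracy, which the tests do not measure.

## Problem sizes used in tests

Oracle and recovery suites use 100 random trees (≤ ~200 nodes), 60-sample
classifications, 1,000 randomized STR windows, AMOVA instances up to
n = 12, 20 ASD and 50 rho star replicates, and 100 polytomy-resolution
fixtures — sizes at which every independent oracle (exhaustive track
search, brute-force run counting, enumerated parsimony, naive SS loops,
lattice Steiner search) is itself computable exactly.
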