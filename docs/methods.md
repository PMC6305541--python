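# Methods

## The detection model

A prophage is treated, operationally, as a dense run of genes homologous
to known phage proteins.  Detection therefore has two ingredients: a
per-gene homology signal and a positional density model.

**Homology.**  Each CDS of the input genome may carry alignment hits
against a phage protein collection.  Hits are accepted at percent
identity ≥ `min_identity` (default 80, boundary inclusive) and e-value ≤
`max_evalue` (default 1e-5).  Identity is taken over the aligned region
as reported in the hits table; no coverage filter is applied.  By
default only the best hit per gene is kept (highest bitscore, ties by
lower e-value then lexicographically smallest subject id) — the
conservation call needs a single source phage per gene.  The source
phage is parsed from the subject id, by default the prefix before the
first `|`; a regex override handles other naming conventions.

**Density clustering.**  Each phage-homologous gene contributes one
point: its genomic midpoint ((start+end)//2), which is symmetric in
strand and gene length.  Points are clustered in 1-D.  The production
algorithm is HDBSCAN\* (mutual-reachability distances with core
distance over MinPts neighbours, minimum spanning tree, condensed tree,
excess-of-mass cluster selection), with `min_cluster_size =
min_samples = MinPts`.  MinPts — the minimum number of phage genes a
region must contain — is the single density parameter exposed to users;
its default of 4 is the smallest defensible phage cassette.  Because
excess-of-mass selection cannot choose the hierarchy root, a genome
containing exactly one dense group would come back all-noise; the
production path detects that outcome and retries allowing a single
cluster.  DBSCAN and OPTICS (extracting DBSCAN-like clusters at cut
`eps`, default 10 kb) are provided as alternatives, and a textbook
O(n²) density-reachability DBSCAN serves as the test oracle.  All paths
are deterministic; ties are broken by processing points in coordinate
order, and final labels are canonicalized (0..k−1 by leftmost member).
A cluster becomes a candidate region spanning min gene start .. max
gene end.  Circular genomes are clustered as linear; a prophage
straddling the origin would be reported as two regions.

## Evidence

Evidence is annotative, never eliminative: a region failing both tests
is still reported with its flags false.

**G+C deviation.**  A sliding window (default 1000 bp, step 100 bp)
moves over the whole genome; per-window G+C fractions give a mean μ and
*population* standard deviation σ (the windows enumerate the genome
rather than sample it).  A member gene is deviant iff its G+C (computed
on its genomic span; strand-irrelevant) is strictly above μ+σ or
strictly below μ−σ; the region is supported iff the deviant fraction is
≥ `gc_gene_fraction` (default 0.80, boundary inclusive).  Note a
structural property of this rule: μ and σ are computed over the whole
genome *including* any prophages, so when cassettes with shifted
composition occupy a large share of the genome (several 15–45 kb
cassettes in a 200 kb sequence) they inflate σ and mask themselves.
The rule is sharp when prophages are a small fraction of the
chromosome, the situation it targets in real (Mb-scale) genomes.  The
step of 100 bp balances resolution against cost; both window and step
are configurable.

**tRNA insertion sites.**  Phages preferentially integrate at tRNA
genes.  A region gains support when a tRNA lies inside it or within
`flank_distance` (default 2000 bp) of either boundary; qualifying tRNAs
are reported with their signed distance to the nearest boundary
(negative upstream, 0 inside, positive downstream).  The 2 kb default
is a pragmatic reading of "flanking"; note the flank is measured from
the *detected* boundary (the gene extent), which can sit inside the
true element.

**Conservation.**  Genes vote for the phage of their best hit; the
region is *potentially conserved* when the top phage's fraction of all
member genes (no-hit genes stay in the denominator) is ≥
`conservation_threshold` (default 0.80).  Ties go to the
lexicographically smallest phage id, with all counts reported.

## Benchmarking

Predictions are matched to reference prophage intervals (1-based
inclusive) under `any_overlap` — a single shared base pair counts, the
weakest defensible reading of "detected" — or `min_fraction(f)`, which
demands the overlap cover ≥ f of the reference length.  Many-to-one
matches count a reference once.  Sn = detected/total references;
PPV = detected/(detected + predictions matching nothing).

Cluster-validity indices operate on the 1-D midpoints with noise points
excluded (a labeling with fewer than two clusters after noise removal
is undefined and raises).  Silhouette uses the standard (b−a)/max(a,b)
form (singleton clusters score 0, the scikit-learn convention); Dunn is
min single-linkage separation / max diameter, returning +inf when every
cluster is a point mass; Davies–Bouldin is computed directly from its
centroid/dispersion definition (the scikit-learn implementation rejects
the legitimate all-singleton case, which scores 0).  DBCV follows its
published construction — all-points core distances (inverse-distance
power mean, dimension exponent 1 for 1-D coordinates),
mutual-reachability minimum spanning trees per cluster, density
sparseness = the largest internal MST edge (endpoints of degree > 1,
falling back to the largest edge for clusters too small to have any),
density separation = the smallest mutual-reachability distance between
clusters, validity = (separation − sparseness)/max(·,·), aggregated by
cluster size over the non-noise points.  All four implementations are
tested against brute-force evaluations of the defining formulas at
1e-9.

## The synthetic-data generator

The generator emulates the controlled setting the pipeline is validated
in: a chromosome of i.i.d. nucleotides at background G+C 0.45, with
non-overlapping prophage cassettes (default 3, 15–45 kb) whose
composition is shifted +0.10, separated from each other and from the
genome ends by ≥ 10 kb of background.  Genes are tiled left-to-right:
600–1200 bp (multiples of 3), gaps of 20–150 bp inside cassettes
(10–30 genes each) and a background density of ~0.9 genes/kb outside —
typical bacterial coding density.  With probability 0.5 a tRNA (75 bp)
is placed within 2 kb of a cassette boundary; occasional background
tRNAs are kept > 5 kb from cassettes so flank truth stays unambiguous.
Every cassette gene receives a hit to its cassette's phage at identity
U(85, 100), minus a 5% dropout; background genes draw a spurious hit at
rate 1%, at identity U(82, 98) so that spurious hits *survive* the 80%
filter and act as genuine clutter for the clustering.  CDS translations
are computed from the emitted sequence (table 11) so the annotation is
internally consistent.  Output is byte-reproducible for a fixed seed.

What the generator does **not** model: codon structure and
reading-frame realism, sequence-level homology (hits are declared, not
aligned), decayed/cryptic prophages, repeat-driven integration, and
real phage gene content.  Passing tests on this generator demonstrates
the pipeline's signal processing — clustering, composition statistics,
bookkeeping — not performance against real databases.

## Study sizes and numerical choices

The recovery study runs 20 genomes of 200 kb with 2–4 cassettes (for
4-cassette genomes the cassettes are drawn 15–30 kb, the feasible range
under the 10 kb spacer constraint) and hit noise 1%/5%; pooled Sn and
PPV both reach 1.0 at the documented defaults.  G+C-rule behavior is
characterized on single-cassette genomes (150 kb, cassette 15–25 kb,
shift +0.12 ≈ 3 window-σ), where 100/100 cassettes are supported, and
on uniform-composition controls (shift 0), where support is essentially
never granted.  These sizes keep each property measurable in seconds
while staying in the regime the method assumes (cassettes small
relative to the genome for the G+C rule; ≥ MinPts genes per cassette
for the clustering).

Degenerate inputs are defined rather than fatal: fewer phage genes than
MinPts → all noise, zero regions, exit 0; genome shorter than one G+C
window → a single whole-genome window (warning); a gene with no
countable A/C/G/T bases → explicit undefined-G+C error; empty reference
list → Sn is NaN.  CDS with lengths not divisible by 3 are translated
on their longest in-frame prefix with a warning.

## Known limitations

Detection is purely homology-driven: a prophage with no relative in the
protein collection is invisible (composition evidence only reinforces,
it never initiates).  Region boundaries are gene extents, not
attachment sites (attL/attR are not modeled).  The G+C rule self-masks
when prophages dominate the sequence, as noted above.  Identity is
aligned-region identity without a coverage requirement, so short
high-identity alignments can pass the filter.  OPTICS at cut eps is
included for algorithm comparison, not production use.
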