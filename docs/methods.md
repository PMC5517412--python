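# Methods

`gbscore` reimplements, as one testable chain, the computational side of
a genotyping-by-sequencing (GBS) germplasm survey for a clonally
propagated crop: reference-free marker calling from barcoded
reduced-representation reads, Gower-distance redundancy screening to
build a core collection, complete-linkage clustering with bootstrap
supports, principal-coordinates analysis, and admixture-model structure
inference with Delta-K model choice. Because raw data of such surveys
are rarely deposited, the package ships a synthetic-germplasm generator
that reproduces the statistical structure those analyses assume, so
every stage can be validated against planted truth.

## The synthetic study design

The generator emulates a germplasm bank of a sterile, vegetatively
propagated species:

* **Population structure.** K_true latent populations diverge from
  shared ancestral allele frequencies under a Balding–Nichols model:
  ancestral frequencies p_l ~ Uniform(0.1, 0.9), population frequencies
  p_kl ~ Beta(p_l (1−F)/F, (1−p_l)(1−F)/F) with F the divergence
  (fst) parameter. Default design: 3 populations, fst 0.3.
* **Clonal redundancy.** Accessions are haploid binary haplotypes drawn
  from their population's frequencies. Clone groups (default sizes
  2/3/5/8/10) copy a founder haplotype and flip each locus
  independently at the somatic-mutation rate (0 by default; the noise
  design uses 0.002). Technical replicates are exact haplotype copies
  carried through library construction under their own barcode.
* **The library.** A uniform random ACGT genome (sized ~120 kb per
  requested fragment) is digested in silico with PstI (CTGCAG) and NspI
  (RCATGY, IUPAC honoured, both strands via palindromy). Only "mixed"
  fragments — one end per enzyme, 30–60 bp, no AlwI site (GGATC) on
  either strand — are retained, mimicking the assay's selective
  amplification. Both enzymes are modelled as cutting at the midpoint
  of their recognition motif, so every fragment begins with the PstI
  half-site and ends with the NspI half-site regardless of orientation;
  the real overhang chemistry is irrelevant downstream and not
  modelled. One fragment is a high-copy chloroplast-like decoy
  (copy weight 40, >10% of reads at the default library size) — the
  contaminant that motivates AlwI counter-selection in the real assay.
* **Polymorphism.** One biallelic SNP per chosen fragment (260 by
  default), planted away from the half-sites, plus whole-fragment
  presence/absence loci (20 by default) in a disjoint fragment set.
  Both classes are driven by the same population model.
* **Reads.** Single-end, 77 cycles: inline staggered barcode (5–8 nt,
  unique and prefix-free) + the accession's allele sequence + a fixed
  adapter fill. Depth per (sample, fragment) is Poisson(mean_depth ×
  copy_weight), default mean 20. Substitution errors are i.i.d. per
  base (default 0; the noise design uses 0.005) and drop the written
  quality from Q35 to Q12. Identical seeds give byte-identical FASTQ.

What the generator does **not** emulate: diploid heterozygosity (see
below), indels, PCR duplicates, depth overdispersion beyond Poisson,
chromosome structure, polyploid ("giant") accessions, or
quality-by-cycle decay. Passing tests therefore demonstrate the
*algorithms* recover planted truth under the stated noise model, not
that any particular wet-lab library would behave identically.

## Tag processing

Reads are demultiplexed by exact barcode-prefix match (the stringent
criterion; a mismatch budget is available but off by default), filtered
at mean Phred ≥ 20, trimmed, and truncated to the common tag length
`read_length − max(barcode length)` so all tags are Hamming-comparable
without alignment. Identical reads collapse into counted tags.
*Grooming* then merges every count-1 tag lying within Hamming distance
1 of a template tag (pre-grooming count ≥ 2) into that template —
highest count first, ties to the lexicographically smallest sequence,
singletons processed in deterministic order against the fixed
pre-grooming template set so corrections cannot cascade. Grooming
conserves total read mass and is idempotent.

## Marker calling

Tags pooled over samples are clustered by single linkage (transitive
closure) at Hamming distance ≤ 3. Sequences seen fewer than twice in
the entire dataset are excluded beforehand: they cannot contribute to
any marker (an allele must appear in ≥ 2 samples, a fragment needs
depth ≥ 5) and excluding them keeps the pairwise distance computation
tractable.

Within each cluster, candidate allelic pairs are tag pairs at Hamming
distance exactly 1, accepted when (i) the dataset-wide read-count
balance min(c1,c2)/max(c1,c2) ≥ `min_balance` and (ii) each allele is
observed in ≥ 2 samples; tags commit to at most one locus, greedily by
combined count with lexicographic tie-breaks. **On `min_balance`:** for
haploid dominant data the dataset-wide balance of a true allelic pair
is ≈ MAF/(1−MAF), so a threshold of 0.25 silently censors every locus
with minor-allele frequency below ~0.2. Error-derived and
paralog-like pairs sit orders of magnitude lower (recurring sequencing
errors reach ~0.3% of the major allele's count at the default error
rate). The default is therefore 0.02 — low enough to keep genuine
low-MAF loci, high enough to reject error recurrences — and the
parameter is exposed everywhere.

Each locus yields two presence/absence rows (ref/alt; a sample is
missing on both rows when its locus depth < 5). Unpaired tags become
dominant presence/absence ("SilicoDArT") markers: 1 at depth ≥ 5, 0
when the sample is covered overall (≥ 100 reads) but the tag absent,
missing otherwise; monomorphic rows are dropped. Markers are then
filtered on technical-replicate scoring consistency (< 0.95 drops),
mean read depth (< 10 drops, following the reported "over 10
reads/locus" quality bar) and call rate (< 0.8 drops), with per-filter
attrition reported. In the noisy synthetic design most error-derived
SNP loci die at the depth filter, and grooming removes the spurious
alt-presence calls that would otherwise trip replicate consistency.

## Redundancy screening and the core collection

Gower's distance for symmetric binary data is the simple-matching
mismatch fraction over the variables jointly observed in both samples
(missing entries shrink the comparison set; a pair with no shared
variable is an error). An asymmetric (Jaccard) switch is provided but
off by default: for dominant markers, shared absence of a restriction
fragment is genuinely informative. SNP and SilicoDArT matrices are
stacked with equal weight for all distance work.

Redundancy groups are connected components (size ≥ 2) of the graph
joining pairs at distance ≤ epsilon; each group's representative is the
member with the most complete data (ties: smallest id); the core
collection = unique accessions + one representative per group, so
|core| = n_total − Σ(group_size − 1) and the percent reduction is
100 × n_redundant/n_total (the formatter reproduces the published
417 → 286, 31.41% accounting exactly).

**Choosing epsilon.** The threshold separating "redundant" from merely
similar is not derivable from first principles, so it is configurable,
reported in every output, and calibrated by default as
max(inflation × max technical-replicate distance, floor) with
inflation 2 and floor 0.02. The floor matters: replicate pairs measure
*technical* noise only, and after quality filtering (which keeps
replicate-concordant markers by construction) replicate distances can
be exactly zero — yet genuine clone mates still differ by somatic
mutations at a small fraction of marker loci (~0.4% expected at the
simulated rates, with a tail well below 2%), while distinct accessions
under the simulated divergence differ at ≥ 15% of markers. A 2%
ceiling therefore reads as: redundant = more than 98% of dominant calls
agree.

## Clustering, supports and ordination

Complete linkage is implemented directly (inter-cluster distance = max
member pair distance) with a deterministic tie-break — merge the pair
whose smallest original leaf index is lowest — so results are exactly
reproducible and testable against an exhaustive reference. Branch
supports are plain bootstrap proportions: markers are resampled with
replacement, the tree recomputed, and an internal edge's support is the
percentage of replicates containing the same leaf bipartition.
Approximately-unbiased (multiscale) corrections are deliberately out of
scope; on well-separated synthetic populations the separating branch
reaches support > 90, mirroring the behaviour expected of strongly
supported germplasm clusters.

PCoA is classical Torgerson–Gower scaling: B = −½ J D² J,
eigendecomposition, positive eigenvalues kept (tolerance 1e-9 relative
to the leading eigenvalue), coordinates scaled by √λ, and PAVE
(proportion of analysed variance explained) = λ_m / Σ positive λ.
Euclidean inputs reconstruct their distances to 1e-8.

## Structure inference

The admixture model treats each marker row as a haploid biallelic
locus: dominant presence/absence scores cannot be decomposed into
diploid genotypes without an error model the data do not support, so
memberships are over haplotype-like profiles — a documented limitation,
not a bug. The pipeline feeds one presence row per SNP locus (the
ref-allele row); with haploid scores the two allele rows are exactly
complementary and using both would double-count each locus.

Duplicated genotypes — clone mates and technical replicates — violate
the model's assumption of unlinked, non-redundant data and measurably
bias model choice: with duplicates included the data probability keeps
rising past the true K (extra clusters can always absorb a clone
group), and the Delta-K ratio then hinges on which K happens to draw
the smallest between-run variance. The pipeline therefore fits the
sampler on the deduplicated core collection when the redundancy
partition is available (`dedupe=True`, the default) and afterwards
assigns every redundant member its representative's memberships — the
members were declared redundant precisely because they are genetically
indistinguishable at the markers. With `dedupe=False` the full panel
is used and a warning records the assumption violation.

Gibbs sampling per sweep: z_il ~ Categorical(q_ik p_kl^x (1−p_kl)^{1−x})
(missing loci skipped), p_kl | z ~ Beta(λ+n1, λ+n0) with λ = 1,
q_i | z ~ Dirichlet(α + counts) with α = 1 fixed (no hyperprior — kept
simple and testable; both priors are exposed). Posterior means are
accumulated after burn-in; the per-run data-probability estimate is
lnPD = mean(lnL) − var(lnL)/2 over the post-burn-in trace of the
z-marginalised observed-data log-likelihood. Runs are replicated with
derived seeds; label switching across replicates is repaired by greedy
correlation matching of Q columns.

Delta K = |mean L(K−1) − 2 mean L(K) + mean L(K+1)| / sd(L(K)), defined
for interior K of a contiguous range of length ≥ 3 with positive
between-run sd (flagged undefined otherwise); the selected K is the
argmax. With the survey's original K range 1–3 only K = 2 is interior,
so the library recommends widening the range (the acceptance
experiments sweep 1–5). Samples are assigned to argmax_k q_ik when that
membership reaches the threshold (default 0.8) and labelled "admixed"
otherwise; per-cluster mean memberships are reported as percentages.

## Pipeline, evaluation and problem sizes

`pipeline.run_all` chains the stages from one TOML-able config with a
single global seed; reruns are byte-identical. Cross-method concordance
is the pairwise adjusted Rand index between (i) the dendrogram cut at
the selected K, (ii) structure assignments (admixed samples excluded
and counted), and (iii) a complete-linkage cut of Euclidean distances
over the leading PCoA axes (enough axes for 95% cumulative PAVE,
between 2 and 5).

Truth-based evaluation on synthetic runs reports: exact group-level
recovery of planted identity groups (clone groups plus replicate
pairs); SNP sensitivity over *discoverable* planted variants — those
whose minor allele is carried by ≥ 2 sequenced accessions, since a
reference-free caller cannot report a non-segregating site — along
with the count of called loci matching no planted variant; and the
error-tag count (tags outside the truth allele set) before and after
grooming.

The default experiment sizes are chosen for single-workstation runs:
60 accessions, 300 fragments (260 SNP + 20 presence/absence loci),
depth 20, and a reduced MCMC for K sweeps (burn-in 2,000, 5,000 reps, 3
runs per K). The survey-scale MCMC settings (burn-in 10,000, 20,000
reps, 5 runs, K 1–3) remain the library defaults in `StructureConfig`
and `PipelineConfig`. On this design the noise-free run recovers 100%
of clone groups, 100% of discoverable SNPs with zero false loci after
filtering, selects K = 3 over a 1–5 sweep, and the three grouping
methods agree perfectly; the noisy run (0.5% error, somatic rate
0.002) keeps group recovery at 100% while grooming removes ~80% of
error tags. These numbers are recomputed, not asserted from memory, by
`scripts/acceptance.py` and the test suite.

## Known limitations

* Haploid genotype model end to end; heterozygous accessions would
  halve the information in the two-row SNP coding and the structure
  module would need a diploid likelihood.
* One SNP per fragment by default; multi-SNP tags are not parsed into
  haplotype series.
* The balance criterion is dataset-wide; a per-sample balance (natural
  for diploid heterozygotes) is not implemented.
* Bootstrap supports are plain proportions, known to be conservative
  relative to AU corrections for small trees.
* Evanno's Delta K cannot evaluate K = 1; when the truth is a single
  population the mean-lnPD fallback applies.
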