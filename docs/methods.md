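# Methods

## Model

A patient's tumor is modeled as a mixture of `n` clones: clone 1 is the
diploid normal (copy-number state (1, 1) everywhere) and clones 2..n are
tumor clones carrying somatic copy-number aberrations (CNAs) and possibly
one clonal whole-genome duplication (WGD). The genome is partitioned into
`m` clusters of bins; cluster `s` has one allele-specific integer state
(a_{s,i}, b_{s,i}) per clone, collected in matrices `A` and `B`
(m × n). Sample `p` mixes the clones with proportions u_{i,p} (columns of
the n × k matrix `U` on the simplex); tumor purity is μ_p = 1 − u_{1,p}.

The data determine, per cluster and sample, the allele-specific
*fractional* copy numbers f^A_{s,p} = Σ_i a_{s,i} u_{i,p} and
f^B_{s,p} = Σ_i b_{s,i} u_{i,p}. Inference runs in two stages: estimate
F^A, F^B from read counts, then factor F^A ≈ AU, F^B ≈ BU.

## Signals

* **RDR** (read-depth ratio): the tumor read share of a bin divided by
  its matched-normal share. It is proportional to the bin's total
  fractional copy number f with an unknown per-sample constant, because
  tumor read totals are normalized by the (unknown) average genome length
  of the mixture.
* **BAF** (mirrored B-allele frequency): minor-allele read fraction over
  heterozygous germline SNPs, in [0, 0.5]; equals min(f^A, f^B)/f in
  expectation.

Per-bin BAF is estimated by a two-component binomial EM that assigns each
SNP's minor side before pooling (naive min(ref, alt) pooling is biased
low near 0.5). Two further estimator subtleties matter:

1. **Folded-likelihood degeneracy.** At β = 0.5 the folded binomial
   mixture has zero Fisher information, so the EM/MLE estimate is biased
   below 0.5 at any depth. Cluster-level BAFs therefore use a moment
   estimator of δ² = (β − 1/2)²: E[(alt − T/2)² − T/4] = T(T−1)δ²
   side-independently, which is unbiased, with a snap to exactly 0.5 when
   the estimate is within twice its null standard error.
2. **Selection bias.** Clustering bins on their noisy folded BAF and then
   estimating cluster centroids from the same SNPs would confirm whatever
   noise drove the split. The SNPs of each bin are therefore split into
   two interleaved halves: clustering features use one half, cluster-level
   centroid estimation uses the held-out half.

## Global clustering

Bins are clustered jointly across samples on the 2k-vector of per-sample
(RDR, BAF), standardized per feature (scale floored at 0.02 so that
near-constant features are not noise-amplified), with a Dirichlet-process
Gaussian mixture (diagonal covariance, concentration prior 0.01, up to 50
components, 10 initializations keeping the best ELBO). Post-processing:
clusters below 0.1% of the clustered genome dissolve into the nearest
centroid, and cluster pairs whose centroids differ by less than tol_r
(default 0.04) in RDR and tol_baf (default 0.02) in BAF in *every* sample
are merged iteratively, closest pair first. The defaults reflect
cluster-level (not bin-level) centroid uncertainty at 30x coverage and
50 kb bins; pairs separated by a subclone below ~5% proportion are below
this resolution and will merge.

## Scaling to fractional copy numbers

RDR is proportional to f with an unknown per-sample factor γ_p. Under the
no-WGD hypothesis the largest cluster with balanced BAF in all samples is
taken as diploid (1, 1), giving γ_p = 2 / r_{anchor,p}. Under the WGD
hypothesis that cluster is (2, 2) and a second clonal cluster with a
distinct total ω is needed; candidate states are those reachable by one
single-copy gain or loss before or after the WGD ((2,0), (2,1), (3,2),
(4,2), (3,1), (4,3)). Candidates must be large (≥ 2% of the genome),
preserve their RDR/BAF ordering against other large clusters across
samples (a clonal state cannot flip), and give a consistent BAF when the
per-sample 2×2 linear system

    γ_p r_anchor,p + (ω_anchor − 2) u_{1,p} = ω_anchor
    γ_p r_z,p      + (ω_z − 2) u_{1,p}      = ω_z

is solved for (γ_p, u_{1,p}); the system is non-singular exactly when
r_anchor (ω_z − 2) ≠ r_z (ω_anchor − 2). Among adequate candidates the
largest cluster wins, ties preferring ω closest to 4. If no candidate
survives, the WGD hypothesis is dropped for the patient. Both scaled
matrices are carried into the factorization; choosing between them is
deferred to model selection.

## Factorization

The objective is the length-weighted L1 distance
D = Σ_s Σ_p ℓ_s (|f^A − (AU)| + |f^B − (BU)|), minimized under: the
normal clone fixed at (1,1); a_{s,i} + b_{s,i} ≤ c_max (default 12);
tumor proportions 0 or ≥ u_min (default 0.03; 0.15 is advisable for
noisy inputs); and the evolutionary side constraint that per cluster and
allele all tumor clones lie on one side of θ (1 without WGD, 2 with WGD)
— an allele cannot be amplified in one clone and deleted in another.

Coordinate descent alternates two exact updates:

* **Copy numbers** (U fixed): the problem separates by cluster. For up to
  four tumor clones the exact minimizer is found by enumerating the
  a-side state vectors (ordered by distance from (θ,…,θ) then
  lexicographically, which implements the tie-break) against an
  axis-accumulated prefix-minimum table over the b lattice that handles
  the a+b ≤ c_max coupling; beyond four clones a monotone per-clone
  block descent refines an exact 4-clone core.
* **Proportions** (A, B fixed): per sample, an LP over the simplex for
  each support set of tumor clones (semi-continuity handled by support
  enumeration), best support kept. Inside the descent loop a fast variant
  (relaxed LP + threshold + one refit) is used with a monotonicity guard;
  the best trajectory is polished with the exact update at the end.

Restarts (default 20 standalone, 8 in the model grid where warm starts
exist) draw U columns from a symmetric Dirichlet and, alternating, from a
uniform-purity scheme that reaches extreme purities more often. For n > 2
half the budget is seeded by splitting tumor clones of a quickly-fit
(n−1)-clone solution, mirroring how subclones arise. Converged restarts
with a nonzero objective attempt one escape move per tumor clone —
swapping its proportions with the normal clone — because a tumor clone
impersonating the normal is the most common local trap. Tumor clones
with identical state vectors are merged afterwards (proportions summed).

An exact mixed-integer program (HiGHS via scipy) over proportions
discretized to a 0.01 grid serves as a global oracle for small instances
(m ≤ 12, n ≤ 3, k ≤ 3); copy numbers enter the bilinear products through
a binary bit expansion with big-M linearization. Off the grid the oracle
can exceed the continuous optimum by at most c_max·(n−1)·grid/2 per
entry.

## Model selection

For each scaling hypothesis the factorization is fit for n = 2, 3, …
(warm-starting n+1 from n, so D is non-increasing), stopping when the
objective reaches the measurement-noise floor (within a factor 1.5),
when the relative improvement (D(n) − D(n+1))/D(n) drops below τ = 0.05,
or at n_max = 6. The noise floor is estimated empirically per cluster
and sample by split-half resampling — even vs odd member bins for the
RDR centroid, halved held-out SNP sets for the BAF — propagated through
the scaling; this captures estimator pathologies (such as the folded-BAF
noise) that closed-form binomial errors miss. The selected n* per
hypothesis is the smallest n reaching the floor, falling back to the
elbow.

Between the hypotheses, absolute or relative objective comparisons turn
out to be uninformative: the two scalings differ by a factor ~2 in f
units (biasing raw D toward the diploid reading) while the doubled
lattice is twice as fine in RDR units (biasing scale-normalized D toward
the WGD reading), and with spare clones both hypotheses descend to the
noise level. Worse, a diploid tumor with a single dominant clone admits
an exact genome-doubled re-interpretation (states doubled, purity
remapped to μ/(2−μ)), so even an oracle cannot separate the hypotheses
by fit. What cannot be faked is parity: the doubled re-interpretation
uses only even allele copy numbers, whereas a genuinely doubled genome
carries odd copies wherever a single-copy gain or loss happened around
the doubling.

The WGD call is therefore made before the factorization, directly from
the scaled matrices (`choose_hypothesis`): every cluster is matched to
its best single tumor-clonal state given per-sample normal proportions
(implied by the anchors under the WGD hypothesis; fit by a purity grid
search under the diploid one, with the misfit normalized by the clonal
lattice spacing so the purity→0 limit cannot win trivially). A cluster
counts as clonally explained when its residual is below 0.25 lattice
spacings per sample; the WGD hypothesis is accepted when at least 15%
of the genome is clonally explained by states with an odd allele copy
number. Both constants were fixed once on a 16-patient simulated
calibration cohort (seeds disjoint from any evaluation cohort), where
genuine WGDs showed odd-evidence fractions ≥ 0.16 and doubled-diploid
re-interpretations ≤ 0.11 (almost always 0). Working from the scaled
matrices rather than the factorization keeps the decision independent
of solver restarts, and only the chosen hypothesis is factorized.

When a model grid does contain both hypotheses, `select_solution`
additionally applies the subclonality trade-off (the WGD reading must
reduce the tumor-subclonal genome fraction, computed over clones with
at least 10% proportion somewhere; margins 0.01 with the same parity
tie-break).

The same asymmetry drives the WGD second-anchor search: each candidate
(cluster, state) pair implies per-sample (γ, u₁) via the 2×2 system, and
candidates are ranked by the genome-wide misfit to the clonal integer
lattice under that scaling, normalized per sample by the lattice spacing
(1 − u₁) — without the normalization, candidates implying near-zero
purity make the lattice arbitrarily fine and trivially fit everything. A
candidate must also keep its RDR/BAF ordering relative to the anchor
across samples; ordering relative to other (possibly subclonal) clusters
is deliberately not required, because a subclonal bystander crossing a
clonal cluster would otherwise disqualify a valid anchor.

Clusters are classified per sample (sample-clonal iff all tumor clones
present in the sample share one state; the diploid normal is background)
and across the tumor (tumor-clonal iff all tumor clones agree). Purity
and ploidy per sample derive from (A, B, U):
ρ_p = Σ_{i≥2} u_{i,p} L_i / (μ_p L) with L_i = Σ_s c_{s,i} ℓ_s.

## Simulator

The generator emulates multi-sample bulk sequencing of one patient at
the counts level. A random clone tree is drawn (first tumor clone off
the normal root, later clones off random tumor clones); each branch
receives CNA events per size class (defaults per branch: 6 focal
(0.1–1 Mb), 4 small (3–5 Mb), 3 medium (10–20 Mb), 2 arm, 1 whole
chromosome; ±1 copy on a random allele), and the optional WGD doubles
both alleles on the branch to the first tumor clone, making it clonal.
The genome is 22 autosomes with human relative sizes scaled to a
configurable total (3 Gb default; 100 Mb in the evaluation profile).

The critical accounting is that a clone's read share is weighted by its
genome length: v_{i,p} = u_{i,p} L_i / Σ_j u_{j,p} L_j, with per-segment
shares v_{s,i} = ℓ_s c_{s,i} u_{i,p} / Σ_j u_{j,p} L_j. Bin counts are
multinomial over these shares at a 30x-equivalent total read count
(coverage · genome / 100 bp reads); the matched normal is uniform over
the diploid genome. Heterozygous SNPs (one per 2 kb) put their alt allele
on a random haplotype; counts are binomial at the mixed haplotype
fraction with Poisson depth from the local genome content. Somatic
mutations are placed on random tumor branches and one haplotype; the
mutated-copy count is propagated through subsequent gains/losses (a gain
duplicates a uniformly random copy) and through the WGD, and variant
reads are binomial at the implied VAF.

Not emulated: GC/mappability bias, sequencing error, replication-timing
or coverage-variation effects, phased haplotype blocks (SNP phase is
i.i.d. per SNP). Passing tests therefore demonstrate correctness of the
method under its own generative assumptions at realistic count depths,
not robustness to real-data artifacts; a hook for a per-bin
multiplicative RDR correction exists for externally normalized inputs.

## Mutation consistency

Observed VAF v/T gets an equal-tailed 95% credible interval from
Beta(v+1, T−v+1) (uniform prior; boundary counts pin the corresponding
interval end). Predicted VAFs enumerate, per allele side and tumor
clone, mutated-copy counts 0..x_i (no homoplasy; the normal clone never
mutated; the all-zero assignment excluded; enumeration capped at 10^4
with random subsampling). A mutation is explained when some predicted
VAF falls in the interval; summaries exclude observed VAF < 0.2. CCF =
VAF (μ c̄_T + 2(1−μ)) / (m μ) with c̄_T the tumor-average total copy
number at the locus and multiplicity m the positive integer (up to the
maximum allele copy number) bringing CCF closest to 1 subject to
CCF ≤ 1.2, else the smallest attainable; clipped to [0, 1.5].

## Problem sizes and determinism

The evaluation profile uses 100 Mb genomes (2,000 bins at 50 kb), 2–4
clones, 2–3 samples, 30x counts — large enough that cluster centroids
are tight (relative count noise < 1%) while a 16-patient cohort runs in
minutes; the factorization benchmarks use m = 20 clusters. All
randomness flows from explicit integer seeds (NumPy Generator; the
DP-GMM through scikit-learn's random_state), and reruns are
bit-identical. Known limitations: subclones below ~5% proportion are
below clustering resolution; only one clonal WGD is modeled; clusters,
not locally segmented regions, are the unit of inference, so focal
events smaller than the bin size are invisible.
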