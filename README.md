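# clonecn

Joint inference of allele- and clone-specific copy-number aberrations
(CNAs), whole-genome duplications (WGDs), and clone proportions across
multiple bulk DNA-sequencing samples from the same cancer patient —
together with a counts-level simulator of such cohorts and a module that
checks inferred copy numbers against somatic-mutation allele frequencies.

## The problem

A bulk tumor sample superimposes reads from normal cells and from one or
more tumor clones that share clonal CNAs but differ in subclonal ones.
Deconvolving that signal is underdetermined sample by sample: many
combinations of copy numbers and mixing proportions explain the same
read-depth ratios (RDR) and B-allele frequencies (BAF), and a genome
doubling is notoriously easy to confuse with widespread subclonal gains.
`clonecn` attacks the problem jointly across all samples of a patient:

1. compute per-bin RDR and mirrored BAF (50 kb bins by default);
2. cluster bins globally along the genome and across samples — bins with
   the same copy-number state in every clone share one (RDR, BAF)
   signature in every sample;
3. scale cluster RDRs into allele-specific fractional copy numbers
   F^A, F^B under two hypotheses (with / without WGD), using a balanced
   anchor cluster and, for the WGD case, a second clonal anchor;
4. factor F^A ≈ A·U and F^B ≈ B·U with integer allele-specific
   copy-number matrices A, B (clusters × clones) and simplex proportion
   columns U (clones × samples), minimizing the length-weighted L1
   distance D = Σ_s Σ_p ℓ_s(|f^A − (AU)| + |f^B − (BU)|) under a maximum
   total copy number, a minimum clone proportion, and the constraint
   that no allele is amplified in one clone and deleted in another;
5. select the number of clones and the WGD status by an elbow criterion
   on D and parsimony across the two hypotheses.

The factorization is solved by coordinate descent with exact integer and
LP sub-steps; an exact mixed-integer oracle is included for small
instances. See `docs/methods.md` for the full model and the estimator
and solver details.

## Worked example

Simulate a 3-clone patient (two tumor clones, no WGD) with two bulk
samples on a 100 Mb genome at 30x, then run the pipeline:

```
clonecn simulate --out sim/ --seed 5 --clones 3 --samples 2 \
    --genome-length 100000000
clonecn run --tumor-counts sim/bin_counts.tsv --snp-counts sim/snp_counts.tsv \
    --out run/ --seed 5
clonecn summarize --run-dir run/
```

The summary printed for this seed is:

```
SAMPLE   PURITY  PLOIDY   WGD  N_CLONES  SUBCLONAL_FRACTION CLONES_PRESENT
    S1 0.495123 1.75067 False         3            0.310923          1;2;3
    S2 0.906650 1.72078 False         3            0.000000            1;2
```

Read: sample S1 is 49.5% tumor at ploidy 1.75 with no genome doubling
and both tumor clones present; 31% of its genome carries subclonal CNAs
(different states among the tumor clones present). The simulated truth
for this seed has purities 0.494/0.907 and two tumor clones, one absent
from S2 — both recovered. `run/clone_profile.tsv` holds the per-cluster
"a|b" states per clone and the proportion matrix; `clonecn explain`
scores a somatic-mutation table against them and reports the explained
fraction and cancer cell fractions (CCFs).

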