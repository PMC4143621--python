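# pedlod

Two-point parametric linkage analysis on extended pedigrees, with a
simulation framework for calibrating its false-positive behaviour on
null traits.

## The problem

Family-based sequencing studies test whether a variant cosegregates with a
disease through a pedigree. Two-point (single-point) parametric linkage
analysis scores each marker separately with a LOD score

    LOD(theta) = log10 [ L(theta) / L(theta = 1/2) ]

where `L(theta)` is the pedigree likelihood of the observed affection
statuses and marker genotypes under a parametric disease model and
recombination fraction `theta` between the marker and a hypothesized trait
locus. The classic genome-wide significance (GWS) threshold is LOD >= 3.3,
calibrated so that about 1 in 20 genome scans exceeds it by chance. Whether
that calibration survives when *millions* of sequenced variants are scored
in large pedigrees — and when the trait, though unlinked to every marker,
has a polygenic familial correlation — is an empirical question. This
package provides everything needed to study it at desk scale:

- **`pedigree`** — pedigree data model, pre-makeped LINKAGE / PLINK file
  I/O, marriage-graph loop detection and breaking (removal or duplication
  of a connecting individual), recursive kinship matrices.
- **`synthetic_data`** — generation of multi-generation pedigrees (30–90
  members), gene-dropped biallelic genotypes with a rare-variant-heavy
  frequency spectrum, optional founder-haplotype LD blocks, Haldane
  recombination, and masking of ungenotyped individuals (founders
  preferentially). Writes/reads PLINK `.ped/.map` and VCF.
- **`phenotypes`** — two null traits: a quantitative polygenic trait
  (heritability 0.68 by default, mean decreasing with age, multivariate
  normal with covariance `sd^2 (h2 * 2*Phi + (1-h2) I)` from the kinship
  matrix `Phi`) dichotomized at the 20% founder quantile, and a
  complete-null binary trait assigned at random with 10% prevalence.
- **`allele_freq`** — founders-only minor-allele frequency estimates with
  the 0.0001 floor for markers with no observed minor allele.
- **`linkage`** — exact Elston–Stewart peeling over the joint 16-state
  trait–marker diplotype space, two-point LOD at fixed `theta` or maximized
  over a grid, a brute-force enumeration oracle, and a batched genome-scan
  engine.
- **`evaluation` / `pipeline` / `cli`** — per-replicate significant-marker
  accounting, family-wise error rate (FWER) estimates with exact binomial
  intervals, MAF stratification, per-family LOD contribution profiles, and
  an end-to-end, fully seeded experiment runner.

The default disease model is the reduced-penetrance dominant model commonly
used for null-rate scans: disease allele frequency 0.01, penetrance 0.05
for `dd` and 0.5 for `Dd`/`DD`.

## Worked example

`examples/twopoint_lod_basics.py` builds a phase-known nuclear family under
a fully penetrant dominant model and prints:

```
4 nonrecombinant children: LOD(0) = 1.2041 (closed form 4*log10(2) = 1.2041)
1 obligate recombinant:   LOD(0) = -inf (impossible at theta=0)
                          theta_hat = 0.250, max LOD = 0.2272
```

Each unambiguous nonrecombinant meiosis contributes `log10 2 ≈ 0.301` to
the LOD at `theta = 0`; a single obligate recombinant makes complete
linkage impossible (likelihood zero, reported as `-inf`) and moves the
maximum-likelihood estimate of `theta` off zero.

`examples/null_calibration.py` runs the whole pipeline twice on shared
gene-dropped genotypes (5 pedigrees, 500 unlinked markers, 20 replicates):

```
           complete_null: 0/20 replicates with a GWS LOD; FWER estimate 0.000 (95% CI 0.000-0.168); mean significant markers 0.00
  dichotomized_polygenic: 0/20 replicates with a GWS LOD; FWER estimate 0.000 (95% CI 0.000-0.168); mean significant markers 0.00
```

Both traits are unlinked to every marker, so any GWS LOD is a false
positive; at this reduced marker count both scans stay clean, and the
family-wise inflation induced by the polygenic trait only emerges as the
number of (correlated) tests grows toward WGS scale.

The remaining examples cover the likelihood oracle
(`peeling_vs_enumeration.py`), the simulator and founder MAF estimation
(`simulate_study.py`), and trait parameter recovery
(`heritability_and_traits.py`).

A thin command-line interface wraps the same pipeline:

```sh
pedlod run-all --config cfg.yaml --trait-mode complete_null --seed 1 --out-dir out/
pedlod simulate --config cfg.yaml --out-dir study/
pedlod evaluate out/lods_rep*.tsv
```

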