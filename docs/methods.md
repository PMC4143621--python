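# Methods

## The two-locus pedigree likelihood

Each individual's latent state is an **ordered pair of two-locus
haplotypes**: a haplotype carries one allele at the hypothesized trait
locus (`d`/`D`) and one at the marker (major/minor), giving 4 haplotypes
and 16 ordered diplotypes. Phase is kept explicit: the 16-state space has a
simpler transmission algebra than the 10 unordered states and its cost is
negligible at this state-space size.

- **Founder prior.** Founders are draws from a population in linkage
  equilibrium between the two loci: haplotype frequency = (trait allele
  frequency) x (marker allele frequency), diplotype prior = product of the
  two haplotype frequencies. The trait allele frequency comes from the
  `TraitModel` (default `p(D) = 0.01`); the marker frequency is the
  founders-only estimate (below).
- **Transmission.** A parent passes each of its two haplotypes intact with
  probability `(1 - theta)/2` and each recombinant with `theta/2`;
  `theta` is sex-averaged (no sex-specific maps, no interference). A
  child's diplotype is the product of the paternal and maternal gamete
  distributions.
- **Evidence.** Affection status contributes the penetrance of the
  trait genotype (number of `D` copies; default dominant 0.05 / 0.5 / 0.5),
  `1 - penetrance` for unaffecteds, and 1 when unknown. A marker
  observation contributes the indicator that the state's minor-allele
  dosage equals the observed dosage; missing genotypes contribute 1.

The likelihood is the sum over all joint assignments of founder priors x
transmissions x evidence. On loop-free pedigrees it is computed exactly by
**Elston–Stewart peeling**, implemented as sum-product message passing on
the marriage graph (individuals and unions): nuclear families are peeled
onto connector individuals, parents are eliminated jointly (children are
conditionally independent given the parental pair), and every message is
rescaled to unit maximum with the log of the scale accumulated separately.
The rescaling keeps 90-member pedigrees at marker frequency 1e-4 in range;
a likelihood of exactly zero is reported as `-inf`. Multiple connected
components (e.g. after loop-breaking removals) multiply.

`brute_force_log_likelihood` is an independent oracle for pedigrees of at
most 8 members: it evaluates the same factorization as one unoptimized
`einsum` over the full joint state space — plain nested summation, no
peeling, no factorization of the contraction. States whose own evidence is
exactly zero are skipped, which removes only terms that are identically
zero. The test suite fuzzes 1000 random pedigrees against this oracle at
relative error 1e-10.

## LOD scores

`LOD(theta) = log10 L(theta) - log10 L(1/2)`, per family and summed.
At `theta = 1/2` the two loci segregate independently, so the denominator
factorizes exactly into (trait-only likelihood) x (marker-only likelihood);
the batched scan engine exploits this by computing the marker-only term
once per marker panel and the trait-only term once per replicate, and the
identity is asserted against the direct computation in the tests. Zero
likelihood at the tested `theta` (an obligate recombinant under full
penetrance) is a legitimate `-inf` LOD: it is reported, propagated into the
family sum, and excluded from significance counting (it is evidence
*against* linkage). Zero likelihood at `theta = 1/2` means the marker data
are Mendelianly impossible and raises an error naming the family — the
simulator can never produce it, so it indicates corrupted input.

`maximize_theta` evaluates the total LOD on a grid (default
`{0, 0.001, 0.01, ..., 0.5}`) and returns the arg-max with ties broken
toward smaller `theta`; values within 1e-9 LOD of the running maximum
count as ties, since flat profiles carry float noise far below that. The
pipeline's default policy evaluates `theta = 0` only, which is the standard
design for dense-marker two-point scans; the grid policy is available.

## The synthetic study

The generator emulates a family-WGS linkage study at desk scale; all
stages draw from `default_rng(SeedSequence(seed, spawn_key=(stage, ...)))`
with fixed stage codes, so any stage or any single replicate can be
regenerated in isolation and per-replicate randomness depends only on
(seed, replicate index).

- **Pedigrees.** Each family grows from one founder couple over
  `n_generations` (default 4): couples have `1 + Poisson(2.8)` children,
  and each non-terminal child marries a new founder with probability 0.65.
  Growth is resampled until the size lands in `pedigree_size_range`
  (default 30–90). Ages are drawn per generation stratum
  (`Normal(90 - 23g, 6)`, clipped to [1, 105]), so founders are oldest and
  the age trend in the trait is identifiable. Pedigrees are loop-free by
  construction (spouses are always new founders).
- **Markers.** Default spectrum: 70% of markers with MAF uniform on
  (0, 0.01], 30% on (0.01, 0.5] — a rare-variant-heavy spectrum of the kind
  WGS produces. The default inter-marker spacing (1000 cM) makes markers
  effectively unlinked, the design used for null-rate calibration; dense
  maps are obtained by shrinking the spacing.
- **Gene dropping.** Founder haplotypes are Bernoulli draws from the
  marker frequencies, or, when `founder_haplotype_pool = k > 0`, uniform
  picks from a population-level pool of `k` haplotypes per LD block
  (default block: 20 adjacent markers), which produces near-complete
  within-block LD for small `k`. Meioses recombine between adjacent
  markers with the Haldane fraction `(1 - exp(-2d/100))/2` of their map
  distance (0.5 across chromosomes). No genotyping error is simulated.
- **Masking.** `round(fraction x N)` individuals (default 30%) lose all
  genotypes; founders are 3x likelier to be masked, mirroring studies in
  which founders predate genotyping. Genotyped flags are updated on the
  pedigree members.
- **Traits.** The quantitative trait is multivariate normal per pedigree
  with mean `100 - 0.5 x age` and covariance
  `15^2 (h2 * 2*Phi + (1 - h2) I)`, `Phi` the kinship matrix and
  `h2 = 0.68` by default; it never sees a genotype. The baseline mean,
  slope and SD are arbitrary but identifiable — only `h2` and the sign of
  the slope matter to the design. Dichotomization estimates a **single**
  cutoff: the 20% quantile (linear-interpolation estimator, the common
  statistical default) of founder values pooled across **all** generated
  replicates, then labels `value < cutoff` affected per replicate
  (strictly below: a degenerate distribution yields zero affecteds). The
  complete-null trait assigns affected status i.i.d. at 10% prevalence.

## Founder allele frequencies

Per marker: minor-allele count over `2 x` genotyped founders. Markers with
no observed minor allele — including markers where every founder is masked —
take the floor 0.0001 rather than raising, because the pipeline must score
every marker; the count of floored markers is logged. Non-founders never
contribute, even when many founders are masked (the estimate is unbiased
only in founders; the accuracy cost for rare variants is accepted as part
of the design being studied). If the raw frequency exceeds 0.5 the allele
labels *and* the dosage orientation (and the generator's `true_maf`
bookkeeping) are flipped together, so dosages always count the estimated
minor allele.

## Loop handling

Loops are independent cycles of the marriage graph (one node per
individual, one per union; edges spouse–union and union–child), found with
a cycle basis; a loop is *inbreeding* when some union on it joins spouses
with a common ancestor, else *marriage*. Likelihoods are only computed on
loop-free pedigrees; the two breaking strategies are (a) removal of a
connecting individual, cascading to its descendants by default (the
connecting line must be pruned for the loop to open; the cascade is
logged), and (b) duplication: the original keeps its parents and loses its
children, the copy becomes a founder with the same phenotype/genotype data
and receives the children (ids `<id>__dupN` keep files self-describing).
Duplication double-counts one genome; that approximation is acceptable for
null-rate estimation, which is this package's purpose, and both operations
fail loudly if the targeted loop survives.

## Evaluation

A marker is genome-wide significant when its total LOD is `>= 3.3`
(boundary inclusive); 1.9 is the suggestive threshold. Non-finite totals
are excluded from counts and maxima. The FWER estimate is the fraction of
replicates with at least one GWS marker, with a Clopper–Pearson exact 95%
interval (appropriate for the small counts these scans produce). MAF
strata of significant markers are nested (floor 0.0001 ⊂ <0.01 ⊂ <0.05).
Family contribution profiles label each significant marker
`driver_1_2_suggestive` (1–2 families above 1.9), `diffuse` (no family
above 1.0 and 2–5 above 0.5), or `other`. A cross-replicate report lists
markers significant in more than one replicate.

## Heritability recovery

`estimate_heritability_from_sibs` residualizes trait values on age (pooled
least squares), takes **one sib pair per sibship** (the first two
children), double-enters the pairs and doubles the Pearson correlation.
Restricting to one pair per sibship keeps pairs mutually independent so
the Fisher-z interval is valid; using all within-sibship pairs is unbiased
but clustered, and its nominal interval under-covers. Pair observations
from different trait replicates are independent draws and are pooled.

## Problem sizes

The calibration suite uses 10 pedigrees (~500 individuals), 2000 unlinked
markers and 200 complete-null replicates for the FWER bound
(`<= 5% + 3 binomial SE`), and 50 paired replicates on shared genotypes
for the directional contrast between the two null traits (one-sided paired
sign test at alpha 0.05 — the run fails only if the complete-null trait
produces significantly more GWS scans than the polygenic trait). The
acceptance script recovers h2 from ~60 pedigrees x 30 replicates (~20k
sib-pair observations, Monte-Carlo SE ~0.014) and the founder affected
percentage from 20 pedigrees x 50 replicates. These sizes are the
package's chosen desk-scale study design; WGS-scale marker counts are out
of scope, so headline counts from million-marker scans are treated as
qualitative context, not reproduction targets.

## What the simulations do and do not show

Passing tests demonstrate: the likelihood engine is exact (oracle
equivalence), the LOD identities hold, the complete-null FWER at LOD 3.3
is controlled at these problem sizes, the polygenic null trait does not
produce *fewer* false positives than the complete null, and the trait
generator reproduces its own parameters. They do **not** demonstrate
behaviour at 8-million-marker density, under real LD structure beyond the
block-pool model, with genotyping error or imputation artifacts, with
monozygotic twins, liability classes, covariates, or looped pedigrees
analyzed intact — all outside this package's scope.
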