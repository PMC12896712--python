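# Methods

## The simulated study system

The package studies genomic prediction for a small target cattle
population (A) whose reference set is enriched with individuals from
two related donor populations (B, C). All three populations are
simulated forward in time at the haplotype level.

**Shared ancestry.** The populations branch from one ancestral base
cohort simulated under random mating (the `common` section of a run
profile). A shared base is a structural requirement, not a
convenience: cross-population prediction transfers information through
QTL that segregate in both populations and through marker–QTL linkage
phase that is consistent across them. Populations simulated
independently from scratch share neither, and donor-only references
then predict the target at r ≈ 0 regardless of sample size. All three
populations also share one trait architecture (the same QTL positions
and effects), calibrated on the target population's founder cohort.

**Divergence histories.** After the split, each population runs its
own short historical phases that shape its allele-frequency spectrum
and LD: A stays at moderate size and expands (fastest LD decay);
B contracts and re-expands; C passes through a strong terminal
bottleneck (slowest LD decay, largest differentiation from A). Census
sizes interpolate linearly within a phase; mating is random with an
equal sex ratio; no migration. Loci start at frequency 0.5 in the base
generation and drift freely; recurrent mutation (default 2.5 × 10⁻⁵
per locus per generation) toggles alleles between the two states.

**Meiosis.** Per chromosome, crossover counts are Poisson with mean
equal to the map length in Morgans, crossover positions are uniform,
and the starting parental strand is a fair coin. Marker and QTL loci
ride on the same haplotypes; markers are neutral and never enter the
trait model.

**Trait and phenotypes.** QTL effect magnitudes are Gamma(0.4, 1)
with random signs, rescaled by a single constant so that the founder
cohort's TBV variance equals h²·Vp = 0.42 exactly. Phenotypes are
y = μ + TBV + e with e ~ N(0, 0.58); each record is independently
missing with probability 0.05.

**Recent phase.** Ten discrete generations of truncation selection:
every dam produces one offspring per generation by random sire–dam
pairing; EBVs for all recorded animals come from pedigree BLUP
(Henderson's MME with the sparse A-inverse and the true variance
ratio); the configured fractions of sires (e.g. 0.6) and dams (0.3)
with the lowest EBV are culled each generation and replaced by the
highest-EBV same-sex offspring. The last four generations are
genotyped; the first three of them form the reference, the final one
the validation set (its phenotypes are never used in any fit).

## Reference-set construction

For each donor: (1) per-SNP Weir–Cockerham Fst between the target's
and the donor's genotyped cohorts; (2) SNPs with Fst strictly above
0.1 are retained; (3) each phenotyped, genotyped donor individual is
ranked by the Euclidean distance between its allele-count vector and
the target's per-SNP mean vector (centroid) on the retained SNPs —
centroid aggregation is O(n) and gives the same ranking as mean
pairwise squared distance; `mean_pair` and `min_pair` are available as
options; (4) the nearest floor(k·n) donors (k = 10/15/20%) join the
target reference ("cross" scenario) or stand alone ("signal"
scenario). Selection ties break by ascending id so scenario
construction is a pure function of its inputs.

## Prediction models

All models solve Henderson's mixed-model equations with a single
overall mean as the fixed effect and λ = σe²/σa².

- **GBLUP**: random effect covariance G*σa² over reference ∪
  validation animals, G = ZZ′/Σ2pᵢ(1−pᵢ) with Z column-centered by
  2pᵢ (allele frequencies from that same animal set; monomorphic SNPs
  dropped), blended G* = 0.95·G + 0.05·I so G* is invertible.
  Centering is applied although the printed cross-product formula
  omits it; `center=False` reproduces the literal formula.
- **ssGBLUP**: H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹] on the genotyped
  block. The pedigree side uses the ancestor closure of reference ∪
  validation; phenotyped non-genotyped ancestors of the *reference*
  animals contribute records (validation-side ancestors do not, so the
  signal/cross contrast is not diluted through the pedigree). A⁻¹ is
  assembled sparsely by Henderson's rules with inbreeding taken from
  the tabular-A diagonal, so it is the exact inverse.
- **wGBLUP** (two-step): SNP-effect ridge BLUP with W = I, then
  window weights Wⱼ ∝ mean of α̂ₖ² over the 2S+1 window around SNP j
  (S = 20, truncated at chromosome ends, scaled to mean 1), then one
  refit with the new W; GEBV = Zα̂. The ridge is solved in the
  n-dimensional dual, exact for any W.

Variance components default to the true simulated values
(λ = 0.58/0.42); an EM-REML estimator (verified against a direct
Nelder–Mead optimization of the restricted likelihood) is available
with `variance_components: reml`.

Equivalence identities used as oracles: with W = I, shared centering
and an unblended (or vanishingly blended) G, SNP-ridge GEBVs equal
GBLUP GEBVs exactly; with G* := A₂₂, ssGBLUP collapses to PBLUP. The
0.05 blend exists only to guarantee invertibility and is switched to
1e-8 in the identity tests, since exact equivalence requires the same
kernel on both routes.

## Scoring

Accuracy is Pearson's r between GEBV and true breeding value on the
target validation generation; dispersion bias is the regression slope
b = Cov(GEBV, TBV)/Var(GEBV) with its OLS standard error (b ≈ 1 means
neither inflated nor deflated predictions). `run_grid` repeats the
entire pipeline per replicate with seeds derived from one master seed
and emits a tidy per-replicate table; two-way ANOVA or any other
external statistics can be applied to that table directly.

## Desk-scale study conditions

The shipped `desk` profile runs the full design in minutes: genome of
5 chromosomes × 100 cM with 4000 markers and 725 QTL; base cohort of
200 for 80 generations; divergence phases of 12–22 generations; recent
phase with the full-scale sire counts (50/55/50) but the dam side
scaled to ~200 per population. Three scaling choices matter and were
fixed from first principles:

- **Sire counts are not scaled down.** Per-generation inbreeding is
  ΔF ≈ 1/(8Nₛ) + 1/(8N_d); dividing sires by ten would multiply ΔF
  roughly tenfold and collapse the additive variance within ten
  generations — a pure scale-down artifact.
- **Marker density is preserved, not marker count.** The full design
  has ~18 markers/cM; stretching a few thousand markers over the whole
  2715.85 cM map leaves QTL untagged, which over-disperses GEBVs
  (b ≪ 1) and hides heritability from REML. At 8 markers/cM (about
  4 SNPs per QTL), EM-REML recovers h² ≈ 0.42 and b ≈ 1.
- **The QTL count stays at 725.** Gamma(0.4) magnitudes concentrate
  variance in few loci; cutting the QTL count makes per-replicate
  accuracy and bias erratic because one or two large QTL dominate.

The `paper` profile carries the full-scale design (29 chromosomes,
2715.85 cM, 50k markers, 1095 historical generations, ~2000 dams per
population); it is structurally identical but takes hours and is not
exercised by the test suite.

## Parameter-recovery experiments

`crosspop_gs.benchmarks` re-measures the printed simulation parameters
end to end. Heritability and unbiasedness are measured on drift-only
control runs (selection disabled): truncation selection genuinely
depletes the realized additive variance of later generations (Bulmer
effect plus selection-induced drift — Var(TBV) falls from 0.42 to
≈ 0.35 by generation 9 under the default intensities), so the
configured h² is the estimand only in an unselected cohort. This is a
property of the biology, not of the estimators; the selected-population
runs are the basis of all scenario comparisons.

Measured at desk scale (10 replicates, master seed 1): mean EM-REML
h² = 0.438, mean b = 1.013, accuracy ≈ 0.63 within the target
population.

## What the generator does and does not emulate

It emulates: multi-breed divergence with realistic Fst levels
(≈ 0.10–0.12 between target and donors, per-SNP values spanning
0–0.6), LD decay declining with distance at population-specific rates,
family structure under truncation selection, missing phenotypes, and
the reference/validation generation layout. It does not emulate:
genotyping error or array ascertainment (a post-hoc masking utility
exists but is off by default), dominance or epistasis, genotype ×
environment interaction, overlapping generations, or migration.
Passing tests therefore demonstrate internal consistency of the
method chain under an additive, cleanly genotyped world — not
performance on real multi-breed data.

## Numerical choices and degenerate inputs

Centered G is singular along the all-ones vector; anything that
inverts G goes through the blend. Negative per-SNP Fst estimates are
reported as-is (screening uses a strict threshold and is unaffected);
loci monomorphic in both populations are flagged and reported as 0.
Zero-variance markers are dropped from G and skipped (counted) in LD
profiles. All-zero SNP-effect vectors yield uniform window weights
with a warning. MME solutions are checked by their normal-equation
residual (< 1e-8 relative); rank-deficient systems fall back to a
pseudo-inverse with an estimability warning. Every stochastic
component draws from a generator seeded deterministically from the
master seed, so identical seeds give bit-identical studies.

## Known limitations

The desk-scale donor pools are small (≈ 800 candidates), so donor-only
references carry little information and the gain of the cross design
from 10% to 20% donor enrichment, while consistently positive, is
small compared to its full-scale counterpart. ssGBLUP across
populations uses the raw G*/A₂₂ splice without metafounder or
compatibility tuning, which penalizes its signal-group (donor-only)
accuracy. EM-REML is exact but slow near flat likelihoods; the
iteration cap (500) is generous for the shipped designs.
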