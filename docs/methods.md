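# Methods

This note documents the models behind `cfprs`, the defaults and why they
were chosen, and what conclusions the synthetic experiments can and cannot
support.

## Reference panel and subjects

The phased reference panel is produced by a copying-mosaic process on a
single pseudo-chromosome (default 20 Mb, uniform genetic map at 1 cM/Mb,
1-based coordinates, VCF conventions).  Candidate sites (default 5,000)
are placed uniformly; per-site founder allele frequencies are drawn from
U(0.05, 0.95); a small founder set (default 20 haplotypes) is sampled
site-independently; every further haplotype copies segments from all
previously generated haplotypes, switching template as a Poisson process
on the genetic map (default 1 switch/cM) and flipping the copied allele
with a small mutation probability.  Sites with panel MAF below a floor
(default 0.05) are dropped; at the defaults ~4,400–4,600 of 5,000
candidates survive.  Template switching is what creates linkage
disequilibrium that decays with genetic distance — the property the
haplotype-copying imputation exploits — and the test suite asserts that
decay directly (mean pairwise r² below 0.1 cM exceeds that beyond 5 cM).

A mother is generated by the same copying process *from* the panel, so she
is related to, but not a verbatim member of, the reference.  Her mosaic
density and private-variant rate are the two knobs that set how well the
panel represents subjects, and they are deliberately low (defaults:
0.01 switches/cM, 1e-4 flips/site).  The rationale: the study design this
package emulates draws subjects from the same population as a
production-scale imputation reference, where a subject's haplotypes are
locally near-perfect panel mosaics.  A 200-haplotype desk panel can only
reproduce that regime by high relatedness.  Diagnostics during development
showed the residual imputation error at 1.0x under denser mosaics
(0.5 switches/cM) is dominated by mosaic-boundary windows and private
variants and is insensitive to the HMM's switch intensity; matching the
intended "near-perfect high-coverage imputation" regime therefore fixes
these generator defaults, not the HMM.  With them, dosage r² at 1.0x is
≈0.997–0.9995 and the 1.0x-vs-30x PRS correlation sits at ≈0.9995.

The fetus carries one recombinant of the mother's two haplotypes
(crossover count ~ Poisson(map length in Morgans), breakpoints uniform on
the genetic map) and one paternal haplotype generated as an independent
panel mosaic.  Mendelian consistency is asserted on every simulated pair.

## cfDNA pileups

Per-site read depth is Poisson(coverage); each read is fetal with
probability FF, copies one uniformly chosen haplotype of its origin
individual, and flips its observed allele with error probability ε
(default 0.005; base error is not a quantity the emulated assays publish,
and 0.5% is a conservative post-alignment figure for short-read data).
Fragment lengths are truncated normal — maternal mean 166 bp, fetal mean
143 bp (the published peak positions for maternal vs placental cfDNA),
sd 15 bp, bounds [50, 400] bp; only the two peak locations are
literature-anchored, the spread is a free parameter.  Reads are
independent across sites: with panel sites kilobases apart and ~0.25
reads/site, one fragment essentially never covers two panel sites.
Down-sampling keeps each read independently, and the suite checks the
composition property that down-sampling a deep simulation is
distributionally equivalent to simulating the shallower coverage.  The
fragment-length filter simply drops reads below a length floor before
genotyping — the in-silico size selection intended to deplete fetal
fragments.

## Forced genotyping

Likelihood triples P(reads | g) for g ∈ {0, 1, 2} are computed at every
panel position ("forced" positions) from the symmetric error model
P(alt read | g) = (g/2)(1−ε) + (1−g/2)ε, in log space, then normalized
per site; a zero-depth site carries (1/3, 1/3, 1/3).  Per-site scaling is
harmless because the HMM uses the triples as emission factors.  Hard calls
(for the high-coverage arm) take the argmax and mark sites missing below a
depth floor (default 4) or at uniform triples.  No base qualities exist in
the pileup abstraction, so a single error parameter is the entire model.

## Diploid haplotype-copying imputation

The hidden state at each site is an ordered pair (h₁, h₂) of panel
haplotypes.  Between adjacent sites each haplotype independently switches
with probability r = 1 − exp(−n_eff·ΔcM/K), landing uniformly on any of
the K haplotypes (so a "switch" can land on itself); at a site each copied
allele miscopies with probability μ, and the emission is
Σ_g lik(g)·P(g | alleles(h₁), alleles(h₂), μ).  A single scaled
forward–backward pass over the K² states yields per-site posterior
genotype distributions; the dosage is the posterior mean.  The recursion
is exact — no pruning, no pre-phasing, no iterative re-phasing — which is
what makes it verifiable against brute-force path enumeration (the suite
checks equality to 1e-10 at K=3, L≤5).

Defaults: n_eff = 4 (satisfying the calibration requirement that 1.0x
imputation reach dosage r² > 0.99 under the default simulation; accuracy
is flat in n_eff over 1–60, so the value is uncritical), μ = 1e-3,
K_sub = 60.

Cost: transitions factorize per haplotype, so one site costs O(K²); at
the default L ≈ 4,500 and K_sub = 60 one sample imputes in ~0.25 s.
Before running, the panel is collapsed to a copying subset of K_sub
haplotypes chosen by *windowed* allele sharing: the map is cut into 10
windows, each informative site contributes its naive expected alt
fraction, and per-window top scorers are pooled (trimmed/topped-up to
K_sub by total score).  Windowing matters because a haplotype that
matches the target over one segment only can be invisible to a global
score; under the defaults the K_sub = 60 posterior is indistinguishable
from the full K = 200 run.  Full-panel mode (`panel_subset=None`) remains
available and is what the oracle tests use.

Fetal reads are deliberately unmodelled: the HMM assumes a pure diploid
maternal sample, and the mixture experiments measure what that mismatch
costs.  Numerical safeguards: emissions are floored at 1e-300, each
forward/backward step renormalizes, a fully-contradictory (underflowed)
site resets to uniform, and a degenerate forward–backward overlap falls
back to the forward marginal; posteriors are asserted finite and
normalized to 1e-9 in the suite.

## PRS

PRS_j = Σᵢ βᵢ·g̃_ij / M_j over the markers of a scoring panel, where g̃ is
the effect-allele dosage (2 − d when the effect allele is the site's ref).
M_j is the matched non-missing marker count — the per-marker-average
convention.  Any common affine rescaling of scores leaves cross-sample
Pearson correlations and rank-based high-risk labels unchanged (asserted
in the suite), so this convention cannot affect any reported comparison;
it is fixed only for reproducibility.  Markers match a site when position
and unordered allele pair agree; strand-flip resolution is out of scope
because synthetic alleles carry no strand ambiguity (a real-data caveat).
Missing dosages (possible in the hard-called arm) are dropped from both
the sum and M by default; mean imputation as 2×AF is available.  Synthetic
scoring panels draw markers uniformly from panel sites with weights
~ N(0, 1) and a random effect-allele orientation.

## Experiments and evaluation statistics

All experiments are deterministic functions of (config, master seed);
reports embed both, and every stage's randomness comes from seeds spawned
off the master.

* **Coverage** (FF = 0): each subject's 30x pileup is down-sampled in
  silico to 1.0x and 0.2x, mirroring how real down-sampling reuses one
  library.  Low arms are imputed; the 30x arm is hard-called.  Default 10
  subjects × 20 replicate cohorts, scores pooled before correlating.
* **Mixture**: fetal fractions 0/5/10/15% at 0.25x, 7 replicates each,
  default 40 pairs and a 2,000-marker panel; per-sample scores are
  averaged over replicates and each FF arm is correlated against the
  FF = 0 arm (the baseline convention for this study); per-sample
  deviation bias and spread are reported alongside.
* **Cohort analog**: default 450 samples with FF ~ U(0.03, 0.20) — the
  emulated screening population reports FF only as a range, so a flat
  draw over the plausible clinical interval is used — 0.25x cfDNA arm
  imputed, 15x gDNA arm hard-called.  Scoring panels of nominal sizes
  {50, 500, 2000, 5000} (the largest capped at the available site count),
  two per size.  Reported: per-panel Pearson (Spearman as diagnostic),
  correlations stratified by FF (median split into low/high) and by panel
  size, and top-5% high-risk misclassification.

Misclassification is rank-based: each score vector flags its own top
⌈q·n⌉ samples (q = 0.05), ties broken by stable sample order, and the
rate is the fraction of discordant labels — checked against an
independent sort-based oracle in the suite.

Problem sizes above (panel scale, cohort sizes, replicate counts) are the
package's default desk scale: large enough that correlation estimates are
stable to the third decimal, small enough that the full acceptance run
completes in minutes on one CPU.

## What the simulation does and does not show

The generator reproduces the *mechanisms* that matter for this question —
LD-driven imputability, Poisson coverage sparsity, maternal/fetal mixture
with Mendelian structure, origin-specific fragment lengths — under
conditions where the panel represents subjects extremely well.  Passing
tests therefore demonstrate the pipeline's correctness and the *direction*
and rough magnitude of the coverage and FF effects, not clinical
performance: real panels are orders of magnitude larger but represent
subjects less perfectly; real cfDNA has GC bias, mappability artifacts,
duplicated fragments and base-quality structure, none of which are
modelled; real scoring panels have heterogeneous per-marker quality.
Two consequences worth naming:

* Correlation vs panel size is essentially flat here: with i.i.d.
  synthetic weights both the between-sample score spread and the
  imputation-error contribution scale the same way with marker count, so
  the size axis is reported as a diagnostic table rather than asserted as
  a monotone trend.
* The fragment-length filter shows its positive control (with disjoint
  length distributions it removes exactly the fetal reads and recovers
  accuracy) and, with the default overlapping distributions, the
  trade-off between fetal-signal removal and coverage loss.  Which regime
  a given real assay sits in depends on the true length-distribution
  overlap, which the simulator does not claim to know.

## Known limitations

Single pseudo-chromosome; biallelic SNVs only; no population structure or
admixture; no joint maternal–fetal model (the fetal haplotype is noise to
the HMM, not a target); FF is a simulation input, never inferred; no
genome-build or strand handling in scoring-file matching beyond exact
allele identity.
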