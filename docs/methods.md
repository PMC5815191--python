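# Methods

## Model structure

The simulator tracks resistance to two insecticides, each governed by a
single biallelic locus (R = resistance, S = susceptibility), in a randomly
mating, effectively infinite mosquito population with separate sexes and
non-overlapping generations. The state variable is a pair of gamete
(haplotype) frequency vectors, one per sex, over {S₁S₂, S₁R₂, R₁S₂, R₁R₂}.
The model is deterministic: selection and recombination are the only forces.
There is no mutation or migration (resistance alleles are assumed
pre-adaptive, present at the starting frequency), and no genetic drift in
the primary engine.

Each generation applies, in order:

1. **Random union of gametes.** Offspring diploid frequencies are the outer
   product of the female and male gamete pools. The sex ratio is 1:1 and
   both sexes have the same genotype distribution at birth; exposure is the
   only sex-differentiated quantity.
2. **Selection.** Per sex, diploid frequencies are multiplied by the sex's
   marginal fitness and renormalised by mean fitness. Marginal fitness
   mixes two exposure classes: a fraction *x* (the sex's exposure) contacts
   every currently deployed insecticide simultaneously, the remaining
   1 − *x* contacts none. Within a class, fitness is the product over loci
   of the single-locus genotype fitnesses (multiplicative mixture
   interaction; no synergism, antagonism or cross-resistance). A mixture is
   treated as a single co-formulated product, so both insecticides must
   declare the same exposure per sex; unequal mixture exposures are
   rejected rather than silently averaged.
3. **Meiosis.** Every diploid transmits its two parental haplotypes with
   probability (1 − c)/2 each and the two recombinants with probability
   c/2 each, where c ∈ [0, 0.5] is the recombination rate. This rule is
   uniform across genotypes (for non-double-heterozygotes the recombinants
   coincide with the parentals).

The event ordering (union → selection → meiosis) is one of several
equivalent conventions for this model class; alternatives permute the same
maps and give identical dynamics.

## Parameters

Per insecticide (all proportions): effectiveness (default 0.5), exposure per
sex (0.5), resistance restoration (0.5), dominance of resistance (0.5),
starting R frequency (0.01, strictly inside (0,1)), cost of resistance (0)
and dominance of cost (0). Global settings: recombination rate c (default
0.5 — the loci are taken to be on different chromosomes or far apart; the
published generation counts were reproduced under this choice), resistance
threshold (0.5), generation cap (500). Parameter validation is strict
(reject, not clamp) everywhere except calibration, where field data
routinely produce out-of-range estimates (see below).

## Strategies and metrics

*Time-to-resistance* for a locus is the smallest census generation at which
its sex-averaged R frequency is ≥ the threshold, read at integer
generations with no interpolation; a run that reaches the generation cap
reports a not-reached sentinel. The sex-averaged (unweighted mean)
frequency is the headline statistic; with equal sex exposures, as in every
bundled preset, female and male frequencies coincide.

* **single** — one insecticide deployed throughout; the idle locus evolves
  under cost selection only.
* **sequence** — insecticide 1 deployed until its locus crosses; the switch
  takes effect the following generation (the crossing generation counts
  toward phase 1) and is permanent — if costs later push locus 1 back below
  the threshold, insecticide 1 is not redeployed. Total time is the
  generation at which locus 2 crosses.
* **mixture** — both insecticides co-deployed every generation; total time
  is the first generation at which both loci have crossed.

The comparison statistic is mixture total time divided by sequence total
time, reported raw and rounded half-away-from-zero to one decimal (the
convention used for figure annotations); values below 1 favour the
sequence. Whole-generation counts and one-decimal rounding mean reported
ratios can differ by one rounding step from ratios recomputed from the
printed counts.

## Calibration from bioassay data

Genotype-specific survival (alive/(alive+dead) per genotype and arm) stands
in for fitness. All survivals are first divided by the unexposed SS
survival so the reference genotype has fitness 1 (quotients above 1 are
capped at 1 with a warning); if no unexposed arm exists, costs are assumed
zero and unexposed SS survival is taken as 1. The fitness equations are
then inverted:

    effectiveness  = 1 − w_SS(exposed)
    restoration    = (w_RR − w_SS) / effectiveness   (exposed)
    dominance      = (w_SR − w_SS) / (w_RR − w_SS)   (exposed)
    cost           = 1 − w_RR(unexposed)
    dominance_cost = (w_SS − w_SR) / (w_SS − w_RR)   (unexposed)

The dominance-of-cost expression is the interpolation coefficient implied
by the unexposed fitness construction (w_SR = 1 − h_z·z); it is the form
required for the round trip "derive parameters, rebuild fitnesses, recover
the input survivals" to close, which the test suite verifies. Exposure and
the starting frequency are properties of the setting, not the assay, and
must be supplied by the caller.

Clamps, each with a warning: any derived dominance outside [0, 1] is set
to 1 so SR matches RR — apparent underdominance is biologically implausible
for unexposed genotypes and typically reflects assay noise (e.g. control-arm
mortality from handling); restoration below 0 (exposed RR surviving worse
than SS, i.e. no resistance signal) becomes 0; restoration above 1 is capped
at 1. When the two homozygotes have equal fitness the dominance is undefined
and reported as 0, since every value yields the same fitness. Derived
parameters are carried at full precision; two-decimal rounding is applied
only in displayed reports. No statistical uncertainty is propagated —
bioassay genotype classes are often small, and the derived inputs should be
read as illustrative point estimates.

## Numerical conventions

Haplotype-frequency vectors are renormalised every generation and checked
against a 1e-12 tolerance; the one-locus closed-form selection recursion is
reproduced to 1e-10 over 100 generations. Zero mean fitness in either sex
raises an extinction error rather than propagating NaNs. Linkage
disequilibrium is D = f(R₁R₂) − p₁p₂ with D′ = D/D_max (D_max the tighter
marginal bound on the side of D's sign; D′ = 0 when D = 0 or a locus is
monomorphic).

## Finite-population check

`resistsim.montecarlo` implements a Wright–Fisher-style individual-based
counterpart (N diploids per sex; parents sampled proportional to their
sex-specific marginal fitness; gametes drawn from the same recombination
kernel). Its expectation is the deterministic recursion, and the test suite
checks agreement within three standard errors at N = 10,000 per sex after
20 generations. It exists as an independent check and a way to gauge drift
at realistic population sizes; the strategy runners never use it.

## Properties the model exhibits (and their boundaries)

* For sole use, time-to-resistance is non-increasing in effectiveness,
  exposure, dominance and restoration, and non-decreasing in cost.
* Higher effectiveness favours the mixture (each insecticide kills more
  individuals resistant to the other, protecting it); higher exposure
  favours the sequence; dominance, restoration and starting frequency shift
  both strategies similarly and leave the ordering unchanged.
* **Mixture protection.** While its partner is below the resistance
  threshold, an insecticide's resistance trajectory in a mixture is
  pointwise at or below its sole-use trajectory (verified over randomised
  scenarios at c = 0.5). The guarantee is tied to the partner being
  effective: after the partner locus crosses, its exposed resistant
  survivors reweight the exposed class and the focal trajectory can
  marginally overtake sole use (observed differences below 1e-3). Under
  tight linkage (small c), hitchhiking on the positive linkage
  disequilibrium a mixture generates can also erode the guarantee; the
  headline results assume unlinked loci.
* The sign of the mixture-vs-sequence difference is robust to moving the
  threshold between 0.25 and 0.75 on the bundled scenarios.

## Problem sizes

All bundled analyses iterate 4-element frequency vectors for at most 500
generations and complete in milliseconds; the property suite runs a few
hundred such scenarios plus five replicates of the N = 10,000
individual-based check, keeping the full test suite under a minute on one
CPU.

## Limitations

Monogenic resistance only (no polygenic/quantitative variation), no
insecticide decay over time, no rotations or mosaics, constant exposure,
no density dependence or malaria-transmission consequences. The
finite-population model exists only as a verification tool; operational
predictions from the deterministic engine ignore drift, which matters most
at the low starting frequencies where resistance emerges.
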