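# Methods

## Inheritance models and marker classification

Genotype calls count copies of allele B (0/1/2, −1 missing).  Hemizygous
males at heterosomal markers are emitted array-style as 0/2, mirroring how
SNP arrays report the X; a male heterozygous call there is never silently
corrected — it is counted as an inconsistency, because elevated male
heterozygosity is precisely the signal of pseudoautosomal behaviour.

Every complete trio is checked under two models:

- **pseudoautosomal**: the offspring genotype must be composable from one
  sire allele and one dam allele (the standard autosomal check);
- **heterosomal**: a male offspring carries a single maternal allele (a
  heterozygous male call is inconsistent; the sire is ignored, but a trio
  with any missing member is still uninformative); a female offspring
  carries the sire's hemizygous allele (a heterozygous sire call is itself
  inconsistent) plus one dam allele.

A marker is labelled heterosomal when its inconsistency rate is below 1%
under the heterosomal rule **and** at least 5% under the pseudoautosomal
rule, and symmetrically; everything else is undetermined.  The 1% floor is
the same threshold as the downstream QC filter; the 5% ceiling is our
choice of "materially positive" — real misclassified markers show far
higher contrast (≥ 9% vs ≤ 0.31% in the motivating data), so the exact
value is not critical, and both are configurable.  A determinate marker
whose label contradicts the unanimous label of its determinate neighbours
(2 each side, at least 2 found) is removed as discordant — these are
typically genotyping artifacts or misplaced markers.  Contiguous runs of
equal labels form segments.  QC for TRD scans keeps markers with ≥ 100
complete trios and < 1% inconsistency under the assigned model (≥ 10 trios
at preliminary intake).  Male heterozygosity is reported as a diagnostic
but not used for labelling.

## Transmission counts

At a heterosomal marker only heterozygous dams are informative.  Male
offspring resolve the maternal allele directly; female offspring need a
genotyped hemizygous sire (sire A: offspring AA→dam-A, AB→dam-B; sire B:
AB→dam-A, BB→dam-B).  Trios with a heterozygous sire call are excluded as
model inconsistencies rather than reinterpreted; we deliberately do not use
dam-only information for female offspring when the sire is ungenotyped,
since the maternal allele is then not identifiable.

At a pseudoautosomal marker, matings with exactly one heterozygous parent
resolve that parent's transmission; AB×AB matings resolve both parents for
AA/BB offspring, while AB offspring enter a dedicated ambiguous class.  The
ambiguous class is kept as a mixture term in the likelihood —
`P_s(A)P_d(B) + P_s(B)P_d(A)` — rather than split into fractional counts,
preserving the exact multinomial likelihood.  When only one parent is
modelled the mixture term is the constant 1/2 and drops out, which is why
single-parent fits reduce to closed form.

## Bayesian estimation

Allelic parameters have uniform priors on (−0.5, 0.5).  Dam-only,
single-stratum data reduce to `p = 0.5 + α ~ Beta(n_A + 1, n_B + 1)`; the
implementation uses this exact path whenever the model decomposes into
independent binomials, and otherwise a single-chain random-walk
Metropolis-within-Gibbs sampler with 110,000 iterations and 10,000 burn-in.
Proposals reflect at the bounds; the initial scale is 2.4 standard errors
of the count-based estimate and adapts toward ~40% acceptance during
burn-in only, so the retained chain is a fixed-kernel Markov chain.

Bayes factors use the Savage–Dickey density ratio at the null
(`BF = prior ordinate / posterior ordinate at α = 0`; prior ordinate 1 for
allelic, 1/2 for genotypic parameters).  The sampler path estimates the
posterior ordinate by Rao–Blackwellisation: the conditional density of the
tested parameter at 0 given the other parameters is computed by quadrature
on a 2001-point grid and averaged over 200 evenly spaced post-burn-in
draws.  For a single free parameter the conditional equals the marginal,
so the estimate is exact up to quadrature error; log-space accumulation
keeps ordinates of order 10^−20 representable.

The genotypic model reweights the Mendelian offspring-genotype expectation
of each mating class by (1 + α_g, 1 + δ_g, 1 − α_g) for (AA, AB, BB),
renormalised within the class, with uniform priors on (−1, 1) (all weights
are positive on the open box).  This parameterisation matches the sign
semantics of a recessive lethal — α_g < 0 with compensating δ_g > 0 — but
is one concrete choice among the genotypic-TRD variants in the literature;
absolute α_g/δ_g values are therefore comparable only within this
parameterisation.  Mating classes with zero total are skipped.

The empirical null ("probability of random TRD") simulates the resolved
transmissions as Binomial(n, 1/2) at the observed informative total,
applies the same posterior-mean estimator, and reports the upper-tail
class of |α̂| among {≤0.001%, ≤0.01%, ≤0.1%, ≤1%, ≤5%, >5%} with an
add-one adjustment.  10^6 replicates support the finest class; the
distribution is cached per informative total, optionally binned to two
significant digits for large scans.

`n_underrepresented` counts offspring carrying the allele (or genotype
class) whose modelled probability falls below the Mendelian expectation.

## Phasing and window scans

Phasing is rule-based and conservative: hemizygous male calls phase
trivially; female offspring take the sire's hemizygous allele as paternal
and the remainder as maternal; pseudoautosomal heterozygotes resolve only
when a parent is homozygous.  Unresolved sites are flagged and windows
containing a flagged site for an individual exclude that individual.  No
statistical imputation is attempted: on the complete, error-free data the
simulator produces, the rules resolve everything the likelihood needs, and
on real data dropping unresolved sites is strictly conservative.

Sliding windows (2/4/10/20 markers, step 1) never span a region-label
boundary.  Within a window, the dam's second haplotype is the elementwise
complement of the transmitted maternal haplotype against her genotype, so
each trio resolves the dam's phase without pedigree depth.  Each distinct
haplotype with pool frequency ≥ 0.5% is recoded in turn as pseudo-allele A
against all others pooled (the biallelic procedure) and analysed exactly
like a SNP.  Windows with < 10 heterozygous dams or < 50 informative
offspring are discarded.  The recessive scan tabulates female offspring of
heterozygous-carrier dams by sire carrier class and fits the genotypic
model, reporting observed versus Mendelian-expected homozygote counts.

Consolidation smooths per-window peak log10 BF along the marker index with
a Gaussian kernel (default bandwidth: the window size in markers), groups
significant windows (BF ≥ 100 and random-TRD class at the chosen level) by
interval overlap, and reports the member at the smoothed local maximum as
the representative.  This is a documented stand-in for an unspecified
multiple-testing smoother; the grouping, not the exact kernel, carries the
interpretation.

## Simulator

The simulator draws founder haplotypes at configurable allele frequency
(optionally with population LD decaying in map distance via a Markov
copying process, `founder_ld_scale`), assigns one offspring per dam with
sires used round-robin, and transmits:

- **dam meioses**: a recombinant mosaic of the dam's two X haplotypes under
  a uniform 1-Morgan map across the chromosome;
- **sire meioses**: the Y (sons) or X (daughters) heterosomal part without
  recombination, plus a PAR mosaic whose source switches at crossovers
  drawn on a PAR map (default 1 Morgan, linear in physical distance from
  the pseudoautosomal boundary).  The map-distance growth away from the
  boundary is what produces the opposite-sign sire-TRD between sons and
  daughters that decays with distance — the mechanism, not an injected
  effect.

Population-level sire-TRD needs population X/Y linkage, so a configurable
fraction of sires (default 1.0, for clean signatures) carries the same
all-A Y-borne PAR haplotype.  Allelic dam TRD is injected by choosing
between the two complementary gametes of a meiosis at a focal marker (or
focal haplotype) with `P(A) = 0.5 + α`, preserving the recombination
structure; at most one focal selection applies per meiosis.  Recessive
lethality removes homozygous female offspring by rejection, redrawing sex
as part of the rejection (a carrier×carrier mating can only contribute
surviving sons).  Genotyping error (random code replacement) and
missingness are applied last.

Default scale is 200 sires × 5,000 trios × 600 markers (500 heterosomal +
100 pseudoautosomal, spans 29,245–137,034,696 and 143,865,210–148,816,634
bp), which runs in seconds; larger designs scale linearly.  What the
simulator does **not** emulate: multi-generation pedigrees, realistic
allele-frequency spectra, selection, array-specific error modes, or
historical recombination beyond the one-parameter founder-LD process.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not robustness to every artefact of
real array data.

## Numerical and design notes

- Positions are 1-based inclusive bp; missing genotypes are never imputed.
- All stochastic routines take explicit seeds; a fixed seed reproduces
  byte-identical outputs.
- Zero informative transmissions yield a flagged result with no estimate
  and BF = 1; an empirical null at n = 0 is undefined and raises.
- Posterior means at the parameter bounds are handled by reflecting
  proposals; the open-interval guard (10^−12 of the width) keeps the
  likelihood finite.
- The "opposite sire-TRD" pattern label requires decisive BF (≥ 100) in
  both sexes with opposite signs; "single-sex" requires one decisive sex
  and log10 BF < 0.5 in the other (a configurable "null" threshold).
  Pattern labels are assigned with precedence opposite > single-sex > dam >
  recessive > unspecific, so the taxonomy partitions significant results.
- Sliding-window tests at desk scale use hundreds to thousands of trios
  and tens of markers — sizes chosen so the full suite exercises every
  code path in minutes while keeping Monte-Carlo tolerances (3 batch-means
  standard errors; 0.1 log10 units for Bayes factors) meaningful.

## Known limitations

- The genotypic parameterisation is not unique; published additive/
  dominance values under other parameterisations will differ even on
  identical counts.
- The empirical null simulates resolved binomial transmissions only; for
  windows it conditions on the informative total, not on the full mating
  composition, which is exact for dam-only scans and approximate
  otherwise.
- Rule-based phasing discards individuals with unresolved window sites
  rather than imputing them, which loses power on sparse real data.
- Trio sets are single-generation; sibling-pair and half-sib information
  is not used.
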