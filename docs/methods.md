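# Methods

`redqueen` is a forward-in-time Wright–Fisher simulator of PRDM9-dependent
recombination in which meiosis is modelled mechanistically, together with
the closed-form statistics that describe it and a mean-field layer for the
equilibrium regime. This note records the model, its assumptions, the
numerical choices, and what the synthetic study conditions do and do not
capture.

## The model

A population of `N` diploid individuals carries a single chromosome encoded
as `L` discrete slots. One slot is the PRDM9 locus (default: mid-chromosome).
Each PRDM9 allele recognizes `h` target sites at slots drawn uniformly among
the free slots at the allele's birth; different alleles never share sites.
Site `i` has a rescaled binding affinity `y_i = [P]_tot * K_i`; PRDM9 is
assumed non-limiting, so a site is occupied at chemical equilibrium with
probability

    x_i = c y_i / (1 + c y_i)

where `c` is the gene-dosage multiplier: `c = c_hom` (default 2 when dosage
is enabled, 1 otherwise) for homozygotes, `c = 1` for heterozygotes and
hemizygotes.

Each generation:

1. **PRDM9 mutation.** Every gene copy mutates with probability `u`,
   creating a brand-new allele with `h` fresh sites; the population is
   monomorphic for the active variant at each new site.
2. **Target mutation.** Every active site instance (per haploid copy)
   mutates to the inactive state with probability `v`. Inactivation is
   permanent and back-mutation is ignored.
3. **Reproduction.** Exactly `N` offspring are produced. Each gamete comes
   from a parent drawn uniformly with replacement; the parent gets up to
   `n_mei` meiosis attempts, and a fresh parent is drawn if all fail. The
   two gametes of an offspring are drawn independently (selfing possible).

One meiosis attempt: the two homologs replicate into four chromatids; every
active site instance of the carried alleles is bound independently with
probability `x_i`; with `k` bound instances in total, each receives a DSB
with probability `min(1, d/k)` (so about `d` DSBs per meiosis; `k = 0` is
failure). In the full model a DSB is *symmetric* if its site is bound on at
least one chromatid of the other homolog; meiosis fails without a symmetric
DSB, and one symmetric DSB (uniformly chosen) initiates the single
crossover: the chromosome arms beyond the CO locus, including the PRDM9
locus if it lies on that side, are exchanged between the broken chromatid
and one bound chromatid of the homolog. All DSBs — CO and NCO — are repaired
by copying the homolog's site state at the broken locus, which is what
implements biased gene conversion in favour of inactive variants (the
hotspot conversion paradox). One of the four chromatids becomes the gamete.
In the control model (`mode="control_no_symmetry"`), any DSB suffices and
the CO is drawn uniformly among all DSBs; everything else is unchanged.

Assumptions inherited from the modelled biology: repair never uses the
sister chromatid; exactly one CO per successful meiosis (a stand-in for CO
interference); conversion tracts cover exactly the broken site; target
sites are completely inactivated by a single mutation; no competition
between sites for PRDM9 (protein in excess).

## Closed-form statistics

For a genotype with occupancy moments `<x^k>` over its sites (inactive
sites contribute zero; moments are normalized by `h`), the probability that
a DSB falls at a symmetrically bound site is

    q_hom = (2<x^2> - <x^3>) / <x>
    q_het = (2<x^2>_i - <x^3>_i + 2<x^2>_j - <x^3>_j) / (<x>_i + <x>_j)

and fertility is `w = 1 - exp(-d q)` (the symmetric-DSB count is
approximately Poisson with mean `d q`). These formulas are tied to the
simulator by a Monte-Carlo test: empirical success frequencies of the
compiled meiosis kernel on fixed genotypes match `1 - exp(-d q)` within
Monte-Carlo error across affinity scales, DSB numbers and dosages. The
approximation degrades for deeply eroded genotypes (small `k`), where the
Poisson law and the `k >> d` assumption both weaken.

Haplo-insufficiency of an allele is `sigma = (w_hom - w_hemi)/w_hemi`, the
hemizygote computed at dosage 1; `sigma0` is its average over 100 fresh
alleles. The selection coefficient on new alleles, `s0`, is the mean log
fitness of probe alleles (created on the fly, paired as heterozygotes with
every segregating haplotype, never inserted) minus the population mean log
fitness, with fitness `1 - (1-w)^n_mei` (per-parent-draw success). Per-allele
`q` and `w` are carrier averages with weight 2 for homozygotes and 1 for
heterozygotes; population values are frequency-weighted. PRDM9 diversity is
`D = 1/sum f_i^2`.

## Affinity assignment

Site affinities follow an exponential law with mean `ȳ`. By default each
new allele receives the *same* affinity spectrum — the midpoint quantiles
of the exponential, permuted over its loci — rather than `h` i.i.d. draws.
Both choices give the exact exponential marginal across sites, but i.i.d.
draws give every allele an intrinsic, heritable "quality": with `h = 400`
the realized fresh-allele log fertility has a standard deviation of about
7e-3, an order of magnitude larger than the erosion-driven fitness
differences (~1e-3) that power the Red Queen. Under i.i.d. assignment the
polymorphic regime is then dominated by selection on allele quality:
standing alleles are a lucky, selected sample, random fresh probes measure
*negative* `s0`, and carrier-averaged fertility *rises* with allele age —
the opposite of the age-driven turnover this model is built to study, and a
dynamic in which the mean-field layer (which treats fresh alleles as
exchangeable, with a single `q0`) does not apply. Stratified assignment
removes the quality axis while preserving the affinity spectrum, and is
therefore the default study condition; `AffinityDistribution(...,
stratified=False)` restores i.i.d. draws for exploring the quality-driven
regime.

## Mean-field layer

With `g = d/(8h)` the net conversion rate per site per meiosis and
`rho = N v d/(2h) = 4Nvg`, the targets of an allele at frequency `f` erode
as `d theta/dt = -rho f theta`, and `z(t) = rho * Int f dt` (the intrinsic
age) is an analytic proxy for the cumulated erosion. Both relations are
*weak-erosion, quasi-stationary* statements: in simulation the realized
rate matches `rho` within 10% only after the pipeline of segregating
inactive variants has filled (about 100 generations at the test scale —
during the fill the flux is lower) and while erosion is mild (beyond
`1 - theta ≈ 0.2` the per-site rate accelerates, because the `d/k` DSB
probability concentrates the same `d` breaks on fewer active sites). Tests
and the acceptance checks therefore measure the rate inside that window.

`alpha`, the slope of log fitness against erosion, is estimated numerically:
fresh homozygote, top-affinity fraction `z` of sites inactivated (high
affinity sites are the ones preferentially converted), central finite
difference of `ln w(z)` around `z = 0.01`, averaged over 100 alleles at
dosage 1. The closed-form equilibrium approximations for mean erosion,
diversity and the inter-invasion time exist in the underlying theory but
are exposed only as user-registrable formula hooks
(`meanfield.APPROXIMATIONS`), none enabled by default; `tau` is instead
measured from trajectories as the mean spacing between generations at which
a new allele first exceeds frequency 0.1 (the threshold is this package's
operational choice). The regime classifier is: monomorphic if `4Nu <= 10`;
otherwise polymorphic if `sigma0 * tau < 3`, else eviction.

## Parameters and defaults

| name | meaning | default / range |
|------|---------|-----------------|
| `N` | diploid population size | preset-dependent (5000 in the published sets) |
| `u` | PRDM9 functional mutation rate per copy per generation | 5e-6 … 5e-4 (presets) |
| `v` | inactivating mutation rate per target copy per generation | 1e-7 … 5e-5 (presets) |
| `h` | targets per allele | 400 (one mouse chromosome ≈ 800 for calibration) |
| `d` | mean DSBs per chromosome pair per meiosis | 6 (8 or 24 in calibration) |
| `ȳ` | mean rescaled affinity | 0.2 (calibrated); 6 in the scaling reference |
| `c_hom` | homozygote dosage multiplier | 1 (off) or 1.5 / 2 |
| `n_mei` | meiosis attempts per drawn parent | 1 (up to 5) |
| `L` | genome slots | max(1e6, 200 h); slot exhaustion is a fatal error |

Presets (`experiments.preset`) reproduce the published parameter sets; each
accepts a `rescale` factor `lambda` that divides `N` and multiplies `u` and
`v`. This leaves `4Nu`, `4Nv`, `rho` and the equilibrium statistics
approximately invariant while shrinking runtime; the approximation degrades
as population-scaled selection (`2Ns` for the relevant differential) drops
toward 1, which in practice biases the symmetric-mode monomorphic erosion
upward at `lambda > 5`-10 and the neutral-control polymorphic erosion
downward (neutral allele lifetimes are O(N) generations and are *not*
rescaling-invariant). The acceptance script states the `lambda` and horizon
used for every run; they were chosen by runtime budget, largest population
first for the most drift-sensitive quantities.

A deliberate consequence of the illustrative presets: the spec of record
for the trajectory figures pins only `N`, `u` and `v`; this package runs
them at the calibrated affinity scale `ȳ = 0.2` (not the scaling-reference
`ȳ = 6`), because at `ȳ = 6` occupancy saturates (`x ≈ 0.86`), the
young-vs-old fertility differential collapses to ~1e-5, and the reported
dynamics (order-1e-3 differentials, replacement at ~20% erosion) cannot
occur.

## Numerical choices

* The meiosis attempt is one fused, numba-compiled kernel used by both
  `resolve_meiosis` and the generation loop; `bind_chromatids`,
  `place_dsbs` and `find_symmetric_dsbs` are NumPy reference
  implementations of the individual steps for tests and trace inspection.
* Binding at one column (4 chromatid instances) is drawn exactly from one
  uniform via the Binomial(4, x) CDF plus a uniform pattern decode;
  inactive copies are masked afterwards. DSB placement draws the
  Binomial(k, p) count and then a uniform subset of bound instances. Both
  are the exact joint laws of the per-instance Bernoulli description.
* Columns are kept sorted by genomic position (new alleles append to a
  tail that is merged at the next compaction), so the CO arm exchange is
  two contiguous copies; compaction also reclaims extinct alleles' columns
  and genome slots.
* Kernel randomness is an explicit xoshiro256++ state seeded once per
  simulation from the master seed; together with the NumPy generator used
  for mutations and probes, runs are reproducible bit-for-bit at fixed
  seed, independent of NumPy/numba internals.
* Degenerate cases: a genotype with no bindable site fails meiosis
  (`no_binding`); a fully eroded allele has `q = 0` and is flagged sterile
  rather than dividing by zero; `sigma` is undefined (error) for a sterile
  hemizygote; a population in which 1e6 consecutive parent draws fail
  aborts with a diagnostic rather than livelocking.

## What the synthetic conditions do not capture

The generator emulates the published study conditions, not real genomes:
a single chromosome, non-overlapping target sets, complete one-step site
inactivation, repair always from the homolog, one CO per meiosis, no
dominance differences between alleles beyond dosage, no population
structure, and non-overlapping generations. Passing tests therefore shows
that the mechanism — symmetric-binding-gated meiosis plus conversion-driven
erosion — produces the claimed regimes under these idealizations; it says
nothing about, e.g., partial-affinity mutations, sister-chromatid repair,
hybrid sterility, or multi-chromosome genomes (all out of scope).

## Known limitations

* The analytic `q`/`w` layer treats each haplotype's own-allele site states
  as shared by the genotype; segregating (unfixed) inactive variants make
  this an approximation, adequate at the erosion levels studied.
* The probe-based `s0` is doubly *shielded* in polymorphic regimes: a
  heterozygote's `q` weights each allele by its active-site mass `<x>`, so
  an eroded allele hides behind a fitter partner, and the population's own
  genotype `q` up-weights young partners the same way. The measured probe
  advantage is therefore an order of magnitude below the unshielded
  age differential `(alpha/2)·z̄` one might quote from per-allele fertility
  trajectories; both views are computed (`s0` and the per-allele `w`
  records), but only the literal probe statistic is reported as `s0`.
* Speed rescaling is trustworthy down to `lambda ≈ 5`-20 depending on the
  statistic (see above); full-scale runs at `N = 5000` reproduce the
  published operating points more closely but take hours per run.
* With i.i.d. affinities the model enters a qualitatively different,
  quality-driven regime (documented above) that the mean-field layer does
  not describe.
* `tau` requires at least two invasions after burn-in; monomorphic runs at
  small horizons can report NaN.
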