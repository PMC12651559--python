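# Methods

This note documents the models and procedures implemented in `replireset`,
the assumptions behind them, the defaults that matter, and what the
synthetic benchmarks do and do not demonstrate.

## Scope and overall design

The package covers the four bespoke quantitative procedures used to study
transcription–replication collisions (TRCs) and replication reset in
fast-growing *E. coli*:

1. pooled CRISPRi screen analysis — guide counting, negative-binomial count
   modelling, gene fitness, and differential-essentiality ("interaction")
   calling against a control condition;
2. Luria–Delbrück fluctuation analysis — the Ma–Sandri–Sarkar (MSS) exact
   pmf, maximum-likelihood estimation of the expected mutations per culture
   *m*, conversion to a per-generation rate µ, and one-sided comparisons;
3. flow-cytometry DNA-content quantification — kernel-density peak calling
   on DAPI intensities, linear signal→chromosome calibration, and
   chromosome-fraction summaries, plus the simpler plate-reader
   quantifications (reporter normalisation, plating viability, growth
   increments);
4. circular-genome coverage analytics — binning, counts-per-million and
   terminus-relative normalisation, replicate averaging with outlier
   trimming and loess-style smoothing, replichore asymmetry, degradation
   plateau detection, and strand-orientation statistics for DNA-end maps.

Because the real inputs are wet-lab measurements, every pipeline stage is
paired with a generator in `replireset.synth` that produces the same class
of data with known ground truth; the test suite and `scripts/acceptance.py`
quantify recovery of that truth.

The two components that are statistical models fitted to data follow the
statsmodels idiom: a model object constructed from data whose `fit()`
returns a results object with estimates, standard errors, and a
`summary()`. These are `FluctuationModel` → `MutationRateResults` and
`InteractionModel` → `InteractionResults`. The simulators and track/event
quantifications are plain functions over typed containers.

## CRISPRi screen analysis

**Counting.** A read is assigned to a guide iff its first 20 nt equal a
library sequence exactly; everything else increments an unmatched tally, so
`matched + unmatched = total reads` always. No mismatch tolerance is
attempted — with a 20-nt read there is no room for seed heuristics, and
exactness is what makes the planted-count benchmark meaningful.

**Normalisation.** Median-of-ratios size factors (computed over guides
detected in every sample, rescaled to geometric mean 1), then per-guide
method-of-moments NB dispersions `α̂ = max(0, (s² − µ̄)/µ̄²)` on normalised
counts pooled over replicate groups, with a robust (soft-L1) fit of the
trend `α(µ̄) = a0 + a1/µ̄`. The trend value at each guide's mean is the
final dispersion. There is deliberately **no** empirical-Bayes shrinkage of
dispersions or fold changes; the package keeps the estimator simple and
transparent, at the cost of noisier per-guide values, which the gene-level
median absorbs.

**Fold changes and gene fitness.** Guide log2 fold change uses a 0.5
normalised-count pseudocount and a delta-method SE with NB variance
µ + αµ². Guides with pre-induction normalised mean < 10 (configurable) are
excluded as low-coverage. Gene fitness is the **median** of its guides'
fold changes with SE `1.4826·MAD/√n`; the median tolerates the common
failure mode of one inactive guide.

**Interaction calling.** Gene fitness in the experimental condition is
regressed on the control condition by OLS over all shared genes. "Removing
the gene significantly improves the fit" is operationalised as the
externally studentized deleted-residual test: `t_i = e_i/(s_(i)·√(1−h_ii))`
with two-sided p-values on G−3 degrees of freedom, Holm-corrected, called
at family-wise α = 0.05. This is algebraically equivalent to the per-gene
leave-one-out F-test on the drop in residual sum of squares (t² = F), which
the test suite verifies by brute-force refitting. Calling is single-pass
(each gene is removed against the full-fit baseline; no iterative
re-removal).

The residual-normality assumption is only approximate — gene-level medians
of NB-noise fold changes form a scale mixture — so the null family-wise
error is expected to sit slightly above nominal; the benchmark checks it
stays within the binomial band around α. The screen scenario uses four
replicate lineages per condition, matching the duplicate-strain ×
duplicate-colony design such screens use.

## Fluctuation analysis

The mutant-count model is the classical Lea–Coulson ρ = 1 construction: a
culture grown to `N` cells accumulates Poisson(m) mutation events, each at
a uniformly random point of the exponential expansion, so a clone's final
size K has `P(K = k) = 1/(k(k+1))` (simulated as `⌊1/U⌋`, capped at N).
The resulting count distribution satisfies the MSS recursion

    p0 = e^-m,   pk = (m/k) · Σ_{j<k} pj/(k−j+1),

which `luria_delbruck_pmf` evaluates exactly; the generator and the
recursion agree to total variation < 0.01 at 10⁶ cultures, which is the
package's internal consistency check between its two independent
derivations of the same law.

`FluctuationModel.fit()` maximises the log-likelihood over m by bounded 1-D
search (bracket `[10⁻⁶, 10·(mean+1)]`, tolerance 10⁻⁶). The recursion is
evaluated to `K = min(max count, 512)`; counts beyond 512 contribute their
exact right-tail mass (a censored-observation likelihood), which keeps the
O(K²) recursion bounded without approximating the likelihood. The standard
error comes from the numerical observed information; the 95% interval is
Wald on the m scale, truncated at 0. At the 30-culture design scale this
interval shows ~0.95 empirical coverage in simulation.

µ̂ = m̂/N_t by default (per final cell ≈ per generation in binary fission);
`per_division=True` exposes the m̂/(N_t·ln 2) convention. Partial plating
(z < 1) is modelled in the generator (binomial thinning) but the estimator
assumes complete plating and warns when z < 1 is declared; a z-corrected
pmf is out of scope. Rate comparisons are normal-theory z-tests with the
requested one-sided alternative.

## Cytometry and plate-reader quantifications

**Peak detection.** Gaussian KDE (Silverman's rule by default; an absolute
bandwidth in AU can be given) evaluated on a 1024-point grid; peaks are
grid points where the density's first derivative crosses from positive to
negative, kept if their prominence exceeds 5% of the maximum density. For
multi-ploidy samples spanning 1–8 chromosome equivalents an absolute
bandwidth near 10–15 AU (at ~100 AU per chromosome) resolves all four
control peaks; Silverman's global rule over-smooths such strongly
multimodal samples.

**Calibration.** Signal is regressed on assigned integer chromosome number
(the orientation in which control peaks are plotted) and inverted for
conversion; for noise-free peaks `count(signal(n)) = n` exactly.

**Chromosome fractions.** Per-event chromosome estimates are binned around
integer targets with a ±0.45-chromosome window (values ≥ 0.5 are rejected
as ambiguous). With a 10% intensity CV the estimate at two chromosomes has
SD ≈ 0.2, so a ±0.35 window would systematically miss ~8% of genuinely
two-chromosome events; 0.45 captures 97.6% while still assigning each
event to at most one integer. This is the package's own default, chosen by
that closed-form argument.

**Viability and reporter.** Straight arithmetic with validation: percent
survival is the selective-plate CFU/ml over the titer-plate CFU/ml × 100
(invariant to common dilution rescaling); reporter values are
blank-subtracted fluorescence over blank-subtracted OD, scaled to the mean
untreated value; the exponential-phase growth increment is OD(6.5 h) −
OD(5.5 h) on the nearest samples of a 15-min grid (within 7.5 min).

## Circular-genome coverage

Tracks are fixed-width bins (default 1 kb) tiling the circle exactly once;
coordinates are 0-based half-open; every operation wraps. The reference
frame (length, oriC, terminus window, masked intervals, named loci such as
an inverted rRNA operon) ships as a default for *E. coli* K-12 MG1655 but
is entirely configuration — no coordinate constants appear in logic.

**Binning** length-weights partial overlaps, so the binned total conserves
the input signal. **Normalisation**: CPM (idempotent), optionally divided
by the mean CPM over the terminus window so depth reads as copy number
relative to the terminus. **Averaging/trimming/smoothing**: replicates are
averaged per bin; bins deviating > 5 rolling-MAD robust SDs from an 11-bin
rolling median are removed and re-imputed from neighbours; smoothing is a
circular tricube-weighted local linear regression with span 2% of the
genome by default (`span=None` skips smoothing, which profile-shape
detectors prefer — smoothing smears exactly the sharp boundaries they
localise).

**Replichore asymmetry** is the depth at a locus over the depth at the
oriC-equidistant point on the other replichore. Exactly at a
feature boundary the statistic is half-bin sensitive, so evaluation a few
bins distal to the feature is recommended (and used in the benchmarks).

**Degradation plateau detection.** A plateau is a maximal circular run of
bins whose per-bin slope stays within `flatness_tol` (default 5% of the
median depth, with isolated single-bin noise breaches bridged), whose level
range stays within `range_tol` (default 5% — a plateau is a *level*
feature, which also rejects long quasi-flat stretches of genuine
pyramids), and whose mean level lies below the mean of the two flanks'
linear trends extrapolated to the run centre by more than `depth_margin`
(default 2%). Runs are reported with their bp boundaries and level. On
monotone marker-frequency pyramids the detector returns nothing: maximal
runs there span whole slopes and fail the range test, and apex windows are
absorbed into those maximal runs.

**Orientation.** For stranded end maps, the per-bin orientation index is
(R − L)/(R + L); `away_fraction` is the fraction of total end signal on the
strand facing away from oriC along its replichore (forward strand on the
right replichore, reverse on the left). For a mixture with one-ended
fraction f₁ (one-ended ends all face away; two-ended ends split evenly),
the expectation is `f₁ + (1 − f₁)/2`, which the round-trip benchmark
checks at f₁ ∈ {0, 0.7, 1}.

## The replication simulator

Cells in steady exponential growth carry `generations_overlap + 1`
synchronous replication rounds. A cell of age `a` (steady-state density
`2·ln2·2^{−a}` on [0, 1)) has round r (0 = oldest) at arm fraction
`(a + G − r)/(G + 1)`; a round's two forks advance symmetrically on the two
replichores, and each round that has passed a locus doubles its copy
number. This reproduces the classical marker-frequency expectations:
origin:terminus ratio 2ⁿ for n overlapping fork generations, and a flat
profile after run-out (all forks complete, no initiations).

A configured stall locus interrupts run-out. One stall opportunity per
cell is taken by the first fork to arrive (with probability `p_stall`);
trailing re-initiated forks rear-end a stalled fork with probability
`p_rearend_given_stall`, creating a one-ended DNA end without breaking the
parental duplex. The fates are:

- **bypass** (no stall): the round completes;
- **frozen** (stall without rear-end, or any rear-end under Gam): the fork
  pair is held at the block — at the stall-arm fraction and the
  oriC-equidistant point of the sister arm — and persists as a
  non-integer chromosome equivalent (the Gam-stabilised intermediate);
- **reset** (rear-end without Gam): the stalled round's nascent replicore
  is degraded from the DNA end at the stall site through oriC to the
  sister fork; the blockage clears and the remaining rounds complete, so
  the cell reverts exactly one round (e.g. 4 → 2 chromosomes).

Two refinements are parameters of the truth record. `end_resection_bp`
lets the nuclease consume one additional nascent layer just beyond the
stall site (bounded below by the parental copy, which is never degraded).
`sister_escape` changes the reset bookkeeping: instead of the whole
nascent replicore being lost, the sister replisome — resolved at the point
where degradation catches it — finishes its arm, leaving the nascent
fragment distal to the capture point in place. The default (`False`)
gives the clean integer reversion; `True` is the state rendered in the
sequencing scenario, where the surviving distal fragment produces the
sharp depth step at the sister-fork locus that bounds the degradation
plateau, with the stalled-and-frozen fraction providing the matching step
at the block itself. Both behaviours are simplifications of a continuous
process: the simulator represents the *population snapshot at sequencing
time*, not the kinetics that produced it.

Rendering: run-out sequencing tracks are Poisson draws around
`depth × mean copy number` per bin; DAPI intensities are
`Normal(equivalents × AU, cv × mean)` truncated at 0; stranded end tracks
emit site reads on the away-facing strand (one-ended) or split evenly
(two-ended) plus per-bin Poisson background.

## Synthetic benchmark conditions

The generator defaults are the study conditions the benchmarks run under:
2000 genes × 5 guides (genome-scale CRISPRi library), 10⁷ reads per
sample, NB dispersion 0.05, 10 doublings of outgrowth, four replicate
lineages; 30-culture fluctuation assays at titer 10⁹; ~20 000–50 000
flow-cytometry events at 10% CV; 1-kb bins on a 4.64-Mb circular genome
with sequencing depth of order 10³ reads per bin per replicate and three
replicates. The reset scenario places the block at the inverted rRNA locus
(~503 kb from oriC on the left replichore), with two overlapping extra
generations, certain stalling, 80% rear-ending, and a partial run-out
window (advance 0.25 of an arm) so that bypassing forks populate the
flanking slopes. Stall kinetics (pause durations, rear-end rates) are not
quantified by the underlying experiments; `p_stall` and
`p_rearend_given_stall` are free simulator parameters, not estimates.

What passing these benchmarks shows: the estimators invert their own
generative models correctly at realistic noise and design scale. What it
does not show: robustness to real-data pathologies the generators omit —
PCR jackpots and guide-specific biases in screens, phenotypic lag and
partial plating in fluctuation assays, debris/doublet events and
compensation effects in cytometry, mappability and GC bias in coverage.

## Known limitations

- The interaction caller's t-null is approximate for median-aggregated
  NB fold changes; its family-wise error is checked against the binomial
  band rather than assumed nominal.
- The MSS estimator fixes mutant relative fitness at 1 and does not
  correct for partial plating or phenotypic lag.
- The replication simulator's synchronous, symmetric rounds cannot
  represent fork-level asynchrony; its frozen/reset states are end-point
  bookkeeping, not kinetics.
- Peak detection reports KDE modes; closely spaced ploidy states (< ~1.5
  bandwidths apart) merge.
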