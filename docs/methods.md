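# Methods

## Indices and group statistics

BMI and FMI are mass (kg) divided by a squared length (m²); inputs are
taken in grams and millimetres, the field convention for bat
morphometrics, and converted internally. The small-body filter uses
strict inequalities (weight < 40 g AND index < 8 kg/m²), so boundary
species are excluded. Group comparisons use one-way ANOVA for the
omnibus test and Tamhane's T2 for post hocs; T2 is implemented as all
pairwise Welch (unequal-variance) *t*-tests with Satterthwaite degrees
of freedom and a Šidák adjustment, p_adj = 1 − (1 − p)^m for m pairs.
Tamhane's procedure exists in several variants; T2 is the common
default when only the name is given. Degenerate inputs (any group with
n < 2, or zero variance in every group) raise rather than returning an
undefined F.

## IPGTT analytics

The dose is 2 g glucose per kg body mass delivered as a 100 mg/ml
solution; `dose_volume` is pure unit arithmetic. AUC is the **total**
trapezoidal area of glucose vs time (not incremental above baseline),
with time converted to hours so the unit is h·mmol/L; total AUC is the
only convention consistent with per-2-hour values several-fold larger
than the baseline rectangle. Per-cohort AUC defaults to the AUC of the
pointwise mean curve; the mean of individual AUCs is also offered (the
two coincide on a shared grid because the trapezoid rule is linear in
the values, but published summaries are ambiguous about which was
computed, so both are exposed). Per-timepoint comparisons use classic
mean-centered Levene for variance homogeneity and the equal-variance
Student's *t* (a Welch option exists but is not the default, matching
the named procedure). When a timepoint has no sampling variance at
all, the tests are reported as p = 1 for equal means rather than NaN.

## Promoter conservation and indels

Alignment coordinates are 1-based inclusive. A column is *universally*
conserved when every row carries the same base; a gap or N never
counts as universally conserved. A non-universal column is conserved
*within* a group when all group members agree; by default a gap shared
by the whole group does count there, on the grounds that a shared
deletion is shared history. The opposite convention is switchable
(`shared_gap_conserves_group=False`) because published conserved-site
counts do not state how shared-gap columns were treated. A group's
conservation level is 100·(universal + group-specific)/columns,
reported to one decimal.

Shared indels are maximal column runs gapped in **every** carrier and
ungapped in **every** non-carrier; the carrier set may be the union of
several group labels (the fruit-bat deletion is shared by both
fruit-bat groups, so neither group alone satisfies the
"non-gap in all non-members" condition).

## Tajima's relative rate test

For an aligned triplet (two ingroup taxa plus an outgroup), columns
containing any gap, N or other non-ACGT symbol are dropped (complete
deletion within the triplet, the common default of desktop phylogeny
tools). m₁ counts sites where taxon A differs while B equals the
outgroup, m₂ the reverse; sites where all three differ are
unassignable and ignored. The statistic is (m₁−m₂)²/(m₁+m₂) against
χ²(1); m₁+m₂ = 0 yields χ² = 0, p = 1. The test is exactly symmetric
under swapping the ingroup taxa and invariant to column order and to
triplet-constant columns.

The NJ tree is a fast distance-based surrogate for model-based
phylogeny reconstruction (which is out of scope): p or Kimura
two-parameter distances with pairwise deletion, neighbor joining via
scikit-bio, negative branch lengths clamped to zero. K2P saturation
(non-positive log argument) raises an error naming the offending pair.

## PWM scanning

PFM counts become frequencies via
(count + pseudocount·background)/(colsum + pseudocount) with uniform
background 0.25 and pseudocount 0.8 by default (a common JASPAR-tool
convention; both are configurable since only the scan threshold is
standardised). Log-odds are log₂(freq/background); the relative score
of a word is (raw − Σmin)/(Σmax − Σmin) over per-column extremes,
and scanning keeps every window at or above the threshold (0.99 by
default). All overlapping hits are reported — no greedy merging.
Reverse-strand hits are scored on the reverse complement and reported
with forward coordinates and strand "−". Windows containing N never
score. Hits found on a degapped alignment row can be mapped back to
alignment columns and intersected with a deletion event: *lost* when
fully inside, *truncated* when partially overlapping.

## Relative expression

Livak 2^−ΔΔCt with amplification efficiency fixed at 1 (perfect
doubling), justified when primer efficiencies are validated near 1; an
efficiency-corrected (1+E)^−ΔΔCt variant is exposed. Replicate wells
are averaged per role within a reaction, and replicates are averaged
at the ΔCt level (the standard Livak convention). The calibrator is
the species with the largest mean ΔCt, so the minimum fold is exactly
1. Folds are shift-invariant in Ct and invariant to uniform shifts of
the reference gene.

## Synthetic-data generators

The generators define the study conditions for all tests; they are
deterministic given a seed, with one named, salted PCG64 stream per
generator call so different generators (and different species within a
cohort) never share randomness.

**Morphometrics.** Per dietary group: lognormal weights, body length
= a·weight^b·(1+ε), forearm = ratio·body·(1+ε), ε Gaussian with
relative sd 11.5%. Defaults use the study's group sizes (244/581/24/8/3
species) and were calibrated once, analytically then checked by
simulation, so that group mean BMI (~7.7/4.1 kg/m²), mean FMI
(~13.9/6.0/11.6 kg/m²) and the overall forearm-vs-body-length R²
(0.933 ± 0.01 across seeds) match the reported inter-species pattern;
the shared allometric exponent 0.36 (near isometric cube-root scaling)
is the value jointly consistent with the frugivore and insectivore BMI
and FMI means. An optional linear glucose model
(glucose = 11.2 − 0.37·FMI + noise) encodes the reported negative
inter-species association. No distributional information beyond group
means and R² was available, so lognormal weights and multiplicative
Gaussian length noise are a minimal realistic choice.

**IPGTT.** The surge g(t) = baseline + A·(t/tp)^s·exp(s(1−t/tp)) rises
fast, peaks exactly at tp and decays smoothly. Defaults: peak at
30 min, per-sample noise 0.8 mmol/L, cohort sizes 9 (fruit bat,
baseline 6.0) and 6 (insect bat, baseline 7.5); amplitudes 10.581 and
18.866 mmol/L are solved so the noiseless trapezoidal AUC on the
standard 8-point grid equals 24.9 and 38.0 h·mmol/L respectively
(hence a 52.6% noiseless excess).

**Promoters.** Each group is a star topology from one random root:
iid per-site substitutions per lineage, then the embedded motif is
restored in all lineages, then the shared deletion overwrites its
carriers with gaps. Defaults (275 columns; 4+5+7 taxa) use per-lineage
substitution probabilities 0.089/0.061/0.0704 solved from
(1−p)^n = expected conserved fraction so that the expected
universal-column count is ~79 and group conservation levels ~70.2%,
74.2% and 60.0%; the 11-bp deletion shared by both fruit-bat groups
starts at column 227 with the repressor word CTCCAC embedded at
228–233 inside it. No indel-length distributions or among-site rate
heterogeneity are simulated — the generator supports conservation and
rate-test testing, not realistic sequence evolution.

**Ct tables.** Target Ct is lowered by log₂(fold) per species around
fixed baselines (reference 18, target 26 cycles) with additive
Gaussian noise in cycle units; defaults encode folds 1.0/1.3/7.2/31.0
with two individuals × two runs per species and zero noise, so the
pipeline recovers the folds exactly.

**What passing tests do and do not show.** The generators reproduce
the low-order structure the analyses rely on (group means, an
allometric correlation, surge-shaped curves, group-structured
conservation, encoded folds). They do not reproduce phylogenetic
autocorrelation between species, measurement-protocol biases (e.g.
tail inclusion in body length), alignment uncertainty, or qPCR
efficiency drift — agreement on synthetic data validates the
computations, not the biological conclusions.

## Numerical choices and limitations

- Problem sizes in the test suite (e.g. 1000 equal-rate triplets of
  500 bp for type-I calibration, 10⁵-permutation nulls, 10⁶-point
  Riemann oracles) were chosen as the smallest sizes at which the
  asymptotic approximations under test are expected to hold.
- The χ² relative-rate test is discrete in (m₁, m₂); its finite-sample
  size oscillates around the nominal 5% level, which is why the
  calibration check uses a ±2% band.
- Real deposited promoter sequences and the species-level supplementary
  morphometric table are not bundled; analyses of the real data require
  the user to supply the aligned FASTA / CSV via the documented
  interfaces. MUSCLE-style alignment construction, model-selected ML
  phylogeny and molecular-clock testing are explicitly out of scope.
- Ties in the qPCR calibrator (identical mean ΔCt) resolve to the
  first species in pandas' index order.
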