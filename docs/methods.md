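# Methods

## Model and procedure

The package measures time-lagged causal structure between channels of a
multichannel timeseries with convergent cross mapping (CCM) and organizes
the result as interaction profiles.

**Delay embedding.** A channel y is embedded with unit lag as points
[y_t, y_{t−1}, …, y_{t−(E−1)}].  A point exists at index t only when all E
source samples are non-missing; no imputation is performed anywhere in the
cross-mapping core.

**Simplex cross map.** To quantify the influence of a channel x (the
candidate cause, "effect series") on a channel y (the driven channel,
"predictor series"), the embedding of y forecasts x at target offset
tp ≤ 0 (time t + tp).  Per repeat, `library_size` valid embedded indices
are drawn without replacement (independently across repeats); each library
point is forecast leave-one-out from its E + 1 nearest library neighbors
(Euclidean distance, ties broken toward the smaller index).  Neighbor
weights are w_i = exp(−d_i/d_1) normalized to sum 1; when the nearest
distance is zero the zero-distance neighbors share the weight equally.
Skill is the Pearson correlation between observed and predicted values,
averaged over repeats; it is signed and not clamped at zero.  A Theiler
window (`exclusion_radius`) removes temporally adjacent neighbors when
serial correlation would otherwise produce trivial matches (relevant for
short, smooth recordings; default 0).

**Interaction profiles.** Scanning tp over a grid gives skill-versus-delay
curves; each curve is min-max normalized to [0, 1] per pair (a constant
curve maps to zeros and is flagged).  The 12 ordered pairs among four
channels form a profile set.  Group-average profiles are computed by
normalizing per individual, averaging, and re-normalizing.

**Displayed delays.** For generative benchmarks with a coupling
"x_{t−d} enters y_{t+1}", the coupling surfaces at tp = −(d + 1), because
the newest embedding coordinate y_t sits one step downstream of the value
x_{t−d} shaped.  Profiles expose both axes (`tp`, `displayed_delays`,
`tp_seconds`).

**Profile similarity and groups.** Two profile sets are compared by the
mean Spearman rank correlation over their 12 corresponding profiles
(computed on raw skills; identical on normalized skills by rank
invariance).  Null significance comes from Fourier phase-randomized
surrogates, which keep each channel's power spectrum and destroy nonlinear
cross-dependence; gappy series are restricted to their longest jointly
gap-free stretch before randomization.  Distinctness of group A from
group B is the percentage of A-members whose most similar profile (self
excluded) lies in A, compared against 1000 size-preserving label
permutations; the attained fraction is the share of permuted percentages
strictly below the observed one (ties count as not-less).  Nearest-profile
ties are broken by a seeded shuffle of candidate order.  The test is
directional by construction.

## Choice of embedding dimension

The embedding dimension plays two different roles and the defaults differ
accordingly.

*Lag identification on the benchmark uses E = 2.*  With E = 2 the pair
(y_t, y_{t−1}) determines exactly one lagged driver value, so a planted
coupling produces a sharp profile peak at its generative delay.  Each
added lag coordinate adds deeper exactly-determined targets: with E = 10
the profile of the single-coupling benchmark becomes a broad hump whose
maximum sits near the middle of the determined range (displayed delay
8–9), several samples past the generative lag.  Minimal embedding is
therefore the right tool when the question is "at which delay does the
coupling act".  Profiles still change smoothly with E — consecutive
scanned dimensions give rank correlations above 0.9 — so profile *shape*
comparisons are robust to the choice.

*Worm-style profiling defaults to E = 10* (the `CrossMapConfig` default),
which resolves higher-dimensional driving dynamics when the goal is
fingerprinting rather than pinpointing a single lag; the
`optimal_embedding_scan` utility scans E from 2 to 40 at a fixed best
delay and reports the argmax (ties toward smaller E).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `E` | 10 (2 for benchmark lag recovery) | embedding dimension, unit lag |
| `tp` grid | −32…0 samples (−2…0 s at 16 Hz) | target offsets scanned |
| `library_size` | 200 (or `"all"` for short series) | embedded indices per repeat |
| `n_repeats` | 250 | library resamples averaged |
| `exclusion_radius` | 0 | Theiler window in samples |
| filter | NA fraction < 0.25, length > 200 | record quality gate (strict) |
| resampling grid | 0.1 s | common tp grid for cross-rate comparison |
| `n_perm` | 1000 | label permutations in the distinctness test |

Tests and the acceptance script use scaled-down repeat counts (3–100) and
library sizes (100–200); the Monte-Carlo error of the skill estimate
scales as ~1/√(repeats · library) and the scaled settings keep it well
below the effect sizes being asserted.

## Synthetic data

Two generators provide all inputs.

*Coupled logistic benchmark* — x_{t+1} = x_t(3.8 − 3.8 x_t) driving
y_{t+1} = y_t(3.5 − 3.5 y_t + Σ c_k x_{t−L_k}).  Initial conditions are
uniform in (0.2, 0.8) from the seed; 200 burn-in samples are discarded;
generation fails loudly if a trajectory leaves (0, 1).  Boundedness
requires Σ c_k < 2√r_y − r_y ≈ 0.242, which is why the dual-coupling
strength progression used in tests is (0.1, 0.05) → (0.1, 0.10) →
(0.1, 0.15) rather than anything reaching a total of 0.3.

*Synthetic eigenmode records* — four chaotic logistic units with distinct
growth rates (3.8, 3.7, 3.9, 3.75), lagged couplings added inside the
driven unit's update, Gaussian observation noise (sd 0.01, a few percent
of the signal sd), and NaN gaps with geometric lengths (mean 8 samples)
up to a target missing fraction (default 5%), at 16 Hz for 120 s.  Two
constraints shaped these defaults: growth rates must sit above the
band-merging point of the logistic family (~3.68), because below it two
*independent* channels share a strict period-2 alternation that cross
mapping reads as large spurious skill; and couplings into a unit with rate
r must total less than 2√r − r (~0.147 at r = 3.7).  Observation noise
above ~0.02 blurs the lag imprint by about one sample; 0.01 represents
clean tracking.  An oscillator-based generator was considered and
rejected: near-periodic dynamics violate CCM's applicability conditions
(no synchrony) and make lag recovery ill-posed.

What the generator does *not* emulate: nonstationary behavioral state
switching within a record, channel cross-talk from imperfect posture
decomposition, heavy-tailed tracking noise, or realistic eigenmode power
spectra.  Passing tests therefore demonstrate correct machinery and
recoverability under the stated conditions, not performance on real
recordings.

## Numerical choices

- Distance ties in neighbor search: stable sort, smaller index first —
  reproducible and identical to the brute-force oracle.
- Skill undefined (zero-variance observed or predicted segment, degenerate
  constant embedding): NaN with a warning; a profile with no resolved
  delay raises.
- Normalization of a constant profile: all zeros, flagged.
- Profile interpolation onto the 0.1-s grid is linear between resolved
  delays, never extrapolates, and reproduces native grid points exactly
  (grids are built by integer division so coincident points are bit-equal).
- Determinism: every stochastic step derives per-task seeds from a base
  seed via `SeedSequence`; identical config and inputs give bit-identical
  results.
- Local maxima of a profile are found on the normalized curve with a
  prominence threshold (default 0.05) to suppress Monte-Carlo wiggles;
  endpoints are never peaks.

## Limitations

- CCM assumes weak-to-moderate nonlinear coupling and no synchrony;
  strongly synchronized or purely stochastic channels will not be
  interpreted correctly.
- The displayed-delay convention is exact for couplings that enter the
  driven map's update directly; for chains of indirect influence the
  profile peak reflects an average information-transfer delay.
- Profiles of short windows (hundreds of samples) have high Monte-Carlo
  variance; use `library_size="all"` and interpret single-window profiles
  cautiously.
- The distinctness test's attained fraction is a permutation quantile, not
  a calibrated p-value, when group sizes are small (its null support is
  discrete with atoms of size ~1/|A|).
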