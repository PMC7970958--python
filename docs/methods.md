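# Methods

## Empirical mode decomposition

EMD extracts intrinsic mode functions (IMFs) by sifting: connect the
local maxima and the local minima by cubic splines, subtract the mean of
the two envelopes, and repeat. We fix the sift count at 10 per IMF
rather than using a convergence criterion; a fixed count keeps the
decomposition deterministic and preserves the dyadic filter-bank
behaviour on broadband noise (about one octave per order, roughly
log2 N IMFs from N samples) on which the whole mode lattice relies.
Decomposition stops when the residue has at most two extrema.

Numerical choices:

* **Extrema.** Strictly interior maxima/minima; a plateau contributes a
  single extremum at its (lower) midpoint index, so ties break
  deterministically.
* **Envelopes.** Not-a-knot cubic splines through the extrema. Before
  fitting, two extrema at each end are mirror-reflected across the
  first/last sample to suppress end swings; the envelope is evaluated
  only on the original support. With fewer than four knots the envelope
  degrades to linear interpolation (this happens on short, almost
  monotone residues). The spline solver is a compiled moment
  (second-derivative) formulation; the test suite verifies exact
  agreement with an independent spline implementation. An alternative
  boundary rule that anchors the envelopes at the signal endpoints was
  evaluated and rejected: it destroys the dyadic octave structure on
  white noise.
* **Early termination.** If a sift candidate loses all its maxima or
  minima, sifting stops early; this is recorded, never an error —
  residues legitimately become monotone.

Reconstruction (sum of IMFs plus residue equals the input) holds to
machine precision by construction, since each IMF is subtracted from the
running residue.

## Improved CEEMDAN with complementary noise pairs

Plain EMD on single noisy trials suffers from mode mixing, and the IMF
order then stops being a consistent frequency axis across trials,
channels and subjects — which the mode lattice needs. We therefore use
the improved (residue-averaging) CEEMDAN recursion: at order k, each of
the ensemble's white-noise realizations w contributes a perturbed
residue sift of r̃_{k-1} + β_{k-1}·E_k(w), where E_k(w) is the k-th EMD
mode of the noise ("adaptive noise", i.e. noise living at the same time
scale as the mode being extracted) and β_k = ε_k·std(r̃_k)/std(E_{k+1}(w))
sets the perturbation SNR with ε_k = 0.2 at every order. The k-th IMF is
the difference of consecutive ensemble-mean residues, so the output
telescopes and reconstruction is exact whatever the ensemble.

* **Complementary pairs.** Every realization enters together with its
  negation, cancelling odd-order noise terms in the ensemble mean.
  Because sifting is sign-equivariant, decomposing −w explicitly and
  negating E_k(w) coincide; we decompose explicitly by default and
  expose the cheaper sign shortcut as an option (a test pins their
  equality). The benefit is measured as the seed-to-seed variance of
  the output at equal total realization count; it grows with ε and is
  decisive at ε = 0.4 (the packaged statistical check runs there),
  marginal at ε = 0.2.
* **Ensemble size.** l complementary pairs, default l = 50 (2l
  realizations). Tests and the acceptance runs use l = 1–2: at those
  sizes a single decomposition of a 256-sample epoch costs ~10 ms,
  which is what makes hundreds of full-pipeline replicates feasible,
  and the calibration results show no degradation.
* **Mode count.** K = floor(log2 N) − 2 by default: the dyadic bank
  supports about log2 N orders and stopping two short guarantees every
  trial/channel can deliver the same K, a precondition for a common
  lattice. The residue is stored as order K+1.
* **Noise sharing.** One ensemble per trial, shared across channels
  (promotes inter-channel order consistency); per-channel independent
  ensembles are available by configuration. Per-trial seeds are spawned
  from the master seed with `SeedSequence`, so results are independent
  of execution order.

## Instantaneous frequency and the mode range

The IF of an IMF is the centred difference of the unwrapped analytic
(Hilbert) phase, clipped to [0, fs/2]. The *representative frequency* of
an IMF is the mode of its IF histogram over 48 log-spaced bins spanning
0.25–64 Hz (six bins per octave — uniform resolution for a dyadic bank).
Quantities derived from representative frequencies are therefore
quantized at sixth-octave resolution, and the edge bins saturate; order
medians outside roughly 0.3–55 Hz are excluded from ratio diagnostics.

The lattice bounds are data driven: p_min is the lowest order whose
dataset-median representative frequency falls below `hi_cut` (default
30 Hz, the conventional ERP low-pass edge) and `trend_start` the lowest
order below `lo_cut` (default 2 Hz, bottom of the delta band). Orders
from `trend_start` through the residue are aggregated into a single
trend block written `q+`. When no order is below `lo_cut`, the trend
block is the residue alone. Dataset-wide medians (over trials and
channels, pooled over subjects in the pipeline) are used because the
lattice must be common to all units.

## The mode lattice

With M = trend_start − p_min + 1 lattice orders there are M(M+1)/2
modes: per trial the constituent IMF orders are summed, then averaged
over the condition's trials. Averaging is linear, so every composite
mode equals the sum of its pure constituents exactly, and baseline
correction (subtracting the per-mode, per-channel mean of a pre-event
window) commutes with both. Time binning averages half-open bins
[t, t+Δ) and drops a partial trailing bin; when the bin width exceeds
the approximate period of a mode's fastest constituent (estimated as
fs/2^(p+1) for order p), a warning names the affected modes — exclusion
is the caller's choice.

## Adjacency

Mode neighbourhood is the XOR rule: neighbours iff the symmetric
difference of constituent-order sets has exactly one element. The trend
block is treated as a *single pseudo-ordinal*, so `3:5` and `3:6+` are
neighbours; this matches the lattice display in which the trend occupies
one column, and it keeps the slow edge of the lattice connected. The
expanded interpretation (trend = its individual orders, making `3:5` and
`3:6+` non-neighbours whenever more than one slow order exists) is
available behind a switch. Channels are neighbours strictly below a
40 mm Euclidean distance; time bins when adjacent. Lattice nodes are
adjacent iff they are neighbours in exactly one active dimension and
identical in the others.

## Cluster statistics

Pointwise statistics (paired t, one-sample t, Pearson r against a
subject-level covariate, one-way repeated-measures F) are computed per
lattice node; zero-variance nodes get statistic 0 and a flag. The
RM-ANOVA applies no sphericity correction — permutation inference does
not require it.

**CBnPP.** The map is thresholded at the parametric critical value
(97.5th t-quantile for two-sided α = 0.05 by default; one-sided for F),
positive and negative excursions are clustered separately through the
graph, and each cluster's mass (sum of statistic values) is referred to
the permutation distribution of the maximum |mass| over both signs
(zero when a permutation has no cluster) — two-sided familywise
control. Permutation schemes: sign flips of the paired difference
(paired/one-sample t), within-subject condition shuffles (F), covariate
order permutation (r). When the requested permutation count exceeds the
number of distinct permutations (2^n sign patterns, n! orders), the
distinct set is enumerated exhaustively and the result flagged. P
values use the add-one convention (1 + #{null ≥ observed})/(1 + n_perm),
which never returns 0.

**TFCE.** Each sign's map is enhanced by integrating
extent(h)^E · h^H · dh with the original defaults E = 0.5, H = 2 and
dh = max|stat|/100 resolved once from the observed map and reused for
every permutation. The integral is evaluated at midpoint thresholds
(j − ½)·dh with an incremental union-find over descending thresholds,
making the discretisation error O(dh²) — on an isolated plateau of
extent a and height h0 the transform matches a^E·h0^{H+1}/(H+1) to
~10⁻⁵ relative error. Node-wise corrected P values come from the
permutation distribution of max |TFCE|.

**Compact mode maps** reorganise a 3-D result per time bin as an
initial-order × end-order triangle for one electrode cluster: a cell is
opaque iff some member channel sat in a significant cluster *and* the
parametric P of the cluster-mean statistic is below 0.025. The mean-T
P value is a display gate (the t reference with the test's df is an
approximation for an average of correlated t values), not an inference.

Bonferroni across a-priori sensor sets is supported as a reporting
choice by passing a divided α; it is never applied silently.

## Synthetic experiments

The generator emulates what the analysis assumes of epoched EEG: trials
are sums of Hann-windowed oscillatory bursts (centre frequency,
amplitude, latency, optional Gaussian latency jitter, per-condition
gain) on 1/f^χ background (spectrally shaped white noise, default χ = 1,
σ = 1 µV) plus white sensor noise (default σ = 0.25 µV). Defaults: 16
subjects, 30 trials per condition, fs = 128 Hz, epochs −0.5..1.5 s.
Ground-truth noiseless component sums are stored per condition. The
pseudo-condition construction duplicates a condition's trials and adds
white noise with variance = per-trial signal variance / SNR (default
SNR = 4), giving an exchangeable two-condition null with realistic
autocorrelation.

What the generator does **not** model: volume conduction and realistic
topographies (channels are a synthetic 30 mm line unless a montage is
supplied), artifacts, non-stationary background, or cross-frequency
coupling. Passing tests therefore demonstrate the algorithmic
properties — calibration, scale recovery, determinism — under the
stated generative assumptions, not performance on arbitrary real EEG.

## Problem sizes and observed behaviour of the checks

The packaged end-to-end checks run at desk scale: calibration uses 200
replicates of 16 subjects on a 15 × 50 lattice with 500 permutations;
scale recovery uses 10 subjects × 20 trials of 2 s epochs at 128 Hz with
l = 2; the pseudo-condition null uses 8 subjects × 30 trials and 20
replicates. Two behaviours of these stochastic checks are worth
knowing:

* A Hann-windowed burst straddles *two* consecutive dyadic orders (a
  5 Hz burst at fs = 128 lands in orders 3–4); scale-recovery assertions
  treat that pair as the critical set. This is intrinsic to the dyadic
  bank, and exactly why composite modes and the XOR neighbourhood exist.
* A *perfectly* latency-locked identical burst interacts with added
  noise systematically (the order-3/4 split shifts coherently across
  subjects), which an exchangeability check would report as a true
  effect. The pseudo-condition study therefore jitters the burst
  latency (σ = 25 ms), the realistic regime for evoked responses. With
  jitter, rejections occur at the nominal familywise rate: the min-P
  distribution over replicates is consistent with the ~5–6% FWER
  measured in the calibration runs.

## Known limitations

* Only within-subject designs (paired/one-sample t, one-way RM-ANOVA,
  correlation); between-subject and mixed ANOVAs are out of scope.
* No correction is offered if the IMF order/time-scale correspondence
  breaks down across units; the consistency table (per-order quantiles
  of representative frequency) is the diagnostic, re-sorting is not
  attempted.
* EEMD and the original (2011) CEEMDAN are not implemented.
* Hilbert-Huang spectra and inter-trial phase clustering are natural
  follow-ups and deliberately out of scope.
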