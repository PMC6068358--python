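# Methods

## The problem

A multichannel electrophysiology recording rarely measures the potential at
an electrode in isolation: every "unipolar" channel is the difference
between local neural activity and whatever the reference electrode picks
up, and nearby electrodes additionally share volume-conducted activity from
non-neural sources. Writing the recorded signal as

    y_i(t) = x_i(t) - u(t),            u(t) = r(t) - vc_i(t),

with x_i the neural signal of interest, r the (global) reference
contribution and vc_i a distance-attenuated volume-conducted contribution,
any component of u common to two channels leaks into every pairwise
statistic computed from them. `commonsig` quantifies that leakage for the
three statistics practitioners combine most often — power, coherence, and
spectral Granger causality — and provides the diagnostics the framework
suggests.

## Model and measures

All quantities derive from the 2×2 cross-spectral density matrix Q(ω) of a
channel pair (auto-spectra S_ii, S_jj on the diagonal, cross-spectrum S_ij
off it). For a stationary bivariate AR process

    y(t) = Σ_l A(l) y(t−l) + e(t),   cov(e) = Σ = [[S, γ], [γ, Γ]],

Q(ω) = H(ω) Σ H(ω)* with H the transfer function (inverse of the operator
polynomial evaluated on the unit circle). From Q and the factorization
(H, Σ):

* coherence C(ω) = |S_ij|² / (S_ii S_jj);
* directional Granger causality f_{i→j}(ω) = ln S_jj / (H̃_jj Γ H̃_jj*)
  (and symmetrically f_{i←j}), where H̃_jj = H_jj + (γ/Γ) H_ji and
  H̃_ii = H_ii + (γ/S) H_ij fold the innovation cross-correlation into the
  own-channel transfer entry. The correction is applied unconditionally;
  it is the identity when γ = 0. (Some published statements of these
  corrections transpose the subscripts of the cross terms; the form here is
  the one that follows from orthogonalizing the innovations, and the only
  one under which directional GC is nonnegative for exactly factorized Q.);
* instantaneous interaction f_{i·j}(ω) = ln (H̃_ii S H̃_ii*)(H̃_jj Γ H̃_jj*)/det Q,
  computed directly from this closed form; the identity below is evaluated
  as a cross-check and its residual recorded, because the two diverge when
  the factorization is imperfect;
* the decomposition −ln(1 − C) = f_{i→j} + f_{i←j} + f_{i·j} at every
  frequency, splitting (a transform of) coherence into lagged and
  instantaneous parts.

An independent common signal with power U(ω)U*(ω) adds that power to every
entry of Q. At frequencies where the neural signals themselves are
independent — in practice, frequencies too high for genuine coupling — the
resulting coherence depends only on the neural-to-common signal ratio
NCR = (neural power)/(common power):

    C = 1/(NCR + 1)²,    inverted as    NCR = 1/√C − 1.

This is the package's central diagnostic: implausibly high coherence at
implausibly high frequencies measures the contamination affecting all
frequencies. Because differencing adjacent channels cancels an identical
common contribution, bipolar derivations largely remove it — except that
two bipolar channels built from a shared unipolar channel inherit that
channel as a new common signal, bounded by the same law (coherence ≤ 0.25
when the three neural powers are equal; more generally by the NCR law at
the geometric-mean NCR of the flanking channels).

Directional GC is nonnegative for PSD inputs; the instantaneous term can
go slightly negative when assumptions or numerics are imperfect. It is
reported as-is, flagged, never clipped. The instantaneous percentage
100·f_{i·j}/(−ln(1−C)) is undefined (NaN) where the denominator vanishes,
e.g. for an uncontaminated disconnected pair.

## Wilson factorization (non-parametric engine)

`wilson_factorize` obtains (H, Σ) directly from Q without fitting an AR
model. Numerical choices:

* Q on [0, Nyquist] (n points) is mirrored onto the full circle of
  2(n−1) uniform points via Q(−ω) = Q(ω)ᵀ.
* Initialization: the symmetric PSD square root of the frequency-averaged
  Q (a flat, always-valid starting factor).
* Iteration: ψ ← ψ [ψ⁻¹ Q ψ⁻* + I]₊, where the causal operator [·]₊ keeps
  positive lags whole and splits the Hermitian lag-0 coefficient into half
  its diagonal plus its full strictly-lower triangle — the anti-Hermitian
  correction that pins the otherwise arbitrary unitary factor.
* Convergence: relative change of both Σ and ψ below `tol` (default 1e-9,
  max 1000 iterations). The change in ψ must be tracked because Σ alone is
  exactly invariant under the first update from the symmetric-sqrt
  initialization and would fire a Σ-only criterion immediately.
* Degenerate Q: eigenvalues below 1e-10 of the mean diagonal trigger a
  warning and a diagonal jitter of that size before factorization.
* Output: H normalized so its zero-lag coefficient is the identity
  (minimum phase), Σ = A₀A₀ᵀ, both returned on the input grid.

For analytic AR spectra on a 512-point grid the round trip recovers Σ to
better than 1e-4 entrywise and reproduces Q to ~1e-15. For *noisy*
empirical spectra the iteration converges to a fixed point with a small
irreducible residual (~1e-3 relative): bin-to-bin estimation noise has
cepstral content beyond the n−1 causal lags the grid can represent. The
pipeline therefore accepts factorizations up to a relative residual of
0.05 (configurable) when deriving GC from multitaper estimates, while the
analytic route enforces 1e-3.

## Empirical pipeline

Stage order and defaults (all configurable via `AnalysisConfig`, unknown
keys rejected against a published JSON schema):

1. **Epoching**: 8 consecutive epochs of 2.25 s at 1000 Hz.
2. **Line-noise removal** per epoch: sliding-window multitaper harmonic
   regression at 50 and 150 Hz (3 tapers, 0.75 s window, 0.375 s step);
   the fitted sinusoids of overlapping windows are overlap-averaged and
   subtracted once. This is a deliberately simple harmonic regression
   whose contract is ≥ 20 dB attenuation on a pure line tone and < 1 dB
   change more than 2 Hz away from the line frequencies.
3. **Preprocessing** per epoch and channel: linear detrend, then z-score
   across time. A channel constant after detrending is an error.
4. **Multitaper CSD** per channel pair per epoch: K = 9 DPSS tapers with
   time–bandwidth NW = (K+1)/2, giving half bandwidth (K+1)/(2T) =
   2.22 Hz for T = 2.25 s. Two-sided density scaling (S = E|X|²/fs).
5. **Epoch averaging**: arithmetic mean of the per-epoch Q's.
6. **Connectivity** per pair: coherence from the averaged Q; total GC and
   instantaneous interaction via Wilson factorization.
7. **Separation groups**: pairs binned by electrode distance — 25, 50,
   75–150, 175–325 μm (±1 μm edge tolerance); metrics averaged within
   each bin. The group %instantaneous is the ratio of the group-mean
   instantaneous term to the group-mean transformed coherence (more
   stable than averaging per-pair ratios whose denominators can vanish).
8. **Power summary**: channel-averaged 10·log₁₀ S_ii(ω), computed from
   line-cleaned, detrended but *not* z-scored epochs. Z-scoring equalizes
   per-channel variance by construction, which would make the
   unipolar-vs-bipolar power comparison vacuous — the amplitude
   difference between referencing schemes is exactly what this summary
   quantifies. All ratio-based measures use the fully preprocessed data.
9. **NCR estimate**: NCR = 1/√C − 1 applied to the band-mean coherence of
   one separation group, by default the long-distance (175–325 μm) group
   over 200–450 Hz — frequencies above plausible genuine coupling for fly
   LFP at this sampling rate, and separations least affected by volume
   conduction. The band coherence is first bias-corrected by the standard
   first-order term E[Ĉ] ≈ C + (1−C)²/n_eff with n_eff = epochs × tapers
   (= 72 at defaults); without it, estimates at high NCR (low coherence)
   are biased low by ~15–20%.

The pipeline is fully deterministic: identical recording and configuration
give bit-identical outputs.

## Synthetic generator

`generate_session` emulates a linear-array fly-LFP preparation with known
ground truth; its defaults are the package's study conditions.

| parameter | default | meaning |
|---|---|---|
| n_channels / pitch_um | 15 / 25 μm | linear probe geometry |
| fs_hz, n_epochs × epoch_s | 1000 Hz, 8 × 2.25 s | recording structure |
| slow_ar / slow_var | 0.97 / 1.0 | slow neural rhythm (AR(1)), dominant power, decaying with frequency |
| slow_corr_adjacent | 0.9 | spatial correlation of the slow rhythm between adjacent channels (Gaussian profile over distance) |
| fast_ar / fast_var | 0.3 / 0.08 | fast local activity, independent across channels |
| reference_power | 0.13 | variance of the global white reference signal r(t) |
| vc_power / vc_lambda_um | 0.02 / 100 μm | white volume-conducted source at the array center, amplitude decaying as exp(−d/λ) |
| line_amp_50hz | 0 | optional mains contamination |

The two-component neural model is the essential design choice: slow LFP
components have a much larger spatial reach than fast ones, so adjacent
channels record highly similar slow activity (bipolar derivations are
small and unipolar power dominates bipolar power at every frequency)
while high-frequency activity is local (bipolar pairs decorrelate at high
frequencies unless they share a unipolar channel, in which case the shared
channel acts as a common signal with ceiling 0.25). A single AR(1) per
channel with a frequency-flat spatial correlation profile cannot produce
all three behaviors at once. `reference_power = 0.13` puts the
high-frequency NCR near 0.4 — i.e. high-frequency unipolar coherence near
0.5, the regime where a thorax reference makes the common signal about
twice the neural signal. Ground truth (per-channel neural, reference and
volume-conduction spectra and the implied NCR) is computed analytically
from the configuration, never estimated from the realization.
`reference_power_for_band_ncr` inverts the analytic band NCR so parameter
sweeps can target exact ground-truth values.

What the generator does **not** emulate: genuine low-frequency coupling
between distant sites (its long-distance coherence at low frequency is
common-signal only), non-Gaussian or nonstationary dynamics, biophysically
detailed volume conduction, electrode drift or artifacts. Passing tests
therefore demonstrate that the pipeline recovers *this* class of ground
truth, not that fly LFP satisfies the assumptions.

The four canonical two-node scenarios (connected/disconnected × with/
without a flat common signal whose power equals the mean neural power) are
available analytically (`scenario_spectral_matrix`) and as time-domain
recordings (`scenario_recording`). The disconnected system is realized as
two independent streams whose marginals match the connected system's:
channel 1 reuses its AR(1); channel 2 filters white noise through the
minimum-phase system obtained by cepstral factorization of the connected
S₂₂ on a 4096-point circle. Simulations discard a 1000-sample burn-in and
draw all randomness from one seeded generator.

## Numerical conventions and edge cases

* Frequency grids run from 0 to Nyquist inclusive; the analytic default is
  512 linearly spaced points in normalized radians, the empirical grid is
  the rFFT grid of the epoch (even epoch lengths only, so the grid reaches
  Nyquist exactly).
* AR models are stored in operator sign convention (lag-0 identity,
  leading minus); the public constructor accepts natural coefficients.
  Stability requires companion spectral radius < 1 − 1e-6.
* Coherence is clipped into [0, 1] only within 1e-12 slack; a transform of
  coherence exactly 1 is an error unless an explicit cap is supplied.
* Problem sizes in tests and the acceptance script: 512-point analytic
  grids; 2×10⁵-sample scenario realizations; default 18 s sessions; an
  NCR sweep over five target values with one session each — sizes at which
  every stochastic tolerance has comfortable margin while the whole suite
  runs in well under a minute of compute.

## Known limitations

* Strictly pairwise: no conditional/partial GC, no multivariate
  (>2-channel) factorization exposed, no significance testing.
* The volume-conduction coherence expression is used only qualitatively;
  no attempt is made to fit the distance profile.
* Near-unit-root spectra and rank-deficient Q slow the Wilson iteration
  markedly (convergence is linear in the worst case); the jitter floor
  bounds but does not eliminate this.
* The line-noise remover assumes stationary line amplitude within each
  0.75 s window and does not track fast amplitude modulation.
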