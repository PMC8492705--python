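# Methods

## The model

A recording is a real matrix `s ∈ R^{N×T}` (N channels, T samples, µV) with
sampling rate `fs`. Each row is extended to its analytic signal
`Ψ_j(t) = s_j(t) + i·H[s_j](t) = A_j(t) e^{iθ_j(t)}`, computed with the
FFT-based discrete Hilbert transform. The analytic signal — not the Hilbert
transform alone — is used, because the polar decomposition into an
instantaneous envelope and phase only holds for the full complex extension,
and the measured signal would otherwise be discarded.

At every sample the channel vector is normalized across channels:

    Ψ̂_j(t) = Ψ_j(t) / sqrt(Σ_k |Ψ_k(t)|²),   P_j(t) = |Ψ̂_j(t)|².

`P(·, t)` is a probability distribution over electrodes — the "state" at
time t. Two consequences are worth stating explicitly:

- the construction is invariant under global rescaling and global phase
  rotation of the input, so amplifier gain does not matter;
- the normalization couples channels: `P_j` is a *relative* energy share,
  not an absolute amplitude.

### Observables

Electrode positions `(x_j, y_j)` are the orthographic projection of the 3-D
montage onto the horizontal plane (z dropped; nose in +y). With positions
fixed and probabilities time-varying:

    ⟨x(t)⟩  = Σ_j x_j P_j(t)
    ⟨p_x(t)⟩ = m · d⟨x(t)⟩/dt = m Σ_j x_j dP_j(t)/dt     (m = 1)
    ⟨x²(t)⟩ = Σ_j x_j² P_j(t)

The momentum identity is an Ehrenfest-style relation; because both sides are
finite sums under the same finite-difference scheme, the package's two ways
of computing `⟨p⟩` agree to rounding, and the test suite asserts this at
1e-12.

Derivatives are taken **per sample interval** (spacing 1, central
differences at interior samples, one-sided second-order at the two ends — a
single scheme shared by every momentum expression). Momenta therefore carry
cm per sample interval and products cm² per sample interval; at the default
250 Hz this is the cm²/4 ms unit quoted in the output tables.

### Region occupancy

For a region G (a set of electrode labels), `Prob_G(t) = Σ_{j∈G} P_j(t)` and
`f_G = (1/T) Σ_t Prob_G(t)`. The occupancy uses the *normalized* state: an
unnormalized version would not be a frequency in [0, 1], and when the groups
partition the montage, `Σ_G f_G = 1` exactly.

### Momentum basis

The momentum representation is a scattered-to-scattered (type-3) 2-D
discrete Fourier transform from electrode positions to a fixed grid of
momentum points:

    φ_k(t) = Σ_j Ψ̂_j(t) · exp(−i(p_xk x_j + p_yk y_j)),
    P̃_k(t) = |φ_k(t)|² / Σ_m |φ_m(t)|².

Conventions, all fixed and documented rather than derivable:

- forward sign is the negative exponent (position → momentum);
- momenta are in reciprocal centimetres, consistent with the kernel;
- `P̃` is renormalized per sample so it acts as a probability over the grid
  (the raw `|φ|²` is available with `normalize=False`);
- the default grid has exactly 92 points: the integer lattice
  `p_x ∈ {−4..4} × p_y ∈ {−4..5}` ordered by `p_x` then `p_y` (both
  ascending), followed by `(−5,−4)` and `(−4,−5)`. With the default
  92-channel montage this makes momentum index k pair one-to-one with
  electrode index j.

**Implementation note.** The transform is evaluated *exactly*: the
`N_p × N` kernel matrix is precomputed and applied to all samples in one
matrix product. At the sizes this package targets (tens to a few hundred
points on each side) this is faster than FFT-accelerated nonuniform
transforms and has no approximation error; the `tol` argument is validated
for range and trivially satisfied. An explicit per-sample summation
(`nudft_direct`) is retained as an independent oracle and the suite checks
agreement at 1e-8 on study-sized problems.

### Uncertainty products and K

    Δx(t)  = sqrt(⟨x²(t)⟩ − ⟨x(t)⟩²)
    Δp_x(t) = sqrt(⟨p_x²(t)⟩ − ⟨p_x(t)⟩²)

`⟨p_x⟩` comes from the Ehrenfest route; `⟨p_x²⟩` from the momentum-basis
expression

    ⟨p_x²(t)⟩ = m² Σ_j (x_j² / P̃_j(t)) · [dP_j(t)/dt]²,

with electrode j paired to momentum point j under the fixed orderings above.
This pairing is a convention, not a derived fact: the value of `⟨p²⟩`
depends on both orderings, and users substituting their own montage or grid
must keep the pairing fixed across analyses for comparability. The spectral
mean `Σ_k P̃_k p_k` is computed as a diagnostic but never substituted into
the spread.

Numerical policy:

- `P̃` is floored at 1e-12 before the division (near-zero momentum
  probabilities would otherwise dominate the sum);
- position variances in `[−1e-12, 0)` are rounding and clip to zero; worse
  violations raise, because they indicate inconsistent inputs;
- momentum variances below −1e-12 are *flagged and excluded*, not clipped:
  the two momentum moments come from different constructions and the model
  does not guarantee their consistency sample by sample. Flag counts are
  reported per recording and logged.

Per recording, the products `Δx·Δp_x` and `Δy·Δp_y` are summarized by
min/max/mean/SD over defined samples (ties in the minimum broken by the
earliest sample, which also selects the exported probability map). The
cohort **K estimate** is the mean of per-recording minima pooled over x and
y, with its across-recording SD.

K is montage-dependent: a 20-channel downsample of the same recordings
yields a systematically smaller K than the 92-channel analysis (the
acceptance script computes both), so K values are only comparable between
identical montages.

## The synthetic generator

`SynthSpec` defaults describe the target study conditions: 92 channels at
250 Hz, a few oscillatory components (10 Hz at 20 µV, 6 Hz at 8 µV, 22 Hz at
5 µV — an alpha-dominant mixture with slower and faster activity at
plausible scalp amplitudes), white Gaussian sensor noise at 5 µV, and 10 s
duration. Each component gets an independent random phase per channel;
spatial structure comes from per-component Gaussian profiles and/or the
localization mechanism, which rescales the target region's channels so the
*realized* squared-amplitude fraction on that region equals
`localization_strength` exactly. "Rest"-tagged cohort members localize
anteriorly (default strength 0.6); "task"-tagged members are spatially flat
— so the anterior-at-rest ordering of `f_G` is recoverable by construction
and serves as a parameter-recovery check, not as evidence about brains.

What the generator does **not** emulate: 1/f background spectra (white noise
is deliberate — the fixtures test the pipeline's mathematics, not EEG
realism), volume conduction and inter-channel correlation from shared
sources, artifacts (eye, muscle, line noise), and non-stationarity. Passing
tests therefore validate the computational chain and its invariants, not any
physiological claim about real recordings, whose preprocessing (channel
rejection, ICA cleaning) is assumed done upstream.

`delta_state` (all probability on one electrode, constant) and `ramp_state`
(probability moving linearly between two electrodes) have closed-form
observables — zero spreads; constant momentum `(x_{j2}−x_{j1})/(T−1)` — and
anchor the sign, scaling and difference-scheme conventions.

## Bundled montage and grouping

No public listing exists of the 92-of-129 channel subset or the
label→region map this analysis style is used with, so the bundled
`egi92_montage.csv` / `egi92_grouping.csv` are **synthetic stand-ins**
generated by `montage._default_layout()`: 92 labelled points on a 9 cm head
disc, grouped by a geometric rule (anterior = largest y, occipital =
smallest y, left/right by sign of x) that reproduces the canonical
per-region counts — Occipital 10/10, Parietal 17/17, Posterior 10/11,
Anterior 8/9, summing to 92. The 20-channel subset (`subset20_labels.txt`)
spreads 20 of those labels across all eight regions, approximating 10–20
coverage; it is likewise a fixture. Analyses of real data should supply the
actual montage and grouping files.

## Edge handling and defaults

The discrete Hilbert transform has wrap-around artifacts at the record
edges. The default edge trim is 0 (the library never silently drops data,
and a warning is emitted); analyses in the documentation and test suite trim
50 samples (200 ms at 250 Hz) per edge before statistics, which empirically
removes the artifact for the generator's band-limited signals. Channels are
used as-is (no demeaning); a DC offset inflates the analytic-signal envelope
and is the user's preprocessing decision.

Problem sizes in the test suite and acceptance script (recordings of 2.5 k
samples, cohorts of 6, 50-sample transforms against the explicit-sum
oracle) were chosen as the smallest sizes at which every property is
exercised at the study's channel count; all quantities they compute are
scale-stable in T well below these sizes.

## Known limitations

- The electrode/momentum index pairing in `⟨p²⟩` is conventional (see
  above); results are only comparable under a fixed pairing.
- K depends on montage size and geometry; no normalization across montages
  is attempted.
- Group-level inferential statistics (ANOVA-style condition contrasts) are
  out of scope; the package reports per-recording and cohort descriptive
  summaries only.
- EDF support covers single-rate, annotation-free files; the writer encodes
  to the standard 16-bit range (round-trip exact only to quantization).
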