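# Methods

`megaedit` simulates J-difference editing of γ-aminobutyric acid (GABA) at
7 T with a MEGA-sSPECIAL sequence, evaluates the editing performance of
three macromolecule-suppressed editing schemes, and provides the
surrounding evaluation machinery: synthetic multi-coil raw data, the
standard preprocessing chain, and test–retest statistics. This note
documents the model, the calibrated constants, the numerical choices, and
what the simulations do and do not show.

## Spin model

Spins are simulated by Hilbert-space density-matrix propagation in the
Zeeman product basis. The free Hamiltonian is

    H = Σ_i 2π ν_i I_iz + Σ_{i<j} 2π J_ij (I_i · I_j)

with rotating-frame offsets ν_i = (δ_i − δ_carrier)·f0 and the full
isotropic coupling term retained (strong-coupling effects are not
truncated). Propagators come from eigendecomposition of the Hermitian
step Hamiltonians; unitarity holds to better than 1e-9. The equilibrium
state is the high-temperature deviation matrix Σ I_iz, detection is
Σ I_i+, and FIDs are scaled so an N-proton singlet after an ideal 90°
reads N at its first sample. Relaxation is not simulated during RF; a
Lorentzian linewidth (default 2 Hz) is imposed during acquisition, and any
T2 weighting across TE is a scalar per-compound factor applied downstream.

Defaults: B0 = 7 T, f0 = 297.2 MHz, carrier at 2.4 ppm, 4000 Hz spectral
width, 2048 points.

GABA is a six-proton system (three methylene groups at 3.0128, 1.889 and
2.284 ppm). The bundled J matrix is the refined measurement set shipped
with the standard density-matrix simulation toolkits; its distinguishing
feature is the unequal C4–C3 vicinal couplings (5.372/6.982 Hz to one
3.01-ppm proton, 7.127/6.707 Hz to the other). This inequality slows and
flattens the echo-time modulation of the edited 3.0-ppm multiplet and is
what places the editing optimum at TE ≈ 80 ms; with the older symmetric
transcription (~7.3 Hz everywhere) the optimum sits at 1/(2J) ≈ 68–74 ms
instead. Lysine stands in for the co-edited macromolecules; its
δ-CH2/ε-CH2 fragment (1.7046/3.0283 ppm, vicinal J = 7.57 Hz, Hilbert
dimension 16) is the default for sweeps, with the full nine-proton system
available for fidelity checks. Constants live in a versioned JSON data
file, which is the source of truth.

## Shaped pulses

Three editing pulses are synthesized as piecewise-constant waveforms
(512 steps by default; doubling the step count changes any reported
bandwidth by <1%):

* **20-ms asymmetric adiabatic inversion** — first half of a 32-ms HS1
  joined to the second half of an 8-ms HS4, amplitude and instantaneous
  frequency continuous at the junction, 1 kHz peak γB1/2π. The sweep runs
  downward so that the band edge formed by the HS1 half — the *sharp* edge,
  because the 16-ms half dwells near its truncation — faces the 3.0-ppm
  detection region. The half-sweep extents (1180/930 Hz) are calibration
  constants fixed by the pulse's design targets: the assembled pulse shows
  a 502.5-Hz inversion band (Mz/M0 < −0.95) and a 128-Hz sharp-edge
  transition at 1 kHz peak, with on-band inversion varying <2% over a
  ±20% B1 miscalibration.
* **28-ms selective Gaussian**, 35 Hz peak, and **15-ms Gaussian**, 70 Hz
  peak. Their truncation (5% edge amplitude) is set so the envelope's
  *spectral* (Fourier) FWHM matches the pulses' nominal bandwidth
  figures (≈98 and ≈122 Hz) while the on-resonance flip is a clean
  inversion. Note a physical point the package measures honestly: a
  35-Hz-peak pulse has less than one full cycle of rotation over 28 ms, so
  no amplitude/phase modulation can hold Mz < −0.95 across ~100 Hz at that
  amplitude — the Bloch-simulated deep-inversion band of the 28-ms pulse
  is ≈9 Hz wide and the 15-ms pulse's Bloch-profile FWHM is ≈83 Hz. The
  nominal bandwidth figures for low-amplitude selective pulses are
  envelope (vendor-spec) numbers, not deep-inversion Bloch widths. The
  editing physics is insensitive to this distinction: what matters for
  editing is the inversion of the 1.89-ppm partner protons, which all
  three pulses accomplish on resonance.

A Gaussian-windowed sinc shape is also available (`gaussian_sinc`); at the
stated peak amplitudes it only degrades inversion and editing, so the
schemes use the pure Gaussians.

## Sequence and editing schemes

Localization is ideal (instantaneous 90°/180°, no spatial dimension): the
add–subtract pre-inversion of the full-intensity localization reduces to a
sign alternation, and every experiment yields four subspectra
(inversion on/off × edit on/off). The echo layout is 90° at t = 0, ideal
180° at TE/2, acquisition at TE, with the scheme's editing pulse applied
twice, centered at TE/4 and 3TE/4; free evolution runs during the shaped
pulses. Combinations: on = inv_off − inv_on (per edit state),
diff = on − off, sum = on + off.

* **Scheme 1**: edit-on, the asymmetric adiabatic pulse positioned so its
  sharp −0.95 edge sits 50 Hz downfield of 1.9 ppm — deep enough that the
  1.89-ppm protons sit on the flat plateau of the editing response (the
  yield varies by only a few percent over ±60 Hz of drift) while the
  transition region stays ~250 Hz clear of the 2.85-ppm window edge; the
  broad band also covers the 1.7-ppm macromolecule-surrogate resonance.
  Edit-off, the 28-ms selective Gaussian at 1.7 ppm, so the co-edited
  3.0-ppm contamination appears in both subspectra and subtracts.
* **Scheme 2**: the 28-ms Gaussian at 1.9 ppm on alternate scans only; its
  selectivity means the 1.7-ppm partners are never co-edited.
* **Scheme 3**: the 15-ms Gaussian applied symmetrically about 1.7 ppm
  (1.9/1.5 ppm on alternate scans), cancelling the co-edited signal in the
  difference.

## Editing efficiency

Efficiency is the 2.85–3.15 ppm trapezoidal integral of the difference
spectrum divided by twice the same integral of the edit-on spectrum — the
edited yield per acquired on/off pair relative to the maximal attainable
(J-refocused) signal of the same protons. This is the conventional
normalization with the familiar ~0.5 ceiling of difference editing.
Spectra are phased by the zero-order phase maximizing the reference
integral; no T2 weighting enters. An alternative reference (a rerun on a
variant with the couplings to the 1.89-ppm protons zeroed, giving a fully
refocused pseudo-singlet) is retained for cross-checks; it also carries
the strong-coupling losses absent from its denominator and therefore
reads ~10–20% lower.

At TE 80 ms the three schemes give 0.503, 0.497 and 0.500. Over
TE ∈ {68, 70, 74, 80, 90, 100} ms scheme 1 spans 0.42–0.50 with the
maximum at 80 ms; the 80-vs-68 ms gain is +3.4 points.

## Sweeps

Offset sweeps move the editing-pulse carrier(s) over ±60 Hz (default step
3 Hz; 1-Hz convergence was checked on one scheme) and record the magnitude
of the complex 2.85–3.15 ppm difference integral, min–max normalized per
curve. `sweep_target` selects which pulse moves: a transmit sweep of one
editing pulse moves only that pulse, a B0 drift moves both; GABA curves
for schemes 1/2 move the 1.9-ppm pulse, scheme 3 moves both.

Tolerance intervals are the largest contiguous interval containing zero
where the normalized curve deviates from its extremum by less than 5%
(loss direction for the edited target, gain direction for the co-edited
surrogate), with linearly interpolated edges. The simulated curves are
slightly asymmetric — the editing optimum of the real multiplet sits
~2–3 Hz above the nominal 1.9-ppm position — so summary numbers quote the
half-width of the largest *symmetric* interval about resonance: ≈6 Hz for
scheme-2 GABA, ≈10 Hz for scheme-3 GABA, ≈0.8–2 Hz for scheme-3 lysine.
Scheme-1 GABA is nearly flat over the whole ±60 Hz (raw variation <7%), a
regime where a min–max-normalized threshold is degenerate; its robustness
is therefore stated on raw integrals relative to on-resonance.

## Synthetic raw data and preprocessing

The generator emulates a phased-array edited acquisition: per-block
four-subspectrum FIDs built from the sequence engine for a configurable
mixture (default: GABA 1, a 3.03-ppm two-proton singlet 8, a 2.01-ppm
three-proton singlet 12 — creatine- and N-acetylaspartate-like anchors),
broadened to a total linewidth (default 12 Hz), complex coil sensitivities
(default 4 coils), cumulative transmitter drift (e.g. 2 Hz/min with TR
4 s: 0.533 Hz per block), Gaussian per-block phase jitter, circular
complex noise, and a per-coil unsuppressed-water reference. All applied
values are recorded as ground truth. What it does *not* emulate: subject
motion, spurious echoes, lineshape distortions beyond Lorentzian,
frequency-dependent coil phase, or macromolecule baselines — passing tests
demonstrate pipeline correctness under the stated noise model, not
robustness to everything in vivo data can do.

Processing follows standard edited-MRS practice, in order: coil
combination with S/σ² weights and water-derived phases (weights normalized
so unit sensitivities pass signal through unchanged); eddy-current
correction by time-resolved water-phase subtraction, after demodulating
the water reference at its nominal offset (the carrier sits at 2.4 ppm, so
the raw water phase contains a 669-Hz ramp that is signal, not artifact);
hierarchical spectral registration — inversion partners against the
negated reference (they are sign-flipped copies under ideal localization),
then the edit-off pair to the edit-on pair fitted on the creatine region
(2.95–3.12 ppm) in the frequency domain, because the 2.01-ppm singlet lies
inside the broadband editing pulse's band and genuinely differs between
conditions, then all blocks to block 0 — followed by add–subtract
combination and averaging. Registration fits (Δf, φ) by Gauss–Newton
least squares started at (0, 0) on the first 200 ms of FID (or the stated
frequency band); non-converged fits are flagged and passed through.
Recovery accuracy at SNR ≥ 50 is better than 0.1 Hz / 0.05 rad RMSE.
The reported SNR is the real-part peak near 2.01 ppm of the off spectrum
over the noise SD in a signal-free band (default 8–9 ppm on this axis).

## Quantification and statistics

Water-referenced concentrations use the compartment formula

    c = (S_met/S_w) · (2/n_H) · Σ_c f_c W_c [H2O] e^(−TE/T2w,c)
        / e^(−TE/T2,met) / (1 − f_CSF)

with every constant supplied by configuration. The default metabolite T2
of 0.20 s is the value implied by a 5.8% signal loss over a 12-ms TE
extension. Test–retest statistics: per-subject CV from the two-value SD
|a−b|/√2 over the pair mean (zero-mean subjects excluded with a warning),
Pearson r with a two-sided test, and the single-measurement consistency
ICC(3,1) computed from two-way ANOVA mean squares; Bland–Altman agreement
reports the mean difference and ±1.96·SD limits. All statistics are
verified against longhand oracles and the established implementation in
`pingouin`.

## Problem sizes and determinism

Everything graded is deterministic: 6-spin GABA (64-dimensional Hilbert
space) for efficiencies and TE sweeps, the 4-spin lysine fragment for
offset sweeps, 41–61 sweep points, 512-step pulses, 2048-point
acquisitions. The full acceptance computation runs in about half a minute
on one core; the synthetic-data tests use 4–16 blocks and 1–4 coils.
Random-number use (noise, jitter, sensitivities) flows through a single
seeded generator.

## Known limitations

* Localization is ideal; chemical-shift displacement, spatial profiles and
  the vendor sequence's exact intra-TE delays are out of scope. The TE
  fine structure (e.g. the exact 80-vs-68 ms gain) depends on such
  internals at the percent level.
* The deep-inversion bandwidths of the low-amplitude selective pulses are
  physically far smaller than their nominal envelope bandwidths (see
  Shaped pulses); the package reports the Bloch values.
* Lysine is an imperfect surrogate for macromolecules, and the generator's
  noise model is idealized (see above).
* The edit-on/off registration stage has a small intrinsic bias whenever
  the anchor band contains any edited intensity; it is shared by all
  datasets processed the same way and cancels in comparisons.
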