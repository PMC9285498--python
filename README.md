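# megaedit

Density-matrix simulation and evaluation of J-difference-edited GABA
magnetic resonance spectroscopy with a MEGA-sSPECIAL sequence at 7 T.

γ-aminobutyric acid (GABA), the brain's main inhibitory neurotransmitter,
is hard to measure by in vivo ¹H-MRS: its three methylene multiplets
(3.01, 2.28, 1.89 ppm) are buried under creatine, glutamate and
macromolecules. MEGA (Mescher–Garwood) editing exploits the J-coupling
between the 1.89- and 3.01-ppm protons: a frequency-selective pulse
applied at 1.9 ppm on alternate scans refocuses the 3.0-ppm multiplet's
outer lines, so the edit-on − edit-off difference retains GABA while the
overlapping creatine singlet cancels. Macromolecules coupled between
~1.7 and ~3.0 ppm co-edit and contaminate the result; this package
implements and compares three suppression schemes (a 20-ms asymmetric
adiabatic HS1/HS4 hybrid paired with a 28-ms selective Gaussian at
1.7 ppm; the 28-ms Gaussian alone at 1.9 ppm; a 15-ms Gaussian applied
symmetrically at 1.9/1.5 ppm), using lysine as the macromolecule
surrogate.

The simulator propagates the full spin density matrix,
ρ → U ρ U† with U = exp(−iHt) and

    H = Σ_i 2π ν_i I_iz + Σ_{i<j} 2π J_ij (I_i · I_j),

through the four-subspectrum add–subtract experiment (inversion on/off ×
edit on/off), with the shaped editing pulses applied as piecewise-constant
propagators and characterized separately by Bloch simulation. On top of
the engine sit the paper-style analyses — editing efficiency
diff/(2·edit-on) over 2.85–3.15 ppm, echo-time sweeps, editing-pulse
frequency-offset (drift-tolerance) sweeps — plus a synthetic multi-coil
raw-data generator, the standard preprocessing chain (S/σ² coil
combination, eddy-current correction, hierarchical spectral registration,
add–subtract averaging) and test–retest statistics (CV, Pearson r,
ICC(3,1), Bland–Altman).

See `docs/methods.md` for the model, calibrations and numerical choices.

## Worked example

Editing efficiencies of the three schemes at TE 80 ms (6-spin GABA,
2-Hz linewidth, 4000 Hz / 2048 points):

```
$ megaedit efficiency
scheme1 @ TE 80 ms: efficiency 0.503 (edit_on_pair)
scheme2 @ TE 80 ms: efficiency 0.497 (edit_on_pair)
scheme3 @ TE 80 ms: efficiency 0.500 (edit_on_pair)
```

Each number is the 2.85–3.15 ppm difference-spectrum integral divided by
twice the edit-on integral — the edited GABA yield per acquired on/off
pair relative to the maximal J-refocused signal, with its conventional
~0.5 ceiling. The echo-time dependence shows the editing optimum:

```
$ megaedit te-sweep
TE  68.0 ms: efficiency 0.469
TE  70.0 ms: efficiency 0.486
TE  74.0 ms: efficiency 0.495
TE  80.0 ms: efficiency 0.503
TE  90.0 ms: efficiency 0.485
TE 100.0 ms: efficiency 0.422
maximum at TE = 80 ms
```

and the Bloch profile of the asymmetric adiabatic pulse confirms its
engineering targets (502-Hz inversion band, 128-Hz sharp edge facing
3.0 ppm, ~1-kHz diffuse edge on the far side):

```
$ megaedit pulse-profile --kind asymmetric_ahp --peak-hz 1000
{
 "inversion_bw_hz": 502.46,
 "transition_bw_hz": 128.39,
 "transition_bw_low_hz": 998.16,
 "transition_bw_high_hz": 128.39,
 ...
}
```

Drift-tolerance sweeps (`megaedit sweep --scheme 2 --system gaba`),
synthetic-data processing (`megaedit process --drift 2.0`) and
reproducibility statistics from a CSV of paired sessions
(`megaedit stats --in measurements.csv`) follow the same pattern; every
command is a thin wrapper over functions in `megaedit.analysis`,
`megaedit.processing` and `megaedit.quant_stats`.

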