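# Methods

## The physical model

A cell suspended in a non-uniform AC electric field experiences a
dielectrophoretic (DEP) force proportional to the real part of the
Clausius-Mossotti (CM) factor,

    CM(f) = (ε*_p − ε*_m) / (ε*_p + 2 ε*_m),

where ε*_x = ε0 εr − j σ/(2πf) is the complex permittivity of the particle
(p) or suspending medium (m). Re[CM] > 0 is positive DEP (attraction to
high-field regions at the electrode edges), Re[CM] < 0 negative DEP. For
physical inputs Re[CM] is bounded in [−0.5, 1].

The cell is idealized as a single-shell particle: a conductive cytoplasm
sphere of radius r bounded by a thin, poorly conducting membrane described
by its specific capacitance Cspec (F/m²) and specific conductance Gspec
(S/m²). In the thin-shell limit the effective particle permittivity is

    ε*_p = r C*_spec ε*_cyto / (r C*_spec + ε*_cyto),
    C*_spec(ω) = Cspec − j Gspec/ω.

This parameterization is used (rather than an explicit membrane-thickness
two-layer form) because Cspec and Gspec are exactly the whole-cell
quantities a DEP analyzer reports, so model parameters and measurements
live in the same space.

Key consequences the package relies on:

- At low frequency with an insulating membrane (Gspec = 0),
  Re[CM] → −0.5 for any conductive medium.
- The first crossover frequency (lowest zero of Re[CM]) obeys
  f_x1 ≈ √2 σ_m / (2π r Cspec) when the membrane is insulating and the
  cytoplasm is much more conductive than the medium. Lower membrane
  capacitance ⇒ higher crossover, which is the entire basis for
  capacitance-based sorting: between the two archetype crossovers one cell
  type feels positive DEP and the other negative.

## Parameters, units and defaults

SI units internally (m, F/m², S/m², S/m, Hz); the CSV dialects and CLI use
laboratory units (μm, mF/m², μS/cm) with exact conversion at the I/O
boundary only (100 μS/cm = 0.01 S/m).

| parameter | default | why |
|---|---|---|
| medium conductivity | 100 μS/cm | standard low-conductivity DEP buffer |
| medium εr | 78 | aqueous buffer |
| cell radius | 8 μm | typical adherent glioma cell; supplied, never fitted |
| cytoplasm σ | 0.5 S/m | mammalian-cell literature value |
| cytoplasm εr | 60 | mammalian-cell literature value |
| Gspec | 0 S/m² | archetype modeling; floated in spectrum fits |

The radius, cytoplasm and medium-permittivity values are *assumptions* — a
relative-force DEP spectrum cannot identify them jointly with Cspec — and
every API accepts overrides.

## Root finding

Crossovers: sign scan of Re[CM] on a log grid at 60 points/decade, then
Brent bisection to relative tolerance 1e-6. Tangencies (Re[CM] touching 0
without a sign change) are not crossovers. The separation window between
two archetypes is the widest contiguous interval of a 200 points/decade
refinement where Re[CM] of the high-capacitance cell is positive and that
of the low-capacitance cell negative, with endpoints tightened to the
bracketing roots. Re[CM] = 0 exactly classifies as negative DEP everywhere
(deterministic, conservative tie-break).

## Spectrum fitting

The analyzer signal is modeled as r_i = A·Re[CM(f_i; Cspec, Gspec,
σ_cyto)] with one positive scale A per spectrum and zero offset, because
the instrument reports a *relative* force whose absolute field-gradient
prefactor is unidentifiable. Weighted least squares (1/sd² when per-point
sd is given, else unweighted) via lmfit's trust-region least-squares
backend; multi-start with n = 8 log-uniform starts over Cspec ∈ [1, 100]
mF/m² and Gspec ∈ [0, 5000] S/m² (alternate starts pinned at Gspec = 0),
start placement from a fixed seed so fits are reproducible. Fitting
requires ≥ 8 points over ≥ 2.5 decades. Failure to converge is a flag in
the result, not an exception.

Midpoint frequencies are read off the *fitted* curve: the membrane
midpoint is the half-rise frequency between the low-frequency plateau
(curve value at the bottom of the band) and the curve maximum, on the
rising branch; the cytoplasm midpoint is the half-fall frequency between
the maximum and the band-top value. Both are located by bracketing on a
400 points/decade grid plus Brent refinement. The cytoplasm midpoint is
flagged *unavailable* when the maximum lies in the top decade of the band
or the decline from maximum to band top is under 10% of the rise
amplitude — concrete, deterministic stand-ins for a spectrum that "does
not decrease enough" at high frequency to locate a half-fall. These
midpoint definitions are a documented choice of this package (recorded in
fit metadata), not a claim about any particular instrument's internals.

## Virtual sorting

Classification is by Re[CM] at the applied frequency only: two-way sends
positive DEP to the focused (inner-channel) outlet; three-way sends
Re[CM] ≥ τ to outlet 1, 0 < Re[CM] < τ to outlet 2, and Re[CM] ≤ 0 to
outlet 3. Default τ = 0.1, configurable — the strong/weak positive-DEP
boundary is not a measured quantity. Drive voltage and flow rate are
provenance metadata, not model inputs: without a field map or trajectory
model, the sign of the induced force is the defensible separation
principle, and it is the one the device concept itself states. An optional
seeded Bernoulli capture probability (< 1) models imperfect focusing;
default off.

The frequency chooser maximizes J(f) = fraction-positive(pop A, f) −
fraction-positive(pop B, f) on a 30 points/decade log grid, ties to the
lowest frequency.

## Dose-response and gating

IC50: Y = 100 / (1 + 10^((logIC50 − X)·h)), X = log10(concentration in
μM), top/bottom fixed at 100/0 (the normalized-response, variable-slope
model). Levenberg-Marquardt least squares, multi-start over 7 logIC50
values spanning the measured range × {−1, +1} slope starts. The slope may
fit with either sign and is reported as fitted. Zero-concentration wells
belong to normalization (untreated → 100%, blank → 0%), never to the
log-dose fit. A flat response is non-identifiable and returns
converged=False with a diagnostic. Bootstrap CIs (seeded, n=1000 case
resampling) are optional; none are computed by default.

Gating: the 50% gate is the median of the control sample; percent-high
counts intensities *strictly* above the gate, so values equal to the
threshold count as low. With an even number of distinct control values the
control reads exactly 50% against its own gate; an all-identical control
reads 0% and is flagged degenerate. The statistic is rank-based and
therefore invariant under any strictly increasing intensity transform.

## Synthetic data

The generators produce the statistical structure the analysis assumes:

- Populations: Cspec from a truncated normal within the preset bounds
  (control-like D54: 14.2–27.5 mF/m²; resistant-like D54-TR: 5.1–19.8
  mF/m²), with mean = range midpoint and sd = range/4 — the bounds are
  measured ranges, the shape within them is an assumption. Radii truncated
  normal around 8 ± 1 μm. GBM1/GBM2 are degenerate point presets at 20 and
  10 mF/m².
- Spectra: r_i = A·Re[CM(f_i)]·(1 + cv·z_i) + sd_add·w_i on the 20-point,
  10 kHz–45 MHz instrument grid; default cv = 5%.
- Dose-responses: the logistic model forward plus multiplicative noise.
- Lectin intensities: log-normal; the resistant preset shifts the log-mean
  down (default −0.5), taking only the *direction* of reduced binding from
  the biology.

Every generator owns its seed, so streams are independent and adding one
call never perturbs another.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: cell-to-cell correlation between Cspec, Gspec
and radius; multi-modal or skewed capacitance distributions;
frequency-correlated instrument noise and well-to-well drift; device
hydrodynamics (cells near the τ boundary being stochastically missorted);
dose-response floors above 0% at high drug; autofluorescence and
spillover in intensity data. Conclusions here are about the correctness of
the computational chain under its stated model, not about biology.

## Problem sizes and runtime

Default verification sizes: 50 noisy spectra per archetype for recovery
checks, 2000-cell mixtures for sorting, 20 seeded replicates for IC50
bias, 10⁴ draws for distributional checks, 10⁵ evaluations for the CM
bound sweep. The full test suite runs in ~15 s and the acceptance script
in ~15 s on one CPU.

## Known limitations

- Single-shell only: no nucleus/organelle dispersion, so the
  high-frequency falling branch is a single cytoplasm dispersion.
- Relative Re[CM] only; no force magnitudes in newtons, no trajectories.
- Cspec is identifiable only given the radius; if the supplied radius is
  biased, recovered Cspec is biased by the same factor.
- The spectrum fit assumes homogeneous per-well populations; a well
  containing a capacitance mixture yields an effective average.
- The midpoint and unavailability definitions are this package's
  operationalization and may differ numerically from any given
  commercial analyzer's.
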