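# Methods

## The measurement being modelled

A confocal FCS instrument parks a diffraction-limited laser focus in a
cell nucleus and records photon counts in short bins (15.0 µs
illumination periods; 60-s records made of six consecutive 10-s
segments).  Fluorescently tagged protein molecules crossing the
detection volume produce intensity fluctuations whose autocorrelation
decays on the timescale of their transit; molecules bound stably
inside the volume do not exchange and instead photobleach, producing
an exponential decay of the mean intensity at the start of a record.
The detection volume is modelled as a 3D Gaussian with lateral 1/e²
radius ω and axial radius S·ω; the default S = 5 reflects a volume
roughly 400 nm wide and 2000 nm high.

## Autocorrelation

The normalized autocorrelation is `G(τ) = ⟨I(t)I(t+τ)⟩ / ⟨I⟩²`, with
the convention G → 1 at full decorrelation (so the fluctuation
amplitude G(0) − 1 equals 1/N for N independent emitters).  The
correlator uses the standard multi-tau scheme: 16 lags per octave, the
signal coarsened pairwise between octaves, and each lag normalized
symmetrically by the means of the two overlapping windows (this
removes the leading finite-length bias).  The base lag equals the
trace's bin width: photon-timestamp input is binned at 0.2 µs, while
15-µs binned traces start at 15 µs — no information relevant to the
fit is lost because the fit range starts at 50 µs.  The maximum lag
defaults to min(3.4 s, duration/10); a user-specified lag violating
the 10× rule is an error.  Cross-segment standard deviations (floored
at 10⁻⁶) provide the per-lag weights; a single segment falls back to
unit weights with a warning, after which χ² loses its absolute meaning
but nested-model comparison remains valid.

## Photobleach handling

The envelope fit `y(t) = A e^{-kt} + y0` is performed on the 0.1-s
re-binned rate, decoupling the seconds-scale decay from microsecond
shot noise.  A record is flagged as bleaching when all three hold:
bleached fraction A/(A+y0) > 5%, decay time 1/k shorter than the
record, and the exponential reduces the RMS residual by ≥ 20% relative
to a constant fit.  The criterion is scale-free; the thresholds encode
the qualitative distinction between visibly decaying and flat records.
Excision windows are presets (20 s for silk-gland cells, 10 s for
HeLa) and are applied only when the flag fires, matching the original
workflow in which only bleaching constructs had their initial period
removed.

## The diffusion model and its fitting

The M-component model (M = 1–3) is the standard two-factor
3D-Gaussian form with an additive baseline of 1; α = 1 is free
Brownian diffusion, α < 1 obstructed diffusion (fitted only on
request).  The triplet-blinking factor is excluded by default: the fit
range starts at 50 µs, far above triplet relaxation, and including the
term changes the fitted parameters negligibly.  S is fixed at its
calibrated value by default because free-S three-component fits are
ill-conditioned.

Fitting minimizes the σ-weighted χ² with `scipy.optimize.least_squares`
on a transformed parameter vector: ln N, stick-breaking coordinates
for the fractions (Σ Fᵢ = 1 holds exactly), ln τᵢ with bounds
[1 µs, 10 s], α ∈ (0.1, 1].  Label switching is broken by sorting
components in ascending τ after optimization.  Eight seeded starts
(the first from an amplitude/lag heuristic or a user-supplied
initialization, the rest log-normal perturbations of it) guard against
local minima; the fit is deterministic for a fixed seed.  Parameter
uncertainties come from the Jacobian covariance propagated to the
natural parameters by the delta method.

## Model selection

Candidates are compared with AICc and stepwise nested F-tests
(`DF = N_fit − K − 1`; p from the upper tail of F(ΔDF, DF₂)).  A more
complex model is accepted at p < 0.05 — a conventional threshold —
and only when the AICc agrees; on disagreement the simpler model is
kept with a warning (conservative, mirroring the joint use of both
criteria).  Fits with a component fraction below 1% (too little
amplitude to carry a reliable diffusion time) or a diffusion time
pinned at the bounds are rejected as unphysical.  With ≥ 3 replicate
curves a dispersion screen flags any candidate whose per-parameter
coefficient of variation (sample SD / mean) exceeds 200%.  Note that
with only three replicates a CV of 200% is unreachable for
non-negative parameters (the sample-SD/mean of three such values is
bounded by √3 ≈ 173%); the screen becomes informative at the replicate
counts of real datasets (n ≈ 7–29).

Under the null (data truly from the simpler model) the F-test is
conservative: the extra component's fraction sits on the boundary
F = 0 and its diffusion time is unidentified, so the nominal
F-reference overstates the expected improvement.  The measured
rejection rate at p < 0.05 is ~2% rather than 5%, which biases
selection toward the simpler model — the desirable direction for this
procedure.

## Derived quantities

ω is calibrated from a reference dye (rhodamine 6G by default,
D = 414 µm²/s at 25 °C — a value the user should confirm for their
instrument and temperature), then `Dᵢ = ω²/(4τᵢ)`.  Apparent masses
follow the Stokes–Einstein cube law anchored at the 27 kDa EGFP
monomer, `Mwᵢ = 27·(τᵢ/τ_EGFP)³`, and are reported both unrounded and
at 2 significant figures; mass-over-monomer ratios are reported in
both conventions (rounding before or after the division can move the
leading digit).  Because D is convex in τ, the mean of per-measurement
D values exceeds D evaluated at the mean τ on a dispersed sample
(Jensen gap) — both conventions are available.  Motif spacing treats
bases as independent with a given composition (uniform by default);
the expected spacing is the reciprocal of the product of per-position
IUPAC match probabilities on a single strand.

## FRAP

Series are normalized to the mean of the pre-bleach frames (three by
default) with the time origin at the first post-bleach frame, then
fitted with `y(t) = offset + plateau(1 − e^{-kt})` on the post-bleach
samples.  The bleach depth (offset) is fitted rather than fixed, for
robustness to incomplete bleaching.  `t_half = ln2/k`; the recovery
fraction is offset + plateau.  A fitted half-time below two frame
intervals is reported as below resolution rather than as a number —
the regime of freely diffusing fluorophores whose recovery the frame
rate cannot resolve.

## The synthetic-data generator

`simulate_trace` propagates mobile particles with independent per-axis
Gaussian steps of variance 2DΔt in a periodic cube, weights each by
the Gaussian detection profile centred in the box, adds immobile
particles that bleach irreversibly (per-particle geometric
step-survival at rate k, drawn as a geometric lifetime), and draws
Poisson counts per bin.  The propagation step equals the bin width:
at nuclear-scale D the RMS step (≈ 27 nm at 25 µm²/s and 15 µs) is
well below ω, so sub-stepping is unnecessary.  All randomness derives
from one generator seeded with the config seed; repeated runs are
bit-identical.

Defaults mirror the emulated experiment: 60-s records, six 10-s
segments, 15-µs bins, ω = 0.2 µm, S = 5.  The default box is a 3 µm
cube — 15 waists laterally but only 3 axial radii, a compromise
between fidelity and cost.  The open-volume analytic ACF is therefore
a valid oracle only up to lags where lateral decay dominates: beyond
roughly the lowest axial wrap-around mode time, (L/2π)²/D, the
periodic images distort the tail.  The validation experiments respect
this: the one-component check fits up to 4 ms (10 diffusion times, at
L = 3 µm), and the two-component check uses a 6 µm box with the fit
capped at 10 ms.  Finite records also bias the extreme tail of the
estimated ACF downward (the classic ⟨I⟩-estimation bias of order
τ_c/T), which is why validation uses 10–20 s records and restricted
fit windows rather than the full 3.4-s range.

What the generator does not emulate: triplet blinking and other fast
photophysics, detector afterpulsing and dead time, flow or active
transport, anomalous-diffusion trajectories (α < 1 curves are
available analytically through `synthesize_acf` but not as
trajectories), and the cell-to-cell variability of real nuclei.
Passing the synthetic-data tests therefore demonstrates correctness of
the estimators under the model's own assumptions, not instrument-level
realism.

Validation problem sizes (chosen to keep the suite fast while leaving
clear statistical margin): one-component agreement uses ten 10-s
traces of 100 particles; two-component agreement averages ten 20-s
traces of 120 particles in the larger box; selection rates use 20
synthetic curves per truth class at σ = 0.005; the F-test null uses
200 replicates; the bleach false-positive screen uses 100 cheap
millisecond-binned traces.

## Known limitations

- Correlation curves are computed from binned counts; sub-bin photon
  history (true 0.2-µs resolution from timestamp inputs) is supported
  only insofar as the input is binned on read.
- The F-test and AICc both assume well-estimated per-lag σ; with unit
  weights only their comparative use is meaningful.
- `write_report` summarizes constructs by mean ± SD, which understates
  uncertainty for small n; per-curve detail is always written
  alongside.
- No reader for proprietary instrument raw files; export to delimited
  text or timestamp lists first.
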