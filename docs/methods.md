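# Methods

`filmcal` implements a dose-calibration pipeline for Gafchromic EBT3
radiochromic film read on a flatbed scanner, built around two estimators —
a conventional red-channel net-optical-density power-law fit and a
seven-subnet hierarchical neural network (HNN) — plus a cubic lot-transfer
refit and a synthetic film-response simulator used for all testing.

## Measurement model

A film is scanned before irradiation (*prescan*, supplying the per-channel
background pixel value, BPV) and ~24 h after (*postscan*, the irradiated
pixel value, IPV), both as 16-bit RGB TIFFs at a fixed dpi. In the
calibration geometry the film stands parallel to the beam axis with its
midline on the central axis inside a solid phantom, so each depth row of
the midline receives the dose

D(z) = MU · k · PDD(z)/100,

with k the machine calibration (1 cGy/MU under reference conditions) and
PDD the verified percentage-depth-dose curve. One film therefore yields a
few hundred (features, dose) samples. Midline pixel values are means over
a lateral window (default ±5 px at a 5 px step, ≈1 mm sampling at
127 dpi); the window and step are not dictated by the geometry and are
configurable.

Per sample, three families of scanner read-outs are computed:

* net optical density, `NOD_W = log10(PV_pre / PV_post)`;
* the raw irradiated and background pixel values per channel;
* inverse transmittance, `IT_W = (2^16 − 1) / PV_post`.

## Conventional calibration

Delivered dose is fitted to the red-channel NOD with
`D = a·NOD + b·NOD^c` in two stages: stage 1 bounds `c ∈ [1, 3]` (trust-
region least squares, multi-start over c₀ ∈ {1.5, 2.0, 2.5}, a₀ from a
linear pre-fit); the fitted exponent is rounded to the nearest tenth and
stage 2 refits `a, b` with `c` held fixed, warm-started from stage 1. We
read the protocol's "second fit started with the same parameter values" as
warm-starting `a, b` with `c` *fixed* — rounding the exponent would be
pointless if it were immediately re-freed. On noiseless data drawn from
the model with a tenth-valued exponent the procedure recovers (a, b, c)
exactly (c) and to <0.5% (a, b); this is a regression test.

The conventional method's weakness is the aging effect: film sensitivity
drifts with shelf life, so a calibration fitted months earlier
systematically mis-doses new exposures even though NOD subtracts the
background level itself.

## The hierarchical network

The ten features are grouped as (1) R-NOD, (2) R-IPV/R-BPV,
(3) G-IPV/G-BPV, (4) B-IPV/B-BPV, (5) R-IT/G-IT/B-IT and fed to five leaf
subnets; a combiner O6 merges the three pixel-value subnets and the head
O7 merges O1, O5, O6 into the dose estimate H:

| subnet | widths | hidden activation |
|---|---|---|
| O1 | 1-20-10-7-1 | selu |
| O2 | 2-10-7-2-1 | linear |
| O3 | 2-10-7-1 | linear |
| O4 | 2-10-7-1 | linear |
| O5 | 3-15-7-1 | softplus |
| O6 | 3-10-7-1 | selu |
| O7 | 3-20-6-1 | selu |

All subnet output layers are linear; the total trainable parameter count
is 1209 (verified analytically in the tests). The graph is trained
end-to-end against delivered dose with a single mean-squared-error loss at
O7 (no auxiliary losses), Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7),
batch 20, 500 epochs, initial weights uniform in [−0.05, 0.05] (biases
zero) from a fixed seed (default 435), and 45% of the samples held back
for validation (seeded shuffle, tail split, reproducible). Training
records per-epoch MSE (cGy²), MAE (cGy), validation MSE/MAE, and an
exact-match "accuracy" metric that is kept only for protocol completeness
and is meaningless for regression. The network is implemented directly in
NumPy (dense blocks with cached forward passes and manual backpropagation
through the subnet DAG); at ~1200 parameters this trains in tens of
seconds on one CPU core.

Two numerical choices deserve explanation:

* **Internal standardisation.** Inputs and target are z-scored inside
  `fit()` (statistics stored on the model and inverted at prediction
  time; `scale_inputs=False` disables it). The features themselves are
  defined and emitted unscaled; but raw pixel values of order 10⁴ against
  a uniform ±0.05 initialisation leave Adam hopelessly ill-conditioned at
  this epoch budget, and standardisation also puts the small-variance
  background features on an equal footing so the age signal is learnable.
* **Activation placement.** The architecture names five activation
  functions without mapping them to layers, so the placement is this
  package's choice (fully configurable per subnet). The background-PV
  subnets O2–O4 use *linear* hidden layers: their role is to extract the
  film's shelf-age proxy, which is linear in the pixel values, and a
  linear block extrapolates that proxy exactly to shelf ages beyond the
  training range. In convergence experiments, nonlinear hidden layers in
  O2–O4 left a ~1% extra systematic dose bias on films aged past the
  training window and roughly doubled the aging-test MSE.

The background (prescan) inputs are what lets the network compensate
aging: the background level drifts with shelf age, so O2–O4 hand the head
an age estimate alongside the dose-dependent signals. Ablating them
(replacing the BPV columns by constants) measurably degrades the aging
verification — a regression test asserts this directionally.

## Lot transfer (cubic refit)

A network trained on one lot mis-doses other lots because net-OD
sensitivity differs between lots, but the map from the network estimate H
to true dose is smooth and monotone. A cubic
`D_rfit = e·H³ + f·H² + g·H + k`, ordinary least squares of delivered
dose on H over a single calibration session of the new lot, corrects all
later sessions of that lot. The printed form of the corresponding
percentage-error definition in the source material is garbled
("E = D_rd = D_d/D_d"); it is implemented as `(D_rd − D_d)/D_d × 100%`,
by symmetry with the conventional method's error definition. The cubic is
only trusted on the H range it was fitted on — cubics diverge — so
evaluations outside `[min H, max H]` are counted and flagged in every
report, and the bundled study design gives each new lot a two-film first
calibration (250 and 400 MU) so the fitted range covers the verification
range. For the training lot itself no refit is applied (D_rd = H); that
is how the aging verification runs.

## Synthetic film simulator

No real film scans ship with the package, so a phenomenological generator
emulates the data properties the pipeline must survive. Net OD for
channel W at dose D (cGy) and shelf age t (months):

netOD_W = s_L · (1 + r_s·t) · (α_W·D/(D + β_W) + γ_W·D)

with background `PV_pre = B_W · (1 − r_b·t)` and
`PV_post = PV_pre · 10^(−netOD)`; each emitted pixel value is multiplied
by independent Gaussian noise N(1, σ). Defaults:

| parameter | R | G | B | meaning |
|---|---|---|---|---|
| α (net OD) | 0.55 | 0.50 | 0.30 | saturating amplitude |
| β (cGy) | 300 | 600 | 800 | half-saturation dose |
| γ (OD/cGy) | 2e-4 | 1.5e-4 | 1e-4 | residual linear slope |
| B (16-bit PV) | 44000 | 47000 | 42000 | fresh background |

These give EBT3-like behaviour: red is the most sensitive channel at
clinical doses (α/β ordering red > green > blue is enforced), green and
blue saturate later. Lot-to-lot variation is a sensitivity multiplier
s_L; aging drifts sensitivity by r_s = +0.8%/month and background by
r_b = −0.15%/month; scanner noise is σ = 0.003 per emitted value. The
synthetic beam is 6 MV-like: linear build-up to d_max = 15 mm, then
exp(−0.0055·(d − d_max)) attenuation. Depth sampling starts at d_max
(the build-up region is excluded, as is standard dosimetry practice) and
runs to 245 mm at 1 mm steps, ≈231 samples per film, each film spanning
a factor ≈3.5 in dose.

The bundled study design mirrors the method's intended workflow: a
training lot with 17 sessions — sessions 1–16 evenly spread over months
0–16 cycling through 100/200/300/400 MU, session 17 four months after the
16th at 400 MU — and two held-out lots (sensitivity ±7%/−5%, 7 and 3
sessions) whose films use ≥250 MU so verification doses stay above
~70 cGy, the low end of the clinical verification range.

What the simulator does **not** model: film-chemistry kinetics and
post-exposure darkening, scanner lateral-response and warm-up artefacts,
film inhomogeneity and dust, orientation effects, or edge artefacts.
Passing tests on this generator therefore demonstrate the pipeline's
statistical behaviour under controlled dose response, drift and noise —
not performance on any particular scanner/film combination.

## Verification protocol and what the numbers mean

`filmcal.study.run_verification_study(seed)` runs the whole design:
portion I (sessions 1–11) trains the network used for the intralot tests;
portion II (sessions 1–16) trains the one used for the aging test on
session 17; the conventional fit on session 16 provides the comparison on
the aged session. Reported per test: signed per-sample percent errors,
max and mean |percent error|, MSE/RMSE/MAE in cGy units.

Two caveats, measured and intentional, frame the error statistics:

* A single sample's dose information is noise-limited. Propagating the
  σ = 0.003 pixel noise through the response model gives a per-sample
  Cramér–Rao dose uncertainty of ~0.9% at 130 cGy and ~1.55% at 70 cGy
  even when all three channels are pooled optimally; a *maximum* over
  hundreds of verification samples therefore has an irreducible floor of
  several percent under these noise conditions, whatever the estimator.
  The network's scatter runs ~1.3–1.5× this bound.
* Estimating shelf age from noisy background values is an
  errors-in-variables problem: regression attenuates the age signal, so
  predictions on films aged *beyond* the training window keep a small
  systematic bias (~1–2% at a 4-month extrapolation) on top of the
  scatter.

Both effects are properties of the study conditions, not tunables; the
package reports them rather than hiding them. The qualitative claims are
robust and asserted in the test suite: the network's aged-film errors are
several times smaller than the conventional power-law's (mean ~1.8% vs
~4.5%, MSE ~27 vs ~143 cGy² at seed 1), the background inputs carry the
aging compensation, and the cubic refit transfers the model across
sensitivity-shifted lots.

A further measured limitation: lot-to-lot *background-level* differences
confound the age proxy. A base-background shift of only +0.5% reads as
≈3.3 months of apparent shelf age (because r_b is small), which pushes a
new lot's first calibration outside the trained background range and
leaves an age-growing residual (~0.5%/month) that the one-session cubic
refit cannot absorb. The bundled held-out lots therefore differ in
sensitivity only; users transferring to lots with shifted background
levels should expect degraded aging compensation.

## Degenerate inputs and tie-breaks

Non-positive pixel values are rejected wherever a logarithm or division
is taken; the power fit requires ≥4 samples with non-constant NOD; the
cubic refit requires ≥4 samples spanning a nonzero range; training
requires at least one full batch and aborts with the epoch number if the
loss becomes non-finite. Even image widths take `floor(width/2)` as the
midline column; 8-bit scans are promoted to the 16-bit scale by ×257;
profile pairing matches positions to 1e-9 mm and drops unmatched rows.
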