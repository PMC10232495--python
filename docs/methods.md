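# Methods

`dcsflow` models and analyzes diffuse correlation spectroscopy (DCS)
measurements of tissue blood flow, in both the traditional homodyne form
and the heterodyne (interferometric) form in which the weak diffusely
backscattered field is mixed with a strong reference split from the same
laser. This note records the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Forward models

**Siegert relation.** For Gaussian speckle fields the measured intensity
autocorrelation is `g2(τ) = 1 + β |g1(τ)|²`, with coherence parameter β set
by source coherence, detected mode count and stray light. Heterodyne
detection instead gives

```
g2(τ) = 1 + β (I_S/I_T)² |g1(τ)|² + β (2 I_S I_R / I_T²) |g1(τ)| ,
```

with sample, reference and total mean intensities `I_S`, `I_R`,
`I_T = I_S + I_R`. In the reference-dominant regime (`I_R ≫ I_S`, the
operating point of a camera-based interferometric instrument) the measured
fluctuation is proportional to `|g1|`, not `|g1|²` — the origin of both the
noise advantage and the fitting subtlety addressed below.

**Field autocorrelation.** The field decorrelation accumulated along a
photon path of length `s` is `exp(-(1/3) k0² n² ⟨Δr²(τ)⟩ s/l*)` with vacuum
wavenumber `k0 = 2π/λ`, tissue index `n`, transport mean free path
`l* = 1/μs'`, and mean squared scatterer displacement modeled as diffusive,
`⟨Δr²(τ)⟩ = 6·BFi·τ`. The blood flow index BFi (= α·Db, cm²/s) is the
quantity all fits report. `g1` is the pathlength-distribution average of
this kernel; for a homogeneous semi-infinite medium in reflectance it has
the closed form implemented in `semi_infinite_g1` (extrapolated-boundary
solution with `K(τ) = sqrt(3 μa μs' + 6 k0² n² μs'² BFi τ)`, `r1`, `rb`,
`zb`, and the standard polynomial `Reff(n)`).

Units are centimeters and seconds throughout; the default wavelength is
1064 nm and the default tissue index 1.4 (a community convention — tissue
indices are rarely measured per subject). The `n²` factor is kept explicit
rather than folded into an effective wavenumber, matching the printed form
of the correlation-diffusion solution.

## Correlation Monte Carlo

`mc_transport` implements a layered-slab photon Monte Carlo whose purpose
is correlation synthesis, not dosimetry: for each detected photon it
tallies the per-layer pathlength `s_j` and the per-layer dimensionless
momentum transfer `Y_j = Σ(1 - cos θ)`. Because `E[Y_j] = s_j/l*_j`, the
homogeneous pathlength kernel generalizes to layers as

```
g1(τ) = Σ_i w_i exp(-2 k0² τ Σ_j n_j² BFi_j Y_ij) / Σ_i w_i ,
```

so a single simulation supports any assignment of per-layer flows (e.g. a
baseline and an activated brain state reuse the same records).

Choices, with rationale:

* **Phase function** — Henyey–Greenstein with g = 0.9 and
  `μs = μs'/(1-g)`; similarity keeps diffuse observables comparable while
  the momentum-transfer tally remains exact per scattering event.
* **Boundaries** — unpolarized Fresnel reflection/refraction against the
  ambient index (default air) at the top (and bottom, if the last layer is
  finite); internal interfaces are index-matched by default but per-layer
  indices are honored when set.
* **Absorption** — applied once at detection as `exp(-Σ μa,j s_j)` (weighted
  exit), which is unbiased for every tallied functional and keeps the
  random-number stream short and reproducible (single stream per run,
  seeded).
* **Detector** — an annulus centered on the source exploiting cylindrical
  symmetry. This trades an exact fiber footprint for orders of magnitude in
  detection statistics; the recorded `ρ` is the annulus mid-radius.
* **Domain truncation** — photons are terminated beyond a kill depth
  (8 cm), a lateral margin (annulus outer radius + 6 cm) or an accumulated
  absorption optical depth of 12 (residual weight < 1e-5). Varying these
  bounds moves the synthesized `g1` by less than the Monte Carlo noise at
  the problem sizes used.

The homogeneous cross-checks (closed-form `g1`, diffusion-theory mean
pathlength, momentum-transfer/pathlength equivalence) are part of the test
suite.

## Plateau fit range and the weighted heterodyne objective

All fits use the semi-infinite model and restrict the lag range to where
the curve's above-baseline component exceeds 5% of its plateau (plateau
from the first three lags; baseline from the last 10% of lags). On
multilayer tissue this convention makes homodyne (`|g1|²`) and heterodyne
(`|g1|`) fits genuinely different measurements: a `|g1|`-proportional curve
stays above the 5% threshold far longer, so an unweighted fit is dominated
by late lags that carry mostly superficial (scalp) dynamics, depressing
both the baseline BFi and the resolved fraction of a cerebral flow change.

The heterodyne objective therefore supports data-driven weighting,

```
obj = Σ_τ ( g1,meas(τ) − A·g1,model(BFi, τ) )² · ⟨g1,meas(τ)⟩_T^x ,
```

with the weights taken from the time-averaged measured curve over the whole
measurement and a tunable exponent x. Implementation choices: the reference
curve is clipped at zero and renormalized to a maximum of 1 on the fit
range before exponentiation (so x changes weight shape, not scale); the
amplitude A — and for homodyne fits β — is fitted jointly with BFi rather
than fixed; the optimizer is bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-10) initialized from a
coarse logarithmic BFi scan over 1e-10..1e-6 cm²/s.

`optimize_weight_exponent` scores each candidate x by the squared relative
baseline-BFi mismatch plus the squared difference in fractional response
between the weighted `|g1|` fit and the `|g1|²` fit, equally weighted — the
simplest symmetric choice given that the goal is equivalence of both the
level and the response. Ties (scores equal within numerical noise, as in a
homogeneous medium where all exponents are equivalent) break toward smaller
x. On the representative forehead geometry below, the score curve is
unimodal with its minimum at x = 2.5, where the weighted `|g1|` fit matches
the `|g1|²` fit in both baseline and response to within a few percent,
whereas the unweighted fit resolves only ~40% of the `|g1|²` response.

## Representative forehead geometry

The packaged default three-layer slab (overridable via YAML or the
`LayeredSlab` API):

| layer | thickness | μa [1/cm] | μs' [1/cm] | n | g | BFi [cm²/s] |
|-------|-----------|-----------|------------|-----|-----|-------------|
| scalp | 5 mm | 0.15 | 8 | 1.4 | 0.9 | 1e-8 |
| skull | 7 mm | 0.10 | 9 | 1.4 | 0.9 | 2e-9 |
| brain | semi-infinite | 0.13 | 10 | 1.4 | 0.9 | 6e-8 |

These are typical long-wavelength adult-forehead values; the skull BFi is a
conventional low-perfusion bone figure. The packaged experiment probes this
slab at ρ = 2.5 cm (annulus ±0.25 cm) with 0.8–3 × 10⁶ launched photons
(roughly 2–7 × 10⁴ detected). The exponent optimum is very stable at these
budgets; the unweighted resolved fraction is the noisiest reported quantity
(its response signal lives in the late-lag tail carried by relatively few
deep photons) and retains a few percentage points of seed-to-seed spread. Larger separations (the 3.5 cm
used clinically) are supported but cost proportionally more photons; the
optimal exponent is geometry-dependent and should be re-derived when layer
thicknesses or flows differ materially.

The experiment fits with deliberately mismatched homogeneous properties
(μa 0.13, μs' 9) — fitting layered data with a homogeneous model and
assumed properties is exactly the situation the weighting addresses.

## Synthetic-data generators

All generators are pure functions of (configuration, seed).

* **Correlation noise** — zero-mean, lag-correlated noise with per-lag sd
  `∝ sqrt(1 + β|g1|²) / sqrt(count_rate · T)`, a shot-noise-limited
  stand-in with the canonical scaling. It reproduces neither detector
  afterpulsing nor the full multi-tau covariance of a real correlator.
* **Pulsatile BFi** — a gamma-shaped systolic rise/diastolic decay waveform
  with Gaussian beat-to-beat jitter, multiplicative task epochs
  (baseline/activation/recovery schedules mirroring 60 s baselines with
  30 s manipulations), and ground-truth beat onsets for gating tests.
  Defaults: mean BFi 1e-8 cm²/s, pulsatility fraction 0.3, 60 bpm. There is
  no autoregulation, respiration or vasomotion model.
* **Curve streams** — one forward-model curve per instrument window (100 Hz
  long-separation, 10 Hz short-separation conventions) from window-mean
  BFi, through either detection model, plus optional correlation noise.
* **Linescan frames** — per-pixel independent complex circular-Gaussian
  fields with a prescribed temporal autocorrelation (exponential or the
  semi-infinite model; circulant-embedding synthesis), interfered with a
  constant reference, plus: per-pixel quadratic drift, a rank-1 smooth
  common-mode signal, integrate-while-read leakage modeled as
  `obs_t = (1-c)·true_t + c·obs_{t-1}`, and Gaussian read noise. Artifact
  magnitudes are order-of-magnitude placeholders — the real instrument's
  artifact statistics are not published — so passing recovery tests shows
  the chain inverts the modeled artifacts, not that it would clean any
  particular camera's data. Exposure-time integration within a line is
  neglected (fields are sampled at line times).

## Preprocessing chain

Each step is the simplest faithful form of the corresponding cleaning
operation, behind named options: exact inverse filtering for the line
leakage; per-window least-squares quadratic detrending with the window mean
re-added (idempotent); non-overlapping k-pixel averaging; common-mode
removal by per-channel regression on the across-camera mean (or first
principal component, selectable — with tens of channels the two are nearly
equivalent on rank-1 contamination). Windowed normalized intensity
autocorrelation uses a multi-tau-style lag grid (16 linear lags then
logarithmic), excludes lag 0 (noise spike), and averages channels; 10 ms
windows give the conventional 100 Hz curve rate.

On the full synthetic chain the recovered BFi carries a small (~3%)
positive bias from finite-window normalization of the autocorrelation
estimator; the end-to-end test allows for it explicitly.

## Physiological analytics

Beat-to-beat filtering assigns per-RR-interval means to beat centers and
linearly interpolates back to the original rate. Cardiac gating linearly
time-warps each beat onto a fixed number of phase bins (default 100),
groups consecutive beats into traces (default 3 cycles per trace), and
reports per-phase mean, sd and CoV = sd/mean across traces. Relative BFi
divides each trial by its own mean over the 20 s preceding the event onset.
Cross-correlation alignment maximizes the normalized correlation over
integer lags with parabolic sub-sample refinement; perfectly periodic
inputs make the offset ambiguous up to a whole period (physiological jitter
resolves this in practice). Bland–Altman agreement reports
`bias = mean(y-x)`, the sample sd of differences, and 1.96-sd limits;
pairing is per-beat by convention. Beat detection itself is out of scope —
beat times enter as given (ECG-derived in practice); a simple peak-picker
ships as a test utility only. Trials with artifacts are flagged, never
auto-rejected.

## Known limitations

* Slab layers only — no curved or voxelized anatomy, no analytic multilayer
  inverse model.
* The Monte Carlo is CPU-bound single-stream; the annulus detector is an
  approximation to a discrete fiber footprint.
* The heterodyne speckle model assumes fully developed, polarized,
  per-pixel-independent speckle with a noiseless reference; fiber-motion
  and vibration artifacts are represented only by the generic common-mode
  term.
* The optimal weighting exponent is a property of the simulated geometry;
  2.5 is the optimum for the packaged representative slab, not a universal
  constant.
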