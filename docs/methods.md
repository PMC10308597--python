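# Methods

## Sensing model

The sensing zone of the square microaperture (30 μm × 30 μm at its
narrowest, ~30 μm long) filled with conductive buffer is modelled as a
lumped network: fluid resistance `R_f` in parallel with a parasitic
electrode capacitance `C_p`, plus a small series lead inductance `L_s`,

    Z_base(ω) = jωL_s + R_f / (1 + jωR_f C_p).

The magnitude is flat (≈ `R_f`) below the RC corner `1/(2πR_f C_p)` and
declines above it; the phase is ~0° at low frequency, capacitive near the
corner and inductive only above the LC resonance. Impedances use the
`e^{+jωt}` convention, so capacitive phase is negative; phase is reported
in degrees throughout.

A transiting bead perturbs the slab of fluid it occupies — a fraction
`eta_slab` of `R_f` (default 0.3; `R_slab = eta_slab·R_f`). The bead
element is

    ΔB(ω) = (R_slab + ΔR) ∥ 1/(jωC_b) [∥ (R_sh + 1/(jωC_sh))] − R_slab,

with the shell branch present only for metallized beads, and the total
impedance during a transit is

    Z(ω) = jωL_s + (R_f + s·ΔB(ω)) ∥ 1/(jωC_p),

where `s(t) ∈ [0, 1]` is the occupancy pulse. `s = 0` reproduces the
baseline exactly (same algebraic form, bit-for-bit).

`ΔR` is the DeBlois–Bean resistive-pulse amplitude with the square
aperture replaced by an equal-area circle (`D_eff = 2·side/√π ≈ 33.9 μm`):

    ΔR = 4ρd³/(πD_eff⁴) · [1 − 0.8(d/D_eff)³]⁻¹,

strictly increasing in diameter and asymptotically cubic for `d ≪ D_eff`.
At ρ = 0.625 Ω·m (≈1× PBS) an 8.2 μm bead gives ΔR ≈ 338 Ω, comfortably
above the 110 Ω detection threshold.

### Metallization shell

The silver deposit is not a conformal conductive layer but a nanostructured
mesh of metal spheroids and electrolyte. It is modelled as a resistor
`R_sh` in series with a metal–electrolyte interface capacitance `C_sh`, in
parallel with the nonconductive bead element. A metallization density
`m ∈ [0, 1]` maps to the shell as `R_sh = r0/m`, `C_sh = c0·m`
(`r0 = 0.1·R_slab = 625 Ω`, `c0 = 50 pF`): the shell vanishes as `m → 0`
and its conduction onset moves down in frequency as `m` grows. At
frequencies where `1/(ωC_sh) ≪ R_slab` the shell short-circuits the
displaced slab and ΔZp turns negative — but at 45 kHz the interface
capacitance still blocks, so the low-frequency pulse stays positive and
detectable (≈275 Ω even at `m = 1`). Setting `C_sh → ∞` recovers the
conformal-layer model, which dips at **all** six carriers; the contrast
between the two behaviours is a core qualitative check in the test suite.

## Calibration

The instrument's element values are not observable from the published
record, so the defaults are calibrated once to reproduce the qualitative
spectral signatures at the six carriers (45 kHz, 150 kHz, 380 kHz, 2 MHz,
11 MHz, 35 MHz):

| parameter | default | rationale |
|---|---|---|
| `R_f` | ρ·L/A ≈ 20.8 kΩ | geometry at 1× PBS (ρ = 0.625 Ω·m) |
| `C_p` | 2.55 pF | RC corner at 3 MHz: keeps the baseline flat through 2 MHz and puts the bead-induced phase-change maximum on the 2 MHz carrier |
| `L_s` | 0.1 μH | inductive behaviour only above the band (LC resonance ≈ 315 MHz) |
| `C_b` | 1.814 F/m³ · d³ (1 fF at 8.2 μm) | volume-scaled effective dielectric contribution of the bead |
| `r0`, `c0` | 625 Ω, 50 pF | negative dip from 150 kHz upward at full metallization while preserving the 45 kHz pulse |

Two couplings constrain this calibration tightly. First, a nonconductive
bead must give ΔZp > 0 at *all* six carriers (negative dips are exclusively
a metallization signature): above the network corner, the bead's
capacitive component rotates into a magnitude *reduction*, which bounds
`C_b` from above (≈3 fF at 8.2 μm with the 3 MHz corner); `C_b` is scaled
with bead volume so the bound holds across the 3.9–20.1 μm size range.
Second, the peak phase change of the nonconductive bead must be maximal on
the 2 MHz carrier: the phase sensitivity of the network to a series
perturbation peaks at the RC corner, so the corner is placed at 3 MHz —
below √(2·11) ≈ 4.7 MHz, which is where the maximum would migrate to the
11 MHz carrier.

## Synthetic data

`synthesize_trial` emulates a lock-in acquisition at 57,000 samples/s over
six carriers, default 1.5 s and 60 beads per trial:

* **Transit pulses.** Symmetric Gaussian bells, `s(t) = a·exp(−(t−t0)²/2σ²)`
  with FWHM τ derived from the 10 μL/min flow through the aperture
  cross-section (~0.2 ms, ~12 samples); apexes are placed on the sample
  grid, uniformly at random with ≥10τ spacing (a too-short duration raises
  an error). The off-centre factor `a` is 1.0 ± 0.05.
* **Dose → metallization.** A saturable 4PL-shaped link maps probe
  concentration to mean metallization density (floor 0.002, ceiling 0.85,
  half-effect 20 nM, Hill 1.5); each bead's density is a mean-preserving
  lognormal draw (sd 0.6 on the log scale) clipped to [0, 1]. The
  continuous density spectrum, not hard-coded clusters, produces the
  M_hi/M_med/M_lo structure after gating.
* **Imperfections.** i.i.d. Gaussian noise per channel (10 Ω magnitude,
  0.5° phase) and a slow sinusoidal magnitude drift (200 Ω at 1 Hz),
  which is what the detection stage's high-pass filter exists to remove.

Everything is a pure function of (trial spec, aperture, acquisition
config) including the two seeds, which are combined into a single
generator stream. `synthesize_bead_records` is a fast record-level path
(noise-free peak signature per bead plus measurement noise) used for
metric- and dose-level studies where the waveform stage is not under test.

What the generator does **not** emulate: coincident/overlapping transits,
off-centre pulse-shape distortion (only an amplitude factor), electrode
double-layer electrochemistry, aperture clogging, and 1/f or burst noise.
Passing tests therefore demonstrate the pipeline's correctness under the
stated noise model, not robustness to every instrument pathology.

## Detection

A first-order Butterworth high-pass applied forward-backward (zero phase)
removes DC and drift; ΔZp and Δφp are then measured relative to the
filtered zero baseline. The default cutoff is 15 Hz: apex loss grows with
cutoff × pulse width (~1% at 15 Hz for 0.2 ms pulses) while drift leakage
falls as 1/cutoff² (~0.7% of the pulse height for a 500 Ω, 1 Hz drift), and
the feasible window for meeting both 2% contracts is roughly 9–29 Hz.

Peak finding runs on the filtered 45 kHz magnitude with the 110 Ω
threshold applied post-filter; candidates are strict local maxima, pruned
greedily by height so survivors are ≥ `min_separation` (default 3τ ≈ 34
samples) apart. The implementation (scipy `find_peaks`) is held equal to a
brute-force enumeration oracle in the tests. Apex timestamps directly
index all 12 channels (optionally a ±window extremum search, off by
default). Overlapping transits are counted as one record — a documented
limitation, not de-doubled.

## Gating, metric, dose-response

Gates: a record is *metallized* if ΔZp < 0 (strict) at any of the three
middle carriers; within that set, a 45→150 kHz decrease ≥ the drop
threshold (default ΔR(8.2 μm)/2 ≈ 169 Ω — an absolute scale tied to the
working bead, chosen because the published criterion is qualitative) marks
M_hi, the rest M_med; all other records are M_lo. The three labels
partition every record set.

Metric: features are ΔZp and Δφp at 11 MHz, z-scored with pooled
(both-class) training statistics that are reused unchanged on test trials
— required for transferring the model to clinical-style trials. The
discriminant is the two-class Fisher direction `w ∝ S_w⁻¹(μ_hi − μ_lo)`
(no priors, no shrinkage), unit-normalized, with the sign fixed so more
metallization scores higher; a singular scatter raises an error with a
regularization hint rather than silently regularizing. The decision
threshold is the midpoint of the projected class means; ties at the
threshold classify as negative (strict `>` for positive).

Dose-response: 4PL least squares (`scipy.optimize.least_squares`, TRF)
fit in linear concentration — the form `y = d + (a−d)/(1+(x/c)^b)` is
valid at x = 0 for b > 0, so blanks anchor the floor without a log-axis
offset. Initialization is data-driven (a = response at the lowest
concentration, d = at the highest, c = concentration nearest
mid-response, b = 1) with bounds b ∈ [10⁻³, 50], c > 0; the fit is
deterministic and degenerate inputs return a flagged non-converged fit.
The LOD is the closed-form inverse-4PL crossing of mean(blank) +
3·sd(blank), flagged "beyond tested range" when the cutoff exceeds the
fitted ceiling and 0 when it is below the fitted floor.

## Problem sizes

Default study conditions: 60 beads/trial, 1.5 s acquisitions (85,500
samples × 12 channels), 100-trial batches for detector completeness,
100 seed pairs for trial-ordering checks, 200 seeds for noisy 4PL
recovery and 100 for LOD recovery — sizes chosen so the full suite runs
on a laptop-class single core in well under half an hour.

## Known limitations

* Element values (`R_f`, `C_p`, `L_s`, shell parameters) are calibrated to
  qualitative spectral behaviour, not fitted to instrument data; absolute
  ΔZp magnitudes at the upper carriers are small differences of large
  numbers and should not be over-interpreted.
* Whether the shell branch sits across the whole bead element or only the
  displaced slab is one consistent reading of the circuit topology; the
  slab placement adopted here is what makes negative dips possible with
  `eta_slab < 1`.
* The LOD criterion (blank mean + 3 sd) is one standard choice; published
  bead-assay LODs computed with other rules are not directly comparable.
* The discriminant uses only the two 11 MHz features by default; extra
  features can be passed to `fit_lda` directly but are deliberately not
  part of the default surface.
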