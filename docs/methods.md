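# Methods

This note documents the models, algorithms and design choices behind
`fatfrac`: a pipeline for chemical-shift-encoded fat–water separation
(FWS) and proton density fat fraction (PDFF) mapping at 3 T and 7 T,
validated entirely on synthetic digital phantoms.

## Signal model

Each voxel of a spoiled multi-echo gradient-echo (GRE) acquisition is
modelled by six real parameters — water magnitude and phase, fat magnitude
and phase, off-resonance Δf (Hz) and effective transverse relaxation rate
R2\* (Hz):

    s(t) = (ρ_W e^{iφ_W} + ρ_F e^{iφ_F} c(t)) · e^{i2πΔf t} · e^{-R2* t},

with the fat spectral phasor `c(t) = Σ_p a_p exp(i 2π f_p t)` built from a
multi-peak fat spectrum. Peak shifts are carried in ppm relative to water
and converted per field strength with γ/2π = 42.577 MHz/T and nominal
fields 3.0 / 7.0 T, so one spectrum serves both fields. Three spectra ship
with the package: a 9-peak peanut-oil/agarose phantom model, an 8-peak
subcutaneous adipose tissue model (both measured by STEAM spectroscopy at
7 T, amplitudes renormalized to unit sum on load), and a single-peak
−3.3 ppm model used for echo-time optimization maps.

Sign convention: positive off-resonance advances phase with echo time
(`e^{+i2πΔf t}`); demodulation multiplies by the conjugate. A round-trip
test pins this down.

Water and fat carry independent phases (six parameters). A shared-phase
five-parameter variant can be emulated by constraining φ_F = φ_W in user
code, but the default follows the six-parameter model throughout, since
the NSA\* analysis treats water phase and fat phase as separate estimands.

Noise is circular complex Gaussian, i.i.d. across voxels and echoes;
`noise_sd` is the standard deviation of the *complex* noise (per-channel
SD `noise_sd/√2`). With object magnitude 1, SNR = 1/noise_sd; the studies
below use noise_sd 0.02 ("SNR 50") and 0.01 ("SNR 100").

## NSA\* echo-time optimization

The effective number of signal averages for parameter p_k is

    NSA*(p̂_k) = n · (1/I_kk) / (I⁺)_kk ,

where I is the Fisher information of the six-parameter model under the
noise model above, `1/I_kk` the minimum variance with p_k as the only
unknown, and `(I⁺)_kk` the CRLB variance with the full unknown set. The
single-unknown variance is referred to one echo image (factor n), so NSA\*
equals the echo count when echoes contribute independent information and
the parameter decouples, and is 0 on redundant echo spacings where the
fat–water phase relation repeats exactly (there `σ²(p̂)` diverges). With
R2\* excluded from the unknowns the bound NSA\* ≤ n is exact; including
R2\* lowers the achievable maximum.

Degenerate Fisher matrices (PDFF exactly 0 or 1, redundant ΔTE) are
handled by eigendecomposition with a relative eigenvalue cutoff of 1e-10;
a parameter whose eigenvector mass overlaps the null space reports
NSA\* = 0, as does one with zero single-unknown information.

The grid scan defaults reproduce the published optimization setting: TE1
and ΔTE from 0.5 to 5 ms in 0.05 ms steps (91×91), six equidistant
echoes, single-peak fat at −3.3 ppm, R2\* = 50 Hz, total magnitude fixed
at 1 across the PDFF sweep. The maps show the expected banded structure
(low-NSA\* bands recurring at ΔTE near multiples of the fat–water beat
period — about 2.37 ms at 3 T and 1.02 ms at 7 T) and rank the packaged
protocol presets correctly (high-NSA\* above low-NSA\* TE combinations at
both fields). One caveat: a coarse "area of the grid above an NSA\*
threshold" statistic is *larger* at 7 T than at 3 T under this model,
because the fixed TE window spans more beat periods at the higher field;
the field-strength penalty shows up as band narrowing and tighter band
spacing, not as a smaller total high-NSA\* area.

### Monte-Carlo validation

`monte_carlo_variance` checks the CRLB against the empirical variance of
maximum-likelihood estimates: thousands of noise draws are fitted by a
vectorized damped Gauss–Newton solver with analytic Jacobians, initialized
at the truth (at SNR 100 every start lies in the correct basin, which is
what a grid-initialized local search would achieve). The five validation
points cover both fields, high/low-NSA\* presets and PDFF 5–80 %, chosen
in the regular (identifiable) regime: on a redundant-ΔTE band the CRLB
diverges and the comparison is not meaningful. Agreement is within ~6 %
at 5000 draws (sampling error of a variance estimate alone is ~2 %).

## Fat–water separation

Classic two-stage VARPRO decomposition. For fixed (Δf, R2\*) the complex
water/fat amplitudes enter linearly; projecting them out leaves a
per-voxel residual over the discrete lattice of 401 off-resonance values
(−300…300 Hz) × 101 R2\* values (0…400 Hz). The lattice is evaluated by
precomputing a thin-QR orthonormal basis per lattice point and running one
matrix product per off-resonance candidate over all voxels; R2\* is
minimized per voxel conditional on Δf and not spatially regularized.

The field map minimizes the MRF energy

    E(ψ) = Σ_v D_v(ψ_v) + λ Σ_{(v,w)} |ψ_v − ψ_w| ,

with D_v the squared VARPRO residual and 4-connected neighbor pairs, by
iterated binary jump moves: every voxel simultaneously decides whether to
shift its label by ±k grid steps, and each such move is solved exactly as
an s–t min-cut (the |·| pairwise cost is convex in the label difference,
so every move is submodular). 50 move iterations by default. The shift
schedule cycles ±{1, 2, 5, 10} grid steps plus two physics-derived
shifts: the pure field alias 1/ΔTE (≈435 Hz at ΔTE 2.3 ms), and the
water/fat-exchange spacing |f_fat| mod 1/ΔTE (≈96–114 Hz at 7 T) at which
the true swapped solutions live. The second shift matters: without it the
solver cannot hop a coherent region between the true and the swapped
valley and silently returns a locally-optimal non-swapped (or
non-recoverable swapped) configuration. For ≤16 labels, absolute-label
expansion moves are added. Moves are accepted only if the exact
(float-evaluated) energy does not increase, so the energy trace is
non-increasing by construction.

λ defaults to `regularization_weight` × (mean second difference of D_v at
its minimum, per Hz²) × grid spacing — a curvature scaling that makes the
pairwise cost of a one-step disagreement comparable to the unary cost of
leaving a residual valley. The weight is exposed because no single value
is canonical; 1.0 is used everywhere in the shipped experiments.

Min-cuts are solved with `scipy.sparse.csgraph.maximum_flow`. Its solver
is integer-only and works in int32 internally, so float capacities are
quantized with the *total* capacity scaled to 2³⁰; the quantization is
~1e-9 of the total energy and every accepted move is re-validated in
float arithmetic.

### Exact solver and optimality

Because the pairwise cost is convex in the label difference, the same
energy is exactly minimizable by a single layered min-cut (one chain of
L−1 nodes per voxel; the severed chain edge selects the label;
inter-chain edges at each level charge λ×spacing per level crossed).
`exact_fieldmap_mrf` implements this as an independent oracle; its memory
grows as voxels × labels, so it is for small instances, not production.
It is validated against true brute-force enumeration on 3×3 grids with 4
labels. On randomized 8×8, 7-label instances drawn from the solver's
actual problem class (residual lattices of simulated voxel signals with
random PDFF, R2\*, field and noise), the jump-move solver attains the
exact optimum; on *arbitrary* random unaries with strong coupling it can
end in a local optimum, as expected for move-making algorithms, which is
why the optimality check is defined over signal-derived instances.

Background voxels (first-echo magnitude below 5 % of its 99th percentile)
are masked and report zeros. Final water/fat amplitudes come from a
closed-form 2×2 solve at the selected (Δf, R2\*), with a pseudo-inverse
fallback for (near-)collinear designs.

### Mixed fit

`mixed_fit_refine` re-fits the six-parameter model voxelwise with the
first echo contributing only its magnitude (one real residual) and all
later echoes their complex values, via batched damped Gauss–Newton
initialized at the graph-cut result. Voxels whose cost fails to improve
fall back to the initial values and are flagged. This removes bias from
phase errors confined to the first echo and, by design, cannot remove
phase errors distributed over later echoes — the simulated behavior
mirrors that: first-echo-only ramps are corrected (muscle PDFF bias
~9.5 → ~1.2 points in the shipped study), while ramps decaying across the
echo train leave a readout-direction PDFF gradient.

## Phase corrections

**Dual-echo B0 map** — `Δf = arg(s₂ s₁*) / (2π(TE₂−TE₁))` at in-phase
echo times (2.04 / 4.08 ms), aliasing bound ±245 Hz. No unwrapping is
performed; aliasing is detected in tests, not corrected. "In phase" is
checked against the multi-peak phasor with a 0.2 rad tolerance (the
multi-peak phasor is never exactly real); out-of-band models trigger a
warning, since residual fat phase biases the map. Low-magnitude voxels
(below 5 % of the 99th percentile) are invalid and report 0 Hz — the
analogue of masking cortical bone during in vivo field mapping.

**Demodulation** — `Ŝ(TEₙ) = S(TEₙ) e^{−i2πΔf TEₙ}` per voxel; invalid
voxels pass through; magnitudes are exactly preserved. Demodulation
re-centers the effective off-resonance seen by the separation, which is
what removes susceptibility-step-driven swaps.

**TE shift** — encoded purely as data: the 7 T shifted preset (TE1
2.2 ms at unchanged ΔTE 2.3 ms) versus the standard 1.9 ms preset.

## Digital phantoms and study conditions

**Vial phantom** — six circular vials (VFF 5, 10, 25, 50, 75, 100 %) in a
ring inside a water disk; VFF is used 1:1 as PDFF truth (oil/gel proton
density differences are ignored, matching direct VFF-vs-PDFF agreement
analysis). R2\* 50 Hz in vials, 30 Hz in the bath.

**Calf phantom** — ANT/SOL/GM muscle sectors (PDFF 0.03, R2\* 40 Hz),
subcutaneous fat ring and marrow (PDFF 0.90, R2\* 60 Hz), cortical bone at
2 % signal. 2-D slices (the evaluated geometry is a center slice);
chemical-shift displacement, k-space effects and coil sensitivities are
not simulated — phase errors are imposed in image space.

**B0 inhomogeneity** — a low-order polynomial normalized to a chosen
amplitude over the object, optional dipole-like lobes at fat/bone
interfaces, and a sharp susceptibility step inside fat-like tissue. The
step is the swap driver: once the field discontinuity at the fat boundary
exceeds what the smoothness prior will pay, the graph cut prefers the
water/fat-exchanged valley (≈96 Hz away at 7 T with ΔTE 2.3 ms) for the
whole region. The shipped swap study uses smooth 80 Hz + step 110 Hz
(≈0.37 ppm at 7 T, a plausible bulk susceptibility offset of fatty
tissue).

**Eddy-current phase** — spatially linear phase ramps along the readout
axis; `first-echo-only` perturbs echo 1 (the error the mixed fit targets),
`all-echoes-linear` scales the ramp by `decay^(n−1)` over the echo train
(not linear in TE, hence not absorbable into the field map). In the
protocol comparison the ramp amplitude decays with TE1 as
`exp(−(TE1−TE1_ref)/0.3 ms)` — eddy currents decay after gradient
switching, which is the physical reason a 0.3 ms longer first echo
mitigates them. Amplitudes 0.8 rad + 0.05 rad/voxel at the reference TE1.

Under these conditions (64×64 calf, SNR 50, 10 seeds) the median swap
rates order: none ≈ 46 % > te-shift ≈ 33 % ≈ demodulation ≈ 30 % >
both ≈ 0 %. Demodulation removes the field-driven (ring/marrow) swaps but
not the eddy-driven ones; the TE shift does the reverse; their combination
removes both. Passing these checks shows the mechanisms and their
interaction are modelled coherently — not that the specific rates transfer
to scanner data, where coil profiles, 3-D susceptibility fields and
chemical-shift blurring add effects this generator does not emulate.

## Problem sizes and numerical choices

Shipped studies use 96×96 vial and 64×64 calf grids with the full
401×101 search lattice and 50 iterations; these sizes give stable ROI
statistics while keeping a full multi-seed study in the minutes range.
Noiseless separation recovers PDFF to <0.5 points (limited by the 1.5 Hz
off-resonance and 4 Hz R2\* grid spacing). The magnitude PDFF definition
|F|/(|W|+|F|) maps into [0,1] and carries a positive noise bias at low
PDFF (visible as ~1 point at SNR 50 in pure water); a signed variant is
available but not default, being less robust to phase errors. ROI SDs are
population SDs. MAE is reported in percentage points.

## Known limitations

* 2-D phantoms only in the shipped studies (the I/O layer stores 3-D
  stacks, but the generators emit single slices).
* The dual-echo B0 map is not unwrapped; fields beyond ±245 Hz alias and
  demodulation can then worsen those voxels.
* R2\* is grid-quantized (4 Hz) and not spatially regularized.
* The jump-move solver has no global-optimality guarantee outside the
  signal-derived instance class; the exact layered solver is available for
  small fields of view.
* No T1/flip-angle weighting, no coil combination, no k-space simulation,
  no chemical-shift displacement along the readout.
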