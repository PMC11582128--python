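# fatfrac

Chemical-shift-encoded fat–water separation and proton density fat
fraction (PDFF) mapping for multi-echo gradient-echo MRI at 3 T and 7 T —
acquisition-parameter optimization, reconstruction and validation in one
package, runnable end-to-end on synthetic digital phantoms.

PDFF — the fraction of ¹H signal originating from fat,
`PDFF = |F| / (|W| + |F|)` — is the standard quantitative imaging marker
of fatty tissue replacement in muscle and liver. Measuring it at 7 T is
attractive (SNR) but hard: echo-time choices are constrained, field
inhomogeneities are larger, and eddy-current phase errors are stronger.
This package implements the full workflow a quantitative-MRI scientist
needs to design and debug such a protocol:

* **Echo-time optimization** via the Cramér–Rao lower bound. The
  effective number of signal averages of a parameter estimate,
  `NSA*(p̂_k) = n (1/I_kk) / (I⁺)_kk`, is scanned over (TE1, ΔTE) grids
  for the six-parameter voxel model
  `s(t) = (ρ_W e^{iφ_W} + ρ_F e^{iφ_F} c(t)) e^{i2πΔf t} e^{−R2* t}`
  with a multi-peak fat phasor `c(t)`. Protocol presets for
  low/high-NSA\* echo combinations at both fields are built in.
* **Fat–water separation** by VARPRO residuals over an off-resonance/R2\*
  lattice (401 values −300…300 Hz × 101 values 0…400 Hz) with graph-cut
  field-map regularization: iterated binary jump moves, each solved
  exactly by min-cut, 50 iterations — plus an exact layered-cut MRF
  solver usable as an oracle on small instances.
* **Phase-error mitigation**: dual-echo B0 mapping at in-phase echo
  times, complex-signal demodulation, TE-shifted protocols, and a mixed
  magnitude/complex per-voxel refinement that discards the first echo's
  phase.
* **Digital phantoms**: an oil/agarose vial phantom (VFF 5–100 %), a
  calf-like phantom with muscle ROIs, smooth-plus-local B0 fields with
  tissue-susceptibility steps, echo-dependent eddy-current phase ramps,
  and seeded complex Gaussian noise.
* **Quantification**: magnitude PDFF maps, ROI statistics, mean absolute
  error against known fat fractions, regression/rank agreement.

## Worked example

Vial-phantom accuracy under a high- versus low-NSA\* echo combination at
7 T (96×96 phantom, SNR 50):

```python
import numpy as np
import fatfrac as ff

phantom = ff.make_vial_phantom(grid_size=96)
model = ff.FatSpectrumModel.named("peanut_oil_phantom_9peak")
vials = [f"vial-{k}" for k in range(1, 7)]
vff = np.array([phantom.pdff_truth[phantom.mask(v)].mean() for v in vials])

for preset in ("7T-highNSA", "7T-lowNSA"):
    series = ff.simulate_acquisition(
        phantom, model, ff.protocol_preset(preset), noise_sd=0.02, seed=1
    )
    result = ff.separate(series, ff.FwsConfig(fat_model=model))
    stats = ff.roi_stats(result.pdff(), [ff.RoiSpec(v, phantom.mask(v)) for v in vials])
    measured = stats.set_index("name").loc[vials, "mean"].to_numpy()
    print(preset, "MAE = %.2f pts" % ff.mae(vff, measured),
          " per-vial PDFF:", np.round(measured, 3))
```

prints

```
7T-highNSA MAE = 0.22 pts  per-vial PDFF: [0.051 0.1   0.25  0.501 0.749 0.99 ]
7T-lowNSA MAE = 0.48 pts  per-vial PDFF: [0.052 0.1   0.249 0.501 0.75  0.975]
```

The high-NSA\* echo spacing (ΔTE 2.3 ms) recovers every vial within
~1 percentage point of its true fat fraction; the low-NSA\* spacing
(ΔTE 2.0 ms, close to two fat–water beat periods) doubles the MAE, with
the pure-oil vial worst — the noise-amplification effect the NSA\* maps
predict. The same machinery runs the swap-mitigation study (calf phantom
with a susceptibility step at the subcutaneous fat: median swap rates
order none > te-shift ≈ demodulation > both) and the mixed-fit study
(first-echo phase ramps corrected, all-echo ramps not).

A CLI mirrors the library:

```bash
fatfrac phantom make --kind vial --grid-size 96 --out ph
fatfrac sim run --phantom-stem ph --protocol 7T-highNSA --noise-sd 0.02 --seed 1 --out ser
fatfrac fws run --input ser --out maps
fatfrac nsa report --out nsa_maps
fatfrac experiment run --preset calf-swap-mitigation --out swapstudy
```

Echo series and maps are NIfTI (real/imaginary or magnitude/phase pairs
with JSON sidecars); tables are CSV; experiment configs are YAML with
named presets matching the published acquisition protocols.

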