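# ramanmix

Deconvolution of conformational exchange from Raman spectra.

Solution Raman spectra of flexible molecules such as ribonucleosides are not
the spectrum of any single structure: conformers interconvert on ps–ns
timescales, and the observed bands are population-weighted blends of the
spectra of the individual conformer regions. `ramanmix` implements the full
workflow for reading such a spectrum as a mixture of conformer populations:

* **Conformer classification** — glycosidic torsion χ (syn: −90° ≤ χ < 90°)
  and ribose pseudorotation phase P by the Altona construction (south:
  90° ≤ P < 270°), per-frame labelling of trajectories, populations, and
  exchange kinetics (transition rates in ns⁻¹, mean conformer lifetimes).
* **Spectrum synthesis from harmonic modes** — frequency scaling,
  activity→intensity conversion for a given laser wavelength and temperature
  (defaults 532 nm, 293 K), Lorentzian broadening (default 5 cm⁻¹ FWHM), and
  ensemble averaging.
* **Spectra from dynamics** — the Raman spectrum as the Fourier transform of
  the autocorrelation function of the molecular polarizability along a
  trajectory, with finite-field assembly of polarizabilities from dipole
  traces and Voronoi-cell integration of gridded (Gaussian CUBE) electron
  densities.
* **Experimental preprocessing** — water-background subtraction, asymmetric
  least squares baseline correction, windowing to 600–1600 cm⁻¹.
* **The mixture fit** — the core of the package, described next.

## The mixture model

Each conformer region *j* contributes a sub-spectrum, represented by a cubic
spline f^{fit,j} and evaluated on the experimental grid after a per-spectrum
frequency rescaling r_j and a global shift s:

    y_i^{conf,j}(r_j, s) = f^{fit,j}(r_j · x^{grid,i} + s)

The weights w, rescalings r and shift s minimize a penalized least-squares
loss

    L(w, r, s) = Σ_i { y_i^exp − Σ_j w_j y_i^{conf,j} }²
               + c_weight (Σ_j w_j − 1)²
               + c_rescaling Σ_j (|r_j − 1| − r_eq)²
               + L_shift(s)

with L_shift a step penalty of c_shift outside [s_min, s_max]. Defaults:
c_weight = 1.0×10⁸, c_rescaling = 1.0×10², c_shift = 5.0×10⁸, r_eq = 0.05,
s ∈ [0, 200] cm⁻¹. The weight penalty is tight relative to a data term of
order ~10², so fitted weights sum to 1 to high precision and can be read
directly as relative conformer populations. Minimization is BFGS (analytic
gradients) from 50 seeded random restarts, keeping the best result.

## Worked example

Fit a synthetic two-conformer observation (true populations 70/30, noise
σ = 0.01) with the default configuration:

```python
import numpy as np
from ramanmix import (GridSpec, MixtureFitConfig, SubSpectrumSet,
                      fit_mixture, populations_from_fit)
from ramanmix.synthetic_data import (SEPARATED_PRESET, SimConfig,
                                     gen_mixture_observation, gen_subspectrum)

grid = GridSpec(600.0, 1600.0, 0.5)
subs = [gen_subspectrum(SEPARATED_PRESET[i], SimConfig(seed=100 + i, grid_spec=grid),
                        label=label)
        for i, label in enumerate(["syn/south", "syn/north"])]
obs, truth = gen_mixture_observation(subs, w=[0.7, 0.3], r=[1.0, 1.0], s=0.0,
                                     sim=SimConfig(seed=19, noise_sigma=0.01,
                                                   grid_spec=grid))
result = fit_mixture(obs, SubSpectrumSet(tuple(subs)), MixtureFitConfig(seed=1))
pops = populations_from_fit(result)
print("fitted weights:", np.round(result.w, 4))
print("populations (%):", {k: round(v, 1) for k, v in pops.as_percent().items()})
print("loss terms:    ", {k: round(v, 4) for k, v in result.loss_components.items()})
```

Output:

```
fitted weights: [0.7008 0.2992]
populations (%): {'syn/south': 70.1, 'syn/north': 29.9}
loss terms:     {'data': 0.1907, 'weight': 0.0, 'scaling': 0.4919, 'shift': 0.0}
```

The fitted weights recover the generating populations to a few parts per
thousand; the data term is consistent with the injected noise
(≈ N_grid·σ² = 0.2), and the weight penalty is numerically zero because the
weights sum to 1.

The same operations are exposed on the command line (`ramanmix broaden`,
`conformers`, `aimd`, `ff-alpha`, `fit`, `combine`, `preprocess`,
`simulate`); run `ramanmix --help`.

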