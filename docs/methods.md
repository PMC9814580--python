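# Methods

This note records the models implemented in `ramanmix`, the defaults chosen
where the design was genuinely open, and what the synthetic test conditions
do and do not establish about real data.

## Conformer space and classification

A ribonucleoside's conformational space is reduced to two coordinates: the
glycosidic torsion χ (O4′-C1′-N9-C4 for purines, O4′-C1′-N1-C2 for
pyrimidines) and the ribose pseudorotation phase P. P and the pucker
amplitude τ_m are obtained from the five endocyclic torsions ν₀…ν₄ by
inverting the generating relation ν_j = τ_m·cos(P + 144°·(j−2)), with
ν₂ = C1′-C2′-C3′-C4′ as the reference torsion so that P ≈ 18° corresponds to
c3′-endo (north) and P ≈ 162° to c2′-endo (south). The implementation uses
the atan2 quadrant-safe form and recovers τ_m as the hypotenuse of
(ν₂, [(ν₄+ν₁)−(ν₃+ν₀)]/[2(sin36°+sin72°)]), which is exact for all P
including cos P = 0; the forward/inverse pair round-trips to < 1e-9 degrees.

Classification is total and deterministic with half-open boundaries:
syn iff χ ∈ [−90°, 90°) after wrapping to (−180°, 180°], south iff
P ∈ [90°, 270°). The conventional prose definitions use open intervals and
leave the boundary unassigned; a measure-zero tie-break cannot affect
populations but a fixed rule is required for reproducible labelling.

Dihedral angles follow the IUPAC sign convention (positive = clockwise
rotation of the far bond viewed along the central bond), validated against
MDAnalysis `calc_dihedrals` on random geometries.

Exchange rates are counting estimates: k[a→b] = (number of a→b label
changes)/(total time in a), and mean lifetimes are mean contiguous dwells.
Label series are used raw by default. An optional hysteresis buffer
(suggested 10°) re-classifies the stored χ/P series with a widened boundary
in favour of the current state before counting, suppressing recrossing
inflation; it is off by default because raw counting is the plainer
definition, and rate comparisons with debounced analyses will differ
accordingly.

## Spectrum synthesis from harmonic modes

Harmonic frequencies are multiplied by a user-supplied scaling factor
(method/basis-dependent; no default other than 1 is imposed). Raman
activities S_i (Å⁴·amu⁻¹) are converted to intensities with the standard
differential-cross-section form

    I_i ∝ (ν̃₀ − ν̃_i)⁴ · S_i / { ν̃_i · [1 − exp(−c₂ ν̃_i / T)] }

where ν̃₀ = 10⁷/λ(nm) and c₂ = hc/k_B (CODATA, via scipy.constants). The
global prefactor is irrelevant because all spectra are max-normalized before
comparison. Defaults: λ = 532 nm, T = 293 K.

Lines are broadened with area-normalized Lorentzians,
I_i·(Γ/2π)/[(ν̃−ν̃_i)² + (Γ/2)²], Γ = 5 cm⁻¹ FWHM by default (intrinsic
lifetime width). For a uniform Γ, area- and height-scaling differ only by a
constant that normalization removes. The default synthesis grid is
600–1600 cm⁻¹ at 0.5 cm⁻¹, matching the experimental analysis window; the
grid step must satisfy step ≤ Γ/2 so lines are resolved.

Resampling between grids uses cubic splines with out-of-domain values set to
0 rather than extrapolated: the mixture fit shifts and rescales sub-spectra,
probing beyond their measured range, and extrapolated cubics diverge.

## Spectra from polarizability dynamics

The Raman spectrum of a trajectory is estimated as the Fourier transform of
the polarizability autocorrelation function. The tensor series is split into
the isotropic mean ᾱ(t) = tr α/3 and the traceless anisotropic part β(t);
the spectrum is a_iso·F[C_iso] + a_aniso·(3/2)Σ_ij F[C_{β_ij}] with the
standard unpolarized invariant weights (45, 7) by default. The ACF is
mean-removed and overlap-count normalized (unbiased at each lag, so
C(0) equals the series variance exactly — this is what makes the closed-form
and Parseval tests sharp; the biased FFT normalization would shift only
amplitudes, not peak positions). The truncated ACF (default max lag = half
the series) is tapered with the positive-lag half of a Hann window (leakage
suppression; 'none' is available and used for the Parseval identity),
reflected to even symmetry, zero-padded ×4 and transformed; the frequency
axis is ν̃_k = k/(M·dt·c). Output is restricted to 0–4000 cm⁻¹ and
max-normalized. A harmonic quantum-correction prefactor
βhcν̃/(1−e^{−βhcν̃}) is available but off by default, since max-normalized
fingerprint-region comparisons are insensitive to it.

Polarizabilities are assembled from finite-field dipole responses,
α_ij(t) = [μ_i^{E_j}(t) − μ_i^0(t)]/E, forward difference with an explicit
zero-field reference (field 5×10⁻⁴ a.u. by default, well inside the linear
regime); central differences are used when ± traces are supplied. The raw
tensor is symmetrized as (α+αᵀ)/2 and the maximum asymmetry reported, as a
linearity diagnostic.

Molecular dipoles can be integrated from gridded electron densities
(Gaussian CUBE): each voxel is assigned to its nearest atom by plain
Euclidean distance (non-periodic box; ties to the lowest atom index), and
the electronic moment −Σρ(r−r_ref)ΔV over the subset's cells is combined
with the nuclear point charges. Radical/weighted Voronoi refinements are out
of scope.

## The mixture fit

Sub-spectra enter as cubic splines f^{fit,j}; the model intensity at grid
point i is Σ_j w_j f^{fit,j}(r_j x_i + s). The loss is the plain sum of
squared residuals over the experimental grid restricted to the analysis
window, plus three penalties:

* **Weights**: c_weight(Σw_j − 1)², c_weight = 1×10⁸. An alternative literal
  form c_weight(Σw_j² − 1)² is selectable; the sum form is the default
  because only it makes the weights interpretable as relative populations
  summing to 100%, which is how fitted population tables are reported.
* **Rescalings**: c_rescaling Σ(|r_j − 1| − r_eq)², c_rescaling = 1×10²,
  r_eq = 0.05. This is implemented literally: it attracts |r_j − 1| toward
  the equilibrium value 0.05 rather than toward 0. A consequence worth
  knowing: even for a self-fit the optimum trades a small data misfit
  (~10⁻³) against this penalty, so the data term at the optimum is not
  exactly zero. Setting r_eq = 0 recovers a conventional ridge on r.
* **Shift**: a step penalty of c_shift = 5×10⁸ outside s ∈ [0, 200] cm⁻¹.
  Restart initialization keeps s inside the box, so quasi-Newton iterates
  rarely probe the discontinuity; a logistic-smoothed variant (width
  1 cm⁻¹) is available for robustness.

Weights are unconstrained by default; negative recovered weights are
reported and flagged, and a squared-parametrization non-negative mode
exists. Optimization is BFGS from 50 restarts drawn from a seeded generator
(w uniform on the simplex, r uniform in [1−2r_eq, 1+2r_eq], s uniform in
[s_min, s_max]); the best restart is kept and all restart losses returned.
Analytic gradients are supplied (subgradient at the |r−1| kink, zero
gradient through the step penalty): the penalty scales span ~8 orders of
magnitude and finite-difference gradients stall far from the optimum.
Deterministic given (seed, config, inputs).

Residuals are computed on the unrenormalized weighted combination; the
weight penalty, not renormalization, keeps the prediction on the
experimental intensity scale.

Fixed-weight combination (e.g. weights taken from simulated conformer
populations) renormalizes the supplied weights over the supplied sub-spectra
— simulated region weights need not sum to 1 when only the dominant regions
were simulated — and max-normalizes the result.

## Experimental preprocessing

Water background is subtracted at scale 1 (identically acquired solvent
spectrum); a least-squares-optimal scale is available for synthetic work.
Baselines use asymmetric least squares: a Whittaker smoother with
second-difference penalty λ and asymmetric weights (p above the baseline,
1−p below), iterated 10 times. Defaults λ = 1×10⁵, p = 0.01 follow common
AsLS practice; for spectra with a known-smooth background and heavy-tailed
(Lorentzian) peaks, a stiffer λ (~10⁶) and stronger asymmetry (p ~ 10⁻³)
reduce tail clipping of peak heights to ≲1.5%. A polynomial-basis variant
(default degree 3) under the same reweighting is selectable, since
"asymmetric least squares with a low-order polynomial" is a common
description of either procedure. Spectra are windowed to 600–1600 cm⁻¹.

## Synthetic study conditions

The generators define the conditions under which the pipeline is validated:

* Sub-spectra: three Lorentzian peaks each on 600–1600 cm⁻¹ at 0.5 cm⁻¹,
  well separated across conformers by default so that recovery tolerances
  measure the optimizer, not identifiability; an overlapping-peak preset
  probes the hard regime. Mixture observations add Gaussian noise σ = 0.01
  (≈1% of the normalized maximum, a realistic noise floor for accumulated
  solution spectra).
* Exchange: discrete-time Markov chains with per-frame transition
  probability 1−exp(−kΔt), k in the 0.1–3 ns⁻¹ regime of nucleoside
  exchange, observed every 10 ps; rate recovery is tested at 5×10⁵ frames
  (5 μs equivalent). Continuous torsion series use wrapped Gaussian noise
  (default sd 8°) around label-dependent means (χ: 0°/180°; P: 162°/18°).
* Polarizability traces: damped cosines at fingerprint frequencies,
  0.5 fs timestep, 17.5 ps length (3.5×10⁴ frames).
* Densities: normalized Gaussian blobs with analytic charge and first
  moment.

These conditions establish correctness of the estimators and the optimizer
under known truth. They do not establish that real conformer sub-spectra
are identifiable (real sub-spectra overlap strongly and share band
positions), that exchange is Markovian two-state, or that experimental noise
is white — conclusions on real data inherit those caveats.

## Numerical choices and limitations

* Spectrum I/O is two-column text with 6 significant digits; mode tables and
  tensor/dipole traces are CSV; trajectories are multi-frame XYZ read via
  MDAnalysis with a JSON torsion-atom specification (no topology
  perception).
* Problem sizes in the test suite and acceptance script (2001-point grids,
  5×10⁵-frame chains, 3.5×10⁴-frame traces) were chosen as the smallest
  sizes at which the statistical tolerances are comfortably attributable to
  the estimators rather than sampling noise.
* The frequency scaling factors for harmonic spectra are user inputs; no
  optimized values are shipped.
* No uncertainty quantification of fitted weights is provided (no bootstrap
  is implemented), and model selection over which conformer regions to
  include is out of scope.
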