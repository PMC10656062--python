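# Methods

This note records the models, conventions, parameter choices and known
limitations of `nmremu`. Everything quantitative stated here is computed by
the test suite or the acceptance script; nothing is quoted from elsewhere.

## Spin systems and operators

Sites are spin-1/2 nuclei with gyromagnetic ratios stored as dimensionless
ratios to ¹H (¹H = 1, ¹³C = 0.2514502, ¹⁹F = 0.9409401, ³¹P = 0.4048074 —
the standard NMR frequency ratios; only positive-γ nuclei are tabulated).
Magnetization observables are therefore in "γ-reference" units; absolute
units are irrelevant because every FID is normalized to FID(0) = 1.

The scalar-coupling Hamiltonian is `Σ_{i<j} 2π J_ij S_i·S_j + Σ_i 2π s_i
S_i^x` in rad/s, with J and the shifts `s_i` supplied in Hz. Two
conventions are worth flagging:

* the pair sum runs over `i < j`, counting each physical coupling once —
  this is what produces the J and 2J lines of the methyl fixture;
* the chemical-shift term is kept on the **x** axis. The conventional
  high-field form uses z; the x form is retained deliberately and
  zero-field mode ignores shifts entirely, so nothing in the package's
  default workflows depends on this choice.

Site `i` maps to qubit `i` with site 0 as the most significant bit of the
computational index, and bit value 0 meaning spin up (so amplitude damping,
which decays qubits to |0⟩, pumps toward maximum positive magnetization —
matching hardware reset conventions).

Dipolar couplings use the full, untruncated form `b_ij [S_i·S_j −
3(S_i·ê_ij)(S_j·ê_ij)]` with `b_ij = μ₀ γ_i γ_j ħ / (4π r_ij³)` from
absolute γ values and coordinates in Å. No secular truncation flag exists:
the package's solid-state mode targets zero field, where the full form is
the correct one. Orientations are unit quaternions; powder averaging draws
them Haar-uniformly over the whole rotation group (an axially symmetric
system merely wastes one Euler angle).

Dense matrices cap the system at 12 sites (4096-dimensional). This is a
desk-scale guard, not an algorithmic limit.

## Exact dynamics

One eigendecomposition of H yields both the FID (a sum of cosines at level
differences, manifestly real) and the transition table: lines at
`(E_a − E_b)/2π > 0` with amplitudes `|⟨a|M|b⟩|²`, degenerate frequencies
merged within 10⁻⁹ Hz (the methyl group's permutation symmetry produces
exact degeneracies) and amplitudes below 10⁻⁹ dropped.

The basis-state form evolves only the states with strictly positive
magnetization weight (8 of 16 for the methyl fixture). Its raw value is
exactly half the raw trace — the magnetization spectrum is odd under the
global spin flip, which is a symmetry of H — so the two agree exactly after
normalization; the suite checks this to 10⁻¹⁰ on random heteronuclear
systems.

Spectra are the real part of the FFT of the (by default DC-removed) FID on
a uniform grid of `n` points over `[0, t_max)`; frequency spacing is
`1/t_max`. The default acquisition grid is 4096 points over 6 s (spacing
1/6 Hz ≈ 0.167 Hz, Fourier floor ≈ 0.083 Hz). Dephasing is available as a
phenomenological `exp(−t/T2)` envelope whose spectral signature (Lorentzian
of HWHM `1/(2πT2)`) is verified in closed form.

## Circuit emulation

Time evolution is compiled by a clustered first-order product formula: per
step, each cluster's internal Hamiltonian is exponentiated exactly into a
block gate, followed by one pair-exponential `exp(−i 2π J τ S_i·S_j)` per
nonzero inter-cluster coupling. Singleton clusters give plain first-order
Trotter; the suite verifies the O(1/n_steps) operator-norm error (log-log
slope −1 ± 0.15).

Depth is counted in arbitrarily connected two-qubit gates. A pair
exponential costs 1. A k-qubit block is charged by a configurable cost
model: the default "generic" model uses the parameter-counting bound
⌈(4^k − 3k − 1)/4⌉ (61 for k = 4), appropriate for resource accounting of
arbitrary unitaries; the "couplings" model charges one gate per
intra-cluster coupling (3 for the methyl fixture), appropriate for shallow
compiled circuits.

Noise is amplitude damping (Kraus `{[[1,0],[0,√(1−p)]], [[0,√p],[0,0]]}`)
and phase damping (`{√(1−q) I, √q Z}`) applied to every qubit a gate
touches, after the gate, once per two-qubit-gate equivalent. Both channels
are diagonal, so their n-fold composition has the closed form
`p → 1−(1−p)ⁿ`, `(1−2q) → (1−2q)ⁿ`, which the emulator uses (and tests
against literal repetition). The defaults p = 0.005, q = 0.035 are the
per-gate damping parameters of the emulated hardware; noise placement
(both qubits, after the gate) is isolated behind `NoiseModel` so it can be
changed in one place.

The shot-sampled FID estimator runs each positive-magnetization initial
state through the circuit (density matrix, 2^N ≤ 4096), samples the
outcome distribution (1000 shots by default), combines the empirical
magnetization means with the basis-state weights, and normalizes by the
exact t = 0 value. One root seed deterministically derives one substream
per (time point, state); identical configurations reproduce bit-identical
results.

### The pipeline's depth profile

The hardware experiment compiled each evolution time into a numerically
synthesized circuit whose two-qubit depth grows with the entanglement
generated and then saturates. Plain Trotterization cannot stand in for this
at full accuracy: reaching sub-0.1 Hz frequency accuracy over a 6 s window
with singleton clusters would need ~10⁶ steps per point (the measured
Trotter coefficient of the fixture is a ≈ 1.7×10⁵ Hz·gates). The emulated
pipeline therefore treats the whole (≤ 7-spin) molecule as one cluster —
each step block is an exact propagator, playing the role of the synthesized
circuit — and models the depth profile as `n_steps(t) = min(⌈t/0.25 s⌉, 3)`
blocks charged under the "couplings" cost (3 gate-equivalents per block, so
depth ramps to a saturated 9 gate-equivalents). The ramp reproduces the
early-time decoherence envelope of the hardware FID; the saturation
reproduces the entanglement-limited depth of compiled 4-qubit circuits and
keeps late-time signal above the 1000-shot noise floor. Both knobs
(`step_s`, `step_cap`) are configuration, not physics.

## Compressed sensing

Schedules: gaps between kept indices are Poisson with mean `λ sin(θ)`, θ
ramping 0 → π/2 over the gap ordinal, so sampling is dense at short times
(where the decaying signal lives) and sparse late. λ is bisected — with the
same seed, so the draw is reproducible — until exactly `n_keep` indices
span the grid; index 0 is always kept. The exact historical
parameterization of sine-weighted Poisson-gap sampling differs in detail;
this sampler is a documented, seeded stand-in with the same qualitative
density profile, and the suite checks the mean gap (≈ n_grid/n_keep within
10%) and the early/late density contrast.

IST-S: starting from the zero-filled FID, each iteration FFTs, soft-
thresholds at `τ_k = 0.99 · 0.99^k · max|S|`, inverse-FFTs and restores the
measured points, for 800 iterations. These defaults were calibrated for
convergence on the noiseless two-line fixture signal (the residual artifact
floor drops ~40× relative to a faster threshold decay at the same final
threshold); they are exposed as configuration. The returned spectrum is
measurement-consistent by construction (final replacement precedes the
output transform), and the final transform may be zero-padded (the
pipeline uses 4×) to interpolate between grid frequencies — interpolation
only, so uncertainty floors stay tied to the acquisition window.

Peak fitting: a sum of Lorentzians `A w²/((f−c)² + w²)` **plus a constant
baseline** is fitted under an ℓ₁ (IRLS with ε-smoothing, ε = 10⁻⁶·max
intensity) or ℓ₂ norm. The baseline term matters: without it, one component
of a multi-peak fit on artifact-ridden zero-filled spectra reliably
degenerates into a broad artifact absorber. Initialization takes the
largest local maxima (grid-scan fallback); each center is constrained to
±3 Hz of its starting maximum and the half width is capped (5 Hz in the
pipeline) so components cannot wander across the spectrum. The search
excludes f < 2 grid spacings; the pipeline's default window starts at 5 Hz
to exclude the slow relaxation-baseline residue.

The reported center uncertainty is `max(fit standard error, fitted HWHM,
half the acquisition grid spacing)`. The width term is deliberate: the
center of an artifact-distorted line is not meaningful below its own half
width, and formal covariance errors understate it badly when the "noise" is
correlated sampling artifacts rather than independent noise. Clean narrow
lines fall through to the Fourier floor (0.083 Hz on the 6 s grid).

Before spectral analysis the pipeline removes a quadratic-in-time trend
fitted to the measured points: it absorbs the conserved-magnetization DC
component and the slow amplitude-damping baseline while the >100 Hz
oscillations of interest average out of it.

## Estimator statistics and powder averages

Term sampling over the weighted basis-state sum supports uniform and
importance (∝ |weight|) designs, both unbiased, with closed-form
single-draw variances used to verify that importance sampling never does
worse on the fixture's weight list. The N² variance bound applies to the
estimator of the **normalized** FID (raw traces grow as 2^N); the suite
checks both the closed-form worst case and empirical shot noise against it.

`powder_fid` draws a Haar orientation per group, builds J + dipolar H, and
estimates the FID value either exactly or by importance-sampled shots
(initial state ∝ weight, then one projective outcome). Group variances use
the unbiased (n−1) convention; the between-orientation component is
bias-corrected by subtracting `var_shot/shots`. The law-of-total-variance
identity `var_total ≈ var_shot + var_orient` is verified within 5% at 200
orientations × 100 shots on a 3-proton dipolar toy (a 0.4 s computation),
and the powder mean is checked invariant under a global rotation of the
molecule.

## Resource model

Linewidth versus depth is modeled additively, `Δf(D) = a/D + D ln(1/F) /
(2πT)`: the first term is the first-order-Trotter resolution limit, the
second the depolarizing-decoherence broadening accumulated over D gates in
a simulated window T. The closed-form optimum `D* = √(2πTa/ln(1/F))`,
`Δf* = 2√(a ln(1/F)/(2πT))` is cross-checked against numerical
minimization to 0.1%.

The Trotter coefficient `a` is calibrated empirically: the effective
Hamiltonian of one product-formula step, `H_eff = i log(U_step)/τ`, gives
the exact line positions of the Trotterized evolution; exact eigenstates
are tracked to effective ones by eigenvector overlap and the
amplitude-weighted line shift is fitted against depth. On the methyl
fixture the shift scales as 1/D (slope −1.00). A genuinely informative
subtlety: for molecules with **non-degenerate** spectra the first-order
shift of every level vanishes identically (the Trotter correction `iΣ[H_j,
H_k]` is imaginary Hermitian, so its diagonal in real eigenvectors is
zero), and line shifts fall as 1/D². Symmetric molecules — the methyl
group, and the clustered symmetric groups of the larger compounds the model
targets — have degenerate multiplets, where the same correction splits
levels at first order, giving the 1/D law. Calibrations that deviate from
1/D are flagged on the emitted curve, not silently corrected, and the
curve ordering (larger clustered molecules are harder at equal F; better
gates give finer resolution) holds either way.

## What the synthetic data does and does not emulate

The generator of clustered random molecules reproduces the interaction
*topology* that makes real midsize molecules classically hard — dense
strong clusters of 4–7 spins, weak single bridges — with round-robin
heteronuclear isotopes, intra-cluster couplings ~100 Hz and bridges ~5 Hz.
It does not reproduce real bond geometries, coupling-constant correlations,
or the symmetry-induced degeneracies of real functional groups (its random
couplings give non-degenerate spectra; see the resource-model subtlety
above). Passing tests therefore demonstrate the estimator, reconstruction
and scaling *machinery* on structurally realistic inputs, not agreement
with any particular molecule's spectrum beyond the acetonitrile fixture.

## Problem sizes

The default study conditions are themselves desk-scale (a 16-dimensional
Hilbert space; 102 circuits × 8 states × ≤3 density-matrix steps), so the
test suite runs them unreduced: ten full pipeline seeds take ~25 s, the
powder decomposition 200 × 100 draws, calibrations use 256-dimensional
step unitaries at most.

## Known limitations

* Spins > 1/2, relaxation superoperators, chemical exchange,
  magic-angle-spinning time dependence, and hardware-native gate sets are
  out of scope.
* The depth profile of the emulated pipeline is a two-parameter model of
  compiled-circuit depth, not a compiler.
* The ℓ₁ fit's uncertainty is a robust heuristic (MAD-scaled covariance
  plus the width term), not a calibrated confidence interval.
* Intensity ratios of emulated spectra are validated only as orderings;
  absolute intensities depend on the noise model's baseline handling.
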