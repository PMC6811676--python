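# Methods

## Exchange models

All magnetization models are linear rate equations dM/dt = K·M over a
small set of longitudinal pools. The generator K carries first-order
exchange rates on its off-diagonals, and each diagonal element is minus
the pool's total outflow minus the shared auto-relaxation rate R1
(seconds and s^-1 throughout; volumes are arbitrary units with V0 = 1 by
default). Propagation uses one eigendecomposition of K vectorized over
all mixing times, falling back to scipy's scaling-and-squaring matrix
exponential if the eigenvector matrix is ill-conditioned (condition
number above 1e8, i.e. a defective or nearly defective K). Closed forms,
the eigen propagator and adaptive ODE integration agree to better than
1e-8 relative in the test suite.

Peak labels are two characters, "detected pool" + "origin pool", so aA
is magnetization that started on the major-conformer proton A and is
detected at the minor-conformer frequency a. This matches the ratios
the fits consume: aA/(AA + aA) shares the origin A, and Ab/(AB + Ab)
shares the detected pool A.

**Two-site z-z exchange.** Pools (major, minor) with forward rate k1 and
reverse rate k_rev; k_ex = k1 + k_rev, populations p_major = k_rev/k_ex,
p_minor = k1/k_ex. The closed-form auto and cross curves factor into a
pure-exchange part times e^{-R1 t} because R1 is shared — which is also
why R1 cancels exactly in diagonal-normalized ratios.

**NH2/NH scheme.** The amine (NH2, major) and imine (NH, minor) pools of
the metal-binding cytosine interconvert, but conversion of the amine
carries only a fraction of its magnetization forward: one of the two
amine protons is displaced by the metal. This fraction is the
`retention_factor`, default 1/2 (the observable NH inherits the
magnetization of one of two equivalent amine protons); the reverse flux
deposits the NH magnetization into the combined NH2 pool. The constraint
that the imine proton feeds both amine protons equally fixes the reverse
branch; the forward branch is a modelling choice and is exposed as a
parameter. `retention_factor = 1` reduces the scheme exactly to the
symmetric two-site model, which is how it is validated.

**Four-pool NOE network.** One observed proton (A/a) and one
cross-relaxation partner (B/b) per conformer. Exchange couples A↔a and
B↔b at (k1, k_rev); cross-relaxation couples A↔B and a↔b at |σ|.
σ is stored with its relaxation-matrix sign (negative for slow tumbling);
only its magnitude enters the transfer rates, and the sign convention is
documented rather than enforced. Exchange-mediated peaks (Ab, aB) vanish
when σ = 0 and when k_ex = 0, which the tests assert.

## Fitting

All estimators are trust-region least squares
(`scipy.optimize.least_squares`, rates bounded at zero) with a
deterministic three-point multistart at k_ex ∈ {1, 10, 50} s^-1; the
lowest-SSR solution wins. Standard errors come from the Gauss–Newton
approximation s²(JᵀJ)^-1 at the optimum. Inverse-variance weights are
applied when the input TSV carries a sigma_volume column; otherwise fits
are unweighted (the source experiments report no per-point errors).
Intensity normalization conventions (e.g. scaling to the 200-ms point)
do not affect the estimators: every fit carries free per-curve or
per-origin amplitudes, and the two ratio fits are scale-free by
construction.

The global z-z fit shares (k1, k_rev, R1) across all four NH2/NH curves
with one amplitude per origin — five parameters against 64 points on the
default grid. The mediated-NOE ratio is fitted against the exact
four-pool prediction with free (k1, k_rev, |σ|) and R1 fixed at zero,
since the shared R1 divides out of the ratio; |σ| is weakly identified
there (the ratio is nearly σ-independent at small σ), which is harmless
because only the rates are reported. Degenerate inputs are flagged, not
silently fitted: all-zero build-up curves, monotone-only data (R1
unconstrained), and σ = 0 mediated input (no NOE path) each set a named
flag on the result, and `aggregate_sites` excludes non-converged entries
and reports the exclusion count. Site aggregation is an unweighted mean
± sample standard deviation; fitted minor populations are reported as
they come and are never forced to match a nominal 3:1 species ratio.

A numerical caveat found while testing: the mediated ratio
Ab/(AB + Ab) is monotone non-decreasing in mixing time only when the two
conformers share one σ. With distinct σ_major ≠ σ_minor the ratio can
overshoot and relax back by a few 1e-3. The shared-σ form is what the
ratio fit assumes and what the property test asserts.

## Karplus analysis

The coupling model is the generalized three-bond relation

    J(φ) = A cos²φ + B cosφ + C + Σ_i Δχ_i (D + E cos²(ξ_i φ + F|Δχ_i|))

with the Haasnoot–de Leeuw–Altona coefficients A = 13.70, B = -0.73,
C = 0, D = 0.56, E = -2.47, F = 16.9°. The shipped default substituent
set describes the H1′-C1′-C2′-H2′ fragment of a 2′-deoxyribonucleotide:
O4′ (Δχ = 1.207, ξ = +1), the glycosidic nitrogen (Δχ = 0.724, ξ = -1)
and C3′ (Δχ = 0.209, ξ = +1), where each Δχ is a Huggins group
electronegativity attenuated by 0.14 per β substituent. With these
defaults J = 6.5 Hz inverts to 142.1° on the 90–180° branch. All
coefficients are overridable through `KarplusParams`, and a plain
three-term parameterization is available via `KarplusParams.plain`.

Inversion brackets sign changes of J(φ) - J* on a 0.25° grid and refines
each root with Brent's method to 1e-6°; couplings outside the attainable
range raise with the min/max J reported, and an exact-extremum coupling
resolves to its tangent point. The forward/inverse round trip is exact
to 1e-6 Hz over the attainable range.

## Pseudorotation and ensemble geometry

Phase and amplitude follow the Altona–Sundaralingam convention:
ν_j = ν_max cos(P + 144°(j-2)), recovered from measured torsions via
x = ν2, y = ((ν4+ν1) - (ν3+ν0)) / (2(sin36° + sin72°)),
P = atan2(y, x), ν_max = hypot(x, y) — the hypot form keeps ν2 ≈ 0
(P near ±90°) well-behaved, and a near-planar ring (amplitude < 1e-9°)
classifies as "planar/undefined" instead of dividing by zero. The pucker
wheel has twenty half-open 18° sectors, envelopes centred at
18° + 36°k (C3′-endo at 18°, O4′-endo at 90°, C2′-endo at 162°) and
twists between them; the class depends on P only, so it is invariant
under amplitude scaling.

Torsions use the standard IUPAC sign convention
φ = atan2(|b2| b1·(b2×b3), (b1×b2)·(b2×b3)), cross-checked atom-by-atom
against Bio.PDB's `calc_dihedral` on random geometries. Ensemble
dihedrals are summarized with circular mean and circular standard
deviation (scipy), so values straddling ±180° do not average towards
zero. Ensemble r.m.s.d. superposes each model onto a reference model
(Kabsch/SVD with determinant correction) over the heavy atoms common to
all models and reports per-model values plus mean ± sd over the
non-reference models; the rotation is cross-checked against scipy's
`Rotation.align_vectors`.

PDB input goes through gemmi (gzip-transparent); atom names are
normalized (typographic primes and `*` to `'`, leading-digit proton
dialects rotated, `H2'2` → `H2''`), altlocs resolve to highest occupancy
with ties broken by label order, and models that disagree on their
residue sets reduce to the intersection with a warning.

## NOE restraints

Isolated spin-pair calibration r_i = r_ref (V_ref/V_i)^{1/6} against a
reference pair, default pyrimidine H5–H6 at 2.45 Å (covalently fixed,
overridable). Distances are binned by thresholds that coincide with the
printed upper bounds of the strong/medium/weak categories — r < 3.0 Å
strong, 3.0–4.5 medium, 4.5–6.0 weak, ≥ 6.0 very weak, half-open on the
right — because the volume→category rule of the original calibration
software is not published; binning on the calibrated distance is the
reproducible choice. Category bounds are fixed at strong (1.8, 3.0),
medium (1.8, 4.5), weak (3.0, 6.0), very weak (4.0, 7.0) Å. Pseudo-atom
bound corrections are off by default. Range classes follow |i-j|:
0 intra, 1 sequential, ≥2 long-range; per-residue density divides the
total by the duplex residue count (28 for the 14-mer duplex, both
strands). The XPLOR writer emits
`assign (resid i and name A) (resid j and name B) d dminus dplus` with d
the bound midpoint; numbers are formatted at one decimal with standard
float rounding.

## Synthetic data

Generators emit exactly the TSV dialects the analysis stages read, plus
a ground-truth sidecar, and are deterministic under their mandatory
seed. Default conditions are the study conditions: z-z scheme k1 = 3.5,
k_rev = 7.7 s^-1; NOESY scheme k1 = 4.3, k_rev = 8.8 s^-1, σ = -1 s^-1;
R1 = 2 s^-1; 16 mixing times log-spaced on 0.01–0.5 s (the build-up
maximum near 0.17 s sits inside the grid); multiplicative Gaussian
volume noise with sd fraction 0.05, the factor clipped at 1e-6 so
volumes never change sign. Multiplicative noise was chosen over additive
because integrated peak-volume errors scale with intensity in practice.

The structure generator builds idealized furanose rings by least-squares
refinement of a puckered pentagon against the ideal torsion pattern
(equal 1.53 Å bonds, weak 103° angle prior to fix the gauge) and places
H1′/H2′ tetrahedrally on opposite ring faces; the resulting
Φ1′2′-vs-phase relation lands within ~1° of the empirical
121.4° + 1.03 ν1 rule for deoxyribose, without being fitted to it.
Multi-model "ensembles" jitter the pucker phase per model and can append
a mercury HETATM. These files are synthetic stand-ins for deposited NMR
ensembles: they exercise parsing, torsion extraction, circular
statistics and superposition, but contain no experimental coordinates,
so passing ensemble tests demonstrates the machinery, not agreement with
any deposited structure.

What the synthetic data do not emulate: lineshapes and spectral overlap,
baseline and integration artefacts, spin diffusion (volumes are exact
r^-6 in the peak tables), field- or condition-dependent rate changes,
and inter-site correlation of noise. Recovery results on synthetic data
therefore bound estimator behaviour under the stated noise model only.

## Problem sizes

The default test and reproduction runs use 16-point delay grids, 100
noisy replicates for the z-z recovery study (30 in the unit suite),
20-model ensembles, and 958-peak restraint tables — sizes chosen to
match the scale of the experiments they emulate while keeping a full
run in tens of seconds.
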