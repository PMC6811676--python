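# metallonmr

Quantitative analysis of slow conformational exchange in duplex DNA
carrying metallo base pairs (C–Hg(II)–T), as measured by solution NMR.
The package is aimed at structural-biology groups who quantify two-state
interconversion from z-z exchange (EXSY) and NOESY peak-volume build-up
curves, infer sugar geometry from scalar couplings and deposited
multi-model structures, and calibrate NOE volumes into distance
restraints — and who want every stage testable against synthetic data
with known ground truth.

## The model

A major and a minor duplex conformer interconvert slowly on the
chemical-shift time scale:

    major  ⇌  minor        (forward k1, reverse k-1, s^-1)

During a mixing delay t_m, longitudinal magnetization migrates between
the two pools at these rates while every pool relaxes with a shared
longitudinal rate R1. For magnetization prepared on the major species,

    V_AA(t) = V0 (p_A + p_B e^{-k_ex t}) e^{-R1 t}
    V_aA(t) = V0 p_B (1 - e^{-k_ex t}) e^{-R1 t}

with k_ex = k1 + k-1 and equilibrium populations p_A = k-1/k_ex,
p_B = k1/k_ex. Exchange-mediated NOE cross peaks are modelled by a
four-pool network (one proton pair per conformer) combining exchange with
intra-conformer cross-relaxation σ. The package fits

* all four NH2/NH z-z exchange curves globally with shared (k1, k-1, R1),
* single cross peaks to V(t) = C(1 - e^{-k_ex t})e^{-R1 t} for k_ex,
* the diagonal-normalized ratio aA/(AA+aA) = p_B(1 - e^{-k_ex t}) to
  separate k1 and k-1 (R1 cancels), and
* the mediated ratio Ab/(AB+Ab) against the exact four-pool model.

Geometry tools cover the generalized Karplus equation
J(φ) = A cos²φ + B cosφ + C (+ electronegativity corrections) for
³J(H1′,H2′) ↔ Φ1′2′ conversion, Altona–Sundaralingam pseudorotation
(P, ν_max) with the 18°-sector pucker wheel, and circular-mean dihedral /
heavy-atom r.m.s.d. statistics over multi-model PDB ensembles. NOE
restraint tools implement r_i = r_ref (V_ref/V_i)^{1/6} calibration,
four-category binning (strong 1.8–3.0 Å, medium 1.8–4.5 Å, weak
3.0–6.0 Å, very weak 4.0–7.0 Å) and an XPLOR-dialect writer.

## Worked example

Simulate a z-z exchange experiment at the study conditions (k1 = 3.5,
k-1 = 7.7, R1 = 2.0 s^-1, 16 mixing times 0.01–0.5 s, 5% volume noise)
and fit it back:

```sh
$ metallonmr simulate-zz --seed 7 --out demo
$ metallonmr fit-zz demo/zz_site0.tsv
parameter       estimate        stderr  units
k1      3.4831  0.191   s^-1
k_rev   7.79721 0.162   s^-1
r1      1.96307 0.0997  s^-1
# converged=True ssr=0.0163456 n=64 flags=-
```

The global fit recovers the generating rates within their standard
errors: the major→minor isomerization runs at ~3.5 s^-1 and the reverse
at ~7.7 s^-1, i.e. a ~2–3:1 population ratio in favour of the major form.
Inverting the H1′–H2′ Karplus relation at ³J = 6.5 Hz on the 90–180°
branch gives the sugar dihedral of an O4′-endo-puckered cytosine:

```sh
$ metallonmr karplus --j 6.5 --branch 90:180
142.1
```

A one-command generate→fit→compare loop reports recovery error over
noisy replicates:

```sh
$ metallonmr recover --scenario default_zz --reps 5 --seed 7
median_rel_err_k1       0.0151
median_rel_err_k_rev    0.0126
```

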