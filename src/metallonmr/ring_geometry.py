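"""Karplus coupling/dihedral conversion and sugar pseudorotation analysis.

Three-bond scalar couplings report on the intervening H-C-C-H dihedral via
the Karplus relation; for furanose sugars the five endocyclic torsions are
summarized by a pseudorotation phase P and amplitude nu_max
(Altona-Sundaralingam convention), whose value classifies the pucker
(C3'-endo ~ A-form, C2'-endo ~ B-form, O4'-endo intermediate).  The module
also provides dihedral measurement from coordinates and circular statistics
over multi-model ensembles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import circmean, circstd

from .structure_io import ModelEnsemble, normalize_atom_name

__all__ = [
    "KarplusParams",
    "KarplusSubstituent",
    "RingTorsions",
    "PuckerState",
    "karplus_forward",
    "karplus_invert",
    "pseudorotation_from_torsions",
    "torsions_from_pseudorotation",
    "pucker_class",
    "dihedral_from_coords",
    "ensemble_dihedral",
    "ensemble_rmsd",
    "kabsch_rmsd",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class KarplusSubstituent:
    """Electronegative substituent term of the generalized Karplus equation.

    ``delta_chi`` is the group electronegativity difference to hydrogen
    (Huggins scale, attenuated by 0.14 per beta substituent); ``xi`` is the
    +/-1 orientation factor of the substituent relative to the coupled
    protons.
    """

    delta_chi: float
    xi: int

    def __post_init__(self) -> None:
        if self.xi not in (-1, 1):
            raise ValueError("xi must be +1 or -1")


@dataclass(frozen=True)
class KarplusParams:
    """J(phi) = A cos^2 phi + B cos phi + C  (+ electronegativity terms).

    Each substituent contributes
    ``delta_chi * (D + E cos^2(xi * phi + F * |delta_chi|))`` with the
    Haasnoot-de Leeuw-Altona coefficients D = 0.56, E = -2.47, F = 16.9 deg
    by default.  With no substituents this is the plain three-term Karplus
    equation.
    """

    a: float
    b: float
    c: float = 0.0
    substituents: tuple[KarplusSubstituent, ...] = ()
    d: float = 0.56
    e: float = -2.47
    f: float = 16.9

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("leading Karplus coefficient A must be > 0")

    @classmethod
    def plain(cls, a: float, b: float, c: float = 0.0) -> "KarplusParams":
        """Three-term J = A cos^2 + B cos + C with no corrections."""
        return cls(a=a, b=b, c=c)

    @classmethod
    def deoxyribose_h1p_h2p(cls) -> "KarplusParams":
        """Generalized parameterization for H1'-C1'-C2'-H2' in 2'-deoxyribose.

        Substituents: O4' and the glycosidic nitrogen on C1', C3' on C2'
        (the fourth position carries H2'').  Group electronegativities with
        beta-substituent attenuation: O4' 1.27 - 0.14*0.45, N1
        0.85 - 0.14*0.90, C3' 0.45 - 0.14*1.72.
        """
        return cls(
            a=13.70,
            b=-0.73,
            c=0.0,
            substituents=(
                KarplusSubstituent(1.207, +1),   # O4'
                KarplusSubstituent(0.724, -1),   # glycosidic N
                KarplusSubstituent(0.2092, +1),  # C3'
            ),
        )


def karplus_forward(phi: float | np.ndarray, params: KarplusParams) -> float | np.ndarray:
    """Evaluate the (generalized) Karplus equation at dihedral phi (degrees)."""
    phi_r = np.asarray(phi, dtype=float) * _DEG
    j = params.a * np.cos(phi_r) ** 2 + params.b * np.cos(phi_r) + params.c
    for s in params.substituents:
        j = j + s.delta_chi * (
            params.d
            + params.e * np.cos(s.xi * phi_r + params.f * abs(s.delta_chi) * _DEG) ** 2
        )
    if np.isscalar(phi) or np.asarray(phi).ndim == 0:
        return float(j)
    return j


def _attainable_range(params: KarplusParams) -> tuple[float, float]:
    grid = np.arange(0.0, 360.0, 0.05)
    j = karplus_forward(grid, params)
    return float(np.min(j)), float(np.max(j))


def karplus_invert(
    j: float,
    params: KarplusParams,
    branch: tuple[float, float] | None = None,
) -> list[float]:
    """All dihedral roots of J(phi) = j on [0, 360), degrees.

    Roots are bracketed on a 0.25 deg grid and refined by Brent's method to
    1e-6 deg.  When a ``branch`` window (lo, hi) is given, only roots inside
    it are returned.  A coupling outside the attainable range of J raises
    with the min/max J reported.
    """
    jmin, jmax = _attainable_range(params)
    if j < jmin - 1e-9 or j > jmax + 1e-9:
        raise ValueError(
            f"J = {j} Hz is unattainable for these Karplus parameters "
            f"(range {jmin:.3f} to {jmax:.3f} Hz)"
        )
    grid = np.arange(0.0, 360.0 + 0.25, 0.25)
    vals = karplus_forward(grid, params) - j
    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0:
            roots.append(
                float(brentq(lambda p: karplus_forward(p, params) - j,
                             grid[i], grid[i + 1], xtol=1e-6))
            )
    if abs(vals[-1]) < 1e-12 and not any(abs(r - 360.0) < 1e-6 for r in roots):
        pass  # 360 aliases 0, already covered
    # extremum tangencies (e.g. J exactly at a max): pick up near-touching points
    if not roots:
        idx = int(np.argmin(np.abs(vals)))
        if abs(vals[idx]) < 1e-6:
            roots.append(float(grid[idx] % 360.0))
    # deduplicate within 1e-5 deg (mod 360)
    dedup: list[float] = []
    for r in sorted(r % 360.0 for r in roots):
        if not dedup or abs(r - dedup[-1]) > 1e-5:
            dedup.append(r)
    if branch is not None:
        lo, hi = branch
        dedup = [r for r in dedup if lo <= r <= hi]
    return dedup


# ---------------------------------------------------------------------------
# Pseudorotation

@dataclass(frozen=True)
class RingTorsions:
    """Five endocyclic furanose torsions nu0..nu4, degrees.

    nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', nu2 = C1'-C2'-C3'-C4',
    nu3 = C2'-C3'-C4'-O4', nu4 = C3'-C4'-O4'-C1'.
    """

    nu0: float
    nu1: float
    nu2: float
    nu3: float
    nu4: float

    def __post_init__(self) -> None:
        for name in ("nu0", "nu1", "nu2", "nu3", "nu4"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} = {v} outside (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.nu0, self.nu1, self.nu2, self.nu3, self.nu4])


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase P (deg, [0, 360)), amplitude nu_max and class."""

    phase: float
    amplitude: float
    pucker_class: str


# twenty 18-deg sectors; envelopes centred at 18 + 36 k, twists between them
_ENVELOPES = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]
_SECTOR_NAMES: list[str] = []
for _k in range(20):
    if _k % 2 == 1:
        _SECTOR_NAMES.append(_ENVELOPES[_k // 2])
    else:
        _prev = _ENVELOPES[(_k // 2 - 1) % 10]
        _next = _ENVELOPES[_k // 2]
        _SECTOR_NAMES.append(f"{_prev}/{_next} twist")


def pucker_class(phase: float) -> str:
    """Pucker class from phase via the 18-deg sector wheel, [lo, hi) sectors.

    Sector k is centred at 18 k deg; C3'-endo at 18, O4'-endo at 90,
    C2'-endo at 162.
    """
    p = phase % 360.0
    k = int(math.floor((p + 9.0) / 18.0)) % 20
    return _SECTOR_NAMES[k]


_AMP_DENOM = 2.0 * (math.sin(36.0 * _DEG) + math.sin(72.0 * _DEG))


def pseudorotation_from_torsions(t: RingTorsions) -> PuckerState:
    """Altona-Sundaralingam phase/amplitude from five endocyclic torsions.

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
    quadrant-corrected via atan2; nu_max recovered as the hypotenuse of
    (nu2, numerator/denominator) so that a nu2 near zero is not a failure.
    """
    y = ((t.nu4 + t.nu1) - (t.nu3 + t.nu0)) / _AMP_DENOM
    x = t.nu2
    amplitude = math.hypot(x, y)
    if amplitude < 1e-9:
        return PuckerState(phase=0.0, amplitude=0.0, pucker_class="planar/undefined")
    phase = math.degrees(math.atan2(y, x)) % 360.0
    return PuckerState(phase=phase, amplitude=amplitude, pucker_class=pucker_class(phase))


def torsions_from_pseudorotation(phase: float, nu_max: float) -> RingTorsions:
    """Ideal torsions nu_j = nu_max cos(P + 144 (j - 2)), j = 0..4."""
    if nu_max < 0:
        raise ValueError("nu_max must be >= 0")
    nus = [nu_max * math.cos((phase + 144.0 * (j - 2)) * _DEG) for j in range(5)]
    return RingTorsions(*nus)


# ---------------------------------------------------------------------------
# Dihedrals from coordinates

def dihedral_from_coords(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: three collinear points")
    b2_hat = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(b2_hat, np.cross(n1, n2)))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


_DEFAULT_PHI_ATOMS = ("H1'", "C1'", "C2'", "H2'")


def ensemble_dihedral(
    ensemble: ModelEnsemble,
    residue: str,
    atom_names: Sequence[str] = _DEFAULT_PHI_ATOMS,
) -> dict:
    """Per-model dihedral over a structure ensemble plus circular mean/sd.

    ``residue`` is a "chain:resnum" selector; atom names are normalized
    (prime dialects accepted).  Models missing any named atom are skipped
    with a warning; returns dict with per_model (degrees), mean, sd,
    n_used, n_skipped.
    """
    names = [normalize_atom_name(n) for n in atom_names]
    if len(names) != 4:
        raise ValueError("exactly four atom names required")
    values: list[float] = []
    skipped = 0
    for i in range(ensemble.n_models):
        try:
            coords = [ensemble.atom_coords(i, residue, n) for n in names]
        except KeyError as exc:
            skipped += 1
            warnings.warn(f"model {i}: {exc}; skipped")
            continue
        values.append(dihedral_from_coords(*coords))
    if not values:
        raise ValueError(f"no model contains atoms {names} in residue {residue}")
    arr = np.asarray(values)
    mean = float(circmean(arr, high=180.0, low=-180.0))
    sd = float(circstd(arr, high=180.0, low=-180.0))
    return {
        "per_model": values,
        "mean": mean,
        "sd": sd,
        "n_used": len(values),
        "n_skipped": skipped,
    }


# ---------------------------------------------------------------------------
# Ensemble r.m.s.d.

def kabsch_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """Least-squares superposition r.m.s.d. between two (n, 3) coordinate sets."""
    P = np.asarray(coords, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ P.T).T - Q
    return float(np.sqrt((diff ** 2).sum() / P.shape[0]))


def ensemble_rmsd(
    ensemble: ModelEnsemble,
    reference: int = 0,
    heavy_only: bool = True,
) -> dict:
    """Heavy-atom r.m.s.d. of every model against a reference model.

    Atoms common to all models (optionally heavy atoms only) are matched by
    (residue, name).  Returns per_model values (reference excluded from the
    summary), mean, sd, n_atoms.
    """
    keys = ensemble.common_atom_keys(heavy_only=heavy_only)
    if not keys:
        raise ValueError("no atoms shared across all models")
    stacks = [
        np.array([ensemble.atom_coords(i, f"{c}:{r}", a) for (c, r, a) in keys])
        for i in range(ensemble.n_models)
    ]
    ref = stacks[reference]
    per_model = [kabsch_rmsd(s, ref) for s in stacks]
    others = [v for i, v in enumerate(per_model) if i != reference]
    return {
        "per_model": per_model,
        "mean": float(np.mean(others)) if others else 0.0,
        "sd": float(np.std(others, ddof=1)) if len(others) > 1 else 0.0,
        "n_atoms": len(keys),
    }
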