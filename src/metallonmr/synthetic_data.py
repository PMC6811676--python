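"""Synthetic datasets with the statistical structure the analyses assume.

Every pipeline stage can be exercised without the study's raw spectra: the
generators here emit z-z exchange curve sets, four-pool NOESY curve sets,
ISPA-consistent NOE peak tables, idealized furanose rings and multi-model
PDB ensembles, each alongside its ground truth and reproducible under a
fixed seed.

Default scenario conditions mirror the experimental design they emulate: a
two-conformer system at roughly 3:1 population interconverting at a few
per second (z-z scheme k1 = 3.5, k_rev = 7.7 s^-1; NOESY scheme k1 = 4.3,
k_rev = 8.8 s^-1), shared R1 = 2 s^-1, 16 mixing times log-spaced on
0.01-0.5 s, and 5% multiplicative Gaussian volume noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .exchange_models import (
    ExchangeSystem,
    NoePairSystem,
    VolumeSeries,
    simulate_exchange_noe,
    simulate_nh2_nh_zz,
    write_volume_series_tsv,
)
from .noe_restraints import DEFAULT_REFERENCE_DISTANCE, NoePeak

__all__ = [
    "ScenarioConfig",
    "default_zz_scenario",
    "default_noesy_scenario",
    "generate_zz_dataset",
    "generate_noesy_dataset",
    "generate_noe_peak_table",
    "build_ring_coordinates",
    "generate_synthetic_ensemble_pdb",
    "apply_multiplicative_noise",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator conditions for one simulated exchange experiment."""

    k1: float = 3.5
    k_rev: float = 7.7
    r1: float = 2.0
    sigma: float = -1.0
    retention_factor: float = 0.5
    delays: tuple[float, ...] = ()
    noise_sd: float = 0.05
    n_sites: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        delays = tuple(float(t) for t in self.delays)
        if not delays:
            delays = tuple(float(t) for t in np.geomspace(0.01, 0.5, 16))
        arr = np.asarray(delays)
        if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("delay grid must be non-negative and strictly increasing")
        object.__setattr__(self, "delays", delays)

    @property
    def system(self) -> ExchangeSystem:
        return ExchangeSystem(self.k1, self.k_rev, self.r1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["delays"] = tuple(data.get("delays", ()))
        return cls(**data)


def default_zz_scenario(seed: int = 0, noise_sd: float = 0.05) -> ScenarioConfig:
    """NH2/NH z-z exchange conditions (k1 = 3.5, k_rev = 7.7 s^-1)."""
    return ScenarioConfig(k1=3.5, k_rev=7.7, r1=2.0, noise_sd=noise_sd, seed=seed)


def default_noesy_scenario(
    seed: int = 0, noise_sd: float = 0.05, n_sites: int = 5
) -> ScenarioConfig:
    """Four-pool NOESY conditions (k1 = 4.3, k_rev = 8.8 s^-1, sigma = -1)."""
    return ScenarioConfig(
        k1=4.3, k_rev=8.8, r1=2.0, sigma=-1.0, noise_sd=noise_sd,
        n_sites=n_sites, seed=seed,
    )


def apply_multiplicative_noise(
    series: VolumeSeries, rng: np.random.Generator, sd: float
) -> VolumeSeries:
    """Multiplicative Gaussian noise, truncated so volumes keep their sign.

    V -> V (1 + sd eps) with eps ~ N(0, 1); the factor is clipped below at
    1e-6 so a positive volume can never become negative.
    """
    if sd == 0:
        return series
    factor = np.clip(1.0 + sd * rng.standard_normal(len(series)), 1e-6, None)
    return VolumeSeries(series.label, series.times, series.volumes * factor)


def generate_zz_dataset(config: ScenarioConfig, out_dir: str | Path | None = None):
    """Per-site NH2/NH z-z exchange curve sets with ground truth.

    Returns (sites, truth) where ``sites`` is a list (one entry per
    reporter site) of label -> VolumeSeries dicts and ``truth`` records the
    generating parameters.  With ``out_dir`` set, each site is written as
    TSV next to a ground_truth.yaml sidecar.
    """
    rng = np.random.default_rng(config.seed)
    sites = []
    for _ in range(config.n_sites):
        clean = simulate_nh2_nh_zz(
            config.system, config.retention_factor, np.asarray(config.delays)
        )
        noisy = {
            lab: apply_multiplicative_noise(s, rng, config.noise_sd)
            for lab, s in clean.items()
        }
        sites.append(noisy)
    truth = {
        "k1": config.k1, "k_rev": config.k_rev, "r1": config.r1,
        "retention_factor": config.retention_factor,
        "noise_sd": config.noise_sd, "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, site in enumerate(sites):
            write_volume_series_tsv(site, out_dir / f"zz_site{i}.tsv")
        Path(out_dir / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
    return sites, truth


def generate_noesy_dataset(config: ScenarioConfig, out_dir: str | Path | None = None):
    """Per-site eight-peak NOESY curve sets from the four-pool network."""
    rng = np.random.default_rng(config.seed)
    system = NoePairSystem(config.system, config.sigma, config.sigma)
    sites = []
    for _ in range(config.n_sites):
        clean = simulate_exchange_noe(system, np.asarray(config.delays))
        noisy = {
            lab: apply_multiplicative_noise(s, rng, config.noise_sd)
            for lab, s in clean.items()
        }
        sites.append(noisy)
    truth = {
        "k1": config.k1, "k_rev": config.k_rev, "r1": config.r1,
        "sigma": config.sigma, "noise_sd": config.noise_sd, "seed": config.seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, site in enumerate(sites):
            write_volume_series_tsv(site, out_dir / f"noesy_site{i}.tsv")
        Path(out_dir / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
    return sites, truth


def generate_noe_peak_table(
    n_peaks: int,
    duplex_length: int,
    seed: int,
    distance_range: tuple[float, float] = (1.8, 7.0),
    reference_distance: float = DEFAULT_REFERENCE_DISTANCE,
    noise_sd: float = 0.0,
) -> tuple[list[NoePeak], dict]:
    """ISPA-consistent synthetic NOE peak table over a duplex.

    Distances are drawn uniformly on ``distance_range``; volumes follow
    V = V_ref (r_ref / r)^6 with optional lognormal noise.  The first peak
    is the reference pair (residue 1 H5-H6 at ``reference_distance``).
    Residue separations mix intra, sequential and long-range contacts.
    Returns (peaks, truth) with the generating distances recorded.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    lo, hi = distance_range
    if not (1.8 <= lo < hi <= 7.0):
        raise ValueError("distance_range must lie within [1.8, 7.0] A")
    rng = np.random.default_rng(seed)
    v_ref = 1000.0
    peaks = [NoePeak(1, "H5", 1, "H6", v_ref)]
    distances = [reference_distance]
    atoms = ("H1'", "H2'", "H2''", "H6", "H8", "H5")
    for _ in range(n_peaks - 1):
        r = float(rng.uniform(lo, hi))
        i = int(rng.integers(1, duplex_length + 1))
        sep = int(rng.choice([0, 1, 2, 3, 4, 5], p=[0.3, 0.45, 0.1, 0.05, 0.05, 0.05]))
        j = min(max(i + sep, 1), duplex_length)
        v = v_ref * (reference_distance / r) ** 6
        if noise_sd > 0:
            v *= float(np.exp(noise_sd * rng.standard_normal()))
        a, b = rng.choice(atoms, size=2, replace=True)
        peaks.append(NoePeak(i, str(a), j, str(b), v))
        distances.append(r)
    truth = {
        "distances": distances,
        "reference_distance": reference_distance,
        "duplex_length": duplex_length,
        "seed": seed,
        "noise_sd": noise_sd,
    }
    return peaks, truth


# ---------------------------------------------------------------------------
# Idealized ring / ensemble builders

def build_ring_coordinates(
    phase: float,
    nu_max: float,
    bond_length: float = 1.53,
) -> np.ndarray:
    """Coordinates (5, 3) of an idealized furanose ring.

    Atoms in endocyclic order O4', C1', C2', C3', C4'.  Starting from a
    puckered regular pentagon, the geometry is least-squares refined so
    its five endocyclic torsions match the ideal pseudorotation pattern
    nu_j = nu_max cos(P + 144 (j - 2)) with equal bond lengths.
    """
    from .ring_geometry import torsions_from_pseudorotation

    target = torsions_from_pseudorotation(phase, nu_max).as_array()
    radius = bond_length / (2.0 * math.sin(math.pi / 5.0))
    angles = 2.0 * math.pi * np.arange(5) / 5.0
    # initial out-of-plane displacements follow the torsion phase pattern
    z0 = 0.2 * np.cos(math.radians(phase) + 4.0 * math.pi * (np.arange(5) - 2) / 5.0)
    x0 = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), z0]
    ).ravel()

    def residual(flat: np.ndarray) -> np.ndarray:
        from .ring_geometry import dihedral_from_coords

        pts = flat.reshape(5, 3)
        res = []
        for j in range(5):
            quad = [pts[(j - 1) % 5], pts[j], pts[(j + 1) % 5], pts[(j + 2) % 5]]
            try:
                nu = dihedral_from_coords(*quad)
            except ValueError:
                nu = 0.0
            diff = (nu - target[j] + 180.0) % 360.0 - 180.0
            res.append(0.1 * diff)  # degrees, down-weighted vs bond lengths
        for j in range(5):
            d = np.linalg.norm(pts[(j + 1) % 5] - pts[j])
            res.append(10.0 * (d - bond_length))
        for j in range(5):  # weak prior on interior angles, fixes the gauge
            u = pts[(j - 1) % 5] - pts[j]
            v = pts[(j + 1) % 5] - pts[j]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            res.append(0.01 * (ang - 103.0))
        return np.asarray(res)

    sol = least_squares(residual, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol.x.reshape(5, 3)


def _h_positions(ring: np.ndarray, target_phi: float | None = None) -> dict:
    """Place H1' on C1' and H2' on C2' roughly tetrahedrally.

    Each proton points away from the mean of its carbon's ring neighbours,
    tilted out of the local ring plane; the resulting H1'-C1'-C2'-H2'
    dihedral follows the ring geometry.
    """
    o4p, c1p, c2p, c3p, c4p = ring
    out = {}
    # H1' above and H2' below the local ring plane, as for the trans-oriented
    # H1'/H2' pair of a beta-D-deoxyribose (phi_1'2' ~ nu1 + 120 deg)
    for name, center, n1, n2, side in (
        ("H1'", c1p, o4p, c2p, -1.0),
        ("H2'", c2p, c1p, c3p, +1.0),
    ):
        away = center - 0.5 * (n1 + n2)
        away /= np.linalg.norm(away)
        normal = np.cross(n1 - center, n2 - center)
        normal /= np.linalg.norm(normal)
        direction = away * math.cos(math.radians(55.0)) + side * normal * math.sin(
            math.radians(55.0)
        )
        out[name] = center + 1.09 * direction / np.linalg.norm(direction)
    return out


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: np.ndarray, element: str, het: bool = False,
) -> str:
    record = "HETATM" if het else "ATOM  "
    pdb_name = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {pdb_name:<4.4s} {resname:<3.3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
    )


def generate_synthetic_ensemble_pdb(
    path: str | Path,
    n_models: int = 20,
    n_residues: int = 4,
    phase: float = 90.0,
    nu_max: float = 38.0,
    phase_jitter: float = 0.0,
    seed: int = 0,
    with_mercury: bool = False,
) -> Path:
    """Write a synthetic multi-model PDB of idealized sugar rings.

    Each residue is a furanose ring (with H1'/H2') built at pseudorotation
    ``phase`` (optionally jittered per model), translated along x.  A
    mercury HETATM can be appended to emulate the metallo site.  The file
    is a synthetic stand-in for a deposited NMR ensemble, intended for
    exercising the ensemble analyses, and carries no experimental content.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for res in range(1, n_residues + 1):
            p = phase + (rng.normal(0.0, phase_jitter) if phase_jitter else 0.0)
            ring = build_ring_coordinates(p, nu_max)
            ring = ring + np.array([6.0 * res, 0.0, 0.0])
            names = ("O4'", "C1'", "C2'", "C3'", "C4'")
            for name, xyz in zip(names, ring):
                lines.append(
                    _pdb_atom_line(serial, name, "DC", "A", res, xyz,
                                   "O" if name.startswith("O") else "C")
                )
                serial += 1
            for name, xyz in _h_positions(ring).items():
                lines.append(_pdb_atom_line(serial, name, "DC", "A", res, xyz, "H"))
                serial += 1
        if with_mercury:
            hg = np.array([3.0, 3.0, 0.0])
            lines.append(
                _pdb_atom_line(serial, "HG", "HG", "A", n_residues + 1, hg, "HG",
                               het=True)
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
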