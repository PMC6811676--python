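"""Forward models of longitudinal magnetization exchange.

Two conformers of a metallo duplex interconvert slowly on the chemical-shift
time scale (major <-> minor, forward rate ``k1``, reverse rate ``k_rev``).
During a mixing delay of a z-z exchange or NOESY experiment, longitudinal
magnetization migrates between the pools at these rates while every pool
relaxes with a shared longitudinal rate ``R1``.  This module provides

* the closed-form two-pool solution for auto and exchange cross peaks,
* a general rate-matrix propagator (the numerical oracle for every closed
  form in the package),
* the NH2/NH z-z exchange scheme, where conversion of the amine pool into
  the deprotonated imine pool carries only a fraction of the magnetization
  (one of two amine protons is displaced by the metal), and
* the four-pool exchange + cross-relaxation network that produces
  exchange-mediated NOE cross peaks.

Peak labels follow the two-character convention ``"xy"``: magnetization that
started on pool ``y`` and is detected on pool ``x``.  Upper case denotes the
major conformer, lower case the minor conformer; ``A``/``a`` is the observed
proton and ``B``/``b`` its cross-relaxation partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExchangeSystem",
    "NoePairSystem",
    "MagnetizationState",
    "VolumeSeries",
    "propagate_rate_matrix",
    "simulate_two_site",
    "simulate_nh2_nh_zz",
    "simulate_exchange_noe",
    "read_volume_series_tsv",
    "write_volume_series_tsv",
]

#: labels accepted on VolumeSeries (z-z exchange, NOESY and NH2/NH schemes)
PEAK_ALPHABET = frozenset(
    {
        "AA", "aa", "aA", "Aa",
        "AB", "ab", "Ab", "aB",
        "BB", "bb", "bB", "Bb", "BA", "ba", "Ba", "bA",
        "NH2", "NH", "NH2'", "NH'",
    }
)


@dataclass(frozen=True)
class ExchangeSystem:
    """Two-state kinetic model of major/minor conformer interconversion.

    Parameters
    ----------
    k1:
        Forward rate major -> minor, s^-1.
    k_rev:
        Reverse rate minor -> major, s^-1.
    r1:
        Shared longitudinal relaxation rate, s^-1.
    """

    k1: float
    k_rev: float
    r1: float
    label_major: str = "major"
    label_minor: str = "minor"

    def __post_init__(self) -> None:
        for name in ("k1", "k_rev", "r1"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def k_ex(self) -> float:
        """Exchange rate k1 + k_rev, s^-1."""
        return self.k1 + self.k_rev

    @property
    def p_major(self) -> float:
        """Equilibrium population of the major conformer, k_rev / k_ex."""
        if self.k_ex == 0:
            raise ValueError(
                "equilibrium populations are undefined when k1 = k_rev = 0"
            )
        return self.k_rev / self.k_ex

    @property
    def p_minor(self) -> float:
        """Equilibrium population of the minor conformer, k1 / k_ex."""
        if self.k_ex == 0:
            raise ValueError(
                "equilibrium populations are undefined when k1 = k_rev = 0"
            )
        return self.k1 / self.k_ex


@dataclass(frozen=True)
class NoePairSystem:
    """Four-pool network: one proton pair (X, Y) in each of two conformers.

    Exchange connects X_major <-> X_minor and Y_major <-> Y_minor only;
    cross-relaxation connects X <-> Y within a conformer only.  The
    cross-relaxation rates are stored with their relaxation-matrix sign
    (negative for slowly tumbling macromolecules); the transfer magnitude
    ``|sigma|`` enters the rate-matrix off-diagonals.
    """

    exchange: ExchangeSystem
    sigma_major: float
    sigma_minor: float

    def __post_init__(self) -> None:
        for name in ("sigma_major", "sigma_minor"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class MagnetizationState:
    """Magnetization per pool at one mixing time (arbitrary units)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.labels),):
            raise ValueError(
                f"need one value per pool: {len(self.labels)} labels, "
                f"values shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("magnetization values must be finite")
        object.__setattr__(self, "values", values)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])


@dataclass(frozen=True)
class VolumeSeries:
    """A labelled peak-volume vs mixing-time curve."""

    label: str
    times: np.ndarray
    volumes: np.ndarray
    sigma_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        if self.label not in PEAK_ALPHABET:
            raise ValueError(
                f"unknown peak label {self.label!r}; expected one of the "
                f"declared alphabet {sorted(PEAK_ALPHABET)}"
            )
        if times.ndim != 1 or volumes.shape != times.shape:
            raise ValueError("times and volumes must be 1-D and equal length")
        if np.any(times < 0):
            idx = int(np.argmax(times < 0))
            raise ValueError(f"negative mixing time at index {idx}: {times[idx]}")
        if np.any(np.diff(times) <= 0):
            raise ValueError("mixing times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if self.sigma_volumes is not None:
            sig = np.asarray(self.sigma_volumes, dtype=float)
            if sig.shape != times.shape:
                raise ValueError("sigma_volumes must match times in length")
            object.__setattr__(self, "sigma_volumes", sig)

    def __len__(self) -> int:
        return self.times.size


def _check_delays(delays: Sequence[float]) -> np.ndarray:
    t = np.asarray(delays, dtype=float)
    if t.ndim != 1:
        raise ValueError("delays must be a 1-D time vector")
    bad = np.flatnonzero(t < 0)
    if bad.size:
        raise ValueError(f"negative delay at index {bad[0]}: {t[bad[0]]}")
    return t


def propagate_rate_matrix(
    rate_matrix: np.ndarray,
    initial: MagnetizationState,
    delays: Sequence[float],
) -> list[MagnetizationState]:
    """Propagate dM/dt = K.M through a list of mixing delays.

    Uses eigendecomposition of ``K`` (one decomposition, vectorized over
    delays) with a fallback to scipy's scaling-and-squaring ``expm`` when
    the eigenvector matrix is ill-conditioned (defective or nearly so).
    Serves as the oracle for every closed-form model in this module.
    """
    K = np.asarray(rate_matrix, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"rate matrix must be square, got shape {K.shape}")
    if K.shape[0] != len(initial.labels):
        raise ValueError(
            f"dimension mismatch: matrix {K.shape[0]} pools, "
            f"state has {len(initial.labels)}"
        )
    off = K - np.diag(np.diag(K))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rate-matrix entries must be >= 0")
    t = _check_delays(delays)
    m0 = initial.values
    trajectory = _propagate(K, m0, t)
    return [MagnetizationState(initial.labels, trajectory[i]) for i in range(t.size)]


def _propagate(K: np.ndarray, m0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Return array (n_delays, n_pools) of M(t); eigen route, expm fallback."""
    try:
        lam, V = np.linalg.eig(K)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenvectors")
        c = np.linalg.solve(V, m0)
        out = np.real((V * c) @ np.exp(np.outer(lam, t)))  # (n_pools, n_t)
        return out.T
    except np.linalg.LinAlgError:
        from scipy.linalg import expm

        return np.stack([expm(K * ti) @ m0 for ti in t])


def _two_site_matrix(system: ExchangeSystem) -> np.ndarray:
    k1, kr, r1 = system.k1, system.k_rev, system.r1
    return np.array([[-k1 - r1, kr], [k1, -kr - r1]])


def simulate_two_site(
    system: ExchangeSystem,
    delays: Sequence[float],
    initial_site: str | None = None,
    v0: float = 1.0,
) -> dict[str, VolumeSeries]:
    """Closed-form two-site z-z exchange curves.

    For magnetization starting entirely on the major conformer A::

        V_AA(t) = V0 (p_A + p_B e^{-k_ex t}) e^{-R1 t}
        V_aA(t) = V0 p_B (1 - e^{-k_ex t}) e^{-R1 t}

    and symmetrically for minor origin.  Returns the four peaks ``AA``,
    ``aA``, ``aa``, ``Aa`` (label = detected pool + origin pool); when
    ``initial_site`` is the major or minor label, only that origin's pair
    is returned.
    """
    t = _check_delays(delays)
    kex, r1 = system.k_ex, system.r1
    decay = np.exp(-r1 * t)
    if kex > 0:
        pa, pb = system.p_major, system.p_minor
        e = np.exp(-kex * t)
        curves = {
            "AA": v0 * (pa + pb * e) * decay,
            "aA": v0 * pb * (1.0 - e) * decay,
            "aa": v0 * (pb + pa * e) * decay,
            "Aa": v0 * pa * (1.0 - e) * decay,
        }
    else:
        zero = np.zeros_like(t)
        curves = {"AA": v0 * decay, "aA": zero, "aa": v0 * decay, "Aa": zero}
    if initial_site is not None:
        if initial_site == system.label_major:
            keep = ("AA", "aA")
        elif initial_site == system.label_minor:
            keep = ("aa", "Aa")
        else:
            raise ValueError(
                f"unknown initial site {initial_site!r}; expected "
                f"{system.label_major!r} or {system.label_minor!r}"
            )
        curves = {k: curves[k] for k in keep}
    return {k: VolumeSeries(k, t, v) for k, v in curves.items()}


def nh2_nh_rate_matrix(system: ExchangeSystem, retention_factor: float) -> np.ndarray:
    """Two-pool generator for the NH2 (major) / NH (minor) z-z scheme.

    The major -> minor flux into the NH pool is scaled by
    ``retention_factor`` (one of the two amine protons is lost on metal
    binding); the minor -> major flux distributes equally into the combined
    NH2 pool, so its summed volume receives the full ``k_rev`` flux.
    """
    if not 0.0 <= retention_factor <= 1.0:
        raise ValueError(f"retention_factor must lie in [0, 1], got {retention_factor}")
    k1, kr, r1 = system.k1, system.k_rev, system.r1
    return np.array(
        [[-k1 - r1, kr], [retention_factor * k1, -kr - r1]]
    )


def simulate_nh2_nh_zz(
    system: ExchangeSystem,
    retention_factor: float = 0.5,
    delays: Sequence[float] = (),
    v0: float = 1.0,
) -> dict[str, VolumeSeries]:
    """NH2/NH z-z exchange curves of the amine <-> imine interconversion.

    Returns four series: ``NH2`` (major-origin auto), ``NH'`` (major-origin
    exchange peak), ``NH`` (minor-origin auto), ``NH2'`` (minor-origin
    exchange peak).  With ``retention_factor = 1`` the curves reduce to
    :func:`simulate_two_site`.
    """
    t = _check_delays(delays)
    K = nh2_nh_rate_matrix(system, retention_factor)
    from_major = _propagate(K, np.array([v0, 0.0]), t)
    from_minor = _propagate(K, np.array([0.0, v0]), t)
    return {
        "NH2": VolumeSeries("NH2", t, from_major[:, 0]),
        "NH'": VolumeSeries("NH'", t, from_major[:, 1]),
        "NH": VolumeSeries("NH", t, from_minor[:, 1]),
        "NH2'": VolumeSeries("NH2'", t, from_minor[:, 0]),
    }


#: pool order of the four-pool NOE network
NOE_POOLS = ("A", "a", "B", "b")


def noe_rate_matrix(system: NoePairSystem) -> np.ndarray:
    """4x4 generator over pools (A, a, B, b): exchange + cross-relaxation.

    ``A``/``a`` are the observed proton X in major/minor, ``B``/``b`` its
    NOE partner Y.  Exchange couples A<->a and B<->b; |sigma| couples A<->B
    and a<->b.
    """
    ex = system.exchange
    k1, kr, r1 = ex.k1, ex.k_rev, ex.r1
    sM, sm = abs(system.sigma_major), abs(system.sigma_minor)
    return np.array(
        [
            [-k1 - sM - r1, kr, sM, 0.0],
            [k1, -kr - sm - r1, 0.0, sm],
            [sM, 0.0, -k1 - sM - r1, kr],
            [0.0, sm, k1, -kr - sm - r1],
        ]
    )


def simulate_exchange_noe(
    system: NoePairSystem,
    delays: Sequence[float],
    initial_pool: str | None = None,
    v0: float = 1.0,
) -> dict[str, VolumeSeries]:
    """Exchange + NOE build-up curves of the four-pool network.

    Propagates unit magnetization from each origin pool and records the
    volumes detected on the observed proton pools ``A`` and ``a``, giving
    the eight peaks AA, aA (exchange), AB, ab (direct NOE), Ab, aB
    (exchange-mediated NOE), aa, Aa.  ``initial_pool`` restricts the
    origins simulated.  With sigma = 0 the network reduces to two
    independent two-site systems; with k_ex = 0 to pure NOE transfer
    within each conformer.
    """
    t = _check_delays(delays)
    K = noe_rate_matrix(system)
    origins = NOE_POOLS if initial_pool is None else (initial_pool,)
    out: dict[str, VolumeSeries] = {}
    for origin in origins:
        if origin not in NOE_POOLS:
            raise ValueError(f"unknown pool {origin!r}; expected one of {NOE_POOLS}")
        m0 = np.zeros(4)
        m0[NOE_POOLS.index(origin)] = v0
        traj = _propagate(K, m0, t)
        for detected in ("A", "a"):
            label = detected + origin
            out[label] = VolumeSeries(label, t, traj[:, NOE_POOLS.index(detected)])
    return out


# ---------------------------------------------------------------------------
# TSV serialization

def write_volume_series_tsv(
    series: Iterable[VolumeSeries] | Mapping[str, VolumeSeries],
    path: str | Path,
) -> None:
    """Write series as TSV with columns label, t_mix_s, volume[, sigma_volume]."""
    if isinstance(series, Mapping):
        series = list(series.values())
    else:
        series = list(series)
    rows = []
    has_sigma = any(s.sigma_volumes is not None for s in series)
    for s in series:
        for i in range(len(s)):
            row = {"label": s.label, "t_mix_s": s.times[i], "volume": s.volumes[i]}
            if has_sigma:
                row["sigma_volume"] = (
                    s.sigma_volumes[i] if s.sigma_volumes is not None else np.nan
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_volume_series_tsv(path: str | Path) -> dict[str, VolumeSeries]:
    """Read a VolumeSeries TSV; a missing sigma_volume column means unweighted."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "t_mix_s", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing TSV columns: {sorted(missing)}")
    out = {}
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("t_mix_s")
        sigma = None
        if "sigma_volume" in grp.columns and grp["sigma_volume"].notna().all():
            sigma = grp["sigma_volume"].to_numpy()
        out[str(label)] = VolumeSeries(
            str(label), grp["t_mix_s"].to_numpy(), grp["volume"].to_numpy(), sigma
        )
    return out
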