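"""Toy Coulomb-explosion simulator: stochastic ionization + classical N-body dynamics.

The physical picture: a femtosecond X-ray pulse strips on the order of one
electron per atom from the sample.  At that ionization level every bond is
broken and the subsequent motion is dominated by pairwise Coulomb repulsion
between the ions, which fly apart and, after a few hundred femtoseconds,
travel on essentially straight asymptotic trajectories at 1e4-1e5 m/s.

This module deliberately simplifies the ionization physics to a single
stochastic charge assignment before the dynamics (sudden approximation):
per-atom charges are Poisson-distributed with element-dependent means,
calibrated so the expected average ionization hits a target (default 1.2
charges/atom, scaling linearly with pulse fluence).  The dynamics is
velocity-Verlet integration of Plummer-softened Coulomb forces,

    V_ij = k q_i q_j / sqrt(r^2 + eps^2),   k = e^2/(4 pi eps0) = 14.3996 eV A,

run from rest until the potential energy is spent or a maximum time is
reached.  Only the asymptotic ejection *directions* and speeds are kept —
those are what a distant detector sees.

Internal units: Angstrom, femtosecond, amu, elementary charge, eV.
1 A/fs = 1e5 m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .structures import AtomCloud

__all__ = [
    "PulseModel",
    "IonEjecta",
    "assign_charges",
    "simulate_explosion",
    "rotate_ejecta",
    "ExplosionError",
    "K_COULOMB",
    "SPEED_TO_MS",
]

#: Coulomb constant e^2 / (4 pi eps0) in eV * Angstrom.
K_COULOMB = 14.399645

#: Acceleration conversion: (eV/A) / amu -> A/fs^2.
ACC_CONV = 9.64853322e-3

#: 1 A/fs in m/s.
SPEED_TO_MS = 1.0e5

DEFAULT_FLUENCE = 5.0e6  # photons / nm^2


@dataclass(frozen=True)
class PulseModel:
    """X-ray pulse parameters; defaults are a feasible soft-X-ray SPI setting.

    Only the fluence enters the toy model (it scales the expected
    ionization); the temporal shape is carried as metadata because charges
    are assigned in the sudden approximation, once, before the dynamics.
    """

    fluence: float = DEFAULT_FLUENCE  # photons / nm^2
    photon_energy_kev: float = 2.0
    peak_time_fs: float = 20.0
    fwhm_fs: float = 10.0


@dataclass
class IonEjecta:
    """Asymptotic ion ejection data from one explosion realization."""

    directions: np.ndarray  # (M, 3) unit vectors
    speeds: np.ndarray  # (M,) m/s
    charges: np.ndarray  # (M,) elementary charges
    masses: np.ndarray  # (M,) amu
    source_label: str = ""
    realization_seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=np.float64)
        self.speeds = np.asarray(self.speeds, dtype=np.float64)
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")
        norms = np.linalg.norm(self.directions, axis=1)
        if len(norms) and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("ejection directions must be unit vectors")

    @property
    def n_ions(self) -> int:
        return len(self.speeds)

    def save(self, path) -> None:
        np.savez(
            path,
            directions=self.directions,
            speeds=self.speeds,
            charges=self.charges,
            masses=self.masses,
            source_label=np.array(self.source_label),
            realization_seed=np.array(-1 if self.realization_seed is None else self.realization_seed),
            metadata_keys=np.array(list(self.metadata.keys())),
            metadata_values=np.array([str(v) for v in self.metadata.values()]),
        )

    @classmethod
    def load(cls, path) -> "IonEjecta":
        with np.load(path) as data:
            seed = int(data["realization_seed"])
            meta = dict(zip(data["metadata_keys"].tolist(), data["metadata_values"].tolist()))
            return cls(
                directions=data["directions"],
                speeds=data["speeds"],
                charges=data["charges"],
                masses=data["masses"],
                source_label=str(data["source_label"]),
                realization_seed=None if seed < 0 else seed,
                metadata=meta,
            )


class ExplosionError(RuntimeError):
    """Raised for unusable explosion inputs or a failed integration."""


# ---------------------------------------------------------------------------
# charge assignment
# ---------------------------------------------------------------------------

def _expected_capped_poisson(lam: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """E[min(X, cap)] for X ~ Poisson(lam), via E[min(X,c)] = sum_{k<c} P(X>k)."""
    out = np.zeros_like(lam)
    kmax = int(cap.max())
    for k in range(kmax):
        active = cap > k
        out[active] += stats.poisson.sf(k, lam[active])
    return out


def assign_charges(
    cloud: AtomCloud,
    pulse: PulseModel | None = None,
    mean_ionization: float = 1.2,
    rng_seed=None,
    element_weights=None,
) -> AtomCloud:
    """Sample per-atom integer charges for one explosion realization.

    Each atom's charge is Poisson with mean proportional to an element
    weight (default: its atomic number Z, i.e. heavier atoms lose more
    electrons), capped at the element's electron count.  The means are
    rescaled by a solved scalar so that the *expected capped total* equals
    ``mean_ionization * N_atoms * (fluence / default fluence)`` — the cap
    (mostly hydrogen's +1 limit) would otherwise bias the realized average
    below target.
    """
    if mean_ionization <= 0:
        raise ValueError("mean_ionization must be > 0")
    pulse = pulse or PulseModel()
    n = cloud.n_atoms
    z = cloud.elements.astype(np.float64)
    if element_weights is None:
        weights = z.copy()
    else:
        weights = np.asarray(
            [element_weights[int(zi)] for zi in cloud.elements], dtype=np.float64
        )
    caps = cloud.elements.astype(np.int64)

    target = mean_ionization * n * (pulse.fluence / DEFAULT_FLUENCE)
    if target >= caps.sum():
        raise ValueError(
            f"target total charge {target:.0f} exceeds the available "
            f"{caps.sum()} electrons"
        )
    lam0 = target * weights / weights.sum()

    def gap(scale: float) -> float:
        return _expected_capped_poisson(scale * lam0, caps).sum() - target

    # capping only ever lowers the mean, so the solved scale is >= 1
    hi = 2.0
    while gap(hi) < 0 and hi < 1e4:
        hi *= 2.0
    scale = optimize.brentq(gap, 1.0 - 1e-9, hi, xtol=1e-10)

    rng = np.random.default_rng(rng_seed)
    charges = np.minimum(rng.poisson(scale * lam0), caps)
    return replace(cloud, charges=charges.astype(np.int64))


# ---------------------------------------------------------------------------
# N-body dynamics
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _accel_kernel(pos, q, minv, eps2, out):
        n = pos.shape[0]
        out[:] = 0.0
        for i in range(n):
            xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
            qi = q[i]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz + eps2
                f = K_COULOMB * ACC_CONV * qi * q[j] / (r2 * np.sqrt(r2))
                fx = f * dx
                fy = f * dy
                fz = f * dz
                out[i, 0] += fx * minv[i]
                out[i, 1] += fy * minv[i]
                out[i, 2] += fz * minv[i]
                out[j, 0] -= fx * minv[j]
                out[j, 1] -= fy * minv[j]
                out[j, 2] -= fz * minv[j]

    @numba.njit(cache=True, fastmath=True)
    def _potential_kernel(pos, q, eps2):
        n = pos.shape[0]
        pe = 0.0
        for i in range(n):
            xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
            qi = q[i]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                pe += qi * q[j] / np.sqrt(dx * dx + dy * dy + dz * dz + eps2)
        return K_COULOMB * pe

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _accel_numpy(pos, q, minv, eps2, out):
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff) + eps2
    np.fill_diagonal(r2, np.inf)
    f = K_COULOMB * ACC_CONV * (q[:, None] * q[None, :]) / (r2 * np.sqrt(r2))
    out[:] = np.einsum("ij,ijk->ik", f, diff) * minv[:, None]


def _potential_numpy(pos, q, eps2):
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff) + eps2
    np.fill_diagonal(r2, np.inf)
    return 0.5 * K_COULOMB * float(((q[:, None] * q[None, :]) / np.sqrt(r2)).sum())


def _accel(pos, q, minv, eps2, out):
    if _HAVE_NUMBA:
        _accel_kernel(pos, q, minv, eps2, out)
    else:  # pragma: no cover
        _accel_numpy(pos, q, minv, eps2, out)


def _potential(pos, q, eps2):
    if _HAVE_NUMBA:
        return _potential_kernel(pos, q, eps2)
    return _potential_numpy(pos, q, eps2)  # pragma: no cover


def simulate_explosion(
    cloud: AtomCloud,
    dt: float = 0.5,
    max_time: float = 250.0,
    softening: float = 0.1,
    include_neutrals: bool = False,
    pe_fraction_stop: float = 0.01,
    check_every: int = 25,
) -> IonEjecta:
    """Integrate the Coulomb explosion of a charged cloud from rest.

    Velocity-Verlet with Plummer softening ``eps`` (default 0.1 A); the run
    ends at ``max_time`` fs (default 250) or earlier once the remaining
    potential energy drops below ``pe_fraction_stop`` of the total.  Total
    energy must be conserved within 5% or the run aborts with advice to
    reduce ``dt``; at the default step the drift is well under 1%.

    Neutral atoms feel no force and are excluded from the ejecta by default;
    with ``include_neutrals`` they are reported at speed 0 along their
    (normalized) initial position — the limiting ballistic direction under
    an infinitesimal outward push.

    Returns the asymptotic unit ejection directions and speeds (m/s).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    charged = cloud.charges > 0
    if not np.any(charged):
        raise ExplosionError("nothing to explode: all charges are zero")

    pos = np.ascontiguousarray(cloud.positions[charged])
    q = np.ascontiguousarray(cloud.charges[charged], dtype=np.float64)
    m = cloud.masses[charged]
    minv = np.ascontiguousarray(1.0 / m)
    eps2 = float(softening) ** 2

    vel = np.zeros_like(pos)
    acc = np.empty_like(pos)
    _accel(pos, q, minv, eps2, acc)

    e_total = _potential(pos, q, eps2)  # starts from rest: E = PE
    n_steps = int(np.ceil(max_time / dt))
    half_dt = 0.5 * dt
    for step in range(1, n_steps + 1):
        vel += half_dt * acc
        pos += dt * vel
        _accel(pos, q, minv, eps2, acc)
        vel += half_dt * acc
        if step % check_every == 0 or step == n_steps:
            pe = _potential(pos, q, eps2)
            if pe < pe_fraction_stop * e_total:
                break

    pe = _potential(pos, q, eps2)
    ke = 0.5 * float((m * (vel * vel).sum(axis=1)).sum()) / ACC_CONV
    drift = abs((ke + pe) - e_total) / e_total
    if drift > 0.05:
        raise ExplosionError(
            f"energy drift {drift:.1%} exceeds 5%; reduce dt (currently {dt} fs)"
        )

    speeds = np.linalg.norm(vel, axis=1)
    moving = speeds > 0
    directions = np.zeros_like(vel)
    directions[moving] = vel[moving] / speeds[moving, None]
    directions, speeds = directions[moving], speeds[moving]
    out_charges = q[moving].astype(np.int64)
    out_masses = m[moving]

    if include_neutrals:
        neutral_pos = cloud.positions[~charged]
        radii = np.linalg.norm(neutral_pos, axis=1)
        ok = radii > 0
        ndirs = neutral_pos[ok] / radii[ok, None]
        directions = np.vstack([directions, ndirs])
        speeds = np.concatenate([speeds, np.zeros(ok.sum())])
        out_charges = np.concatenate([out_charges, np.zeros(int(ok.sum()), dtype=np.int64)])
        out_masses = np.concatenate([out_masses, cloud.masses[~charged][ok]])

    return IonEjecta(
        directions=directions,
        speeds=speeds * SPEED_TO_MS,
        charges=out_charges,
        masses=out_masses,
        source_label=cloud.label,
        metadata={
            "dt_fs": dt,
            "max_time_fs": max_time,
            "softening_A": softening,
            "energy_drift": drift,
            "total_energy_eV": e_total,
        },
    )


def rotate_ejecta(ejecta: IonEjecta, R) -> IonEjecta:
    """Rotate all ejection directions by ``R`` (same operation the detector uses)."""
    return replace(ejecta, directions=ejecta.directions @ R.as_matrix().T)
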