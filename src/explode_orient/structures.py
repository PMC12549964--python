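"""Atom clouds: loading PDB structures, synthesizing globular stand-ins, rigid rotation.

The explosion input is a bare point cloud — positions, element identities,
masses and (initially zero) charges.  No bonded topology is needed: once the
sample is ionized to ~+1 charge per atom every bond is broken and the
dynamics is purely electrostatic.

The lab frame is right-handed with the explosion origin at the cloud's
center of mass; all detector geometry is defined in this frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .rotations import Rotation

__all__ = [
    "AtomCloud",
    "read_pdb",
    "synthesize_cloud",
    "rotate_cloud",
    "jitter_cloud",
    "ELEMENTS",
    "DEFAULT_COMPOSITION",
]

# Standard atomic numbers and weights for elements seen in protein structures.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "HE": (2, 4.0026),
    "LI": (3, 6.94),
    "B": (5, 10.81),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "F": (9, 18.998),
    "NA": (11, 22.990),
    "MG": (12, 24.305),
    "SI": (14, 28.085),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "CL": (17, 35.45),
    "K": (19, 39.098),
    "CA": (20, 40.078),
    "MN": (25, 54.938),
    "FE": (26, 55.845),
    "CO": (27, 58.933),
    "NI": (28, 58.693),
    "CU": (29, 63.546),
    "ZN": (30, 65.38),
    "SE": (34, 78.971),
    "BR": (35, 79.904),
    "I": (53, 126.90),
}

_Z_TO_MASS = {z: m for z, m in ELEMENTS.values()}
_Z_TO_SYMBOL = {z: sym for sym, (z, _) in ELEMENTS.items()}

#: Average protein stoichiometry by atom count (hydrogens included).
DEFAULT_COMPOSITION: dict[str, float] = {
    "H": 0.50,
    "C": 0.32,
    "N": 0.09,
    "O": 0.09,
    "S": 0.005,
}

#: Typical atom number density of a folded protein, atoms per cubic Angstrom.
PROTEIN_NUMBER_DENSITY = 0.11

_WATER_RES = {"HOH", "WAT", "DOD", "H2O", "SOL", "TIP", "TIP3"}

_SIZE_RANGE = (100, 4000)


@dataclass
class AtomCloud:
    """A point cloud of atoms: the object that explodes.

    Attributes
    ----------
    positions : (N, 3) float array, Angstrom, center of mass at the origin.
    elements : (N,) int array of atomic numbers Z.
    masses : (N,) float array, atomic mass units.
    charges : (N,) int array, elementary charges (0 before ionization).
    label : identifier carried through to footprints and reports.
    """

    positions: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    charges: np.ndarray = field(default=None)
    label: str = ""

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        n = len(self.elements)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (N, 3) matching elements")
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.charges is None:
            self.charges = np.zeros(n, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        if not (_SIZE_RANGE[0] <= n <= _SIZE_RANGE[1]):
            warnings.warn(
                f"cloud '{self.label}' has {n} atoms, outside the "
                f"{_SIZE_RANGE[0]}-{_SIZE_RANGE[1]} regime the method targets",
                stacklevel=3,
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.positions / self.masses.sum()

    def centered(self) -> "AtomCloud":
        """Copy with the center of mass translated to the origin."""
        return replace(self, positions=self.positions - self.center_of_mass())

    def save(self, path) -> None:
        np.savez(
            path,
            positions=self.positions,
            elements=self.elements,
            masses=self.masses,
            charges=self.charges,
            label=np.array(self.label),
        )

    @classmethod
    def load(cls, path) -> "AtomCloud":
        with np.load(path) as data:
            return cls(
                positions=data["positions"],
                elements=data["elements"],
                masses=data["masses"],
                charges=data["charges"],
                label=str(data["label"]),
            )


def _masses_for(elements: np.ndarray) -> np.ndarray:
    try:
        return np.array([_Z_TO_MASS[int(z)] for z in elements])
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"no mass table entry for atomic number {exc}") from exc


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed into an atom cloud."""


def read_pdb(path, *, include_waters: bool = False, allow_empty: bool = False) -> AtomCloud:
    """Load a PDB file into an :class:`AtomCloud`.

    The first model and the first altloc are kept; hydrogens are kept when
    present; water molecules are excluded unless ``include_waters``.  The
    returned cloud is translated so its center of mass sits at the origin.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise PDBFormatError(f"cannot parse PDB file {path!s}: {exc}") from exc

    if not include_waters:
        atoms = atoms[~np.isin(atoms.res_name, list(_WATER_RES))]
    if atoms.array_length() == 0:
        if allow_empty:
            return AtomCloud(
                positions=np.zeros((0, 3)),
                elements=np.zeros(0, dtype=int),
                masses=np.zeros(0),
                label=str(path),
            )
        raise PDBFormatError(
            f"{path!s} contains no non-water atoms (pass include_waters=True "
            "or allow_empty=True to override)"
        )

    symbols = np.char.upper(atoms.element.astype(str))
    unknown = [s for s in np.unique(symbols) if s not in ELEMENTS]
    if unknown:
        bad = np.flatnonzero(np.isin(symbols, unknown))[:5]
        names = ", ".join(f"atom {i} ({symbols[i]!r})" for i in bad)
        raise PDBFormatError(f"unknown element symbol(s) in {path!s}: {names}")

    elements = np.array([ELEMENTS[s][0] for s in symbols], dtype=np.int64)
    cloud = AtomCloud(
        positions=atoms.coord.astype(np.float64),
        elements=elements,
        masses=_masses_for(elements),
        label=str(path),
    )
    return cloud.centered()


def synthesize_cloud(
    n_atoms: int,
    composition_weights: dict[str, float] | None = None,
    radius_scale: float = 1.0,
    rng_seed=None,
    min_distance: float = 1.0,
    label: str = "",
) -> AtomCloud:
    """Generate a globular random atom cloud with protein-like composition.

    Atoms are placed uniformly in a ball whose radius scales as
    ``radius_scale * (3 n / (4 pi rho))^(1/3)`` with ``rho`` the typical
    protein atom density (0.11 atoms/A^3), subject to a hard minimum
    interatomic distance (default 1.0 A, the order of a covalent bond).
    Reproducible given ``rng_seed``.
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    comp = dict(composition_weights or DEFAULT_COMPOSITION)
    symbols = [s.upper() for s in comp]
    for s in symbols:
        if s not in ELEMENTS:
            raise ValueError(f"unknown element symbol {s!r} in composition weights")
    w = np.array(list(comp.values()), dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(rng_seed)

    radius = radius_scale * (3.0 * n_atoms / (4.0 * np.pi * PROTEIN_NUMBER_DENSITY)) ** (1 / 3)
    positions = _pack_ball(n_atoms, radius, min_distance, rng, radius_scale)

    counts = rng.multinomial(n_atoms, w)
    elements = np.repeat([ELEMENTS[s][0] for s in symbols], counts)
    rng.shuffle(elements)

    cloud = AtomCloud(
        positions=positions,
        elements=elements,
        masses=_masses_for(elements),
        label=label or f"synthetic-{n_atoms}",
    )
    return cloud.centered()


def _pack_ball(
    n: int, radius: float, min_distance: float, rng: np.random.Generator, radius_scale: float
) -> np.ndarray:
    """Dart-throwing placement with a cell list for the min-distance check."""
    cell = max(min_distance, 1e-6)
    grid: dict[tuple[int, int, int], list[int]] = {}
    pts = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 500 * n
    d2min = min_distance * min_distance
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} atoms with min distance {min_distance} A in a "
                f"ball of radius {radius:.1f} A; increase radius_scale "
                f"(currently {radius_scale})"
            )
        attempts += 1
        p = rng.uniform(-radius, radius, 3)
        if p @ p > radius * radius:
            continue
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for idx in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = pts[idx] - p
                        if d @ d < d2min:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault(key, []).append(placed)
            placed += 1
    return pts


def rotate_cloud(cloud: AtomCloud, R: Rotation) -> AtomCloud:
    """Rigidly rotate a cloud about the origin; pairwise distances are preserved."""
    return replace(cloud, positions=cloud.positions @ R.as_matrix().T)


def jitter_cloud(cloud: AtomCloud, sigma: float = 0.3, rng_seed=None) -> AtomCloud:
    """Perturb atomic positions with isotropic Gaussian noise (std ``sigma``, A).

    Emulates the structural heterogeneity between explosion realizations of
    the same molecule; the cloud is re-centered afterwards.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng_seed)
    jittered = replace(cloud, positions=cloud.positions + rng.normal(0.0, sigma, cloud.positions.shape))
    return jittered.centered()
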