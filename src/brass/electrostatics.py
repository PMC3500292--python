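"""Electrostatic potential sources and pairwise potential differences.

The potential at each functional atom, expressed in the dimensionless
kT/e units written by finite-difference Poisson-Boltzmann solvers, can
come from two sources:

* :class:`PotentialGrid` -- an OpenDX scalar grid (the APBS output
  dialect), sampled by trilinear interpolation; or
* :class:`ChargeSet` -- partial charges and radii from a PQR file,
  evaluated with a screened-Coulomb (Debye-Hueckel) model
  phi(x) = sum_i q_i exp(-kappa r_i) / (4 pi eps0 eps_r r_i).

Both expose ``potential(point)``, so everything downstream is agnostic
to the source.  Potential differences between scaffold positions form an
antisymmetric matrix PD[i][j] = phi_i - phi_j reported pair-by-pair in
the order ab, ac, ad, bc, bd, cd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import constants
from scipy.interpolate import RegularGridInterpolator

from .errors import OutOfGridError, ParseError, SingularityError, UnsupportedFormatError
from .structure import Atom

#: Minimum source-charge distance (A) below which the Coulomb sum is singular.
MIN_CHARGE_DISTANCE = 0.1


@dataclass
class PotentialGrid:
    """Regular orthogonal scalar field in kT/e on grid nodes."""

    origin: np.ndarray  # (3,) A
    spacing: np.ndarray  # (3,) A
    counts: tuple[int, int, int]
    values: np.ndarray  # shape == counts

    _interp: Optional[RegularGridInterpolator] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float).reshape(self.counts)
        if any(c < 2 for c in self.counts):
            raise ValueError("grid needs at least 2 nodes per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.counts[k]) for k in range(3)
        )

    def potential(self, point: Sequence[float]) -> float:
        """Trilinear interpolation; never extrapolates outside the box."""
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.axes(), self.values, method="linear", bounds_error=True
            )
        pt = np.asarray(point, dtype=float)
        try:
            return float(self._interp(pt)[0])
        except ValueError:
            raise OutOfGridError(
                f"point {pt.tolist()} outside potential grid "
                f"[{self.origin.tolist()} .. {(self.origin + self.spacing * (np.array(self.counts) - 1)).tolist()}]"
            )


@dataclass
class ChargeSet:
    """Point partial charges (e) with radii (A) and a Debye-Hueckel model.

    Defaults: eps_r = 78.5 (water), kappa = 0.09 1/A (about 100 mM ionic
    strength), T = 298 K.
    """

    positions: np.ndarray  # (n, 3) A
    charges: np.ndarray  # (n,) e
    radii: np.ndarray  # (n,) A
    eps_r: float = 78.5
    kappa: float = 0.09
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")
        if self.eps_r <= 0:
            raise ValueError("relative permittivity must be positive")
        if self.kappa < 0:
            raise ValueError("inverse screening length must be non-negative")

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def potential(self, point: Sequence[float]) -> float:
        return coulomb_potential(self, point)


PotentialField = Union[PotentialGrid, ChargeSet]


def read_dx(dx_text: str) -> PotentialGrid:
    """Parse an OpenDX scalar field (APBS ``gridpositions`` dialect)."""
    counts = origin = None
    deltas: list[np.ndarray] = []
    data: list[float] = []
    in_data = False
    n_expected = 0
    for raw in dx_text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            if line.startswith(("attribute", "object", "component", "end")):
                in_data = False
                continue
            try:
                data.extend(float(tok) for tok in line.split())
            except ValueError:
                raise ParseError(f"non-numeric data in DX stream: {line!r}")
            continue
        if line.startswith("object") and "gridpositions" in line:
            toks = line.split()
            try:
                counts = tuple(int(t) for t in toks[toks.index("counts") + 1 :][:3])
            except (ValueError, IndexError):
                raise ParseError(f"bad counts line: {line!r}")
        elif line.startswith("origin"):
            origin = np.array([float(t) for t in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append(np.array([float(t) for t in line.split()[1:4]]))
        elif line.startswith("object") and "class array" in line:
            if counts is None:
                raise ParseError("DX data section before grid definition")
            n_expected = int(np.prod(counts))
            in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ParseError("DX stream missing gridpositions/origin/delta records")
    delta = np.vstack(deltas)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise UnsupportedFormatError("non-orthogonal DX deltas are not supported")
    spacing = np.diag(delta)
    if len(data) != n_expected:
        raise ParseError(f"DX value count mismatch: expected {n_expected}, got {len(data)}")
    # APBS writes values with the z index varying fastest
    values = np.array(data).reshape(counts)
    return PotentialGrid(origin=origin, spacing=spacing, counts=tuple(counts), values=values)


def write_dx(grid: PotentialGrid, comment: str = "") -> str:
    """Serialize a grid in the same OpenDX dialect ``read_dx`` consumes."""
    nx, ny, nz = grid.counts
    n = nx * ny * nz
    lines = []
    if comment:
        lines.extend(f"# {c}" for c in comment.splitlines())
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6e} {:.6e} {:.6e}".format(*grid.origin))
    lines.append(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00")
    lines.append(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00")
    lines.append(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(f"object 3 class array type double rank 0 items {n} data follows")
    flat = grid.values.reshape(-1)
    for i in range(0, n, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    return "\n".join(lines) + "\n"


def read_pqr(pqr_text: str) -> ChargeSet:
    """Parse whitespace-delimited PQR ATOM/HETATM records.

    Field order: record serial name resName chainID resSeq x y z charge radius
    (the chainID field may be absent, as PDB2PQR sometimes omits it).
    """
    positions, charges, radii = [], [], []
    for lineno, raw in enumerate(pqr_text.splitlines(), start=1):
        if not raw.startswith(("ATOM", "HETATM")):
            continue
        toks = raw.split()
        if len(toks) not in (10, 11):
            raise ParseError(f"PQR line {lineno}: expected 10 or 11 fields, got {len(toks)}")
        try:
            x, y, z, q, r = (float(t) for t in toks[-5:])
        except ValueError:
            raise ParseError(f"PQR line {lineno}: non-numeric coordinate/charge/radius field")
        positions.append((x, y, z))
        charges.append(q)
        radii.append(r)
    if not positions:
        raise ParseError("no ATOM records in PQR stream")
    return ChargeSet(
        positions=np.array(positions), charges=np.array(charges), radii=np.array(radii)
    )


def write_pqr(charges: ChargeSet, comment: str = "") -> str:
    lines = [f"REMARK   {c}" for c in comment.splitlines()]
    for i, (pos, q, r) in enumerate(zip(charges.positions, charges.charges, charges.radii), 1):
        lines.append(
            f"ATOM {i:6d} X    UNK A {i:4d} "
            f"{pos[0]:10.4f} {pos[1]:10.4f} {pos[2]:10.4f} {q:8.4f} {r:7.4f}"
        )
    return "\n".join(lines) + "\n"


def sample_grid(grid: PotentialGrid, point: Sequence[float]) -> float:
    """Potential at *point* by trilinear interpolation (kT/e)."""
    return grid.potential(point)


def _kt_e_prefactor(temperature: float) -> float:
    """e^2/(4 pi eps0 kB T) in Angstrom: q/r in (e, A) -> phi in kT/e."""
    return (
        constants.elementary_charge**2
        / (4 * np.pi * constants.epsilon_0 * constants.Boltzmann * temperature)
        * 1e10
    )


def coulomb_potential(charges: ChargeSet, point: Sequence[float]) -> float:
    """Screened-Coulomb potential at *point*, in kT/e."""
    pt = np.asarray(point, dtype=float)
    r = np.linalg.norm(charges.positions - pt, axis=1)
    close = r < MIN_CHARGE_DISTANCE
    if np.any(close):
        idx = int(np.argmin(r))
        raise SingularityError(
            f"point {pt.tolist()} is {r[idx]:.3f} A from source charge {idx}"
        )
    pref = _kt_e_prefactor(charges.temperature) / charges.eps_r
    return float(pref * np.sum(charges.charges * np.exp(-charges.kappa * r) / r))


def potentials_at(atoms: Sequence[Atom], field: PotentialField) -> np.ndarray:
    """Potential at each atom's center, with the offending atom named on error."""
    phi = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        try:
            phi[i] = field.potential(atom.position)
        except (OutOfGridError, SingularityError) as exc:
            raise type(exc)(f"atom {atom.label}: {exc}") from exc
    return phi


def pd_matrix(atoms: Sequence[Atom], field: PotentialField) -> np.ndarray:
    """Antisymmetric pairwise potential-difference matrix PD[i][j] = phi_i - phi_j."""
    phi = potentials_at(atoms, field)
    return phi[:, None] - phi[None, :]


def pd_from_potentials(phi: Sequence[float]) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    return phi[:, None] - phi[None, :]


def upper_pairs(matrix: np.ndarray) -> np.ndarray:
    """Flatten the i<j entries in table order (ab, ac, ad, bc, bd, cd)."""
    n = matrix.shape[0]
    return np.array([matrix[i, j] for i in range(n) for j in range(i + 1, n)])
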