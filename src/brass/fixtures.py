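"""Synthetic test structures with planted duplicate scaffolds.

The generator builds small single-chain proteins in which the ground
truth is known by construction:

* a catalytic motif whose functional atoms sit on a realistic
  active-site-scale geometry (pairwise distances 3-15 A);
* ``n_replicas`` planted duplicates, each sharing one designated motif
  residue and carrying fresh residues of the same types at positions
  obtained by rotating the motif geometry about the shared functional
  atom -- exactly congruent at zero jitter, Gaussian-perturbed
  otherwise;
* ``n_decoys`` same-type residues placed far from the site so that any
  scaffold using them violates the spatial cap by a wide margin.

Rotations are drawn and then *validated*: the generator proves, by
exhaustive enumeration over the (tiny) structure, that no accidental
scaffold other than the planted ones is spatially congruent, redrawing
the rotations if necessary.  Residues carry only the backbone (N, CA,
C, O) plus the functional atom; fixtures exercise the search method,
not stereochemistry.

Everything is deterministic in the seed, including the PDB/PQR/DX text
emitted, so identical seeds give byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .electrostatics import ChargeSet, PotentialGrid
from .errors import FixtureError
from .structure import (
    DEFAULT_FUNCTIONAL_ATOMS,
    Atom,
    Residue,
    Structure,
)

#: Default motif residue types and functional-atom coordinates (A) per
#: motif size: synthetic geometries at the pairwise-distance scale of
#: real catalytic sites (methyltransferase-like triangle for n=3,
#: serine-hydrolase-like quartet for n=4).
DEFAULT_MOTIFS: dict[int, tuple[tuple[str, ...], np.ndarray]] = {
    3: (
        ("GLY", "ASN", "GLU"),
        np.array([(0.0, 0.0, 0.0), (9.5, 0.0, 0.0), (-0.3, 4.7, 0.0)]),
    ),
    4: (
        ("GLN", "HIS", "ASP", "SER"),
        np.array(
            [
                (0.0, 0.0, 0.0),
                (9.7, 0.0, 0.0),
                (13.8, 3.4, 0.0),
                (6.2, 0.1, 0.9),
            ]
        ),
    ),
    5: (
        ("GLN", "HIS", "ASP", "SER", "TYR"),
        np.array(
            [
                (0.0, 0.0, 0.0),
                (9.7, 0.0, 0.0),
                (13.8, 3.4, 0.0),
                (6.2, 0.1, 0.9),
                (4.0, 6.0, 3.0),
            ]
        ),
    ),
}

_DECOY_BASE_RADIUS = 25.0  # A from the site centroid; far beyond any d_max


@dataclass
class FixtureSpec:
    """Recipe for one synthetic structure.

    ``motif_types``/``motif_coords`` default to the built-in geometry of
    size ``n``.  ``overlap_index`` is the motif position every replica
    shares.  ``jitter_sigma`` is per-coordinate Gaussian noise (A)
    applied to replica atoms (never to the shared residue).
    """

    n: int = 3
    n_replicas: int = 1
    n_decoys: int = 0
    jitter_sigma: float = 0.0
    mirror: bool = False
    seed: int = 0
    overlap_index: int = 0
    motif_types: Optional[tuple[str, ...]] = None
    motif_coords: Optional[np.ndarray] = None
    d_max: float = 2.0  # cap the decoy-margin guarantee is stated against

    def __post_init__(self) -> None:
        if not 3 <= self.n <= 5:
            raise FixtureError(f"motif size must be 3-5, got {self.n}")
        if self.jitter_sigma < 0:
            raise FixtureError("jitter_sigma must be non-negative")
        if self.motif_types is None or self.motif_coords is None:
            types, coords = DEFAULT_MOTIFS[self.n]
            self.motif_types = self.motif_types or types
            self.motif_coords = np.array(coords) if self.motif_coords is None else self.motif_coords
        self.motif_coords = np.asarray(self.motif_coords, dtype=float)
        if len(self.motif_types) != self.n or self.motif_coords.shape != (self.n, 3):
            raise FixtureError("motif_types/motif_coords must match motif size n")
        if not 0 <= self.overlap_index < self.n:
            raise FixtureError("overlap_index out of range")
        for t in self.motif_types:
            if t not in DEFAULT_FUNCTIONAL_ATOMS:
                raise FixtureError(f"unsupported residue type {t!r}")


@dataclass
class Fixture:
    """Generated structure plus its ground truth."""

    structure: Structure
    motif_spec: list[tuple[str, int, str]]  # (chain, res_seq, res_type)
    planted: list[tuple[tuple[str, int, str], ...]]  # ordered residue keys per replica
    decoy_keys: list[tuple[str, int, str]]
    spec: FixtureSpec


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _backbone(func_pos: np.ndarray, res_type: str, rng: np.random.Generator) -> list[tuple[str, np.ndarray]]:
    """Backbone + functional atom for one residue, randomly oriented."""
    frame = _random_rotation(rng)
    func_name = DEFAULT_FUNCTIONAL_ATOMS[res_type][0]
    atoms: list[tuple[str, np.ndarray]] = []
    if func_name == "N":
        n_pos = func_pos
    else:
        n_pos = func_pos + frame @ np.array([2.4, 0.0, 0.0])
        atoms.append((func_name, func_pos))
    ca = n_pos + frame @ np.array([0.9, 1.2, 0.0])
    c = ca + frame @ np.array([1.3, -0.6, 0.2])
    o = c + frame @ np.array([0.6, -1.0, 0.3])
    return [("N", n_pos), ("CA", ca), ("C", c), ("O", o)] + atoms


def _make_residue(
    res_type: str, res_seq: int, func_pos: np.ndarray, rng: np.random.Generator
) -> Residue:
    atoms = tuple(
        Atom(chain_id="A", res_seq=res_seq, icode=" ", res_type=res_type,
             atom_name=name, position=pos)
        for name, pos in _backbone(func_pos, res_type, rng)
    )
    return Residue(chain_id="A", res_seq=res_seq, icode=" ", res_type=res_type, atoms=atoms)


def _decoy_positions(spec: FixtureSpec, rng: np.random.Generator):
    centroid = spec.motif_coords.mean(axis=0)
    decoys: list[tuple[int, np.ndarray]] = []
    for k in range(spec.n_decoys):
        position_idx = k % spec.n
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = _DECOY_BASE_RADIUS + 6.0 * k
        decoys.append((position_idx, centroid + radius * direction))
    return decoys


def _pairdist(p: np.ndarray) -> np.ndarray:
    return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)


_EPS = 0.05  # A; covers 3-decimal file rounding on the way back in


def _congruence_check(spec: FixtureSpec, site_atoms: dict, planted_sets: list[frozenset]) -> bool:
    """True iff only the motif and the planted replicas are spatially congruent.

    Exhaustive over every ordered tuple of distinct site residues typed
    like the motif.  Jitter is already realized in the coordinates, so
    non-planted tuples only need to breach the cap by a small numerical
    epsilon; decoy-containing tuples must breach it by the stated
    ``d_max + 3 sigma`` safety margin.
    """
    ref_d = _pairdist(spec.motif_coords)
    decoy_margin = spec.d_max + 3.0 * spec.jitter_sigma
    by_type: dict[str, list] = {}
    for key, (res_type, pos) in site_atoms.items():
        by_type.setdefault(res_type, []).append((key, pos))
    pools = [by_type.get(t, []) for t in spec.motif_types]
    ok_sets = set(planted_sets)
    ok_sets.add(frozenset(("motif", i) for i in range(spec.n)))
    iu = np.triu_indices(spec.n, k=1)
    for combo in itertools.product(*pools):
        keys = [k for k, _ in combo]
        if len(set(keys)) != spec.n:
            continue
        cand = np.array([p for _, p in combo])
        dev = np.abs(_pairdist(cand) - ref_d)[iu]
        if frozenset(keys) in ok_sets:
            # planted scaffolds must stay inside the cap and below the
            # default acceptance threshold (1 A per pair)
            if np.any(dev > spec.d_max - _EPS) or dev.sum() > len(dev) - _EPS:
                return False
        else:
            margin = decoy_margin if any(k[0] == "decoy" for k in keys) else spec.d_max + _EPS
            if not np.any(dev > margin):
                return False
    return True


def generate_structure(spec: FixtureSpec, max_retries: int = 500) -> Fixture:
    """Build a synthetic structure with its planted-match ground truth.

    Replica rotations are rejection-sampled one at a time: a rotation is
    kept only if no accidental residue combination mixing the new
    replica with the site built so far is spatially congruent.  If a
    partially built site paints itself into a corner, the whole draw is
    restarted from a fresh deterministic substream.
    """
    coords = spec.motif_coords
    pivot = coords[spec.overlap_index]

    site: dict = {}
    planted_sets: list[frozenset] = []
    for restart in range(20):
        rng = np.random.default_rng((spec.seed, restart))
        # abstract site map: key -> (res_type, functional position)
        site = {("motif", i): (t, coords[i]) for i, t in enumerate(spec.motif_types)}
        planted_sets = []
        for k in range(spec.n_replicas):
            for _ in range(max_retries):
                rot = _random_rotation(rng)
                pos = (coords - pivot) @ rot.T + pivot
                if spec.jitter_sigma > 0:
                    jitter = rng.normal(0.0, spec.jitter_sigma, size=pos.shape)
                    jitter[spec.overlap_index] = 0.0  # shared residue is the motif's own
                    pos = pos + jitter
                keys = []
                trial = dict(site)
                for i, t in enumerate(spec.motif_types):
                    if i == spec.overlap_index:
                        keys.append(("motif", i))
                        continue
                    trial[("rep", k, i)] = (t, pos[i])
                    keys.append(("rep", k, i))
                if _congruence_check(spec, trial, planted_sets + [frozenset(keys)]):
                    site = trial
                    planted_sets.append(frozenset(keys))
                    break
            else:
                break  # replica k unplaceable -> restart from scratch
        if len(planted_sets) == spec.n_replicas:
            break
    else:
        raise FixtureError(
            "could not realize a fixture with unambiguous planted scaffolds "
            "(decoy too close to congruent?)"
        )

    decoys = _decoy_positions(spec, rng)
    for k, (pos_idx, pos) in enumerate(decoys):
        site[("decoy", k)] = (spec.motif_types[pos_idx], pos)
    if not _congruence_check(spec, site, planted_sets):
        raise FixtureError("decoy placement too close to a congruent scaffold")

    # realize residues in a fixed file order with author numbering 10, 20, ...
    order = [("motif", i) for i in range(spec.n)]
    for k in range(spec.n_replicas):
        order += [("rep", k, i) for i in range(spec.n) if i != spec.overlap_index]
    order += [("decoy", k) for k in range(spec.n_decoys)]

    seq_of: dict = {}
    residues = []
    for idx, key in enumerate(order):
        res_type, pos = site[key]
        res_seq = 10 * (idx + 1)
        seq_of[key] = ("A", res_seq, " ")
        residues.append(_make_residue(res_type, res_seq, np.asarray(pos), rng))

    structure = Structure(structure_id=f"FIX{spec.seed % 10000:04d}", residues=residues,
                          source="<fixture>")
    if spec.mirror:
        structure = transform_structure(structure, reflect=True)

    motif_spec = [
        (seq_of[("motif", i)][0], seq_of[("motif", i)][1], spec.motif_types[i])
        for i in range(spec.n)
    ]
    planted = []
    for k in range(spec.n_replicas):
        planted.append(
            tuple(
                seq_of[("motif", i)] if i == spec.overlap_index else seq_of[("rep", k, i)]
                for i in range(spec.n)
            )
        )
    decoy_keys = [seq_of[("decoy", k)] for k in range(spec.n_decoys)]
    return Fixture(structure=structure, motif_spec=motif_spec, planted=planted,
                   decoy_keys=decoy_keys, spec=spec)


def transform_structure(
    structure: Structure,
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
    reflect: bool = False,
) -> Structure:
    """Rigidly transform (and optionally mirror through x -> -x) a structure."""
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    refl = np.diag([-1.0, 1.0, 1.0]) if reflect else np.eye(3)

    def move(p: np.ndarray) -> np.ndarray:
        return rot @ (refl @ p) + trans

    new_residues = []
    for res in structure.residues:
        new_atoms = tuple(
            Atom(a.chain_id, a.res_seq, a.icode, a.res_type, a.atom_name,
                 move(a.position))
            for a in res.atoms
        )
        new_residues.append(
            Residue(res.chain_id, res.res_seq, res.icode, res.res_type, new_atoms,
                    res.is_hetatm)
        )
    return Structure(structure.structure_id, new_residues, structure.source)


def transform_charges(
    charges: ChargeSet,
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
    reflect: bool = False,
) -> ChargeSet:
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    refl = np.diag([-1.0, 1.0, 1.0]) if reflect else np.eye(3)
    new_pos = (charges.positions @ refl.T) @ rot.T + trans
    return ChargeSet(new_pos, charges.charges.copy(), charges.radii.copy(),
                     charges.eps_r, charges.kappa, charges.temperature)


def generate_potential(
    structure: Structure,
    mode: str = "constant",
    seed: int = 0,
    constant_value: float = 0.0,
    charge_scale: float = 0.5,
    charge_offset: float = 1.5,
    spacing: float = 1.0,
    margin: float = 5.0,
):
    """Potential source for a fixture structure.

    ``constant`` -> uniform :class:`PotentialGrid` covering the structure
    (every pairwise potential difference is exactly 0).  ``coulomb`` ->
    :class:`ChargeSet` with seeded partial charges placed a fixed offset
    away from each atom center, so atom centers remain evaluable.
    """
    coords = np.array([a.position for r in structure.residues for a in r.atoms])
    lo, hi = coords.min(axis=0) - margin, coords.max(axis=0) + margin
    if mode == "constant":
        counts = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
        values = np.full(counts, constant_value)
        return PotentialGrid(origin=lo, spacing=np.full(3, spacing), counts=counts,
                             values=values)
    if mode == "coulomb":
        rng = np.random.default_rng((seed, 7))
        offsets = rng.normal(size=coords.shape)
        offsets *= charge_offset / np.linalg.norm(offsets, axis=1, keepdims=True)
        charges = rng.uniform(-charge_scale, charge_scale, size=len(coords))
        radii = np.full(len(coords), 1.5)
        return ChargeSet(positions=coords + offsets, charges=charges, radii=radii)
    raise FixtureError(f"unknown potential mode {mode!r}")


def rasterize_charges(
    charges: ChargeSet,
    structure: Structure,
    spacing: float = 0.25,
    margin: float = 3.0,
    r_clamp: float = 0.3,
) -> PotentialGrid:
    """Sample a ChargeSet onto a regular grid (for DX round-trip tests).

    Node distances to source charges are clamped below ``r_clamp`` A to
    keep node values finite; only nodes essentially on top of a charge
    are affected.
    """
    coords = np.array([a.position for r in structure.residues for a in r.atoms])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    counts = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    axes = [lo[k] + spacing * np.arange(counts[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    # vectorized screened-Coulomb with clamped radii
    from .electrostatics import _kt_e_prefactor

    pref = _kt_e_prefactor(charges.temperature) / charges.eps_r
    values = np.zeros(len(pts))
    for pos, q in zip(charges.positions, charges.charges):
        r = np.linalg.norm(pts - pos, axis=1)
        r = np.maximum(r, r_clamp)
        values += q * np.exp(-charges.kappa * r) / r
    values *= pref
    return PotentialGrid(origin=lo, spacing=np.full(3, spacing), counts=counts,
                         values=values.reshape(counts))
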