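"""Exhaustive duplicate-scaffold search.

Given a structure and its catalytic motif, every ordered tuple of
distinct residues whose types match the motif position-by-position
(exactly, or via stereochemical equivalence groups) is a candidate
scaffold.  Candidates are scored for spatial and electrostatic
congruence against the motif and filtered by the acceptance rules:

  (a) score <= threshold,
  (b) electrostatically compatible (when a potential source is given),
  (c) shares at least one residue with the motif (moonlighting sites
      elsewhere in the protein are deliberately ignored),
  (d) is not the motif itself nor a permutation of its residue set
      (pairwise distances cannot tell mirror images apart, so residue
      sets, not orderings, are the meaningful unit).

Accepted ordered tuples with identical residue sets are collapsed to the
lowest-scoring representative.

Enumeration prunes partial tuples as soon as any placed residue pair
already deviates more than ``d_max`` from the motif geometry; the score
is monotone in the per-pair deviations and one capped pair alone is
penalized beyond any threshold, so pruning never changes the accepted
set (checked against an unpruned oracle in the test suite).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .congruence import ClaspScore, ScoreConfig, clasp_score, distance_matrix, pd_compatible
from .electrostatics import PotentialField, pd_from_potentials, potentials_at
from .errors import MissingAtomError, MotifResolutionError
from .structure import (
    SYMMETRIC_ALTERNATES,
    Atom,
    FunctionalAtomTable,
    Motif,
    Residue,
    Structure,
    functional_atom,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StereoGroup:
    """Named set of stereochemically interchangeable residue types."""

    name: str
    members: frozenset[str]

    def __contains__(self, res_type: str) -> bool:
        return res_type.upper() in self.members


def _group(name: str, members: str) -> StereoGroup:
    return StereoGroup(name, frozenset(members.upper().split()))


#: Built-in equivalence groups for relaxed (stereochemical) matching.
BUILTIN_GROUPS: dict[str, StereoGroup] = {
    g.name: g
    for g in (
        _group("BASIC", "LYS HIS ARG"),
        _group("ACIDIC", "GLU ASP"),
        _group("AMIDE", "ASN GLN"),
        _group("NONPOLAR", "GLY ALA VAL LEU ILE MET"),
        _group("AROMATIC", "PHE TRP TYR"),
    )
}


def parse_groups_file(text: str) -> dict[str, StereoGroup]:
    """Parse ``NAME = RES RES RES`` lines; built-ins are preloaded."""
    groups = dict(BUILTIN_GROUPS)
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad group line {line!r}, expected 'NAME = RES RES'")
        name, members = line.split("=", 1)
        group = _group(name.strip().upper(), members)
        if not group.members:
            raise ValueError(f"group {group.name!r} has no members")
        groups[group.name] = group
    return groups


def group_for_type(res_type: str, groups: Optional[dict[str, StereoGroup]] = None) -> Optional[StereoGroup]:
    """The (first) group containing a residue type, or None."""
    for g in (groups or BUILTIN_GROUPS).values():
        if res_type in g:
            return g
    return None


@dataclass
class ScaffoldMatch:
    """One scored candidate scaffold."""

    residues: tuple[Residue, ...]
    atoms: tuple[Atom, ...]
    d: np.ndarray
    pd: Optional[np.ndarray]
    score: ClaspScore
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def residue_keys(self) -> frozenset:
        return frozenset(r.key for r in self.residues)

    @property
    def sort_key(self):
        return (self.score.total, tuple(r.key for r in self.residues))

    @property
    def label(self) -> str:
        return ",".join(a.label for a in self.atoms)


class _Reference:
    """Motif-side D/PD matrices plus per-position candidate pools."""

    def __init__(
        self,
        structure: Structure,
        motif: Motif,
        config: ScoreConfig,
        potential: Optional[PotentialField],
        table: Optional[FunctionalAtomTable],
        groups_mode: bool,
        all_chains: bool,
        symmetric_alternates: bool,
    ):
        self.config = config
        self.potential = potential
        self.table = table or FunctionalAtomTable()
        self.symmetric_alternates = symmetric_alternates
        self.motif = motif

        self.ref_atoms = tuple(functional_atom(r, self.table) for r in motif.residues)
        self.ref_d = distance_matrix(self.ref_atoms)
        if potential is not None:
            self.ref_pd = pd_from_potentials(potentials_at(self.ref_atoms, potential))
        else:
            self.ref_pd = None

        chain = None if all_chains else motif.chain_id
        pool = structure.searchable_residues(chain)
        self.position_types: list[frozenset[str]] = []
        for i, res in enumerate(motif.residues):
            if groups_mode:
                explicit = motif.groups[i] if motif.groups else None
                group = explicit or group_for_type(res.res_type)
                allowed = group.members if group else frozenset({res.res_type})
            else:
                allowed = frozenset({res.res_type})
            self.position_types.append(allowed)
        self.candidates_per_position: list[list[Residue]] = [
            [r for r in pool if r.res_type in allowed] for allowed in self.position_types
        ]

        # functional-atom options per residue: table atom, plus the
        # symmetric side-chain twin when enabled and present
        self._atom_options: dict[tuple, tuple[Atom, ...]] = {}
        self._phi: dict[tuple[tuple, str], float] = {}

    def atom_options(self, res: Residue) -> tuple[Atom, ...]:
        if res.key not in self._atom_options:
            try:
                primary = functional_atom(res, self.table)
            except MissingAtomError as exc:
                logger.warning("skipping residue: %s", exc)
                self._atom_options[res.key] = ()
                return ()
            options = [primary]
            if self.symmetric_alternates:
                alt_name = SYMMETRIC_ALTERNATES.get(res.res_type, {}).get(primary.atom_name)
                if alt_name is not None:
                    alt = res.atom(alt_name)
                    if alt is not None:
                        options.append(alt)
            self._atom_options[res.key] = tuple(options)
        return self._atom_options[res.key]

    def phi(self, atom: Atom) -> float:
        key = ((atom.chain_id, atom.res_seq, atom.icode), atom.atom_name)
        if key not in self._phi:
            self._phi[key] = potentials_at([atom], self.potential)[0]
        return self._phi[key]


def enumerate_candidates(
    structure: Structure,
    motif: Motif,
    config: Optional[ScoreConfig] = None,
    groups_mode: bool = False,
    all_chains: bool = False,
    prune: bool = True,
    table: Optional[FunctionalAtomTable] = None,
) -> Iterator[tuple[Residue, ...]]:
    """Yield every ordered tuple of distinct residues matching the motif.

    With ``prune=True`` partial tuples whose placed pairs already exceed
    the ``d_max`` deviation cap are cut; such tuples can never be
    accepted, so the accepted set is unchanged.
    """
    config = config or ScoreConfig()
    ref = _Reference(
        structure, motif, config, None, table, groups_mode, all_chains, False
    )
    yield from _enumerate(ref, prune=prune)


def _min_pair_deviation(
    ref: _Reference, i: int, j: int, res_i: Residue, res_j: Residue
) -> float:
    """Smallest |d(cand) - d(ref)| over the functional-atom options."""
    best = np.inf
    for ai in ref.atom_options(res_i):
        for aj in ref.atom_options(res_j):
            d = float(np.linalg.norm(ai.position - aj.position))
            best = min(best, abs(d - ref.ref_d[i, j]))
    return best


def _enumerate(ref: _Reference, prune: bool) -> Iterator[tuple[Residue, ...]]:
    n = ref.motif.n

    def rec(pos: int, partial: list[Residue], used: set) -> Iterator[tuple[Residue, ...]]:
        if pos == n:
            yield tuple(partial)
            return
        for res in ref.candidates_per_position[pos]:
            if res.key in used:
                continue
            if not ref.atom_options(res):
                continue
            if prune and any(
                _min_pair_deviation(ref, i, pos, partial[i], res) > ref.config.d_max
                for i in range(pos)
            ):
                continue
            partial.append(res)
            used.add(res.key)
            yield from rec(pos + 1, partial, used)
            partial.pop()
            used.discard(res.key)

    yield from rec(0, [], set())


def _score_tuple(ref: _Reference, residues: tuple[Residue, ...]) -> ScaffoldMatch:
    """Score one candidate, minimizing over symmetric-atom combinations."""
    option_sets = [ref.atom_options(r) for r in residues]
    best: Optional[ScaffoldMatch] = None
    for atoms in itertools.product(*option_sets):
        d = distance_matrix(atoms)
        if ref.ref_pd is not None:
            pd = pd_from_potentials([ref.phi(a) for a in atoms])
        else:
            pd = None
        score = clasp_score(ref.ref_d, d, ref.ref_pd, pd, ref.config)
        match = ScaffoldMatch(residues=residues, atoms=atoms, d=d, pd=pd, score=score)
        if best is None or match.score.total < best.score.total:
            best = match
    assert best is not None
    return best


def score_candidates(
    structure: Structure,
    motif: Motif,
    config: Optional[ScoreConfig] = None,
    potential: Optional[PotentialField] = None,
    groups_mode: bool = False,
    all_chains: bool = False,
    prune: bool = True,
    table: Optional[FunctionalAtomTable] = None,
    symmetric_alternates: bool = False,
) -> list[ScaffoldMatch]:
    """Enumerate and score all candidate scaffolds (no acceptance rules)."""
    config = config or ScoreConfig()
    ref = _Reference(
        structure, motif, config, potential, table, groups_mode, all_chains,
        symmetric_alternates,
    )
    return [_score_tuple(ref, residues) for residues in _enumerate(ref, prune=prune)]


def apply_rules(
    matches: Sequence[ScaffoldMatch],
    motif: Motif,
    config: ScoreConfig,
    ref_pd: Optional[np.ndarray] = None,
    require_shared_residue: bool = True,
    exclude_motif_set: bool = True,
) -> list[ScaffoldMatch]:
    """Apply the acceptance rules; return collapsed, ordered accepted matches.

    ``ref_pd`` is the motif's own potential-difference matrix (None when
    electrostatics are disabled).  Every match gets its ``accepted`` flag
    and ``rejection_reasons`` filled in place.  Accepted ordered tuples
    sharing a residue set are collapsed to the lowest-scoring one; output
    is sorted by ascending score, ties broken lexicographically on
    residue identifiers.
    """
    thresh = config.threshold_for(motif.n)
    motif_keys = motif.residue_keys
    accepted: list[ScaffoldMatch] = []
    for m in matches:
        reasons = []
        if m.score.total > thresh:
            reasons.append(f"score {m.score.total:.3g} above threshold {thresh:.3g}")
        ok, _ = pd_compatible(ref_pd, m.pd, config)
        if not ok:
            reasons.append("potential-difference deviation above pd_filter")
        if require_shared_residue and not (m.residue_keys & motif_keys):
            reasons.append("shares no residue with the active-site motif (moonlighting)")
        if exclude_motif_set and m.residue_keys == motif_keys:
            reasons.append("identical residue set to the motif (identity/permutation)")
        m.rejection_reasons = reasons
        m.accepted = not reasons
        if m.accepted:
            accepted.append(m)

    collapsed: dict[frozenset, ScaffoldMatch] = {}
    for m in accepted:
        cur = collapsed.get(m.residue_keys)
        if cur is None or m.sort_key < cur.sort_key:
            collapsed[m.residue_keys] = m
    return sorted(collapsed.values(), key=lambda m: m.sort_key)


def reference_scaffold(
    structure: Structure,
    motif: Motif,
    potential: Optional[PotentialField] = None,
    table: Optional[FunctionalAtomTable] = None,
) -> tuple[tuple[Atom, ...], np.ndarray, Optional[np.ndarray]]:
    """The motif's functional atoms and its D and PD matrices."""
    table = table or FunctionalAtomTable()
    atoms = tuple(functional_atom(r, table) for r in motif.residues)
    d = distance_matrix(atoms)
    pd = (
        pd_from_potentials(potentials_at(atoms, potential))
        if potential is not None
        else None
    )
    return atoms, d, pd


def search_self(
    structure: Structure,
    motif: Motif,
    config: Optional[ScoreConfig] = None,
    potential: Optional[PotentialField] = None,
    groups_mode: bool = False,
    all_chains: bool = False,
    prune: bool = True,
    table: Optional[FunctionalAtomTable] = None,
    symmetric_alternates: bool = False,
) -> list[ScaffoldMatch]:
    """Query a structure with its own active-site motif (the BRASS search).

    Returns the collapsed accepted duplicate scaffolds, best first.
    """
    config = config or ScoreConfig()
    matches = score_candidates(
        structure, motif, config, potential, groups_mode, all_chains, prune,
        table, symmetric_alternates,
    )
    _, _, ref_pd = reference_scaffold(structure, motif, potential, table)
    return apply_rules(matches, motif, config, ref_pd=ref_pd)


def cross_query(
    reference_structure: Structure,
    motif: Motif,
    query_structure: Structure,
    config: Optional[ScoreConfig] = None,
    reference_potential: Optional[PotentialField] = None,
    query_potential: Optional[PotentialField] = None,
    groups_mode: bool = False,
    chain: Optional[str] = None,
    prune: bool = True,
    table: Optional[FunctionalAtomTable] = None,
) -> list[ScaffoldMatch]:
    """Search another protein for scaffolds congruent to the reference motif.

    The shared-residue and permutation rules are meaningless across
    proteins and are skipped.  By default all chains of the query are
    searched (give ``chain`` to restrict).  A potential source must be
    supplied per structure or electrostatics are skipped.
    """
    config = config or ScoreConfig()
    table = table or FunctionalAtomTable()
    ref_atoms, ref_d, ref_pd = reference_scaffold(
        reference_structure, motif, reference_potential, table
    )
    use_pd = ref_pd is not None and query_potential is not None

    # re-anchor the motif onto the query by pretending its residues live
    # there: enumeration only needs the per-position residue types
    pool = query_structure.searchable_residues(chain)
    pseudo = Motif(structure_id=query_structure.structure_id, residues=motif.residues,
                   groups=motif.groups)
    ref = _Reference(
        query_structure, pseudo, config, None,
        table, groups_mode, chain is None, False,
    )
    # override: reference geometry/PD come from the reference structure,
    # candidate potentials from the query's own field
    ref.ref_atoms, ref.ref_d = ref_atoms, ref_d
    ref.ref_pd = ref_pd if use_pd else None
    ref.potential = query_potential if use_pd else None
    ref.candidates_per_position = [
        [r for r in pool if r.res_type in allowed] for allowed in ref.position_types
    ]
    matches = [_score_tuple(ref, residues) for residues in _enumerate(ref, prune=prune)]
    return apply_rules(
        matches, pseudo, config, ref_pd=ref.ref_pd,
        require_shared_residue=False, exclude_motif_set=False,
    )
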