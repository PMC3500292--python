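import numpy as np
import pytest

from brass.fixtures import FixtureSpec, _make_residue, generate_structure
from brass.structure import Structure, resolve_motif

MINIMAL_PDB = """\
ATOM      1  N   SER A  15      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  SER A  15      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  OG  SER A  15      12.651   7.921  -4.011  1.00  0.00           O
END
"""


def build_structure(residue_descs, structure_id="TOY", seed=0):
    """Structure from (res_type, res_seq, functional-atom xyz) triples.

    Residues get a full backbone; the functional atom sits exactly at the
    given coordinates.
    """
    rng = np.random.default_rng(seed)
    residues = [
        _make_residue(res_type, res_seq, np.asarray(pos, float), rng)
        for res_type, res_seq, pos in residue_descs
    ]
    return Structure(structure_id=structure_id, residues=residues)


@pytest.fixture
def triad_structure():
    """Minimal structure holding exactly one Gly/Asn/Glu scaffold."""
    return build_structure(
        [("GLY", 10, (0, 0, 0)), ("ASN", 20, (9.5, 0, 0)), ("GLU", 30, (-0.3, 4.7, 0))]
    )


@pytest.fixture
def triad_motif(triad_structure):
    return resolve_motif(
        triad_structure, [("A", 10, "GLY"), ("A", 20, "ASN"), ("A", 30, "GLU")]
    )


@pytest.fixture
def planted_fixture():
    """Two exact planted replicas plus two far decoys."""
    return generate_structure(FixtureSpec(n=3, n_replicas=2, n_decoys=2, seed=42))


def motif_of(fixture):
    return resolve_motif(fixture.structure, fixture.motif_spec)
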