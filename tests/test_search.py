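"""Candidate enumeration, acceptance rules, and cross-protein queries."""

import itertools

import numpy as np
import pytest

from brass.congruence import ScoreConfig
from brass.fixtures import FixtureSpec, generate_structure, transform_structure
from brass.search import (
    BUILTIN_GROUPS,
    apply_rules,
    cross_query,
    enumerate_candidates,
    parse_groups_file,
    score_candidates,
    search_self,
)
from brass.structure import resolve_motif
from conftest import build_structure, motif_of

TRIAD = [("GLY", 10, (0, 0, 0)), ("ASN", 20, (9.5, 0, 0)), ("GLU", 30, (-0.3, 4.7, 0))]
TRIAD_SPEC = [("A", 10, "GLY"), ("A", 20, "ASN"), ("A", 30, "GLU")]


class TestEnumeration:
    def test_motif_only_structure_yields_single_tuple(self, triad_structure, triad_motif):
        tuples = list(enumerate_candidates(triad_structure, triad_motif))
        assert len(tuples) == 1
        assert [r.res_seq for r in tuples[0]] == [10, 20, 30]

    def test_planted_duplicate_doubles_the_count(self):
        s = build_structure(TRIAD + [("GLY", 40, (0.5, 0, 0))])
        m = resolve_motif(s, TRIAD_SPEC)
        assert len(list(enumerate_candidates(s, m))) == 2

    def test_unpruned_count_matches_closed_form(self):
        # 3 GLY x 2 ASN x 2 GLU, all types distinct -> product of counts
        descs = (
            [("GLY", 10 * i, (i, 0, 0)) for i in range(1, 4)]
            + [("ASN", 100 + i, (9.5, i, 0)) for i in range(2)]
            + [("GLU", 200 + i, (-0.3, 4.7, i)) for i in range(2)]
        )
        s = build_structure(descs)
        m = resolve_motif(s, [("A", 10, "GLY"), ("A", 100, "ASN"), ("A", 200, "GLU")])
        tuples = list(enumerate_candidates(s, m, prune=False))
        assert len(tuples) == 3 * 2 * 2
        # brute-force oracle: all ordered products without residue reuse
        pools = [[r for r in s.residues if r.res_type == t] for t in ("GLY", "ASN", "GLU")]
        oracle = [
            c for c in itertools.product(*pools) if len({r.key for r in c}) == 3
        ]
        assert {tuple(r.key for r in t) for t in tuples} == {
            tuple(r.key for r in c) for c in oracle
        }

    def test_yields_are_type_compatible_and_distinct(self, planted_fixture):
        m = motif_of(planted_fixture)
        for t in enumerate_candidates(planted_fixture.structure, m, prune=False):
            assert [r.res_type for r in t] == [r.res_type for r in m.residues]
            assert len({r.key for r in t}) == m.n

    def test_pruning_preserves_accepted_set(self, planted_fixture):
        m = motif_of(planted_fixture)
        s = planted_fixture.structure
        pruned = search_self(s, m, prune=True)
        unpruned = search_self(s, m, prune=False)
        assert [a.residue_keys for a in pruned] == [a.residue_keys for a in unpruned]
        assert [a.score.total for a in pruned] == [a.score.total for a in unpruned]


class TestAcceptanceRules:
    def test_identity_and_permutations_excluded(self):
        # isoceles pair of Asn around Glu: the swapped order scores 0 too
        s = build_structure(
            [("ASN", 1, (0, 0, 0)), ("ASN", 2, (6, 0, 0)), ("GLU", 3, (3, 4, 0))]
        )
        m = resolve_motif(s, [("A", 1, "ASN"), ("A", 2, "ASN"), ("A", 3, "GLU")])
        matches = score_candidates(s, m, prune=False)
        assert len(matches) == 2  # identity + swapped order
        assert all(m_.score.total == pytest.approx(0.0, abs=1e-9) for m_ in matches)
        accepted = apply_rules(matches, m, ScoreConfig())
        assert accepted == []
        assert all(
            any("identity/permutation" in r for r in m_.rejection_reasons)
            for m_ in matches
        )

    def test_moonlighting_scaffold_excluded(self):
        detached = [
            (t, seq + 100, (np.array(pos) + np.array([50.0, 0, 0])).tolist())
            for t, seq, pos in TRIAD
        ]
        s = build_structure(TRIAD + detached)
        m = resolve_motif(s, TRIAD_SPEC)
        matches = score_candidates(s, m, prune=False)
        accepted = apply_rules(matches, m, ScoreConfig())
        assert accepted == []
        moonlighters = [
            m_ for m_ in matches if not (m_.residue_keys & m.residue_keys)
        ]
        assert moonlighters and all(
            m_.score.total == pytest.approx(0.0, abs=1e-9) for m_ in moonlighters
        )
        assert all(
            any("moonlighting" in r for r in m_.rejection_reasons) for m_ in moonlighters
        )

    def test_same_set_orders_collapse_to_best(self):
        # second Asn pair rotated 120 deg about the shared Glu: both orders
        # of the replica score 0 and must collapse to one accepted match,
        # while every mixed Asn pairing deviates beyond the 2 A cap
        s = build_structure(
            [
                ("ASN", 1, (0, 0, 0)),
                ("ASN", 2, (6, 0, 0)),
                ("GLU", 3, (3, 4, 0)),
                ("ASN", 4, (7.964, 3.402, 0)),
                ("ASN", 5, (4.964, 8.598, 0)),
            ]
        )
        m = resolve_motif(s, [("A", 1, "ASN"), ("A", 2, "ASN"), ("A", 3, "GLU")])
        accepted = search_self(s, m, prune=False)
        assert len(accepted) == 1
        assert accepted[0].residue_keys == frozenset(
            {("A", 4, " "), ("A", 5, " "), ("A", 3, " ")}
        )
        # replica coordinates are given to 3 decimals, so "zero" is a few 1e-4
        assert accepted[0].score.total == pytest.approx(0.0, abs=5e-3)

    def test_accepted_sorted_by_score(self, planted_fixture):
        m = motif_of(planted_fixture)
        accepted = search_self(planted_fixture.structure, m)
        totals = [a.score.total for a in accepted]
        assert totals == sorted(totals)


class TestGroupsMode:
    def test_acidic_substitution_found_only_in_groups_mode(self):
        # Asp sits where a Glu-equivalent would: a congruent scaffold only
        # when stereochemical equivalence is allowed
        s = build_structure(TRIAD + [("ASP", 40, (-0.3, 4.7, 0.4))])
        m = resolve_motif(s, TRIAD_SPEC)
        assert search_self(s, m, groups_mode=False) == []
        accepted = search_self(s, m, groups_mode=True)
        assert len(accepted) == 1
        assert {r.res_type for r in accepted[0].residues} == {"GLY", "ASN", "ASP"}

    def test_accepted_matches_respect_group_membership(self):
        s = build_structure(TRIAD + [("ASP", 40, (-0.3, 4.7, 0.4)), ("LYS", 50, (0, 4.7, -0.4))])
        m = resolve_motif(s, TRIAD_SPEC)
        for match in search_self(s, m, groups_mode=True):
            for res, motif_res in zip(match.residues, m.residues):
                group = next(
                    (g for g in BUILTIN_GROUPS.values() if motif_res.res_type in g), None
                )
                allowed = group.members if group else {motif_res.res_type}
                assert res.res_type in allowed

    def test_builtin_groups_membership(self):
        assert BUILTIN_GROUPS["BASIC"].members == frozenset({"LYS", "HIS", "ARG"})
        assert BUILTIN_GROUPS["ACIDIC"].members == frozenset({"GLU", "ASP"})
        assert BUILTIN_GROUPS["AMIDE"].members == frozenset({"ASN", "GLN"})
        assert BUILTIN_GROUPS["NONPOLAR"].members == frozenset(
            {"GLY", "ALA", "VAL", "LEU", "ILE", "MET"}
        )
        assert BUILTIN_GROUPS["AROMATIC"].members == frozenset({"PHE", "TRP", "TYR"})

    def test_groups_file_parsing(self):
        groups = parse_groups_file("HYDROXYL = SER THR TYR\n# comment\n")
        assert groups["HYDROXYL"].members == frozenset({"SER", "THR", "TYR"})
        assert "BASIC" in groups  # built-ins preloaded
        with pytest.raises(ValueError):
            parse_groups_file("BADLINE\n")


class TestCrossQuery:
    def test_self_query_recovers_motif_at_score_zero(self, triad_structure, triad_motif):
        accepted = cross_query(triad_structure, triad_motif, triad_structure)
        assert len(accepted) >= 1
        best = accepted[0]
        assert best.residue_keys == triad_motif.residue_keys
        assert best.score.total == 0.0

    def test_recovers_planted_site_in_transformed_query(self, triad_structure, triad_motif):
        rng = np.random.default_rng(17)
        from brass.fixtures import _random_rotation

        rot = _random_rotation(rng)
        query = transform_structure(triad_structure, rotation=rot,
                                    translation=np.array([30.0, -5.0, 12.0]))
        accepted = cross_query(triad_structure, triad_motif, query)
        assert len(accepted) == 1
        assert accepted[0].residue_keys == triad_motif.residue_keys  # same numbering
        assert accepted[0].score.total == pytest.approx(0.0, abs=1e-9)
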