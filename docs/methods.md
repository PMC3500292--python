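# Methods

## Model

An active-site motif is an ordered tuple of N residues (3 ≤ N ≤ 5, one
polypeptide chain), each represented by a single functional atom. Two
scaffolds are compared through their pairwise functional-atom distance
matrices D (Å) and, when a potential source is available, their pairwise
electrostatic potential-difference matrices PD (kT/e), where
PD_ij = φ(atom_i) − φ(atom_j). The congruence score of a candidate
against the reference motif is an L1 sum over the N(N−1)/2 pairs:

    S = Σ_{i<j} |ΔD_ij| + λ Σ_{i<j} |ΔPD_ij| + P · #{pairs: |ΔD_ij| > d_max}

S = 0 exactly for a perfect replica; S grows monotonically with every
per-pair deviation. Any single pair deviating beyond the spatial cap
`d_max` draws the penalty P, eliminating the candidate outright.

Within one protein, a candidate is accepted as a *duplicate scaffold*
iff

1. S ≤ s_thresh,
2. no single |ΔPD_ij| exceeds `pd_filter` (skipped when no potential
   source is configured),
3. the candidate shares ≥ 1 residue with the motif (a congruent but
   fully detached constellation would indicate a possible moonlighting
   site, which this index deliberately does not count), and
4. the candidate's residue *set* differs from the motif's. Pairwise
   distances are invariant under reflection, so chirality cannot be
   resolved and orderings of the same residues are not distinguishable
   matches; residue sets are the counting unit, and accepted orderings
   with equal sets collapse to the lowest-scoring one.

The per-protein raw index is the number of accepted duplicate scaffolds
(default), or optionally the quality-weighted sum
Σ (s_thresh − S_m)/s_thresh, in which perfect replicas count 1 and
near-threshold matches near 0. Counting is the default because it is
the less parameterized definition; the weighted variant folds match
quality into the index and is bounded above by the count. Over a
protein set, BrassIndex = raw / max(raw), so the broadest-specificity
protein in the set scores 1 and an all-zero set stays 0. The index is
relative to the analyzed set by construction.

## Parameters

| parameter   | default | units   | role |
|-------------|---------|---------|------|
| `d_max`     | 2.0 (5.0 relaxed) | Å | per-pair spatial deviation cap |
| `big_penalty` | 10⁶   | –       | score per capped pair; unreachable by genuine matches |
| `lambda_pd` | 0.01    | (kT/e)⁻¹ | weight of electrostatic deviations; typical PD deviations of tens of kT/e then weigh like Å-scale spatial ones |
| `s_thresh`  | N(N−1)/2 · 1.0 | – | acceptance threshold: a mean of 1 Å per pair |
| `pd_filter` | 150     | kT/e    | hard cap on any single PD deviation; disabled without a potential source |

The exact algebra combining distance and potential terms, the threshold,
and the count/quality mixture were genuinely open design choices; the
defaults above were fixed from the two hard constraints the method must
satisfy (self-match scores exactly 0; a > d_max pair deviation
eliminates a match) plus unit-balance reasoning, and every one of them
is exposed in `ScoreConfig` and on the CLI.

Functional atoms per residue type: SER→OG, THR→OG1, TYR→OH, HIS→NE2,
ASP→OD1, GLU→OE1, ASN→OD1, GLN→NE2, CYS→SG, LYS→NZ, ARG→NH1, TRP→NE1,
MET→SD; backbone N for GLY/ALA/VAL/LEU/ILE/PHE/PRO. The table is
user-replaceable. For the chemically symmetric carboxylate/amide
termini (Asp OD1/OD2, Glu OE1/OE2, Asn OD1/ND2, Gln NE2/OE1) an
optional flag evaluates both atoms and keeps the combination minimizing
the score; by default only the table atom is used.

Stereochemical equivalence groups for relaxed matching: BASIC
{Lys, His, Arg}, ACIDIC {Glu, Asp}, AMIDE {Asn, Gln}, NONPOLAR
{Gly, Ala, Val, Leu, Ile, Met}, AROMATIC {Phe, Trp, Tyr}; user groups
can be added from a text file.

## Electrostatics

Potentials are sampled at the functional atom's center, with no
averaging over neighbors. Three sources:

* **OpenDX grid** (the APBS output dialect), sampled by trilinear
  interpolation; sampling outside the grid box is an error, never an
  extrapolation.
* **PQR charge set** through a screened-Coulomb (Debye–Hückel) model,
  φ(x) = Σ_i q_i e^{−κ r_i} / (4π ε₀ ε_r r_i), converted to kT/e.
  Defaults ε_r = 78.5, κ = 0.09 Å⁻¹ (≈ 100 mM ionic strength at 298 K),
  T = 298 K. This is a far-field approximation — it ignores the
  low-dielectric protein interior and the dielectric boundary, so
  absolute potentials differ from a finite-difference
  Poisson–Boltzmann solution; pairwise *differences* at a congruent
  site are far less sensitive, which is what the score consumes.
  Points within 0.1 Å of a source charge are refused (singularity).
* **none**: the score and acceptance are spatial-only.

Grid-vs-solver fidelity is therefore the caller's responsibility: when
an APBS grid is supplied the method is faithful to a full FDPB
treatment; the built-in Coulomb model is a self-consistent substitute
whose screening constant and permittivity are configurable.

## Search and pruning

Enumeration is depth-first over per-position candidate pools
(position-wise residue types, or groups in relaxed mode), restricted to
the motif's chain by default (flag for all chains). A partial tuple is
pruned as soon as any already-placed pair deviates more than `d_max`:
the score is monotone in deviations and one capped pair alone exceeds
any reasonable threshold, so pruning is admissible — the test suite
proves equality of accepted sets and scores against an unpruned
all-combinations oracle on 50 random structures. Cross-protein queries
(`cross_query`) reuse the reference motif's D/PD matrices against
another structure's residues and skip rules 3–4, which are meaningless
across proteins; all chains of the query are searched unless one is
named.

## Synthetic structures

The fixture generator emulates exactly the geometry the method reasons
about: functional atoms of a motif on an active-site-scale template
(pairwise distances ≈ 3–15 Å), `n_replicas` planted duplicates obtained
by rotating the template about the shared residue's functional atom
(hence exactly congruent at zero jitter), optional per-coordinate
Gaussian jitter, and far-field decoys of matching types (≥ 25 Å out, so
any scaffold using one breaches the cap by construction). Residues
carry a backbone (N, CA, C, O) plus the functional atom at the planted
coordinate, with randomized orientation; replica rotations are
rejection-sampled and then *proved* unambiguous by exhaustive
enumeration over the finished site — no accidental mixed combination is
spatially congruent (within a 0.05 Å numerical epsilon that also covers
3-decimal PDB rounding; decoy combinations must breach the cap by
d_max + 3σ). Generation is deterministic in the seed down to the emitted
PDB/PQR/DX bytes.

What the fixtures do *not* emulate: real side-chain stereochemistry and
rotamers, packing/clash constraints, sequence context, crystallographic
artifacts (altloc disorder beyond the parser tests, missing atoms), and
realistic charge distributions. Passing the recovery and invariance
suites therefore demonstrates correctness of the search, scoring,
filtering and indexing machinery — not that biologically meaningful
duplicates exist in any particular real protein; for that, the
integration tests against published catalytic-site distances (run when
the PDB entries are present under `data/pdb/`) and a user's own APBS
runs are the relevant evidence.

## Numerical choices

* Distances in Å at full double precision internally; reports print D
  and PD to 1 decimal.
* Trilinear grid sampling is exact on nodes; out-of-box points raise.
* Alternate locations: highest occupancy wins, ties break to altloc
  'A'; first NMR model only; non-standard residues (MSE, …) and
  HETATMs are parsed and retained but excluded from search pools.
* Acceptance ordering: ascending score, ties broken lexicographically
  on (chain, residue number) sequences, making reports reproducible
  byte-for-byte.
* Acceptance-script problem sizes: 50 structures for the
  pruning-oracle comparison, 3 × 20 for planted-replica recovery, 6
  isometries for the invariance check, a 3-protein set for
  normalization — sizes at which the all-combinations oracle remains
  exact, which is the point of the comparison.

## Known limitations

* Chirality-blind: mirror-image scaffolds are indistinguishable by
  pairwise distances; this is inherent to the representation and is why
  permutations are excluded rather than scored.
* The BrassIndex is normalized within the analyzed set; values are not
  comparable across differently composed sets.
* One functional atom per residue discards side-chain orientation;
  residues whose functional atom is missing from the model (truncated
  side chains) are skipped from candidate pools with a warning and
  raise an explicit error when they are motif members.
* The built-in Coulomb model is not a Poisson–Boltzmann solution (see
  above); for publication-grade electrostatic filtering supply an APBS
  grid.
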