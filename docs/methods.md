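# Methods

This note documents the models, numerical choices and known limitations of
`clickchem`: what the geometric product assembly actually does, which
parameters matter, what the synthetic reactant generator emulates, and what
passing tests do and do not demonstrate about real molecules.

## Input contract

All reactants are explicit-hydrogen 3D small-molecule models. PDB is the
only exchange format: ATOM and HETATM records are both accepted, only the
first MODEL is read, and altLoc codes other than blank/`A` are dropped.
The element comes from columns 77–78 when present; otherwise it is
inferred from the atom-name field, where protein-style remoteness names
("CA", "NE", "OG") resolve to the one-letter element and genuine
two-letter symbols ("CL", "BR") are recognized case-insensitively. No
hydrogen addition, protonation-state assignment or tautomer handling is
performed: the detectors count explicit hydrogens, so a model missing them
will simply match nothing.

## Bond perception

PDB carries no reliable connectivity, so bonds are inferred from
single-bond covalent radii (Cordero-style values; H 0.31, C 0.76, N 0.71,
O 0.66, S 1.05, Cl 1.02, Br 1.20, I 1.39 Å): atoms are bonded when their
separation lies in `[0.4 Å, r_i + r_j + tol]` with `tol = 0.4 Å` by
default (tunable at the CLI). CONECT-derived bonds are kept (union), and
hydrogens are capped at one bond, keeping the shortest candidate. No bond
orders are stored; multiplicity is inferred contextually (an alkyne is two
bonded sp carbons of degree 2, a carbonyl is a degree-1 oxygen on carbon).
The default tolerance cleanly separates bonded (≤ ~1.97 Å for C–Br) from
non-bonded (≥ 2.5 Å) distances in idealized geometries; perception is not
expected to be robust for severely distorted experimental conformers.

Hybridization is classified from degree and local angles: a
two-coordinate carbon with an angle ≥ 155° is sp; any three-coordinate
C/N/O/S whose angle sum is ≥ 350° is sp2, as is a two-coordinate carbon
with mean angle in [115°, 128°]; everything else of degree ≤ 4 is sp3.
The thresholds are deliberately far (≥ 25°) from every idealized fixture
geometry, so classification is insensitive to small coordinate noise.

Ring perception enumerates simple cycles up to size 8 — ample for
click-relevant chemistry (three-membered epoxides through fused
six-rings) — and deliberately refuses larger macrocycles to avoid
exponential cycle search. "Is this bond in a ring" uses the cheaper
remove-edge connectivity test and therefore recognizes cycles of any size;
branch extraction (`get_branch`) is undefined for such bonds.

## Functional-group detection

Patterns are graph rules over elements, degrees and hybridization, with
three chemistry guards: a nitrogen adjacent to a carbonyl carbon is an
amide, not a reactive amine; the hydroxyl of a carboxyl group is not an
alcohol; and bonded sp2-carbon pairs inside all-sp2 six-rings are treated
as aromatic and excluded from alkene matching (so benzene is never
"epoxidized" in library mode). Kinds are matched in a fixed precedence
order (azide, alkynes, acyl halide, carboxylic acid, epoxide, alkyl
halide, amines, thiol, alcohol, alkene) and an atom claimed by an earlier
match blocks later matches — acyl halides win over alkyl halides, and no
two reported matches ever share an atom. The exclusion rules are this
package's own explicit choices.

Alkyne symmetry — which decides whether one or two cycloaddition
regioisomers exist — is element-labelled graph isomorphism of the two
substituent branches across the triple bond (VF2 via networkx; an
independent permutation-search oracle covers it in the tests). A terminal
alkyne is symmetric only when both substituents are lone hydrogens.

## Product assembly

### Huisgen cycloaddition

The idealized 1,2,3-triazole core is a planar five-ring with bond lengths
N–N 1.33 Å, N–C 1.35 Å, C–C 1.38 Å solved onto a common circumcircle
(interior angles ≈ 108°), plus exocyclic direction points 1.45 Å outward
along each ring bisector at N1, C4 and C5. These values are idealized, not
fit to a crystal structure; downstream checks require only ring planarity
and sane bonded distances.

Assembly per product: (1) fragment the azide along its proximal–medial
N–N bond (keeping the organic fragment with the proximal N as handle; the
medial/distal nitrogens are superseded by core N2/N3) and the alkyne along
its C≡C bond (each side keeps one carbon as handle); (2) place each
fragment by translating its handle exactly onto the corresponding core
atom and rotating about the handle so the handle-adjacent atom points at
the exocyclic direction point — translate-then-rotate rather than a
two-tether least-squares fit, so ring positions are exact even when the
fragment's handle–adjacent distance differs from the core's 1.45 Å
direction-point distance (the spin about the new bond axis is left free
and resolved by steric relief); (3) relieve sterics about each exocyclic
single bond in formation order (azide substituent, C4 substituent, C5
substituent); (4) delete the superseded core atoms, merge, and form the
five ring bonds. Regiochemistry: the larger alkyne branch (more heavy
atoms, then more atoms, then the lower-index branch) at ring position 4
is labelled "1,4"; swapped is "1,5". A symmetric alkyne's single product
is labelled "1,4" — it is simultaneously the 1,5 isomer, and the library
regio policies treat it as both.

### The other core reactions

* **halide → azide**: the halogen is deleted and a linear N₃ arm grafted
  along the former C–X vector with C–N 1.47 Å, N–N 1.24/1.13 Å, angles
  C–N–N 115° and N–N–N 172° (the arm's plane is fixed by the carbon's
  lowest-index remaining neighbor, making the construction deterministic).
* **primary amine → azide**: both N–H hydrogens are deleted and two
  nitrogens continue from the amine nitrogen with the same arm geometry.
* **epoxide opening**: the nucleophile (amine, thiol, or azide via its
  proximal nitrogen) attacks either ring carbon anti to the C–O bond being
  broken (C–N 1.47 Å / C–S 1.82 Å, approach angle 112°); the ring oxygen
  becomes a hydroxyl, capped with the proton the amine/thiol loses. An
  azide has no proton to give, so its products keep an alkoxide-like
  degree-1 oxygen — atom count still sums exactly. When attack at C1 and
  C2 give graph-isomorphic products (decided on the marked scaffold alone,
  independent of the nucleophile) only one is emitted.
* **amide formation**: the acid loses OH (or the acyl halide its halogen),
  the amine loses one N–H, and a planar C–N bond (1.35 Å, 120°) is formed
  with the amine substituent trans to the carbonyl oxygen.
* **alkene epoxidation**: an oxygen is inserted above the C=C midpoint at
  the height giving C–O = 1.43 Å; the carbons are not re-pyramidalized.

### Steric relief

Newly formed single bonds get a discrete dihedral scan: the moving
fragment is rotated about the bond axis in 10° steps over [0°, 360°) and
the angle maximizing the minimum cross-fragment non-bonded distance wins,
ties going to the smallest rotation (so an already-clear geometry is
returned unchanged and results are bit-reproducible). Bond atoms and
bonded cross-pairs are excluded from the criterion. 36 evaluations per
bond is cheap and, by the tests' 1°-grid comparison, within one step's
worst-case drop (`2 r_max sin 5°`) of exhaustive scanning. Ring bonds
cannot be scanned and produce a warning plus a no-op.

### Geometry sanity and clash flags

Every product is screened: bonded atoms must lie within
`[0.7 Å, max(1.9, r_i + r_j + 0.4)]` (the radius-aware upper bound keeps
heavy-halogen bonds like C–Br at 1.97 Å from false-failing), no two
non-bonded atoms may approach within 0.7 Å, and every
N-N-N-C-C five-ring must be planar to 0.1 Å. Products that fail are
*flagged*, never dropped, so library counts stay at the predictable
regio-rule arithmetic.

## Library enumeration

Pairs are processed in sorted-label order; unreadable input files are
skipped with a logged warning and a manifest note rather than aborting the
run. Dry-run counting multiplies detected matches by the regioisomer rule
and the epoxide-symmetry rule — the *same* predicates the full run uses,
with symmetry verdicts cached per match — so dry and full counts agree by
construction (and are asserted equal whenever the full run executes). The
Lipinski flag annotates each product (MW, N–H/O–H donor count, N+O
acceptor count, a coarse per-element logP estimate, pass verdict) without
suppressing any. Manifests are JSON with sorted keys; rerunning with
identical inputs and seed is byte-identical. Per-pair detail is included
for full runs and for dry runs up to 100,000 pairs; million-pair dry runs
keep aggregate counts only.

The logP estimate is a deliberately simple atom-contribution sum (C +0.36,
halogens +0.15…+1.0, N −0.90, O −0.75, carbon-bound H +0.10) meant for
screening-grade triage; it is pluggable and should be replaced by a real
predictor for anything quantitative.

## The synthetic reactant generator

`generate_reactant_set` emulates a commercial reactant pool (hundreds to
thousands of distinct azides, terminal alkynes, or alkyl bromides) with
rooted alkyl scaffolds: an all-anti zigzag chain of 1–16 carbons carrying
the reactive head at C1, with an optional methyl branch at each interior
position. Substituent sides alternate along the backbone, and branch pairs
exactly two positions apart are excluded (they would sit on the same side
2.5 Å apart — a syn-pentane-like strain a rigid builder cannot relax).
The catalog holds 3,024 pairwise non-isomorphic scaffolds; a seeded
permutation selects n of them, so sets are deterministic per seed and
distinct across seeds. Every emitted molecule carries exactly one match of
the requested kind, and generator-built terminal alkynes are always
non-symmetric.

What this emulates — and what it does not: the generated pool has the
*combinatorial* structure of a real reactant library (distinct
constitutional isomers, one reactive group each) but none of its chemical
diversity — no aromatics beyond the fixture panel, no heteroatom
decoration, single conformers, and deliberately greasy long-chain members
(a C28+ triazole honestly fails the rule-of-five logP bound). Passing the
library-scale tests therefore demonstrates the counting arithmetic,
regiochemistry, determinism and geometric robustness of the engine at
scale — not that the package handles every functional-group environment
found in vendor catalogs.

## Problem sizes used in the checks

The end-to-end checks run at the scales the method is meant for: the
46-product worked example (1 azide × 23 non-symmetric alkynes, full 3D
generation) and the 1,215 × 939 library enumeration (2,281,770 products)
in dry-run mode, with full generation spot-verified on a seeded
1,000-pair subsample. Property suites use 500 seeded cases for atom
conservation, the regioisomer rule and superposition self-recovery, 300
for the ring/distance brute-force oracles, and 50 for the relief-scan
grid comparison.

## Known limitations

* No stereochemistry: products are single 3D conformers; epoxide opening
  does no inversion bookkeeping; charged/tautomeric state enumeration is
  out of scope.
* No energies: products are idealized-template geometries relieved by a
  dihedral scan, not force-field minima; no docking or scoring.
* Regioselectivity is not modeled — both Huisgen regioisomers are emitted
  for non-symmetric alkynes (copper(I) catalysis yields only the 1,4
  isomer in practice; filter via the regio policy or the manifest).
* Ring perception stops at eight-membered rings; aromaticity is
  approximated by the all-sp2 six-ring guard, not perceived properly.
* The reaction set is the core click families; the registry is the
  extension point for the broader catalogue (sulfonyl azides, isocyanates,
  …).
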