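# clickchem — click chemistry *in silico*

`clickchem` builds 3D models of click-chemistry reaction products directly
from 3D models of their reactants. It is aimed at computational chemists
assembling virtual-screening libraries who want every candidate compound to
be *easily synthesizable*: if the library is generated only through click
reactions (high-yield, benign-byproduct couplings such as the azide–alkyne
Huisgen cycloaddition), then any virtual hit can actually be made at the
bench. The package perceives reactive functional groups automatically from
coordinates — no manual annotation of linker atoms — and produces products
in three dimensions, skipping the expensive SMILES→3D conversion step for
large libraries.

## What it does

* **Functional-group perception** from explicit-hydrogen PDB models:
  azides (R–N₃), terminal/internal alkynes, alkyl and acyl halides,
  primary/secondary amines, epoxides, carboxylic acids, thiols, alcohols
  and alkenes, each match carrying role-labelled atoms (e.g. the azide's
  proximal/medial/distal nitrogens). Bonds are inferred from covalent
  radii: atoms *i, j* are bonded when
  `d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å`.
* **Geometric product assembly.** For the Huisgen cycloaddition
  (azide + alkyne → 1,2,3-triazole) the engine fragments the alkyne along
  its C≡C bond and the azide along its proximal–medial N–N bond, keeps the
  alkyne carbons and proximal nitrogen as *handles*, superimposes each
  handle on the corresponding atom of an idealized planar triazole core,
  rotates each fragment about its handle to point the handle-adjacent atom
  along the ring's exocyclic direction, relieves steric clashes by a
  discrete dihedral scan, deletes the superseded core atoms and merges.
  Non-symmetric alkynes yield both regioisomers (1,4- and 1,5-); symmetric
  alkynes yield one. The same grammar implements halide→azide and
  amine→azide conversion, epoxide ring opening (amine/thiol/azide
  nucleophiles), amide condensation and alkene epoxidation, behind a
  registry that admits further reactions without engine changes.
* **Combinatorial library generation** over directories of reactant PDBs,
  with an exact dry-run counting mode, per-product rule-of-five
  (Lipinski) annotation (MW ≤ 500, H-bond donors ≤ 5, acceptors ≤ 10,
  logP ≤ 5), deterministic manifests, and a fixture generator that emits
  arbitrarily many structurally distinct azides/alkynes/bromides so every
  test runs download-free.
* A **rigid-body toolbox** underneath: translation, rotation about
  lines/bonds/pivots, tether-based least-squares (Kabsch) superposition,
  molecule merging and minimum intermolecular distance.

## Worked example

```python
import clickchem as cc

azide = cc.build_fixture("methyl_azide")    # CH3N3, idealized 3D
alkyne = cc.build_fixture("propyne")        # CH3-C≡CH
(azm,) = cc.detect_groups(azide)
(alkm,) = cc.detect_groups(alkyne)
for rec in cc.huisgen_cycloaddition(azide, azm, alkyne, alkm):
    print(rec.regio, cc.hill_formula(rec.molecule), len(rec.molecule),
          f"{rec.sanity.max_triazole_deviation:.4f}")
```

prints

```
1,4 C4H7N3 14 0.0000
1,5 C4H7N3 14 0.0000
```

— two regioisomeric triazoles (propyne is non-symmetric), each conserving
every reactant atom (CH₃N₃ + C₃H₄ = C₄H₇N₃, 14 atoms) with the
five-membered ring planar to numerical precision. The same operations are
available from a thin CLI (`clickchem detect|react|library|fixtures`); see
`examples/` for narrative scripts covering detection, cycloaddition,
library enumeration and azide preparation.

A library-scale run is one call:

```python
from clickchem.library import LibraryRunConfig, enumerate_library
manifest = enumerate_library(LibraryRunConfig(
    dir_a="azides/", dir_b="alkynes/", dry_run=True))
print(manifest["total_products"])   # 2 × n_azides × n_alkynes for
                                    # non-symmetric alkynes
```

## Layout

```
src/clickchem/
  structure.py    Atom/Molecule model, fixed-column PDB I/O, formulas
  geometry.py     rigid-body ops, tether (Kabsch) superposition
  perception.py   bond inference, hybridization, rings, branches
  groups.py       functional-group detection with role labels
  templates.py    idealized product cores (triazole, azide arm)
  reactions.py    the reaction engine, steric relief, sanity checks
  library.py      combinatorial enumeration, Lipinski annotation
  fixtures.py     programmatic 3D reactant builders
  cli.py          thin command-line interface
```
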