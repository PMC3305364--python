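"""Enumerate a small combinatorial triazole library.

Generates 5 azides and 5 non-symmetric terminal alkynes, writes them as
PDB files, then runs the library engine twice: a dry-run that counts
products from the detected groups alone, and a full run that builds every
3D product model. The counts agree by construction: 5 x 5 pairs x 2
regioisomers = 50 products.
"""

import tempfile
from pathlib import Path

import clickchem as cc
from clickchem.library import LibraryRunConfig, enumerate_library

with tempfile.TemporaryDirectory() as tmp:
    dir_a = Path(tmp) / "azides"
    dir_b = Path(tmp) / "alkynes"
    out = Path(tmp) / "products"
    dir_a.mkdir(), dir_b.mkdir()
    for mol in cc.generate_reactant_set("azide", 5, seed=7):
        cc.save_pdb(mol, dir_a / f"{mol.label}.pdb")
    for mol in cc.generate_reactant_set("terminal_alkyne", 5, seed=8):
        cc.save_pdb(mol, dir_b / f"{mol.label}.pdb")

    dry = enumerate_library(
        LibraryRunConfig(dir_a=dir_a, dir_b=dir_b, dry_run=True)
    )
    full = enumerate_library(
        LibraryRunConfig(dir_a=dir_a, dir_b=dir_b, out_dir=out, lipinski=True)
    )
    n_files = len(list(out.glob("*.pdb")))
    print(f"dry-run count : {dry['total_products']}")
    print(f"full-run count: {full['total_products']}  (files written: {n_files})")
    print(f"rule-of-five passes: {full['lipinski_pass_count']}/{full['total_products']}")

# The dry run never touches geometry - it multiplies detected azide and
# alkyne matches and the regioisomer rule - which is what makes
# million-product enumerations cheap to size before building them.
#
# Few (often zero) of these particular products pass the rule of five:
# the synthetic reactants are long unsubstituted alkyl chains, so the
# estimated logP of a C28+ triazole far exceeds 5 - a faithful verdict on
# greasy molecules, not a bug in the filter.
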