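"""Build 1,2,3-triazole products of an azide-alkyne Huisgen cycloaddition.

Reacts methyl azide with propyne. Because propyne is a non-symmetric
alkyne, both regioisomers are built: "1,4" places the methyl substituent
para-like to the azide substituent across the ring, "1,5" adjacent. Each
product is a full 3D model assembled on an idealized planar triazole core
and relaxed by a dihedral steric scan.
"""

from pathlib import Path

import clickchem as cc

azide = cc.build_fixture("methyl_azide")
alkyne = cc.build_fixture("propyne")
(azide_match,) = cc.detect_groups(azide)
(alkyne_match,) = cc.detect_groups(alkyne)

records = cc.huisgen_cycloaddition(azide, azide_match, alkyne, alkyne_match)
out = Path("scratch")
out.mkdir(exist_ok=True)
for rec in records:
    path = out / f"triazole_{rec.regio.replace(',', '-')}.pdb"
    cc.save_pdb(rec.molecule, path)
    print(
        f"regio {rec.regio}: {cc.hill_formula(rec.molecule)}, "
        f"{len(rec.molecule)} atoms, ring planarity deviation "
        f"{rec.sanity.max_triazole_deviation:.4f} Å -> {path}"
    )

# Atom bookkeeping: the cycloaddition conserves every reactant atom, so
# CH3N3 + C3H4 gives C4H7N3 in both isomers.
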