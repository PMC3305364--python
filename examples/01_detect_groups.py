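"""Detect click-reactive functional groups in a small molecule.

Builds benzyl azide (an explicit-hydrogen 3D model), perceives bonds from
interatomic distances, and prints every reactive group with its
role-labelled atoms. The roles (proximal/medial/distal nitrogen, attachment
carbon) are exactly the atoms the reaction engine later fragments along.
"""

import clickchem as cc

mol = cc.build_fixture("benzyl_azide")
print(f"{mol.label}: {cc.hill_formula(mol)}, {len(mol)} atoms, {len(mol.bonds)} bonds")

for match in cc.detect_groups(mol):
    print(f"\n{match.kind}:")
    for role, idx in sorted(match.roles.items()):
        atom = mol.atoms[idx]
        print(f"  {role:12s} atom {idx:2d} ({atom.element})")

# The medial nitrogen is bonded to two nitrogens and nothing else; the
# distal nitrogen is terminal - the structural signature of an azide.
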