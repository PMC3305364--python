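"""Convert halides and amines into azides (library preprocessing).

Click libraries are usually built from commercial bromides: the first
in-silico step replaces each C-Br with a linear N3 unit using idealized
azide geometry (C-N 1.47 Å, N-N 1.24/1.13 Å, C-N-N 115°, N-N-N 172°).
Primary amines convert the same way, losing both N-H hydrogens.
"""

import numpy as np

import clickchem as cc

for name, convert in (
    ("benzyl_bromide", cc.halide_to_azide),
    ("methylamine", cc.amine_to_azide),
):
    mol = cc.build_fixture(name)
    (match,) = cc.detect_groups(mol)
    rec = convert(mol, match)
    (azide,) = cc.detect_groups(rec.molecule)
    r = azide.roles
    p = rec.molecule
    u = p.atoms[r["proximal_N"]].coord - p.atoms[r["medial_N"]].coord
    v = p.atoms[r["distal_N"]].coord - p.atoms[r["medial_N"]].coord
    angle = np.degrees(np.arccos(u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
    print(
        f"{name:15s} {cc.hill_formula(mol):8s} -> {cc.hill_formula(rec.molecule):8s} "
        f"(N-N-N angle {angle:.1f}°, sane={rec.sanity.ok})"
    )

# Both products are detected as clean azides, ready for cycloaddition.
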