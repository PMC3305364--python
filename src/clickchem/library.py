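"""Combinatorial enumeration over reactant directories.

A library run crosses every molecule of directory A against every molecule
of directory B (or runs unimolecular transformations over A alone),
counting or building every registry product. Dry-run mode computes exact
product counts — including regioisomer multiplicity and symmetric-epoxide
deduplication — from the detected groups without constructing any 3D
geometry, and is guaranteed to agree with full generation because both
modes share the same counting predicates.

Pair order is deterministic (sorted labels), manifests are JSON, and rerun
with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .groups import FGMatch, detect_groups, is_symmetric_alkyne
from .perception import infer_bonds
from .reactions import (
    DEFAULT_STEP_DEG,
    REGISTRY,
    ProductRecord,
    epoxide_is_symmetric,
    run_reaction,
)
from .structure import Molecule, load_pdb, molecular_weight, save_pdb

log = logging.getLogger("clickchem.library")

REGIO_POLICIES = ("both", "1,4", "1,5")

# per-pair manifest detail is kept only below this pair count (or in full
# runs); million-pair dry runs keep aggregate counts only
PAIR_DETAIL_LIMIT = 100_000


@dataclass
class LibraryRunConfig:
    """Configuration of one combinatorial run.

    ``dir_b=None`` runs unimolecular reactions over ``dir_a`` alone
    (mirroring, e.g., a bromides-to-azides preprocessing pass).
    ``max_products`` caps enumeration in both modes so dry-run and full
    counts stay comparable; ``lipinski`` annotates products with a
    rule-of-five report without suppressing any.
    """

    dir_a: Path
    dir_b: Path | None = None
    out_dir: Path | None = None
    reactions: tuple[str, ...] | None = None  # None = whole registry
    regio: str = "both"
    dry_run: bool = False
    max_products: int | None = None
    seed: int = 0
    lipinski: bool = False
    step_deg: float = DEFAULT_STEP_DEG

    def __post_init__(self) -> None:
        self.dir_a = Path(self.dir_a)
        self.dir_b = Path(self.dir_b) if self.dir_b is not None else None
        self.out_dir = Path(self.out_dir) if self.out_dir is not None else None
        if self.regio not in REGIO_POLICIES:
            raise ValueError(f"regio policy must be one of {REGIO_POLICIES}")
        if self.max_products is not None and self.max_products < 0:
            raise ValueError("max_products must be >= 0")
        known = {rule.name for rule in REGISTRY}
        if self.reactions is not None:
            unknown = set(self.reactions) - known
            if unknown:
                raise ValueError(f"unknown reactions: {sorted(unknown)}")


@dataclass
class _Reactant:
    label: str
    molecule: Molecule
    groups: list[FGMatch] = field(default_factory=list)


def _load_directory(directory: Path, skipped: list[dict]) -> list[_Reactant]:
    reactants = []
    for path in sorted(directory.glob("*.pdb")):
        try:
            mol = infer_bonds(load_pdb(path))
        except Exception as exc:  # noqa: BLE001 - never abort a library run
            log.warning("skipping unreadable file %s: %s", path.name, exc)
            skipped.append({"file": path.name, "reason": str(exc)})
            continue
        reactants.append(_Reactant(mol.label, mol, detect_groups(mol)))
    return reactants


def _regio_multiplicity(policy: str, symmetric: bool) -> int:
    """Products per azide×alkyne pairing under a regio policy. A symmetric
    alkyne's single product is simultaneously the 1,4 and 1,5 isomer, so
    every policy keeps it."""
    if symmetric:
        return 1
    return 2 if policy == "both" else 1


def _count_products(
    name: str,
    primary: FGMatch,
    secondary: FGMatch | None,
    policy: str,
    sym_cache: dict[int, bool],
) -> int:
    """Exact product count without building geometry; must match what
    run_reaction() returns. Symmetry verdicts (graph isomorphism) are
    cached per match so million-pair dry runs stay cheap."""
    if name == "huisgen_cycloaddition":
        assert secondary is not None
        key = id(secondary)
        if key not in sym_cache:
            sym_cache[key] = is_symmetric_alkyne(secondary.molecule, secondary)
        return _regio_multiplicity(policy, sym_cache[key])
    if name == "epoxide_opening":
        key = id(primary)
        if key not in sym_cache:
            sym_cache[key] = epoxide_is_symmetric(primary.molecule, primary)
        return 1 if sym_cache[key] else 2
    return 1


def _apply_regio_policy(records: list[ProductRecord], policy: str) -> list[ProductRecord]:
    if policy == "both":
        return records
    out = []
    for rec in records:
        if rec.reaction != "huisgen_cycloaddition" or rec.regio == policy:
            out.append(rec)
        elif len(records) == 1 and rec.regio == "1,4":
            out.append(rec)  # symmetric alkyne: the lone product is both isomers
    return out


def lipinski_report(mol: Molecule) -> dict:
    """Rule-of-five profile: MW, H-bond donors/acceptors, and a coarse
    atom-contribution logP estimate.

    Donors are O–H and N–H hydrogens; acceptors are all N and O atoms
    (the original counting rules). The logP estimate sums per-element
    contributions (hydrophobic C/halogens positive, N/O negative) and is
    a screening-grade estimate only — swap in a real predictor for
    anything quantitative.
    """
    if len(mol) > 1 and not mol.bonds:
        raise ValueError("lipinski_report needs perceived bonds; run infer_bonds()")
    hbd = 0
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            if any(mol.atoms[j].element in ("N", "O") for j in mol.neighbors(i)):
                hbd += 1
    hba = sum(1 for a in mol.atoms if a.element in ("N", "O"))
    contributions = {
        "C": 0.36, "S": 0.25, "Cl": 0.65, "Br": 0.85, "I": 1.0, "F": 0.15,
        "N": -0.90, "O": -0.75, "P": -0.5,
    }
    logp = 0.0
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            if all(mol.atoms[j].element == "C" for j in mol.neighbors(i)):
                logp += 0.10
        else:
            logp += contributions.get(atom.element, 0.0)
    mw = molecular_weight(mol)
    passes = mw <= 500.0 and hbd <= 5 and hba <= 10 and logp <= 5.0
    return {
        "MW": round(mw, 3),
        "HBD": hbd,
        "HBA": hba,
        "logP_estimate": round(logp, 2),
        "passes": passes,
    }


def _product_filename(rec: ProductRecord) -> str:
    a, b = rec.parents
    regio = rec.regio.replace(",", "-")
    parts = [a, b if b is not None else "none", rec.reaction, regio]
    return "__".join(parts) + ".pdb"


def enumerate_library(config: LibraryRunConfig) -> dict:
    """Run (or dry-run) a combinatorial library; returns the manifest.

    The manifest holds per-reaction counts, the total, skip notes and —
    for full runs or small dry runs — per-pair detail. Full runs write
    every product PDB into ``config.out_dir`` plus ``manifest.json``.
    """
    wanted = set(config.reactions) if config.reactions is not None else None
    skipped: list[dict] = []
    pool_a = _load_directory(config.dir_a, skipped)
    pool_b = _load_directory(config.dir_b, skipped) if config.dir_b is not None else None

    writing = not config.dry_run
    if writing and config.out_dir is None:
        raise ValueError("full runs need an output directory")
    if writing:
        config.out_dir.mkdir(parents=True, exist_ok=True)

    per_reaction: dict[str, int] = {}
    pair_detail: dict[str, int] = {}
    products_meta: list[dict] = []
    sym_cache: dict[int, bool] = {}
    total = 0
    capped = False
    n_pairs = 0
    expected_pairs = (
        len(pool_a) if pool_b is None else len(pool_a) * len(pool_b)
    )
    keep_pair_detail = writing or expected_pairs <= PAIR_DETAIL_LIMIT

    def handle(name: str, primary: FGMatch, secondary: FGMatch | None, pair_key: str) -> bool:
        """Process one applicable reaction; returns False once capped."""
        nonlocal total, capped
        count = _count_products(name, primary, secondary, config.regio, sym_cache)
        if config.max_products is not None and total + count > config.max_products:
            capped = True
            return False
        if writing:
            records = _apply_regio_policy(
                run_reaction(name, primary, secondary, config.step_deg), config.regio
            )
            assert len(records) == count, (name, pair_key, len(records), count)
            for rec in records:
                filename = _product_filename(rec)
                save_pdb(rec.molecule, config.out_dir / filename)
                entry = {
                    "file": filename,
                    "reaction": name,
                    "parents": list(rec.parents),
                    "regio": rec.regio,
                    "clash_flagged": rec.clash_flagged,
                }
                if config.lipinski:
                    entry["lipinski"] = lipinski_report(rec.molecule)
                products_meta.append(entry)
        total += count
        per_reaction[name] = per_reaction.get(name, 0) + count
        if keep_pair_detail:
            pair_detail[pair_key] = pair_detail.get(pair_key, 0) + count
        return True

    def iter_rules(groups_p, groups_s, rule):
        for mp in groups_p:
            if mp.kind not in rule.kinds_primary:
                continue
            for ms in groups_s:
                if ms.kind in rule.kinds_secondary:
                    yield mp, ms

    if pool_b is None:
        for reactant in pool_a:
            n_pairs += 1
            for rule in REGISTRY:
                if rule.arity != 1 or (wanted is not None and rule.name not in wanted):
                    continue
                for m in reactant.groups:
                    if m.kind in rule.kinds_primary and not handle(
                        rule.name, m, None, reactant.label
                    ):
                        break
    else:
        for ra in pool_a:
            for rb in pool_b:
                n_pairs += 1
                pair_key = f"{ra.label}|{rb.label}"
                for rule in REGISTRY:
                    if rule.arity != 2 or (wanted is not None and rule.name not in wanted):
                        continue
                    for gp, gs in ((ra.groups, rb.groups), (rb.groups, ra.groups)):
                        for mp, ms in iter_rules(gp, gs, rule):
                            if not handle(rule.name, mp, ms, pair_key):
                                break

    manifest = {
        "config": {
            "dir_a": str(config.dir_a),
            "dir_b": str(config.dir_b) if config.dir_b is not None else None,
            "out_dir": str(config.out_dir) if config.out_dir is not None else None,
            "reactions": sorted(wanted) if wanted is not None else "all",
            "regio": config.regio,
            "dry_run": config.dry_run,
            "max_products": config.max_products,
            "lipinski": config.lipinski,
            "seed": config.seed,
        },
        "n_inputs_a": len(pool_a),
        "n_inputs_b": len(pool_b) if pool_b is not None else None,
        "n_pairs": n_pairs,
        "skipped": skipped,
        "per_reaction": dict(sorted(per_reaction.items())),
        "total_products": total,
        "capped": capped,
    }
    if keep_pair_detail:
        manifest["per_pair"] = dict(sorted(pair_detail.items()))
    if writing:
        manifest["products"] = products_meta
        if config.lipinski:
            manifest["lipinski_pass_count"] = sum(
                1 for p in products_meta if p.get("lipinski", {}).get("passes")
            )
        (config.out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest


def write_summary_tsv(manifest: dict, stream=None) -> None:
    """Per-reaction count table as TSV."""
    stream = stream or sys.stdout
    stream.write("reaction\tproducts\n")
    for name, count in manifest["per_reaction"].items():
        stream.write(f"{name}\t{count}\n")
    stream.write(f"total\t{manifest['total_products']}\n")
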