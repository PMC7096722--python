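"""Fragment surgery: copy / replace / merge, ligand merging, align-and-mutate.

These are the molecule-editing operations used while fitting domains: copy a
fragment out of the master model, operate on it independently, put it back,
or graft whole molecules and ligands together.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from . import chemdata
from .model import AtomSelection, Atom, Residue, Structure, ensure_selection

__all__ = [
    "select_fragment",
    "replace_fragment",
    "merge_molecules",
    "merge_ligand",
    "MutationPlan",
    "read_fasta_alignment",
    "align_and_mutate",
    "apply_mutation_plan",
    "EmptySelectionWarning",
]


class EmptySelectionWarning(UserWarning):
    pass


def select_fragment(s: Structure, sel) -> Structure:
    """Deep-copy the residues matching an atom selection into a new Structure."""
    sel = ensure_selection(sel)
    frag = Structure(title=s.title)
    for cid, residues in s.chains:
        picked = [r.copy() for r in residues if sel.matches_residue(r)]
        if sel.atom_names is not None:
            for r in picked:
                r.atoms = [a for a in r.atoms if a.name in sel.atom_names]
            picked = [r for r in picked if r.atoms]
        if picked:
            frag.chains.append((cid, picked))
    if frag.n_residues() == 0:
        warnings.warn(f"selection {sel.format()!r} matches nothing",
                      EmptySelectionWarning, stacklevel=2)
    return frag


def replace_fragment(master: Structure, frag: Structure) -> Structure:
    """Overwrite positions (and B, occ) of master atoms with fragment values.

    Every fragment residue must already exist in the master; nothing is
    added or removed.
    """
    out = master.copy()
    missing = []
    for fr in frag.residues():
        target = out.residue(fr.chain_id, fr.seqnum, fr.inscode)
        if target is None:
            missing.append(f"{fr.chain_id}/{fr.seqnum}{fr.inscode}")
            continue
        for fa in fr.atoms:
            ta = target.atom(fa.name, fa.altloc)
            if ta is not None:
                ta.pos = fa.pos.copy()
                ta.b = fa.b
                ta.occ = fa.occ
    if missing:
        raise ValueError(
            "fragment residues absent from master: " + ", ".join(missing))
    return out


_CHAIN_ID_POOL = list(string.ascii_uppercase + string.ascii_lowercase + string.digits)


def _fresh_chain_id(used: set[str]) -> str:
    for cid in _CHAIN_ID_POOL:
        if cid not in used:
            return cid
    for a in _CHAIN_ID_POOL:
        for b in _CHAIN_ID_POOL:
            if a + b not in used:
                return a + b
    raise RuntimeError("chain id namespace exhausted")


def merge_molecules(master: Structure, addition: Structure) -> Structure:
    """Add all residues of ``addition``; colliding chain ids get fresh ids."""
    out = master.copy()
    used = set(out.chain_ids())
    for cid, residues in addition.chains:
        new_id = cid
        if cid in used:
            new_id = _fresh_chain_id(used)
        used.add(new_id)
        copied = []
        for r in residues:
            rc = r.copy()
            rc.chain_id = new_id
            copied.append(rc)
        out.chains.append((new_id, copied))
    out.links.extend(addition.links)
    return out


def merge_ligand(master: Structure, ligand: Residue, gap: int = 1) -> Structure:
    """Merge a ligand residue into the nearest chain of the master.

    The receiving chain is the one with the smallest atom-atom distance to
    the ligand (ties broken by lexicographic chain id); the ligand is given
    seqnum = max seqnum of that chain + ``gap``.
    """
    if master.n_atoms() == 0:
        raise ValueError("cannot merge a ligand into an empty structure")
    if not ligand.atoms:
        raise ValueError("ligand residue has no atoms")
    lig_xyz = np.array([a.pos for a in ligand.atoms])
    best = None
    for cid in sorted(master.chain_ids()):
        xyz = np.array([a.pos for r in master.chain(cid) for a in r.atoms])
        d = np.sqrt(
            ((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if best is None or d < best[0] - 1e-12:
            best = (d, cid)
    _d, chain_id = best
    out = master.copy()
    new = ligand.copy()
    new.chain_id = chain_id
    new.seqnum = max(r.seqnum for r in out.chain(chain_id)) + gap
    new.inscode = ""
    out.add_residue(new)
    return out


# ---------------------------------------------------------------------------
# Align and mutate

@dataclass
class MutationPlan:
    """Differences between a model chain and a target sequence.

    Substitutions and deletions are applied by :func:`apply_mutation_plan`;
    insertions are recorded for the user but not built (no de novo building).
    """

    chain_id: str
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    deletions: list[int] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.mutations or self.deletions or self.insertions)


def read_fasta_alignment(path) -> tuple[str, str]:
    """Read a two-sequence gapped FASTA alignment (model first, target second)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"expected exactly 2 aligned sequences, found {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    return a, b


def align_and_mutate(s: Structure, chain_id: str,
                     alignment: tuple[str, str]) -> MutationPlan:
    """Derive a MutationPlan from a gapped (model, target) alignment pair."""
    model_aln, target_aln = (seq.upper() for seq in alignment)
    if len(model_aln) != len(target_aln):
        raise ValueError("aligned sequences differ in length")
    model_seq = model_aln.replace("-", "")
    chain_seq = s.sequence(chain_id)
    if model_seq != chain_seq:
        for i, (a, b) in enumerate(zip(model_seq, chain_seq)):
            if a != b:
                raise ValueError(
                    f"alignment/model mismatch at chain position {i + 1}: "
                    f"alignment has {a!r}, model has {b!r}")
        raise ValueError(
            f"alignment/model length mismatch: alignment {len(model_seq)} vs "
            f"model {len(chain_seq)} residues")
    residues = s.chain(chain_id)
    plan = MutationPlan(chain_id)
    model_idx = 0  # index into chain residues
    for col, (m, t) in enumerate(zip(model_aln, target_aln)):
        if m == "-" and t == "-":
            continue
        if m == "-":
            anchor = residues[model_idx - 1].seqnum if model_idx > 0 else 0
            plan.insertions.append((anchor, chemdata.ONE_TO_THREE.get(t, "UNK")))
            continue
        res = residues[model_idx]
        if t == "-":
            plan.deletions.append(res.seqnum)
        elif t != m:
            plan.mutations.append(
                (res.seqnum, res.res_type, chemdata.ONE_TO_THREE.get(t, "UNK")))
        model_idx += 1
    return plan


def apply_mutation_plan(s: Structure, plan: MutationPlan,
                        rotamer_library=None) -> Structure:
    """Apply substitutions and deletions of a plan; insertions are skipped.

    Substituted residues keep their backbone; the side chain is rebuilt at
    the most probable rotamer of the new type.  Numbering is left untouched.
    """
    from .backrub import RotamerLibrary  # local import to avoid a cycle

    lib = rotamer_library or RotamerLibrary.load_default()
    out = s.copy()
    residues = out.chain(plan.chain_id)
    for seqnum, from_type, to_type in plan.mutations:
        res = out.residue(plan.chain_id, seqnum)
        if res is None or res.res_type != from_type:
            raise ValueError(
                f"plan expects {from_type} at {plan.chain_id}/{seqnum}, "
                f"model disagrees")
        _mutate_residue(res, to_type, lib)
    delset = set(plan.deletions)
    residues[:] = [r for r in residues if r.seqnum not in delset]
    return out


def _mutate_residue(res: Residue, to_type: str, lib) -> None:
    backbone = {n: res.pos(n) for n in ("N", "CA", "C")}
    kept = [a for a in res.atoms if a.name in chemdata.BACKBONE_ATOMS]
    res.res_type = to_type
    res.atoms = kept
    if to_type == "GLY":
        return
    chis = None
    rots = lib.rotamers(to_type)
    if rots:
        chis = rots[0].chis
    placed = chemdata.build_sidechain(backbone, to_type, chis)
    elements = chemdata.residue_elements(to_type)
    b_mean = float(np.mean([a.b for a in kept])) if kept else 20.0
    for name, pos in placed.items():
        res.atoms.append(Atom(name, elements[name], pos, 1.0, b_mean))
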