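"""Interface contact detection: hydrogen bonds, salt bridges, hydrophobics.

Crystal structures at ~2 A resolution carry no hydrogens, so the hydrogen-
bond criterion is geometric on heavy atoms: donor/acceptor N or O pairs
across the two groups within a distance cutoff, plus an antecedent angle
(covalently bonded neighbour - donor - acceptor) of at least 90 degrees to
exclude head-on clashes.  Charge-charge contacts pair basic nitrogens
(Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) with acidic/phosphate oxygens
(Asp OD*, Glu OE*, phosphate O1P/O2P/O3P/OP1-3); hydrophobic contacts are
carbon-carbon pairs within their own cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import Atom, BACKBONE_ATOMS, StructureModel

__all__ = [
    "HBond",
    "Contact",
    "detect_hbonds",
    "detect_contacts",
    "pocket_residues",
    "contact_number_profile",
    "interface_report",
]

POSITIVE_ATOMS = frozenset({"NZ", "NH1", "NH2", "NE", "ND1", "NE2"})
NEGATIVE_ATOMS = frozenset(
    {"OD1", "OD2", "OE1", "OE2", "O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}
)
COVALENT_MAX_A = 1.9  # heavy-atom bond length ceiling for antecedent lookup


def _atom_label(a: Atom) -> str:
    return f"{a.chain}/{a.resn}{a.resi}{a.icode}/{a.name}"


@dataclass(frozen=True)
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    category: str  # backbone_backbone | backbone_sidechain | sidechain_sidechain

    def __str__(self) -> str:
        return (
            f"{_atom_label(self.donor)} ... {_atom_label(self.acceptor)} "
            f"{self.distance:.2f} A ({self.category})"
        )


@dataclass(frozen=True)
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float
    type: str  # hydrophobic | charge_charge

    def __str__(self) -> str:
        return (
            f"{_atom_label(self.atom_a)} -- {_atom_label(self.atom_b)} "
            f"{self.distance:.2f} A ({self.type})"
        )


def _disjoint_groups(model: StructureModel, groupA, groupB):
    ia = model.select(groupA)
    ib = model.select(groupB)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection")
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("selections must be disjoint")
    return ia, ib


def _antecedent(model: StructureModel, index: int) -> Atom | None:
    """Nearest covalently plausible heavy-atom neighbour in the same residue."""
    atom = model.atoms[index]
    best, best_d = None, COVALENT_MAX_A
    pos = atom.pos
    for other in model.atoms:
        if other is atom or other.residue_key != atom.residue_key:
            continue
        d = float(np.linalg.norm(other.pos - pos))
        if d < best_d:
            best, best_d = other, d
    return best


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hb_category(a: Atom, b: Atom) -> str:
    a_bb = a.name.upper() in BACKBONE_ATOMS
    b_bb = b.name.upper() in BACKBONE_ATOMS
    if a_bb and b_bb:
        return "backbone_backbone"
    if a_bb or b_bb:
        return "backbone_sidechain"
    return "sidechain_sidechain"


def detect_hbonds(
    model: StructureModel,
    groupA,
    groupB,
    d_max: float = 3.5,
    min_angle_deg: float = 90.0,
) -> list[HBond]:
    """Hydrogen bonds between two disjoint atom groups.

    Candidate pairs are N/O heavy atoms across the groups within ``d_max``
    and in different residues; a pair qualifies if either atom, taken as the
    donor, satisfies the antecedent-angle criterion.  When exactly one atom
    is a nitrogen it is reported as the donor (backbone amide convention).
    Output is symmetric in the group arguments and deterministically
    ordered.
    """
    if d_max < 0:
        raise ValueError("cutoff must be nonnegative")
    ia, ib = _disjoint_groups(model, groupA, groupB)
    cand_a = [i for i in ia if model.atoms[int(i)].element in ("N", "O")]
    cand_b = [i for i in ib if model.atoms[int(i)].element in ("N", "O")]
    if not cand_a or not cand_b or d_max == 0:
        return []
    pa = model.coords[cand_a]
    pb = model.coords[cand_b]
    dmat = cdist(pa, pb)
    bonds = []
    for (ii, jj) in zip(*np.nonzero(dmat <= d_max)):
        i, j = int(cand_a[ii]), int(cand_b[jj])
        a, b = model.atoms[i], model.atoms[j]
        if a.residue_key == b.residue_key:
            continue
        d = float(dmat[ii, jj])

        def donor_ok(di: int, acc: Atom) -> bool:
            ante = _antecedent(model, di)
            if ante is None:
                return True  # cannot evaluate geometry; distance rules
            return _angle_deg(ante.pos, model.atoms[di].pos, acc.pos) >= min_angle_deg

        ok_a = donor_ok(i, b)
        ok_b = donor_ok(j, a)
        if not (ok_a or ok_b):
            continue
        # assign the donor: prefer the lone nitrogen, then a passing atom
        if (a.element == "N") != (b.element == "N"):
            donor, acceptor = (a, b) if a.element == "N" else (b, a)
        elif ok_a:
            donor, acceptor = a, b
        else:
            donor, acceptor = b, a
        bonds.append(HBond(donor, acceptor, d, _hb_category(a, b)))
    bonds.sort(key=lambda h: (min(h.donor.resi, h.acceptor.resi),
                              h.distance, _atom_label(h.donor)))
    return bonds


def detect_contacts(
    model: StructureModel,
    groupA,
    groupB,
    hydrophobic_cutoff: float = 4.5,
    charge_cutoff: float = 4.0,
) -> list[Contact]:
    """Hydrophobic (C-C) and charge-charge contacts between two groups."""
    if hydrophobic_cutoff < 0 or charge_cutoff < 0:
        raise ValueError("cutoffs must be nonnegative")
    ia, ib = _disjoint_groups(model, groupA, groupB)
    pa, pb = model.coords[ia], model.coords[ib]
    dmat = cdist(pa, pb)
    contacts = []
    max_cut = max(hydrophobic_cutoff, charge_cutoff)
    for (ii, jj) in zip(*np.nonzero(dmat <= max_cut)):
        a = model.atoms[int(ia[ii])]
        b = model.atoms[int(ib[jj])]
        d = float(dmat[ii, jj])
        if a.element == "C" and b.element == "C" and d <= hydrophobic_cutoff:
            contacts.append(Contact(a, b, d, "hydrophobic"))
        else:
            na, nb = a.name.upper(), b.name.upper()
            pos_neg = (na in POSITIVE_ATOMS and nb in NEGATIVE_ATOMS) or (
                na in NEGATIVE_ATOMS and nb in POSITIVE_ATOMS
            )
            if pos_neg and d <= charge_cutoff:
                contacts.append(Contact(a, b, d, "charge_charge"))
    contacts.sort(key=lambda c: (c.type, c.distance, _atom_label(c.atom_a)))
    return contacts


def pocket_residues(
    model: StructureModel,
    ligand_selection,
    cutoff: float = 4.5,
    receptor_selection=None,
) -> list[dict]:
    """Receptor residues with any atom within ``cutoff`` of the ligand atoms.

    Returns one record per residue (chain, resi, resn, min_distance_A),
    sorted by residue number.
    """
    il = model.select(ligand_selection)
    if il.size == 0:
        raise ValueError("empty ligand selection")
    if receptor_selection is None:
        lig = set(il.tolist())
        ir = np.array([i for i in range(len(model)) if i not in lig], dtype=int)
    else:
        ir = model.select(receptor_selection)
    if ir.size == 0:
        return []
    dmat = cdist(model.coords[ir], model.coords[il])
    mind = dmat.min(axis=1)
    per_res: dict[tuple, dict] = {}
    for k, i in enumerate(ir):
        at = model.atoms[int(i)]
        if mind[k] > cutoff:
            continue
        rec = per_res.get(at.residue_key)
        if rec is None or mind[k] < rec["min_distance_A"]:
            per_res[at.residue_key] = {
                "chain": at.chain,
                "resi": at.resi,
                "resn": at.resn,
                "min_distance_A": float(mind[k]),
            }
    return sorted(per_res.values(), key=lambda r: (r["chain"], r["resi"]))


def contact_number_profile(
    frames,
    groupA,
    groupB,
    cutoff: float = 4.5,
    d_com: list[float] | None = None,
) -> pd.DataFrame:
    """Inter-group heavy-atom contact count per frame, ordered by D_com.

    ``frames`` is a sequence of :class:`StructureModel`; the reaction
    coordinate is taken from ``d_com`` or from each frame's metadata key
    ``d_com_A``.  The diagnostic behind the observation that contacts decay
    to zero as the centre-of-mass separation grows.
    """
    frames = list(frames)
    if d_com is None:
        try:
            d_com = [f.metadata["d_com_A"] for f in frames]
        except KeyError as exc:
            raise ValueError("frame missing d_com_A metadata") from exc
    if len(d_com) != len(frames):
        raise ValueError("d_com length must match frame count")
    rows = []
    for frame, d in zip(frames, d_com):
        ia, ib = _disjoint_groups(frame, groupA, groupB)
        dmat = cdist(frame.coords[ia], frame.coords[ib])
        rows.append({"d_com_A": float(d), "contact_count": int((dmat <= cutoff).sum())})
    return pd.DataFrame(sorted(rows, key=lambda r: r["d_com_A"]))


def interface_report(
    model: StructureModel,
    domain_selection,
    peptide_selection,
    hbond_cutoff: float = 3.5,
    hydrophobic_cutoff: float = 4.5,
    charge_cutoff: float = 4.0,
    pocket_cutoff: float = 4.5,
) -> str:
    """Plain-text interface summary per peptide residue.

    Merged, deduplicated listing of hydrogen bonds (with distances),
    charge pairs, and hydrophobic pocket residues, deterministically
    ordered by peptide residue number then distance.
    """
    pep_idx = model.select(peptide_selection)
    if pep_idx.size == 0:
        return "Interface report\n  no contacts (empty peptide selection)\n"
    hbonds = detect_hbonds(model, domain_selection, peptide_selection, hbond_cutoff)
    contacts = detect_contacts(
        model, domain_selection, peptide_selection, hydrophobic_cutoff, charge_cutoff
    )
    pep_keys = {model.atoms[int(i)].residue_key for i in pep_idx}

    def pep_residue(*atoms: Atom):
        for at in atoms:
            if at.residue_key in pep_keys:
                return at
        return atoms[0]

    by_res: dict[tuple, dict] = {}
    for hb in hbonds:
        at = pep_residue(hb.donor, hb.acceptor)
        by_res.setdefault(at.residue_key, {"resn": at.resn, "items": []})[
            "items"
        ].append((hb.distance, f"H-bond   {hb}"))
    for ct in contacts:
        at = pep_residue(ct.atom_a, ct.atom_b)
        label = "charge   " if ct.type == "charge_charge" else "hydrophob"
        by_res.setdefault(at.residue_key, {"resn": at.resn, "items": []})[
            "items"
        ].append((ct.distance, f"{label} {ct}"))

    lines = ["Interface report", "=" * 60]
    if not by_res:
        lines.append("  no contacts")
    for key in sorted(by_res):
        chain, resi, icode = key
        rec = by_res[key]
        lines.append(f"peptide residue {chain}/{rec['resn']}{resi}{icode}")
        for _, text in sorted(rec["items"]):
            lines.append(f"  {text}")
    lines.append("")
    return "\n".join(lines)
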