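"""Structure container, PDB I/O (via gemmi), and a small selection language.

The container keeps author residue numbering and treats phosphoserine (SEP)
HETATM records as ordinary peptide residues, since phosphopeptides are the
subject of the analyses built on top.  Alternate locations are resolved at
read time to the highest-occupancy conformer (ties broken alphabetically by
altloc id).

Selections use a PyMOL-flavoured mini-language of AND-joined clauses::

    chain A and resi 1560-1594 and name CA

grammar:  expr   := clause (" and " clause)*
          clause := "chain" id[,id...] | "resi" n|n-m[,...]
                    | "name" id[,id...] | "resn" id[,id...]
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["Atom", "StructureModel", "read_pdb", "read_ensemble", "parse_selection"]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: residues kept as peptide residues even when written as HETATM
PEPTIDE_HET = frozenset({"SEP", "TPO", "PTR"})


@dataclass(frozen=True)
class Atom:
    chain: str
    resi: int
    icode: str
    resn: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resi, self.icode)


@dataclass
class StructureModel:
    """A single coordinate model: a flat atom list plus provenance metadata."""

    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = self.coords
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resi, a.icode, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc resolution: {key}")
            seen.add(key)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.atoms)

    def select(self, expr: str | np.ndarray | None) -> np.ndarray:
        """Atom indices matching a selection expression (None = all)."""
        if expr is None:
            return np.arange(len(self.atoms))
        if isinstance(expr, np.ndarray):
            return expr
        pred = parse_selection(expr)
        idx = np.array([i for i, a in enumerate(self.atoms) if pred(a)], dtype=int)
        return idx

    def subset(self, indices: np.ndarray) -> "StructureModel":
        return StructureModel(
            [self.atoms[int(i)] for i in indices], metadata=dict(self.metadata)
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy: r' = R r + t."""
        new_xyz = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, new_xyz)
        ]
        return StructureModel(atoms, metadata=dict(self.metadata))

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms, metadata=dict(self.metadata))

    # -- PDB output ----------------------------------------------------

    def write_pdb(self, path) -> None:
        st = gemmi.Structure()
        st.name = str(self.metadata.get("name", "model"))
        model = gemmi.Model("1")
        for atom in self.atoms:
            chain = None
            for ch in model:
                if ch.name == atom.chain:
                    chain = ch
                    break
            if chain is None:
                model.add_chain(gemmi.Chain(atom.chain))
                chain = model[-1]
            res = None
            if len(chain) > 0:
                last = chain[-1]
                if last.seqid.num == atom.resi and last.name == atom.resn:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = atom.resn
                res.seqid = gemmi.SeqId(atom.resi, atom.icode or " ")
                res.het_flag = "H" if atom.het else "A"
                chain.add_residue(res)
                res = chain[-1]
            g = gemmi.Atom()
            g.name = atom.name
            g.element = gemmi.Element(atom.element)
            g.pos = gemmi.Position(atom.x, atom.y, atom.z)
            g.occ = atom.occupancy
            g.b_iso = atom.bfactor
            res.add_atom(g)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    groups: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        groups.setdefault(at.name, []).append(at)
    kept = []
    for name, group in groups.items():
        if len(group) == 1:
            kept.append(group[0])
        else:
            kept.append(min(group, key=lambda a: (-a.occ, a.altloc or "~")))
    return kept


def _model_to_atoms(model: gemmi.Model) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H" and res.name not in PEPTIDE_HET
            if res.is_water():
                continue
            for at in _resolve_altlocs(res):
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resi=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        resn=res.name,
                        name=at.name,
                        element=at.element.name.upper(),
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        occupancy=at.occ,
                        bfactor=at.b_iso,
                        het=res.het_flag == "H",
                    )
                )
    return atoms


def read_pdb(path, model_index: int = 0) -> StructureModel:
    """Read one model from a PDB file.

    Author residue numbering and insertion codes are preserved; waters are
    dropped; phospho-residue HETATMs (SEP/TPO/PTR) are kept as peptide
    residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed PDB record ({exc})") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate models")
    if model_index >= len(st):
        raise IndexError(f"{path}: model {model_index} of {len(st)} requested")
    atoms = _model_to_atoms(st[model_index])
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records parsed")
    return StructureModel(
        atoms, metadata={"source": str(path), "n_models": len(st)}
    )


def read_ensemble(path) -> list[StructureModel]:
    """All models of a multi-model PDB file, in order."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    out = []
    for i, model in enumerate(st):
        atoms = _model_to_atoms(model)
        out.append(StructureModel(atoms, metadata={"source": str(path), "model": i}))
    if not out:
        raise ValueError(f"{path}: no coordinate models")
    return out


# -- selection mini-language ------------------------------------------


def _parse_int_list(spec: str) -> set[int]:
    out: set[int] = set()
    for tok in spec.split(","):
        tok = tok.strip()
        if "-" in tok[1:]:  # allow negative single numbers
            pivot = tok.index("-", 1)
            lo, hi = int(tok[:pivot]), int(tok[pivot + 1:])
            out.update(range(lo, hi + 1))
        else:
            out.add(int(tok))
    return out


def parse_selection(expr: str):
    """Compile a selection expression into a predicate over :class:`Atom`."""
    clauses = []
    for raw in expr.split(" and "):
        parts = raw.strip().split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {raw!r}")
        kw, arg = parts[0].lower(), parts[1].strip()
        if kw == "chain":
            values = {v.strip() for v in arg.split(",")}
            clauses.append(lambda a, v=values: a.chain in v)
        elif kw == "resi":
            numbers = _parse_int_list(arg)
            clauses.append(lambda a, v=numbers: a.resi in v)
        elif kw == "name":
            names = {v.strip().upper() for v in arg.split(",")}
            clauses.append(lambda a, v=names: a.name.upper() in v)
        elif kw == "resn":
            resns = {v.strip().upper() for v in arg.split(",")}
            clauses.append(lambda a, v=resns: a.resn.upper() in v)
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")

    def predicate(atom: Atom) -> bool:
        return all(c(atom) for c in clauses)

    return predicate
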