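"""Rigid-body superposition (Kabsch), Calpha pairing, and ensemble RMSF."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import StructureModel

__all__ = ["SuperpositionResult", "kabsch_superpose", "pair_ca_atoms", "rmsf_per_atom"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom, after transformation

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns rotation R and translation t with x' = R x + t, plus the RMSD of
    the transformed mobile set against the reference.  A proper rotation is
    enforced by sign-flipping the smallest singular direction (no
    reflections).
    """
    m = np.asarray(mobile, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2 or np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    rot = vt.T @ D @ u.T
    t = r.mean(axis=0) - rot @ m.mean(axis=0)
    diff = (m @ rot.T + t) - r
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd)


def pair_ca_atoms(
    a: StructureModel,
    b: StructureModel,
    selection: str | None = None,
    chain_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pair Calpha atoms of two models by (mapped chain, residue number).

    ``chain_map`` maps chains of ``a`` onto chains of ``b`` (identity by
    default).  Unmatched residues are dropped and counted; the report dict
    carries the matched count in the "185-185 atoms" style of structural
    comparisons.
    """
    def ca_table(model: StructureModel) -> dict[tuple[str, int, str], int]:
        idx = model.select(selection) if selection else np.arange(len(model))
        table = {}
        for i in idx:
            at = model.atoms[int(i)]
            if at.name.upper() == "CA":
                table[at.residue_key] = int(i)
        return table

    ta, tb = ca_table(a), ca_table(b)
    chain_map = chain_map or {}
    pairs = []
    for (chain, resi, icode), ia in sorted(ta.items()):
        key_b = (chain_map.get(chain, chain), resi, icode)
        if key_b in tb:
            pairs.append((ia, tb[key_b]))
    if not pairs:
        raise ValueError("no Calpha atoms could be paired")
    ia, ib = zip(*pairs)
    ca, cb = a.coords[list(ia)], b.coords[list(ib)]
    report = {
        "matched": len(pairs),
        "unmatched_a": len(ta) - len(pairs),
        "unmatched_b": len(tb) - len(pairs),
        "label": f"{len(pairs)}-{len(pairs)} atoms",
    }
    return ca, cb, report


def rmsf_per_atom(
    ensemble: Sequence[np.ndarray],
    superpose_to: str = "first",
    fit_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom RMSF (A) of an ensemble of conformers.

    Frames are first rigidly superposed on the reference subset
    (``fit_indices``; all atoms by default), with the reference being the
    first frame or the iterated ensemble mean.  RMSF_i is the root of the
    mean squared displacement of atom i about its ensemble-mean position.
    """
    frames = [np.asarray(f, dtype=float) for f in ensemble]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("inconsistent atom counts across frames")
    if superpose_to not in ("first", "mean"):
        raise ValueError(f"unknown reference mode {superpose_to!r}")
    fit = np.arange(shape[0]) if fit_indices is None else np.asarray(fit_indices)

    def fit_all(reference: np.ndarray) -> list[np.ndarray]:
        out = []
        for f in frames:
            sup = kabsch_superpose(f[fit], reference[fit])
            out.append(sup.apply(f))
        return out

    aligned = fit_all(frames[0])
    if superpose_to == "mean":
        # two rounds of mean refinement are ample for rigid ensembles
        for _ in range(2):
            mean = np.mean(aligned, axis=0)
            aligned = fit_all(mean)

    stack = np.stack(aligned)
    mean = stack.mean(axis=0)
    return np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=0))
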