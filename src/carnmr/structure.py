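"""C-alpha superposition and pairwise RMSD between crystal structures.

For near-identical ligand-binding-domain structures, rigid-body least-squares
superposition (Kabsch) over sequence-number-paired C-alpha atoms is the
appropriate comparison; residues disordered in either structure are dropped
by intersection pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd


@dataclass
class CoordSet:
    """Ordered C-alpha trace of one chain of one structure."""

    structure_id: str
    chain: str
    residue_numbers: np.ndarray  # int, strictly increasing
    coords: np.ndarray  # (n, 3) Angstrom

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.residue_numbers.size, 3):
            raise ValueError("coordinate array must be (n_residues, 3)")
        if np.unique(self.residue_numbers).size != self.residue_numbers.size:
            raise ValueError("duplicate residue numbers")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return int(self.residue_numbers.size)


def read_calpha(pdb_content: str, chain: str = "A", model: int = 1,
                structure_id: str = "structure") -> CoordSet:
    """C-alpha coordinates of one chain/model from PDB-format text.

    Only the first alternate location of each residue is used; residues are
    ordered by residue number (first occurrence wins on duplicates).
    """
    st = gemmi.read_pdb_string(pdb_content)
    if not 1 <= model <= len(st):
        raise ValueError(f"model {model} not present ({len(st)} models)")
    mdl = st[model - 1]
    chains = [ch.name for ch in mdl]
    target = None
    for ch in mdl:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    seen: dict[int, np.ndarray] = {}
    for res in target:
        num = res.seqid.num
        if num in seen:
            continue
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\0", " ", "", "A"):
                seen[num] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                break
    if not seen:
        raise ValueError(f"no C-alpha atoms in chain {chain!r}")
    nums = np.array(sorted(seen))
    coords = np.stack([seen[n] for n in nums])
    return CoordSet(structure_id, chain, nums, coords)


def read_calpha_file(path: str | Path, chain: str = "A", model: int = 1) -> CoordSet:
    path = Path(path)
    return read_calpha(path.read_text(), chain=chain, model=model,
                       structure_id=path.stem)


def common_residues(a: CoordSet, b: CoordSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates paired by residue-number intersection, order preserved.

    Returns (coords_a, coords_b, residue_numbers)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("coordinate sets must be non-empty")
    common = np.intersect1d(a.residue_numbers, b.residue_numbers)
    if common.size == 0:
        raise ValueError(
            f"no common residues between {a.structure_id} and {b.structure_id}"
        )
    ia = np.searchsorted(a.residue_numbers, common)
    ib = np.searchsorted(b.residue_numbers, common)
    return a.coords[ia], b.coords[ib], common


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of p onto q.

    Returns (rotation, translation, rmsd): rotation is the proper rotation
    (det = +1, enforced by sign correction of the smallest singular vector)
    and translation maps centred p onto q, i.e. x -> R x + t.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if p.shape[0] < 3:
        raise ValueError("at least 3 paired atoms required")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    diff = (pc @ rot.T) - qc
    rmsd = float(np.sqrt((diff**2).sum() / p.shape[0]))
    return rot, trans, rmsd


def rmsd_between(a: CoordSet, b: CoordSet) -> tuple[float, int]:
    """(C-alpha RMSD in Angstrom, number of paired residues)."""
    pa, pb, common = common_residues(a, b)
    _, _, r = kabsch_rmsd(pa, pb)
    return r, int(common.size)


def pairwise_rmsd_matrix(structures: list[CoordSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric RMSD matrix over common residues, plus per-pair residue counts."""
    if len(structures) < 2:
        raise ValueError("at least 2 structures required")
    ids = [s.structure_id for s in structures]
    rmat = pd.DataFrame(0.0, index=ids, columns=ids)
    nmat = pd.DataFrame(0, index=ids, columns=ids)
    for i, a in enumerate(structures):
        nmat.iloc[i, i] = len(a)
        for j in range(i + 1, len(structures)):
            r, n = rmsd_between(a, structures[j])
            rmat.iloc[i, j] = rmat.iloc[j, i] = r
            nmat.iloc[i, j] = nmat.iloc[j, i] = n
    return rmat, nmat
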