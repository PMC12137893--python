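"""Structure and matrix file I/O.

Reads Cα traces from PDB files (first model, first altloc, residues
without a Cα are skipped), reads/writes rigid-superposition matrices in
the TM-align ``-m`` text dialect, and writes alignment reports.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.sequence import ProteinSequence

logger = logging.getLogger(__name__)

_ORTHO_TOL_FILE = 1e-3


@dataclass
class ChainStructure:
    """Ordered Cα residues of one protein chain.

    Parameters
    ----------
    chain_id:
        Chain label from the source file (or a synthetic label).
    res_nums:
        Author residue numbers, in file order.
    ins_codes:
        Insertion codes ("" when absent), parallel to ``res_nums``.
    seq:
        One-letter amino-acid codes, parallel to ``res_nums``.
    coords:
        (n, 3) array of Cα coordinates in Å.
    """

    chain_id: str
    res_nums: list[int]
    ins_codes: list[str]
    seq: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a chain must contain at least one residue")
        if not (len(self.res_nums) == len(self.ins_codes) == len(self.seq) == n):
            raise ValueError("residue annotation lengths disagree with coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite Cα coordinates")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return len(self)

    @property
    def residues(self) -> list[tuple[int, str, str, np.ndarray]]:
        """(author number, insertion code, one-letter code, Cα position) per residue."""
        return [
            (self.res_nums[i], self.ins_codes[i], self.seq[i], self.coords[i])
            for i in range(len(self))
        ]

    def residue_label(self, i: int) -> str:
        """Author residue number plus insertion code for file output."""
        return f"{self.res_nums[i]}{self.ins_codes[i]}"


@dataclass
class Superposition:
    """Rigid map ``x -> rotation @ x + translation`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    _ortho_tol: float = field(default=1e-6, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > self._ortho_tol or abs(det - 1.0) > max(self._ortho_tol, 1e-6):
            raise ValueError(
                f"rotation is not a proper rotation (orthogonality error {err:.2e}, "
                f"determinant {det:.6f})"
            )

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        rt = self.rotation.T
        return Superposition(rt, -rt @ self.translation)


def read_ca_structure(path: str | os.PathLike, chain_id: str | None = None) -> ChainStructure:
    """Read the Cα trace of one chain from a PDB file.

    First model only; for altloc duplicates the first occurrence wins;
    residues lacking a Cα atom are skipped.  When ``chain_id`` is None
    the first chain in the file is used.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"structure file not found: {path}")
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        atoms = pdb.get_structure(pdb_file, model=1, altloc="first")
    except Exception as exc:  # no models / malformed
        raise ValueError(f"no ATOM records parseable in {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise ValueError(f"no ATOM records in {path}")
    if chain_id is None:
        chain_id = str(atoms.chain_id[0])
    chain_mask = atoms.chain_id == chain_id
    if not chain_mask.any():
        raise ValueError(f"chain {chain_id!r} not found in {path}")
    ca = atoms[chain_mask & (atoms.atom_name == "CA") & ~atoms.hetero]
    if ca.array_length() == 0:
        # allow HETATM CA (e.g. modified residues) as a fallback
        ca = atoms[chain_mask & (atoms.atom_name == "CA")]
    if ca.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} in {path} has no Cα atoms")

    res_nums: list[int] = []
    ins_codes: list[str] = []
    letters: list[str] = []
    coords: list[np.ndarray] = []
    seen: set[tuple[int, str]] = set()
    n_dup = 0
    for i in range(ca.array_length()):
        key = (int(ca.res_id[i]), str(ca.ins_code[i]))
        if key in seen:  # duplicate CA for a residue: first occurrence wins
            n_dup += 1
            continue
        seen.add(key)
        res_nums.append(key[0])
        ins_codes.append(key[1])
        try:
            letters.append(ProteinSequence.convert_letter_3to1(str(ca.res_name[i])))
        except Exception:
            letters.append("X")
        coords.append(ca.coord[i])
    if n_dup:
        logger.info("chain %s: skipped %d duplicate Cα records", chain_id, n_dup)
    logger.info(
        "read %d Cα residues for chain %s from %s (first model, first altloc)",
        len(res_nums), chain_id, path,
    )
    return ChainStructure(chain_id, res_nums, ins_codes, "".join(letters), np.array(coords))


_PDB_ATOM = (
    "ATOM  {serial:5d}  CA  {resname:<3s} {chain:1s}{resnum:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def write_ca_structure(chain: ChainStructure, path: str | os.PathLike) -> None:
    """Write a chain as a Cα-only PDB file (occupancy 1.00, B 0.00)."""
    with open(path, "w") as fh:
        for i in range(len(chain)):
            try:
                resname = ProteinSequence.convert_letter_1to3(chain.seq[i]).upper()
            except Exception:
                resname = "UNK"
            fh.write(
                _PDB_ATOM.format(
                    serial=i + 1,
                    resname=resname,
                    chain=(chain.chain_id or "A")[0],
                    resnum=chain.res_nums[i],
                    icode=chain.ins_codes[i] or " ",
                    x=chain.coords[i, 0],
                    y=chain.coords[i, 1],
                    z=chain.coords[i, 2],
                )
            )
        fh.write("TER\nEND\n")


def read_superposition_matrix(path: str | os.PathLike) -> Superposition:
    """Read a rotation/translation file in the TM-align ``-m`` dialect.

    Data rows are ``i t(i) u(i,1) u(i,2) u(i,3)`` for i in 0..2 and map a
    point as ``y = t + U @ x``.  Comment/decoration lines are ignored.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"matrix file not found: {path}")
    rows: dict[int, tuple[float, float, float, float]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5:
                continue
            try:
                idx = int(parts[0])
                vals = tuple(float(p) for p in parts[1:5])
            except ValueError:
                continue
            if idx in (0, 1, 2) and idx not in rows:
                rows[idx] = vals  # type: ignore[assignment]
    if len(rows) < 3:
        raise ValueError(f"fewer than 3 parseable matrix rows in {path}")
    t = np.array([rows[i][0] for i in range(3)])
    u = np.array([rows[i][1:4] for i in range(3)])
    err = np.abs(u @ u.T - np.eye(3)).max()
    det = np.linalg.det(u)
    if err > _ORTHO_TOL_FILE or det < 0:
        raise ValueError(
            f"matrix in {path} is not a proper rotation "
            f"(orthogonality error {err:.2e}, determinant {det:.4f})"
        )
    return Superposition(u, t, _ortho_tol=_ORTHO_TOL_FILE)


def write_superposition_matrix(sup: Superposition, path: str | os.PathLike) -> None:
    """Write a Superposition in the TM-align ``-m`` dialect (17 significant digits)."""
    with open(path, "w") as fh:
        fh.write(" -------- rotation matrix to rotate chain 1 to chain 2 --------\n")
        fh.write(" i          t(i)         u(i,1)         u(i,2)         u(i,3)\n")
        for i in range(3):
            fh.write(
                f" {i} {sup.translation[i]:.17g} "
                + " ".join(f"{sup.rotation[i, j]:.17g}" for j in range(3))
                + "\n"
            )


def write_alignment_report(result, qs: ChainStructure, ts: ChainStructure,
                           path: str | os.PathLike, extra: dict | None = None) -> None:
    """Write a human-readable header plus a residue map TSV.

    The map has three columns: query residue number, target residue
    number, distance in Å (3 decimals).  Residue numbers are author
    numbering from the source files.
    """
    from .metrics import aligned_rmsd, structure_overlap  # local import: avoid cycle

    for i, j in result.pairs:
        if not (0 <= i < len(qs) and 0 <= j < len(ts)):
            raise IndexError(f"alignment pair ({i}, {j}) out of range before output")
    dists = result.distances if result.distances is not None else []
    nali = len(result.pairs)
    rmsd = aligned_rmsd(dists) if nali else float("nan")
    so = structure_overlap(dists) if nali else 0.0
    with open(path, "w") as fh:
        fh.write(f"# query: {qs.chain_id} ({len(qs)} residues)\n")
        fh.write(f"# target: {ts.chain_id} ({len(ts)} residues)\n")
        fh.write(f"# Nali: {nali}\n")
        fh.write(f"# RMSD: {rmsd:.4f}\n" if nali else "# RMSD: nan\n")
        fh.write(f"# SO: {so:.4f}\n")
        fh.write(f"# SP-score: {_fmt(result.sp)}\n")
        fh.write(f"# TM-score: {_fmt(result.tm)}\n")
        if extra:
            for k, v in extra.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("#query_res\ttarget_res\tdistance\n")
        for k, (i, j) in enumerate(result.pairs):
            d = float(dists[k]) if nali else math.nan
            fh.write(f"{qs.residue_label(i)}\t{ts.residue_label(j)}\t{d:.3f}\n")


def _fmt(x) -> str:
    return f"{x:.4f}" if x is not None else "nan"
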