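"""Alignment quality metrics.

Reference-independent: Nali, RMSD over aligned pairs, structure overlap
(percent of aligned pairs within a distance threshold, boundary
inclusive) and its threshold curve.  Reference-dependent: count of
aligned pairs shared with a curated reference (EQR) and that count as a
percentage of the reference length (agreement).
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SO_DEFAULT_THRESHOLD = 3.5
SO_DEFAULT_GRID = [3.0 + 0.5 * k for k in range(9)]  # 3.0 .. 7.0 step 0.5


@dataclass
class MetricsReport:
    nali: int
    rmsd: float
    so: float
    so_curve: list[tuple[float, float]] = field(default_factory=list)
    eqr: int | None = None
    agreement: float | None = None

    def to_json(self) -> str:
        """Single-line JSON record."""
        return json.dumps({
            "nali": self.nali,
            "rmsd": None if math.isnan(self.rmsd) else self.rmsd,
            "so": self.so,
            "so_curve": [[t, v] for t, v in self.so_curve],
            "eqr": self.eqr,
            "agreement": self.agreement,
        })

    def to_text(self) -> str:
        lines = [
            f"Nali      {self.nali}",
            f"RMSD      {self.rmsd:.4f}" if not math.isnan(self.rmsd) else "RMSD      nan",
            f"SO        {self.so:.4f}",
        ]
        for t, v in self.so_curve:
            lines.append(f"SO_th({t:.1f})  {v:.4f}")
        if self.eqr is not None:
            lines.append(f"EQR       {self.eqr}")
        if self.agreement is not None:
            lines.append(f"Agreement {self.agreement:.4f}")
        return "\n".join(lines)


def aligned_rmsd(distances) -> float:
    """sqrt(mean(d²)) over aligned-pair distances; undefined (error) when empty."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("RMSD is undefined for an empty alignment")
    return float(np.sqrt(np.mean(d ** 2)))


def structure_overlap(distances, threshold: float = SO_DEFAULT_THRESHOLD) -> float:
    """100 × fraction of aligned pairs with d ≤ threshold (inclusive boundary)."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        logger.info("structure overlap of an empty alignment: returning 0 by convention")
        return 0.0
    return float(100.0 * np.count_nonzero(d <= threshold) / d.size)


def so_curve(distances, thresholds=None) -> list[tuple[float, float]]:
    """Structure overlap at each threshold of an ascending grid."""
    if thresholds is None:
        thresholds = SO_DEFAULT_GRID
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    return [(float(t), structure_overlap(distances, t)) for t in thresholds]


def _pair_set(aln) -> set[tuple[int, int]]:
    pairs = aln.pairs if hasattr(aln, "pairs") else aln
    return {(int(i), int(j)) for i, j in pairs}


def eqr_agreement(aln, reference) -> tuple[int, float]:
    """Exact shared pairs with a reference alignment, and the percentage of it.

    ``aln`` may be an AlignmentResult or a plain pair list; the reference
    must be non-empty and injective.
    """
    ref = [(int(i), int(j)) for i, j in
           (reference.pairs if hasattr(reference, "pairs") else reference)]
    if not ref:
        raise ValueError("reference alignment is empty")
    _check_injective(ref, "reference")
    eqr = len(_pair_set(aln) & set(ref))
    return eqr, 100.0 * eqr / len(ref)


def _check_injective(pairs: list[tuple[int, int]], what: str,
                     lines: list[int] | None = None) -> None:
    seen_i: dict[int, int] = {}
    seen_j: dict[int, int] = {}
    for k, (i, j) in enumerate(pairs):
        where = f" (line {lines[k]})" if lines else ""
        if i in seen_i:
            raise ValueError(f"{what}: query residue {i} repeated{where}")
        if j in seen_j:
            raise ValueError(f"{what}: target residue {j} repeated{where}")
        seen_i[i] = k
        seen_j[j] = k


def read_reference_alignment(path: str | os.PathLike) -> list[tuple[int, int]]:
    """Read a two-column TSV of residue-number pairs ('#' comments allowed)."""
    pairs: list[tuple[int, int]] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            pairs.append((int(parts[0]), int(parts[1])))
            lines.append(lineno)
    _check_injective(pairs, str(path), lines)
    return pairs


def map_reference_to_indices(pairs: list[tuple[int, int]], query, target
                             ) -> list[tuple[int, int]]:
    """Map author residue numbers to 0-based internal chain indices."""
    qmap = {query.res_nums[i]: i for i in range(len(query))}
    tmap = {target.res_nums[j]: j for j in range(len(target))}
    out = []
    for qn, tn in pairs:
        if qn not in qmap or tn not in tmap:
            raise ValueError(f"reference pair ({qn}, {tn}) not present in the chains")
        out.append((qmap[qn], tmap[tn]))
    return out


def report(distances, so_threshold: float = SO_DEFAULT_THRESHOLD,
           thresholds=None, eqr: int | None = None,
           agreement: float | None = None) -> MetricsReport:
    """Assemble a MetricsReport from aligned-pair distances."""
    d = np.asarray(distances, dtype=float).ravel()
    nali = int(d.size)
    return MetricsReport(
        nali=nali,
        rmsd=aligned_rmsd(d) if nali else float("nan"),
        so=structure_overlap(d, so_threshold),
        so_curve=so_curve(d, thresholds),
        eqr=eqr,
        agreement=agreement,
    )
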