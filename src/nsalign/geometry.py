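"""Rigid-body mathematics: Kabsch superposition, transforms, distances, TM-score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import ChainStructure, Superposition


@dataclass
class DistanceTable:
    """m×n Euclidean distances (Å) between superposed query and target Cα atoms."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance table must be 2-D")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("distances must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _d0_from_length(norm_length: int) -> float:
    return max(0.5, 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8) if norm_length > 15 \
        else 0.5


@dataclass
class TMScoreParams:
    """Normalization for TM-score; d0 is derived from norm_length with a 0.5 Å floor."""

    norm_length: int
    d0_tm: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.norm_length < 1:
            raise ValueError("norm_length must be >= 1")
        if self.d0_tm <= 0.0:
            self.d0_tm = _d0_from_length(self.norm_length)


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Optimal proper rotation + translation mapping `moving` onto `fixed` (least RMSD).

    Reflections are corrected by flipping the sign of the smallest
    singular direction.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError("point sets must have equal shape")
    if mov.ndim != 2 or mov.shape[1] != 3 or mov.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    cm = mov.mean(axis=0)
    cf = fix.mean(axis=0)
    h = (mov - cm).T @ (fix - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return Superposition(rot, cf - rot @ cm)


def transform_points(points: np.ndarray, sup: Superposition) -> np.ndarray:
    """Apply ``rotation @ x + translation`` to each point."""
    return sup.apply(points)


def pairwise_distances(query: ChainStructure, target: ChainStructure,
                       sup: Superposition) -> DistanceTable:
    """All-against-all Cα distances after mapping the query into the target frame."""
    moved = sup.apply(query.coords)
    return DistanceTable(cdist(moved, target.coords))


def tm_score(distances, params: TMScoreParams) -> float:
    """Length-normalized similarity in [0, 1]: (1/L_norm) Σ 1 / (1 + (d/d0)²)."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        return 0.0
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    return float(np.sum(1.0 / (1.0 + (d / params.d0_tm) ** 2)) / params.norm_length)
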