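"""Ground-truthed synthetic fixtures.

Ideal helical Cα traces, non-sequential rearrangements (circular
permutation, segment swap) with a known residue correspondence,
Gaussian coordinate noise, and letter-string toy similarity problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import SimilarityMatrix
from .structio import ChainStructure

# textbook alpha-helix Cα geometry
HELIX_RADIUS = 2.3     # Å
HELIX_RISE = 1.5       # Å per residue
HELIX_TURN = 100.0     # degrees per residue

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GroundTruthPair:
    """A query/target pair with the intended residue correspondence."""

    query: ChainStructure
    target: ChainStructure
    truth_map: list[tuple[int, int]]
    rearrangement: str = "none"     # none | circular | segment_swap
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        qs = [i for i, _ in self.truth_map]
        ts = [j for _, j in self.truth_map]
        if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
            raise ValueError("truth_map must be injective")
        if any(not (0 <= i < len(self.query) and 0 <= j < len(self.target))
               for i, j in self.truth_map):
            raise ValueError("truth_map index out of range")


def make_helix_chain(n: int, seed: int = 0, chain_id: str = "A") -> ChainStructure:
    """Ideal α-helix Cα trace along z (consecutive Cα–Cα spacing ≈ 3.8 Å).

    Coordinates are deterministic in ``n``; the seed only randomizes the
    amino-acid letters.
    """
    if n < 4:
        raise ValueError("need at least 4 residues for a helix trace")
    idx = np.arange(n)
    theta = np.deg2rad(HELIX_TURN) * idx
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * idx,
    ])
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA), size=n))
    return ChainStructure(chain_id, list(range(1, n + 1)), [""] * n, seq, coords)


def rearrange_segments(chain: ChainStructure, mode: str, cut) -> GroundTruthPair:
    """Permute residue record order while keeping per-residue coordinates.

    circular: ``cut`` is an index c (0 < c < n); target order is
    [c..n-1] + [0..c-1].  segment_swap: ``cut`` is (s, e) with
    0 < s < e < n; blocks [0, s) and [s, e) exchange positions, the tail
    [e, n) stays.  ``truth_map`` records original index → new position.
    """
    n = len(chain)
    if mode == "circular":
        c = int(cut)
        if not (0 < c < n):
            raise ValueError("circular cut must be strictly inside the chain")
        order = list(range(c, n)) + list(range(c))
    elif mode == "segment_swap":
        s, e = (int(cut[0]), int(cut[1]))
        if not (0 < s < e < n):
            raise ValueError("segment_swap bounds must satisfy 0 < start < end < n")
        order = list(range(s, e)) + list(range(s)) + list(range(e, n))
    else:
        raise ValueError(f"unknown rearrangement mode {mode!r}")
    coords = chain.coords[order]
    seq = "".join(chain.seq[k] for k in order)
    target = ChainStructure(chain.chain_id or "A", list(range(1, n + 1)), [""] * n,
                            seq, coords)
    new_pos = {orig: pos for pos, orig in enumerate(order)}
    truth = [(i, new_pos[i]) for i in range(n)]
    return GroundTruthPair(chain, target, truth, rearrangement=mode)


def jitter_coords(chain: ChainStructure, sigma: float, seed: int = 0) -> ChainStructure:
    """Add isotropic Gaussian coordinate noise (deterministic under seed)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = chain.coords + (rng.normal(0.0, sigma, chain.coords.shape) if sigma else 0.0)
    return ChainStructure(chain.chain_id, list(chain.res_nums), list(chain.ins_codes),
                          chain.seq, coords)


def make_ground_truth_pair(n: int, mode: str, cut, sigma: float = 0.0,
                           seed: int = 0) -> GroundTruthPair:
    """Helix chain + rearrangement + (target-only) noise, truth map attached."""
    chain = make_helix_chain(n, seed=seed)
    pair = rearrange_segments(chain, mode, cut)
    if sigma > 0:
        pair = GroundTruthPair(pair.query, jitter_coords(pair.target, sigma, seed=seed),
                               pair.truth_map, rearrangement=mode, noise_sigma=sigma)
    return pair


def letter_problem(s1: str, s2: str, match: float = 1.0, mismatch: float = 0.0,
                   gap: float = 0.0) -> SimilarityMatrix:
    """Case-insensitive letter-matching toy similarity matrix."""
    if not s1 or not s2:
        raise ValueError("both strings must be non-empty")
    m, n = len(s1), len(s2)
    s = np.full((m + 1, n + 1), float(gap))
    for i, a in enumerate(s1.lower()):
        for j, b in enumerate(s2.lower()):
            s[i, j] = match if a == b else mismatch
    s[m, n] = 0.0
    return SimilarityMatrix(s, float(gap), m, n)
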