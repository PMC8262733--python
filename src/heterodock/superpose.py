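"""Rigid-body superposition, RMSD and TM-score.

The TM-score of a correspondence between two CA traces is

    TM = max over rigid superpositions of (1/L_norm) * sum_i 1/(1 + (d_i/d0)^2)

with d0(L) = 1.24 (L - 15)^(1/3) - 1.8, floored at 0.5 Å.  The maximization is
approximated by the standard iterative protocol: seed superpositions from
aligned fragments at several lengths and offsets, then for each seed
alternately superpose on the close pairs (distance below a shrinking cutoff)
and rescore, keeping the best score over all seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Correspondence", "RigidTransform", "kabsch", "d0", "tm_score",
           "DegenerateInputError"]


class DegenerateInputError(ValueError):
    """Too few or collinear points for a unique rigid superposition."""


@dataclass(frozen=True)
class Correspondence:
    """An ordered, crossing-free residue mapping between two chains.

    ``pairs`` is a (K, 2) integer array of 0-based indices; both columns are
    strictly increasing (sequential alignment) with no repeats.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "pairs", pairs)
        if len(pairs) > 0:
            if np.any(np.diff(pairs[:, 0]) <= 0) or np.any(np.diff(pairs[:, 1]) <= 0):
                raise ValueError("correspondence indices must be strictly increasing")
            if pairs.min() < 0:
                raise ValueError("negative residue index")

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        idx = np.arange(n, dtype=np.int64)
        return cls(np.column_stack([idx, idx]))

    @classmethod
    def from_columns(cls, idx_a, idx_b) -> "Correspondence":
        return cls(np.column_stack([np.asarray(idx_a, dtype=np.int64),
                                    np.asarray(idx_b, dtype=np.int64)]))

    @property
    def a(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def b(self) -> np.ndarray:
        return self.pairs[:, 1]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, applied as x -> R x + t."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation + translation minimizing the RMSD of the
    transformed ``coords_a`` against ``coords_b`` (reflections excluded), and
    that minimal RMSD.  Requires at least 3 non-collinear paired points.
    """
    A = np.asarray(coords_a, dtype=np.float64).reshape(-1, 3)
    B = np.asarray(coords_b, dtype=np.float64).reshape(-1, 3)
    if A.shape != B.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(A)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 paired points, got {n}")
    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    Ac = A - cen_a
    Bc = B - cen_b
    # exact collinearity: centered points span < 2 dimensions
    if np.linalg.matrix_rank(Ac, tol=1e-10) < 2 or np.linalg.matrix_rank(Bc, tol=1e-10) < 2:
        raise DegenerateInputError("points are collinear; rotation is not unique")
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_b - R @ cen_a
    resid = Ac @ R.T - Bc
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return RigidTransform(R, t), rmsd


def d0(L_norm: int) -> float:
    """TM-score distance normalization constant, floored at 0.5 Å."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    raw = 1.24 * np.cbrt(L_norm - 15.0) - 1.8
    return float(max(0.5, raw))


def _score(dist2: np.ndarray, d0_sq: float, L_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + dist2 / d0_sq)) / L_norm)


def _seed_windows(K: int) -> list[tuple[int, int]]:
    """(start, length) fragment seeds: lengths full, L/2, L/4, >=4 at sliding offsets."""
    seeds: list[tuple[int, int]] = []
    for frac in (1, 2, 4, 8):
        length = max(4, K // frac)
        if length > K:
            continue
        step = max(1, K // 16)
        for start in range(0, K - length + 1, step):
            seeds.append((start, length))
        if (K - length) % step:
            seeds.append((K - length, length))
    # dedupe, preserve order
    seen = set()
    out = []
    for s in seeds:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def tm_score(coords_ref: np.ndarray, coords_mob: np.ndarray, corr: Correspondence,
             L_norm: int, max_iter: int = 20) -> tuple[float, RigidTransform]:
    """TM-score of ``coords_mob`` superposed onto ``coords_ref`` over ``corr``.

    The returned transform maps the mobile coordinates onto the reference and
    achieves the returned score.  ``L_norm`` is the normalizing length (the
    target length by this package's convention; see the methods note).
    """
    if len(corr) == 0:
        raise ValueError("empty correspondence")
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    ref = np.asarray(coords_ref, float).reshape(-1, 3)[corr.a]
    mob = np.asarray(coords_mob, float).reshape(-1, 3)[corr.b]
    K = len(ref)
    d0v = d0(L_norm)
    d0_sq = d0v * d0v

    best_score = -1.0
    best_tf = RigidTransform.identity()
    for start, length in _seed_windows(K):
        sel = np.zeros(K, dtype=bool)
        sel[start:start + length] = True
        prev_sel = None
        for it in range(max_iter):
            if sel.sum() < 3:
                break
            try:
                tf, _ = kabsch(mob[sel], ref[sel])
            except DegenerateInputError:
                break
            dist2 = ((mob @ tf.rotation.T + tf.translation - ref) ** 2).sum(axis=1)
            score = _score(dist2, d0_sq, L_norm)
            if score > best_score:
                best_score = score
                best_tf = tf
            # shrink the inclusion cutoff from d0 to 3 Å over the first half
            # of the iterations, then hold at 3 Å
            frac = min(1.0, it / max(1, max_iter // 2))
            cutoff = max(3.0, d0v - (d0v - 3.0) * frac) if d0v > 3.0 else d0v
            new_sel = dist2 < cutoff * cutoff
            # guarantee enough pairs to keep superposing
            grow = cutoff
            while new_sel.sum() < 3 and grow < 1e3:
                grow += 0.5
                new_sel = dist2 < grow * grow
            if prev_sel is not None and np.array_equal(new_sel, prev_sel):
                break
            prev_sel = sel
            sel = new_sel
    return best_score, best_tf
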