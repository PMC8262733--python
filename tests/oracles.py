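"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive quantities by exhaustive or closed-form means,
sharing no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices


# --- rotation-grid RMSD minimum (oracle for kabsch) -------------------------

def _euler_rotations(alphas, betas, gammas):
    """Batch of Z-Y-Z Euler rotation matrices."""
    A, B, G = np.meshgrid(alphas, betas, gammas, indexing="ij")
    a, b, g = A.ravel(), B.ravel(), G.ravel()
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    R = np.empty((len(a), 3, 3))
    R[:, 0, 0] = ca * cb * cg - sa * sg
    R[:, 0, 1] = -ca * cb * sg - sa * cg
    R[:, 0, 2] = ca * sb
    R[:, 1, 0] = sa * cb * cg + ca * sg
    R[:, 1, 1] = -sa * cb * sg + ca * cg
    R[:, 1, 2] = sa * sb
    R[:, 2, 0] = -sb * cg
    R[:, 2, 1] = sb * sg
    R[:, 2, 2] = cb
    return R


def grid_min_rmsd(A: np.ndarray, B: np.ndarray, levels: int = 4,
                  n_starts: int = 8) -> float:
    """Minimum RMSD over rotations by a multi-start hierarchically refined
    Euler-angle grid.

    Translation is optimal once centroids are superposed, so only rotations
    are searched.  The coarse level keeps the best ``n_starts`` candidates
    (the Euler parametrization distorts distances near the gimbal poles, so
    a single zoom track can follow the wrong basin); each is refined through
    shrinking windows to ~1e-4 rad, leaving a grid-induced RMSD excess far
    below the 1e-3 Å comparison tolerance.
    """
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    n = len(A)
    steps = 13

    def evaluate(alphas, betas, gammas):
        R = _euler_rotations(alphas, betas, gammas)
        rot = np.einsum("rij,nj->rni", R, Ac)
        rmsd = np.sqrt(((rot - Bc) ** 2).sum(axis=(1, 2)) / n)
        return rmsd

    # coarse level over all of SO(3) (in Euler coordinates)
    alphas = np.linspace(0.0, 2 * np.pi, 2 * steps + 1)
    betas = np.linspace(0.0, np.pi, steps + 1)
    gammas = np.linspace(0.0, 2 * np.pi, 2 * steps + 1)
    rmsd = evaluate(alphas, betas, gammas)
    order = np.argsort(rmsd)[:n_starts]

    def unravel(k):
        ka, rem = divmod(int(k), (steps + 1) * (2 * steps + 1))
        kb, kg = divmod(rem, 2 * steps + 1)
        return np.array([alphas[ka], betas[kb], gammas[kg]])

    best = float(rmsd[order[0]])
    coarse_half = np.array([np.pi, np.pi / 2, np.pi])
    for k in order:
        center = unravel(k)
        half = coarse_half / steps * 1.5
        for _ in range(levels - 1):
            al = center[0] + np.linspace(-half[0], half[0], 2 * steps + 1)
            be = center[1] + np.linspace(-half[1], half[1], steps + 1)
            ga = center[2] + np.linspace(-half[2], half[2], 2 * steps + 1)
            r = evaluate(al, be, ga)
            j = int(np.argmin(r))
            if r[j] < best:
                best = float(r[j])
            ja, rem = divmod(j, (steps + 1) * (2 * steps + 1))
            jb, jg = divmod(rem, 2 * steps + 1)
            center = np.array([al[ja], be[jb], ga[jg]])
            half = half / steps * 1.5
    return best


# --- exhaustive-seed TM-score (oracle for tm_score) -------------------------

def _tm_d0(L: int) -> float:
    return max(0.5, 1.24 * np.cbrt(L - 15.0) - 1.8)


def _fit(P: np.ndarray, Q: np.ndarray):
    """Least-squares rotation+translation P->Q via SVD (local helper)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def exhaustive_tm(ref: np.ndarray, mob: np.ndarray, L_norm: int,
                  min_window: int = 4, refine_iters: int = 20) -> float:
    """Best TM-score over superpositions seeded from EVERY contiguous window
    of length >= ``min_window``, each refined by close-pair re-fitting under
    a cutoff shrinking from d0 to 3 Å.  The exhaustive window set is a strict
    superset of any heuristic seed schedule over contiguous fragments."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    K = len(ref)
    d0 = _tm_d0(L_norm)
    best = -np.inf
    for start in range(K - min_window + 1):
        for stop in range(start + min_window, K + 1):
            sel = np.zeros(K, dtype=bool)
            sel[start:stop] = True
            prev = None
            for it in range(refine_iters):
                if sel.sum() < 3:
                    break
                try:
                    R, t = _fit(mob[sel], ref[sel])
                except np.linalg.LinAlgError:
                    break
                d2 = (((mob @ R.T + t) - ref) ** 2).sum(axis=1)
                score = float(np.sum(1.0 / (1.0 + d2 / d0 ** 2)) / L_norm)
                if score > best:
                    best = score
                frac = min(1.0, it / max(1, refine_iters // 2))
                cutoff = max(3.0, d0 - (d0 - 3.0) * frac) if d0 > 3.0 else d0
                new_sel = d2 < cutoff ** 2
                grow = cutoff
                while new_sel.sum() < 3 and grow < 1e3:
                    grow += 0.5
                    new_sel = d2 < grow ** 2
                if prev is not None and np.array_equal(new_sel, prev):
                    break
                prev = sel
                sel = new_sel
    return best


# --- affine-gap global alignment score (oracle for global_align) ------------

def gotoh_score(seq_a: str, seq_b: str, open_pen: float = 11.0,
                extend_pen: float = 1.0) -> float:
    """Independent affine-gap Needleman–Wunsch (Gotoh) score with BLOSUM62.

    End gaps are penalized like internal ones; X scores 0 against everything,
    matching the package's scoring contract.
    """
    blosum = substitution_matrices.load("BLOSUM62")

    def sub(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return float(blosum[x, y])

    n, m = len(seq_a), len(seq_b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b (a aligned to gap)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_pen - extend_pen * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -open_pen - extend_pen * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_pen, Ix[i - 1, j] - extend_pen)
            Iy[i, j] = max(M[i, j - 1] - open_pen, Iy[i, j - 1] - extend_pen)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


# --- sphere-cap buried area (oracle for interface_area) ---------------------

def two_sphere_buried_area(radius: float, center_distance: float) -> float:
    """Closed-form buried area for two equal spheres of ``radius`` (already
    probe-inflated) at ``center_distance``: each sphere loses a cap of area
    2*pi*R*h with h = R - d/2; total buried = 2 caps."""
    if center_distance >= 2 * radius:
        return 0.0
    h = radius - center_distance / 2.0
    return 2.0 * (2.0 * np.pi * radius * h)


# --- rotation RMSD closed form (oracle for lrmsd) ---------------------------

def rotation_rmsd(coords: np.ndarray, axis: np.ndarray, angle_deg: float) -> float:
    """RMSD induced by rotating points about an axis through their centroid:
    RMSD = 2 sin(theta/2) * sqrt(mean squared perpendicular distance)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    centered = coords - coords.mean(axis=0)
    perp = centered - np.outer(centered @ axis, axis)
    mean_sq = float((perp ** 2).sum(axis=1).mean())
    return 2.0 * np.sin(np.deg2rad(angle_deg) / 2.0) * np.sqrt(mean_sq)
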