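"""Residue correspondences from sequence and from structure.

Two alignment paths feed the template search:

* ``global_align`` — Needleman–Wunsch global sequence alignment (BLOSUM62,
  affine gaps open 11 / extend 1), the built-in stand-in for a profile-based
  search; an optional reader ingests HHsearch ``.hhr`` summaries instead.
* ``structural_align`` — sequence-independent alignment in the TM-align
  style: iterate dynamic programming over the distance-derived score matrix
  S_ij = 1/(1 + (d_ij/d0)^2) against re-superposition on the current
  correspondence, seeded from gapless threading offsets; the best
  correspondence by final TM-score wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .structio import ChainStructure
from .superpose import Correspondence, RigidTransform, d0, kabsch, tm_score

__all__ = ["AlignmentResult", "global_align", "structural_align", "read_hhr"]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: constant (non-affine) gap penalty per gap column in the structural DP
STRUCT_GAP_PENALTY = 0.6


@dataclass
class AlignmentResult:
    """A correspondence plus how it was obtained.

    ``seq_identity`` is matches / aligned columns (gaps excluded); ``tm`` is
    set only for structural alignments; ``score`` is the raw alignment score
    (BLOSUM62 sum for the sequence path) used for ranking.
    """

    corr: Correspondence
    seq_identity: float
    method: str                      # "sequence" | "structure"
    tm: Optional[float] = None
    score: Optional[float] = None
    transform: Optional[RigidTransform] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_identity <= 1.0:
            raise ValueError("seq_identity outside [0, 1]")
        if self.method not in ("sequence", "structure"):
            raise ValueError(f"unknown alignment method {self.method!r}")


def _make_aligner() -> Align.PairwiseAligner:
    m = substitution_matrices.load("BLOSUM62").copy()
    # X is the unknown residue: score 0 against everything
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def global_align(seq_a: str, seq_b: str) -> AlignmentResult:
    """Needleman–Wunsch global alignment with BLOSUM62 and affine gaps (11/1)."""
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has non-standard letters {sorted(bad)}")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    idx_a: list[int] = []
    idx_b: list[int] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        idx_a.extend(range(sa, ea))
        idx_b.extend(range(sb, eb))
    corr = Correspondence.from_columns(idx_a, idx_b)
    if len(corr) == 0:
        identity = 0.0
    else:
        matches = sum(seq_a[i] == seq_b[j] for i, j in corr.pairs)
        identity = matches / len(corr)
    return AlignmentResult(corr=corr, seq_identity=identity, method="sequence",
                           score=float(aln.score))


@njit(cache=False)
def _dp_trace(S: np.ndarray, gap: float) -> np.ndarray:  # pragma: no cover - numba
    """Global DP over score matrix S with constant gap penalty.

    Returns a (K, 2) array of aligned index pairs.  Ties are broken toward the
    diagonal move so co-optimal paths prefer smaller |i - j|.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    T = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up (gap in b), 2 left
    for i in range(1, n + 1):
        H[i, 0] = -gap * i
        T[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = -gap * j
        T[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] - gap
            left = H[i, j - 1] - gap
            best = diag
            move = 0
            if up > best:
                best = up
                move = 1
            if left > best:
                best = left
                move = 2
            H[i, j] = best
            T[i, j] = move
    # traceback
    pairs = np.empty((min(n, m), 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        mv = T[i, j]
        if mv == 0 and i > 0 and j > 0:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return pairs[:k][::-1].copy()


def _threading_seeds(n: int, m: int, min_len: int = 8) -> list[Correspondence]:
    """Gapless threading offsets: align i in a to i - offset in b."""
    seeds = []
    min_len = min(min_len, n, m)
    offsets = range(-(m - min_len), n - min_len + 1)
    step = max(1, (n + m) // 24)
    chosen = list(offsets)[::step]
    if 0 not in chosen and -(m - min_len) <= 0 <= n - min_len:
        chosen.append(0)
    for off in chosen:
        lo_a = max(0, off)
        hi_a = min(n, m + off)
        if hi_a - lo_a < min_len:
            continue
        ia = np.arange(lo_a, hi_a)
        seeds.append(Correspondence.from_columns(ia, ia - off))
    return seeds


def structural_align(chain_a: ChainStructure, chain_b: ChainStructure,
                     max_iter: int = 30,
                     gap_penalty: float = STRUCT_GAP_PENALTY) -> AlignmentResult:
    """Sequence-independent structural alignment maximizing TM-score.

    The returned ``tm`` is normalized by the length of ``chain_a`` (the
    query/target by this package's convention); the returned transform maps
    ``chain_b`` coordinates into ``chain_a``'s frame, following
    :func:`~heterodock.superpose.tm_score`.
    """
    if len(chain_a) < 10 or len(chain_b) < 10:
        raise ValueError("structural alignment needs chains of >= 10 residues")
    A = chain_a.ca
    B = chain_b.ca
    n, m = len(A), len(B)
    L_norm = n
    d0v = d0(L_norm)
    d0_sq = d0v * d0v

    best_quick = -1.0
    best_corr: Optional[Correspondence] = None
    for seed in _threading_seeds(n, m):
        corr = seed
        prev_pairs = None
        quick = -1.0
        for _ in range(max_iter):
            if len(corr) < 3:
                break
            try:
                tf, _ = kabsch(A[corr.a], B[corr.b])
            except Exception:
                break
            At = A @ tf.rotation.T + tf.translation
            diff = At[:, None, :] - B[None, :, :]
            S = 1.0 / (1.0 + (diff ** 2).sum(axis=2) / d0_sq)
            quick = float(S[corr.a, corr.b].sum() / L_norm)
            pairs = _dp_trace(S, gap_penalty)
            if prev_pairs is not None and pairs.shape == prev_pairs.shape \
                    and np.array_equal(pairs, prev_pairs):
                break
            prev_pairs = pairs
            corr = Correspondence(pairs)
        if len(corr) == 0:
            continue
        # cheap one-superposition score ranks seeds; the full TM-score
        # optimization runs once, on the winner
        if quick > best_quick:
            best_quick = quick
            best_corr = corr
    if best_corr is None:
        raise ValueError("structural alignment found no correspondence")
    corr = best_corr
    best_tm, tf = tm_score(A, B, corr, L_norm)
    sa, sb = chain_a.sequence, chain_b.sequence
    matches = sum(sa[i] == sb[j] for i, j in corr.pairs)
    identity = matches / len(corr) if len(corr) else 0.0
    return AlignmentResult(corr=corr, seq_identity=identity, method="structure",
                           tm=best_tm, score=best_tm, transform=tf)


_HHR_LINE = re.compile(
    r"^\s*(\d+)\s+(\S+).*?(\d+\.\d+)\s+\S+\s+\S+\s+\S+\s+\S+\s+\d+\s+"
    r"(\d+)-(\d+)\s+(\d+)-(\d+)\s*\(?\d*\)?\s*$")


def read_hhr(path) -> list[dict]:
    """Parse HHsearch ``.hhr`` summary lines into hit records.

    Each record holds the template id, match probability, and 1-based query /
    template ranges; ranges are mapped positionally (gapless) into an
    :class:`AlignmentResult` with method ``sequence``.
    """
    records = []
    in_table = False
    for line in open(path):
        if line.lstrip().startswith("No Hit"):
            in_table = True
            continue
        if in_table:
            if not line.strip():
                break
            m = _HHR_LINE.match(line.rstrip())
            if not m:
                continue
            q0, q1 = int(m.group(4)) - 1, int(m.group(5))
            t0, t1 = int(m.group(6)) - 1, int(m.group(7))
            span = min(q1 - q0, t1 - t0)
            corr = Correspondence.from_columns(np.arange(q0, q0 + span),
                                               np.arange(t0, t0 + span))
            records.append({
                "rank": int(m.group(1)),
                "template_id": m.group(2),
                "probability": float(m.group(3)),
                "alignment": AlignmentResult(corr=corr, seq_identity=0.0,
                                             method="sequence",
                                             score=float(m.group(3))),
            })
    return records
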