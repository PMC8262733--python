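"""Synthetic structure generation: helices, bundles, dimers, decoy libraries.

These generators make every stage of the pipeline testable without external
structure downloads.  Geometries are CA-trace idealizations (α-helix with
1.5 Å rise / 100° twist / 2.3 Å radius; compact random bundles; extended
strands; random coils), with CB pseudo-atoms at a fixed radial offset.  They
emulate fold-level shape and packing, not side-chain chemistry or
Ramachandran statistics.

Every generator takes an explicit seed and owns its random generator, so all
outputs are bit-reproducible; decoy "unrelatedness" (TM-score < 0.4 to the
target subunits) is enforced by rejection sampling, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import AssemblyStructure, ChainStructure
from .template_db import TemplateEntry, TemplateLibrary, extract_interface

__all__ = ["FixtureSpec", "make_helix", "make_strand", "make_coil", "make_bundle",
           "make_chain", "make_dimer", "make_target_dimer", "perturb",
           "make_planted_library", "random_sequence"]

_HELIX_RISE = 1.5       # Å per residue along the axis
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å
_CB_OFFSET = 1.53       # Å, CA->CB distance

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic chain."""

    n_residues: int
    geometry: str = "helix"      # helix | strand | bundle | random_coil
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.geometry not in ("helix", "strand", "bundle", "random_coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def random_sequence(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AA20), size=n))


def _with_cb(ca: np.ndarray, axis_point: np.ndarray | None = None) -> np.ndarray:
    """CB pseudo-atoms at a fixed offset radially away from the local chain axis."""
    n = len(ca)
    if n == 1:
        return ca + np.array([_CB_OFFSET, 0.0, 0.0])
    center = ca.mean(axis=0) if axis_point is None else axis_point
    out = ca - center
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    return ca + _CB_OFFSET * out / norms


def _chain(ca: np.ndarray, sequence: str, chain_id: str) -> ChainStructure:
    cb = _with_cb(ca)
    cb = cb.copy()
    gly = np.array([s == "G" for s in sequence])
    cb[gly] = np.nan
    from .structio import _ONE_TO_THREE
    names = [_ONE_TO_THREE.get(s, "UNK") for s in sequence]
    return ChainStructure(chain_id, np.arange(1, len(ca) + 1), names, ca, cb)


def make_helix(n_residues: int, seed: int = 0, sequence: str | None = None,
               chain_id: str = "A") -> ChainStructure:
    """Ideal α-helix CA trace, poly-alanine unless a sequence is given.

    The first CA sits at the origin; consecutive CA–CA distances are ~3.8 Å.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    k = np.arange(n_residues)
    theta = np.deg2rad(_HELIX_TWIST) * k
    ca = np.column_stack([_HELIX_RADIUS * np.cos(theta),
                          _HELIX_RADIUS * np.sin(theta),
                          _HELIX_RISE * k])
    ca -= ca[0]
    seq = sequence if sequence is not None else "A" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length mismatch")
    return _chain(ca, seq, chain_id)


def make_strand(n_residues: int, seed: int = 0, sequence: str | None = None,
                chain_id: str = "A") -> ChainStructure:
    """Extended strand: 3.3 Å rise with a 1 Å pleat."""
    k = np.arange(n_residues)
    ca = np.column_stack([np.where(k % 2 == 0, 0.5, -0.5),
                          np.zeros(n_residues),
                          3.3 * k])
    seq = sequence if sequence is not None else "A" * n_residues
    return _chain(ca, seq, chain_id)


def make_coil(n_residues: int, seed: int = 0, sequence: str | None = None,
              chain_id: str = "A") -> ChainStructure:
    """Random walk with fixed 3.8 Å steps and mild directional persistence."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3)) if n_residues > 1 else np.zeros((0, 3))
    # persistence: blend each step with the previous direction
    for i in range(1, len(steps)):
        steps[i] = 0.5 * steps[i - 1] + steps[i]
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    ca = np.vstack([np.zeros(3), np.cumsum(3.8 * steps / norms, axis=0)])
    seq = sequence if sequence is not None else random_sequence(n_residues, seed)
    return _chain(ca, seq, chain_id)


def make_bundle(n_residues: int, seed: int = 0, sequence: str | None = None,
                chain_id: str = "A", n_segments: int = 3) -> ChainStructure:
    """Compact bundle of randomly oriented helical segments joined by linkers.

    A cheap stand-in for a folded globular chain: distinct seeds give
    structurally unrelated compact folds.
    """
    rng = np.random.default_rng(seed)
    seg_len = max(6, n_residues // n_segments)
    coords: list[np.ndarray] = []
    pos = np.zeros(3)
    remaining = n_residues
    while remaining > 0:
        length = min(seg_len, remaining)
        k = np.arange(length)
        theta = np.deg2rad(_HELIX_TWIST) * k
        seg = np.column_stack([_HELIX_RADIUS * np.cos(theta),
                               _HELIX_RADIUS * np.sin(theta),
                               _HELIX_RISE * k])
        seg -= seg[0]
        # random orientation per segment
        M = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(M)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        seg = seg @ Q.T
        if coords:
            # step from the previous terminus toward the bundle core
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = coords[-1][-1] + 3.8 * direction
        seg = seg + pos - seg[0]
        coords.append(seg)
        remaining -= length
    ca = np.vstack(coords)[:n_residues]
    # compact toward the centroid to increase contact density
    centroid = ca.mean(axis=0)
    ca = centroid + (ca - centroid) * 0.9
    seq = sequence if sequence is not None else random_sequence(n_residues, seed)
    return _chain(ca, seq, chain_id)


_GEOMETRY_MAKERS = {
    "helix": make_helix,
    "strand": make_strand,
    "random_coil": make_coil,
    "bundle": make_bundle,
}


def make_chain(spec: FixtureSpec, chain_id: str = "A") -> ChainStructure:
    """Build a chain from a :class:`FixtureSpec` (geometry + optional noise)."""
    chain = _GEOMETRY_MAKERS[spec.geometry](spec.n_residues, seed=spec.seed,
                                            chain_id=chain_id)
    if spec.noise_sigma > 0:
        asm = perturb(AssemblyStructure(chains=[chain], source_id="fixture"),
                      spec.noise_sigma, spec.seed + 1)
        chain = asm.chains[0]
    return chain


def _principal_orient(chain: ChainStructure) -> ChainStructure:
    """Center a chain and rotate its principal axes onto (z, y, x).

    Eigenvector signs are fixed deterministically (largest component made
    positive) and the rotation is made proper, so the result is reproducible.
    """
    ca = chain.ca
    if len(ca) < 3:
        return chain.transformed(np.eye(3), -ca.mean(axis=0))
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)          # ascending eigenvalues
    axes = v[:, ::-1]                   # columns: major, middle, minor
    for k in range(3):
        j = int(np.argmax(np.abs(axes[:, k])))
        if axes[j, k] < 0:
            axes[:, k] = -axes[:, k]
    # rows of R map major->z, middle->y, minor->x
    R = np.vstack([axes[:, 2], axes[:, 1], axes[:, 0]])
    if np.linalg.det(R) < 0:
        R[0] = -R[0]
    return chain.transformed(np.eye(3), -ca.mean(axis=0)).transformed(R, np.zeros(3))


def make_dimer(chain_a: ChainStructure, chain_b: ChainStructure,
               axis_separation: float, relative_rotation: float = 0.0,
               seed: int = 0, source_id: str = "dimer",
               resolution: float | None = 2.0) -> AssemblyStructure:
    """Place ``chain_b`` beside ``chain_a`` at a given separation/orientation.

    Each chain is centered and pre-oriented with its longest principal axis
    along z, so the two chains pack side-by-side along their length (a broad,
    dimer-like interface rather than a point contact).  B is additionally
    rotated about the z axis by ``relative_rotation`` degrees, then
    translated along x so that the MINIMAL inter-chain CA–CA distance equals
    ``axis_separation`` (a gap semantics robust to arbitrary chain shapes).
    A small deterministic tilt search on B then maximizes the inter-chain
    contact count at that gap, emulating the shape complementarity of a real
    docked interface.  Deterministic given its inputs.
    """
    if len(chain_a) == 0 or len(chain_b) == 0:
        raise ValueError("chains must be non-empty")
    if axis_separation <= 0:
        raise ValueError("axis_separation must be positive")
    a = _principal_orient(chain_a)
    theta = np.deg2rad(relative_rotation)
    Rz = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                   [np.sin(theta), np.cos(theta), 0.0],
                   [0.0, 0.0, 1.0]])
    b_centered = _principal_orient(chain_b)

    def dock(b_ca: np.ndarray) -> tuple[float, int]:
        """Translate along x to the requested gap; return (t, contact count)."""
        def min_gap(t: float) -> float:
            d = np.linalg.norm(a.ca[:, None, :] - (b_ca + [t, 0.0, 0.0])[None, :, :],
                               axis=2)
            return float(d.min())

        hi = (np.linalg.norm(a.ca, axis=1).max()
              + np.linalg.norm(b_ca, axis=1).max() + axis_separation + 1.0)
        lo = 0.0
        if min_gap(lo) >= axis_separation:
            t_star = lo
        else:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if min_gap(mid) < axis_separation:
                    lo = mid
                else:
                    hi = mid
            t_star = hi
        d = np.linalg.norm(a.ca[:, None, :] - (b_ca + [t_star, 0.0, 0.0])[None, :, :],
                           axis=2)
        return t_star, int((d < 8.0).sum())

    def tilt(ry: float, rz: float) -> np.ndarray:
        cy, sy = np.cos(np.deg2rad(ry)), np.sin(np.deg2rad(ry))
        cz, sz = np.cos(np.deg2rad(rz)), np.sin(np.deg2rad(rz))
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz2 = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Ry @ Rz2

    best = None
    for ry in (-8.0, -4.0, 0.0, 4.0, 8.0):
        for rz in (-8.0, -4.0, 0.0, 4.0, 8.0):
            Rt = tilt(ry, rz) @ Rz
            t_star, n_contacts = dock(b_centered.ca @ Rt.T)
            if best is None or n_contacts > best[0]:
                best = (n_contacts, Rt, t_star)
    assert best is not None
    _, Rt, t_star = best
    b = b_centered.transformed(Rt, np.array([t_star, 0.0, 0.0]))
    a.chain_id, b.chain_id = "A", "B"
    return AssemblyStructure(chains=[a, b], resolution=resolution,
                             source_id=source_id)


def make_target_dimer(n_residues: int = 40, seed: int = 0, gap: float = 4.2,
                      max_attempts: int = 18) -> AssemblyStructure:
    """A benchmark native heterodimer guaranteed to be physically plausible.

    Generates two random bundle subunits and docks them at the given gap and
    a seed-derived rotation; if the resulting native fails the pipeline's
    default physical filters (clashes, contacts, buried area) — which can
    happen for awkwardly convex random shapes — the docking angle is advanced
    deterministically in 20° steps until a plausible complex results.  A
    native that the field's own plausibility criteria would reject is not a
    valid docking target, so validity is enforced here rather than assumed.
    """
    from .assemble import ComplexModel, FilterThresholds, apply_filters

    rng = np.random.default_rng(seed)
    seed_a = int(rng.integers(2 ** 31))
    seed_b = int(rng.integers(2 ** 31))
    base_rot = float(rng.uniform(0.0, 360.0))
    a = make_bundle(n_residues, seed=seed_a, chain_id="A")
    b = make_bundle(n_residues, seed=seed_b, chain_id="B")
    for k in range(max_attempts):
        dimer = make_dimer(a, b, gap,
                           relative_rotation=(base_rot + 20.0 * k) % 360.0,
                           source_id="target")
        model = ComplexModel(chain_a=dimer.chains[0], chain_b=dimer.chains[1])
        if apply_filters([model], FilterThresholds()):
            return dimer
    raise RuntimeError("no physically plausible docking pose found")


def perturb(structure: AssemblyStructure, noise_sigma: float, seed: int = 0
            ) -> AssemblyStructure:
    """Independent Gaussian displacement (std per coordinate) on every atom."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    chains = []
    for c in structure.chains:
        ca = c.ca + rng.normal(scale=noise_sigma, size=c.ca.shape) if noise_sigma > 0 else c.ca.copy()
        cb = c.cb.copy()
        mask = c.has_cb()
        if noise_sigma > 0:
            cb[mask] = cb[mask] + rng.normal(scale=noise_sigma, size=cb[mask].shape)
        chains.append(ChainStructure(c.chain_id, c.res_numbers.copy(),
                                     list(c.res_names), ca, cb, meta=dict(c.meta)))
    return AssemblyStructure(chains=chains, resolution=structure.resolution,
                             source_id=structure.source_id)


def make_planted_library(target_dimer: AssemblyStructure, n_decoys: int,
                         seed: int = 0, plant_sigma: float = 0.3,
                         decoy_tm_max: float = 0.4, max_attempts: int = 50
                         ) -> TemplateLibrary:
    """A DB-Het library hiding a perturbed copy of the target among decoys.

    The plant is the target dimer perturbed at ``plant_sigma`` Å under a
    scrambled source id; decoys are random bundle heterodimers whose chains
    are verified (by structural alignment, with regeneration on failure) to
    have TM-score < ``decoy_tm_max`` to both target subunits.
    """
    from .align import structural_align

    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    target_a, target_b = target_dimer.chains[0], target_dimer.chains[1]

    entries: list[TemplateEntry] = []
    plant = perturb(target_dimer, plant_sigma, seed=int(rng.integers(2 ** 31)))
    scramble = "".join(rng.choice(list("0123456789ABCDEF"), size=6))
    if1, if2 = extract_interface(plant.chains[0], plant.chains[1])
    entries.append(TemplateEntry(source_id=f"T{scramble}", entry_kind="heterodimer",
                                 part1=plant.chains[0], part2=plant.chains[1],
                                 interface1=if1, interface2=if2, resolution=2.0))

    def unrelated(chain: ChainStructure) -> bool:
        for target in (target_a, target_b):
            if structural_align(target, chain).tm >= decoy_tm_max:
                return False
        return True

    for k in range(n_decoys):
        for attempt in range(max_attempts):
            s1 = int(rng.integers(2 ** 31))
            s2 = int(rng.integers(2 ** 31))
            na = int(rng.integers(max(12, len(target_a) - 10), len(target_a) + 11))
            nb = int(rng.integers(max(12, len(target_b) - 10), len(target_b) + 11))
            ca_chain = make_bundle(na, seed=s1, chain_id="A")
            cb_chain = make_bundle(nb, seed=s2, chain_id="B")
            dimer = make_dimer(ca_chain, cb_chain,
                               axis_separation=float(rng.uniform(4.2, 5.5)),
                               relative_rotation=float(rng.uniform(0, 360)),
                               source_id=f"D{k:03d}")
            d1, d2 = extract_interface(dimer.chains[0], dimer.chains[1])
            if not d1 or not d2:
                continue
            if unrelated(dimer.chains[0]) and unrelated(dimer.chains[1]):
                entries.append(TemplateEntry(
                    source_id=f"D{k:03d}", entry_kind="heterodimer",
                    part1=dimer.chains[0], part2=dimer.chains[1],
                    interface1=d1, interface2=d2, resolution=2.5))
                break
        else:
            raise RuntimeError(f"could not generate an unrelated decoy {k}")
    # plant is shuffled into the list so rank-1 recovery is non-trivial
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    return TemplateLibrary(entries=entries, kind="DB_Het",
                           build_params={"planted": True, "n_decoys": n_decoys,
                                         "plant_sigma": plant_sigma, "seed": seed})
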