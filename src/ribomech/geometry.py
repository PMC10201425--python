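"""Geometric trajectory analysis for the ribozyme active site.

Implements the two difference-of-distances reaction coordinates

    ξ_PT = |R(C10:N3) − R(H)| − |R(O6mG:N1) − R(H)|
    ξ_MT = |R(O6mG:O6) − R(Cm)| − |R(A63:N1) − R(Cm)|

(proton transfer and methyl transfer progress, Å), the inline-fitness score
of catalytically competent frames (nucleophile–electrophile distance and
attack angle θ_inl inside a box), Kabsch-superposed RMSD, per-nucleotide
atomic fluctuations with the isotropic B-value convention
B = (8π²/3)·⟨Δr²⟩, and a geometric hydrogen-bond occupancy measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import AtomMap, Frame, Trajectory

B_FACTOR = 8.0 * math.pi**2 / 3.0  # B = B_FACTOR * <Δr²>, isotropic convention


@dataclass(frozen=True)
class ReactionCoordinatePair:
    """(ξ_PT, ξ_MT) in Å for one frame."""

    xi_pt: float
    xi_mt: float

    def __iter__(self):
        yield self.xi_pt
        yield self.xi_mt


@dataclass(frozen=True)
class InlineFitnessCriteria:
    """Catalytic-competence box: distance window (Å) and attack-angle window (deg).

    Defaults are the standard inline-fitness heuristic for nucleophilic
    attack: nucleophile–electrophile distance between 2.75 and 3.50 Å and
    θ_inl between 140° and 180°.
    """

    dist_min: float = 2.75
    dist_max: float = 3.50
    angle_min: float = 140.0
    angle_max: float = 180.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dist_min < self.dist_max):
            raise ValueError("need 0 < dist_min < dist_max")
        if not (0.0 <= self.angle_min < self.angle_max <= 180.0):
            raise ValueError("need 0 <= angle_min < angle_max <= 180")


@dataclass
class FitnessResult:
    """Per-frame graded scores, the binary in-box flags and their fraction."""

    scores: np.ndarray
    in_box: np.ndarray
    fraction: float
    distances: np.ndarray
    angles: np.ndarray


@dataclass
class FluctuationProfile:
    """Per-residue fluctuations ⟨σ_i⟩ (Å) and isotropic B-values (Å²).

    ``convention`` records the B↔σ relation used so downstream consumers
    never have to guess the factor-of-3 convention.
    """

    residue_ids: np.ndarray
    sigma: np.ndarray
    bvalues: np.ndarray
    correlation: float | None = None
    convention: str = "B = (8*pi^2/3) * <dr^2>, <dr^2> = sigma^2 (full 3D)"


def sigma_to_bvalue(sigma: np.ndarray | float) -> np.ndarray | float:
    """Convert RMS 3D displacement σ (Å) to an isotropic B-value (Å²)."""
    return B_FACTOR * np.square(sigma)


def bvalue_to_sigma(b: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`sigma_to_bvalue`; round-trips exactly."""
    return np.sqrt(np.asarray(b, dtype=float) / B_FACTOR)


def _angle_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle a–apex–b in degrees, vectorized over leading axes."""
    u = a - apex
    v = b - apex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def reaction_coordinates(frame: Frame, amap: AtomMap) -> ReactionCoordinatePair:
    """Proton- and methyl-transfer progress variables for one frame."""
    idx = amap.resolve(frame.topology)
    c = frame.coords
    n3, h, n1g, o6, cm, n1a = (
        c[idx["C10:N3"]],
        c[idx["H(N3)"]],
        c[idx["O6mG:N1"]],
        c[idx["O6mG:O6"]],
        c[idx["Cm"]],
        c[idx["A63:N1"]],
    )
    xi_pt = float(np.linalg.norm(n3 - h) - np.linalg.norm(n1g - h))
    xi_mt = float(np.linalg.norm(o6 - cm) - np.linalg.norm(n1a - cm))
    return ReactionCoordinatePair(xi_pt, xi_mt)


def trajectory_reaction_coordinates(traj: Trajectory, amap: AtomMap) -> np.ndarray:
    """(n_frames, 2) array of (ξ_PT, ξ_MT)."""
    idx = amap.resolve(traj.topology)
    c = traj.coords
    n3 = c[:, idx["C10:N3"]]
    h = c[:, idx["H(N3)"]]
    n1g = c[:, idx["O6mG:N1"]]
    o6 = c[:, idx["O6mG:O6"]]
    cm = c[:, idx["Cm"]]
    n1a = c[:, idx["A63:N1"]]
    xi_pt = np.linalg.norm(n3 - h, axis=1) - np.linalg.norm(n1g - h, axis=1)
    xi_mt = np.linalg.norm(o6 - cm, axis=1) - np.linalg.norm(n1a - cm, axis=1)
    return np.column_stack([xi_pt, xi_mt])


def inline_fitness(
    traj: Trajectory,
    amap: AtomMap,
    criteria: InlineFitnessCriteria | None = None,
) -> FitnessResult:
    """Score catalytic competence of every frame.

    A frame is "in the box" when the Cm–A63:N1 distance lies in
    [dist_min, dist_max] and the O6mG:O6–Cm–A63:N1 attack angle in
    [angle_min, angle_max]. Inside the box the graded score is the product
    of two linear ramps (shorter distance and straighter angle are fitter),
    clipped to [0, 1]; outside it is 0. The reported ``fraction`` is the
    binary in-box frame fraction.
    """
    if criteria is None:
        criteria = InlineFitnessCriteria()
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    idx = amap.resolve(traj.topology)
    cm = traj.coords[:, idx["Cm"]]
    o6 = traj.coords[:, idx["O6mG:O6"]]
    n1a = traj.coords[:, idx["A63:N1"]]
    dist = np.linalg.norm(n1a - cm, axis=1)
    ang = _angle_deg(o6, cm, n1a)

    in_box = (
        (dist >= criteria.dist_min)
        & (dist <= criteria.dist_max)
        & (ang >= criteria.angle_min)
        & (ang <= criteria.angle_max)
    )
    ramp_d = (criteria.dist_max - dist) / (criteria.dist_max - criteria.dist_min)
    ramp_a = (ang - criteria.angle_min) / (criteria.angle_max - criteria.angle_min)
    scores = np.clip(ramp_d, 0.0, 1.0) * np.clip(ramp_a, 0.0, 1.0)
    scores = np.where(in_box, scores, 0.0)
    return FitnessResult(
        scores=scores,
        in_box=in_box,
        fraction=float(in_box.mean()),
        distances=dist,
        angles=ang,
    )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix, translation) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("mismatched atom counts for superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    rmat = rot.as_matrix()
    return rmat, tc - mc @ rmat.T


def heavy_atom_rmsd(
    frame_a: Frame,
    frame_b: Frame,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> float:
    """RMSD (Å) between two frames over a selection (default: heavy atoms).

    With ``superpose`` the optimal least-squares rigid superposition is
    applied to ``frame_b`` first; otherwise raw coordinates are compared.
    """
    if selection is None:
        selection = frame_a.topology.heavy_mask()
    a = frame_a.coords[selection]
    b = frame_b.coords[selection]
    if a.shape != b.shape:
        raise ValueError(f"mismatched selections: {a.shape} vs {b.shape}")
    if superpose:
        rmat, t = kabsch(b, a)
        b = b @ rmat.T + t
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_trajectory(
    traj: Trajectory, reference: Frame, selection: np.ndarray | None = None
) -> Trajectory:
    """Return a copy with every frame Kabsch-superposed onto the reference."""
    if selection is None:
        selection = traj.topology.heavy_mask()
    out = np.empty_like(traj.coords)
    ref = reference.coords[selection]
    for i in range(traj.n_frames):
        rmat, t = kabsch(traj.coords[i][selection], ref)
        out[i] = traj.coords[i] @ rmat.T + t
    return Trajectory(traj.topology, out, bfactors=traj.bfactors)


def atomic_fluctuations(
    traj: Trajectory,
    reference: Frame | str = "mean_structure",
    reference_bvalues: np.ndarray | None = None,
    heavy_only: bool = True,
    presuperpose: bool = True,
) -> FluctuationProfile:
    """Per-residue RMS fluctuations and isotropic B-values.

    Frames are globally superposed to the reference (the mean structure by
    default), per-atom σ is the RMS 3D deviation from the reference
    position, and the per-residue value averages σ over heavy atoms. When
    per-atom reference B-values are supplied their per-residue means are
    correlated (Pearson) with the computed B-values.
    """
    if traj.n_frames < 2:
        raise ValueError("fluctuations need at least 2 frames")
    if isinstance(reference, str):
        if reference != "mean_structure":
            raise ValueError(f"unknown reference policy {reference!r}")
        ref = Frame(traj.topology, traj.coords.mean(axis=0))
        # iterate once: superpose to the provisional mean, then re-average
        if presuperpose:
            traj = superpose_trajectory(traj, ref)
            ref = Frame(traj.topology, traj.coords.mean(axis=0))
    else:
        ref = reference
        if presuperpose:
            traj = superpose_trajectory(traj, ref)

    dr2 = np.mean(np.sum((traj.coords - ref.coords) ** 2, axis=2), axis=0)
    sigma_atom = np.sqrt(dr2)

    mask = traj.topology.heavy_mask() if heavy_only else np.ones(traj.n_atoms, bool)
    resids = traj.topology.residue_ids
    uniq = np.unique(resids[mask])
    sigma_res = np.empty(uniq.size)
    for j, rid in enumerate(uniq):
        sel = mask & (resids == rid)
        sigma_res[j] = sigma_atom[sel].mean()
    bvals = sigma_to_bvalue(sigma_res)

    corr: float | None = None
    if reference_bvalues is not None:
        reference_bvalues = np.asarray(reference_bvalues, dtype=float)
        if reference_bvalues.shape == (traj.n_atoms,):
            ref_res = np.array(
                [reference_bvalues[mask & (resids == rid)].mean() for rid in uniq]
            )
        elif reference_bvalues.shape == (uniq.size,):
            ref_res = reference_bvalues
        else:
            raise ValueError("reference_bvalues must be per-atom or per-residue")
        corr = float(np.corrcoef(bvals, ref_res)[0, 1])

    return FluctuationProfile(
        residue_ids=uniq, sigma=sigma_res, bvalues=np.asarray(bvals), correlation=corr
    )


def hbond_occupancy(
    traj: Trajectory,
    triples: list[tuple[tuple[int, str], tuple[int, str], tuple[int, str]]],
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 135.0,
) -> np.ndarray:
    """Fraction of frames each (donor, hydrogen, acceptor) triple is bonded.

    A frame counts as bonded when the donor–acceptor distance is ≤
    ``dist_cutoff`` Å and the donor–H–acceptor angle is ≥ ``angle_cutoff``
    degrees. Triples address atoms as (residue_id, atom_name); the hydrogen
    entry is mandatory.
    """
    if dist_cutoff <= 0 or angle_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    fractions = np.empty(len(triples))
    for k, (don, hyd, acc) in enumerate(triples):
        try:
            hi = traj.topology.find(*hyd)
        except Exception as exc:
            raise ValueError(f"missing hydrogen {hyd} for donor {don}") from exc
        di = traj.topology.find(*don)
        ai = traj.topology.find(*acc)
        d = traj.coords[:, di]
        h = traj.coords[:, hi]
        a = traj.coords[:, ai]
        dist = np.linalg.norm(a - d, axis=1)
        ang = _angle_deg(d, h, a)
        fractions[k] = float(((dist <= dist_cutoff) & (ang >= angle_cutoff)).mean())
    return fractions
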