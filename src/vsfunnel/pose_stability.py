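"""Binding-pose stability scores from replicate trajectories.

Given a protein–ligand complex, a reference (starting) pose, and a set of
replicate trajectories, this module computes:

* per-replicate ligand heavy-atom RMSD series — each frame is rigidly
  superposed onto the reference using binding-site protein atoms only, then
  the ligand RMSD is measured *without* re-fitting the ligand, so genuine
  ligand drift within the pocket is not aligned away;
* **PoseScore** — the mean ligand RMSD from the starting pose over all
  frames of all replicates (Å; lower = more stable pose);
* **PersScore** — the fraction of the reference-pose protein–ligand
  hydrogen bonds still present in the final window (default 2 ns) of the
  simulations, pooled over (bond, frame) pairs across replicates; in [0, 1],
  higher = interactions preserved.

The simulations themselves (metadynamics/MD engines, solvation, heating)
are upstream; trajectories enter as data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (boundaries inclusive).

    ``distance_cutoff``: donor–acceptor heavy-atom distance in Å;
    ``angle_cutoff``: donor–H–acceptor angle in degrees.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 120.0

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class Topology:
    """Atom metadata and role masks shared by all replicates.

    ``donor_h``: mapping donor index -> attached polar-H index.  Roles are
    boolean masks over atoms: ``protein``, ``ligand_heavy``, ``donor``,
    ``acceptor``; an optional ``calpha`` mask marks protein Cα atoms for
    binding-site superposition.
    """

    names: tuple
    elements: tuple
    protein: np.ndarray
    ligand_heavy: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    donor_h: dict
    calpha: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def validate(self) -> None:
        for d in np.flatnonzero(self.donor):
            if int(d) not in self.donor_h:
                raise ValueError(f"donor atom {d} has no attached hydrogen in topology")


@dataclass
class TrajectorySet:
    """Reference pose plus replicate frame series for one complex."""

    topology: Topology
    reference: np.ndarray            # (n_atoms, 3) Å
    replicates: list                 # list of (n_frames, n_atoms, 3)
    times: list                      # list of (n_frames,) ns

    def validate(self) -> None:
        n = self.topology.n_atoms
        if self.reference.shape != (n, 3) or not np.isfinite(self.reference).all():
            raise ValueError("bad reference coordinates")
        if not self.replicates:
            raise ValueError("no replicates")
        for coords, t in zip(self.replicates, self.times):
            if coords.ndim != 3 or coords.shape[1:] != (n, 3):
                raise ValueError("replicate does not match topology")
            if coords.shape[0] < 1 or coords.shape[0] != len(t):
                raise ValueError("frame/time length mismatch")
            if not np.isfinite(coords).all():
                raise ValueError("non-finite coordinates")


@dataclass
class PoseStabilityResult:
    label: str
    pose_score: float
    pers_score: float
    rmsd_series: list            # list of (times, rmsd) pairs per replicate
    initial_hbonds: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "pose_score": self.pose_score,
                "pers_score": self.pers_score,
                "initial_hbonds": [list(b) for b in self.initial_hbonds],
                "rmsd_series": [
                    {"time_ns": list(map(float, t)), "rmsd_A": list(map(float, r))}
                    for t, r in self.rmsd_series
                ],
            },
            indent=1,
        )


def kabsch_superpose(
    ref: np.ndarray, mobile: np.ndarray, fit_mask: np.ndarray | None = None
) -> tuple[tuple, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    The optimal proper rotation (det = +1) and translation are computed on
    the masked atoms and applied to *all* atoms.  Returns
    ``((rotation, translation), fitted_coords)``.  Raises on a degenerate
    (collinear or < 3 atoms) fit mask.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape:
        raise ValueError("coordinate shape mismatch")
    mask = np.ones(len(ref), dtype=bool) if fit_mask is None else np.asarray(fit_mask, bool)
    r = ref[mask]
    m = mobile[mask]
    if len(r) < 3:
        raise ValueError("need >= 3 fit atoms")
    r0 = r - r.mean(axis=0)
    if np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit mask")
    m0 = m - m.mean(axis=0)
    C = m0.T @ r0
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = r.mean(axis=0) - m.mean(axis=0) @ R
    fitted = mobile @ R + t
    return (R, t), fitted


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def binding_site_mask(top: Topology, reference: np.ndarray, radius: float = 8.0) -> np.ndarray:
    """Protein atoms used for superposition: Cα within ``radius`` Å of the
    ligand in the reference pose; falls back to all protein atoms when no
    Cα labels exist or fewer than 3 qualify."""
    lig = reference[top.ligand_heavy]
    candidates = top.calpha if top.calpha is not None and top.calpha.any() else top.protein
    cand_idx = np.flatnonzero(candidates)
    d = np.linalg.norm(reference[cand_idx][:, None, :] - lig[None, :, :], axis=2).min(axis=1)
    near = cand_idx[d <= radius]
    mask = np.zeros(top.n_atoms, dtype=bool)
    if len(near) >= 3:
        mask[near] = True
    else:
        mask[top.protein] = True
    return mask


def ligand_rmsd_series(
    ts: TrajectorySet, replicate: int, fit_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(time ns, ligand heavy-atom RMSD Å) for one replicate.

    Frames are superposed on the binding-site protein mask; the ligand RMSD
    against the reference pose is then computed without further fitting.
    """
    ts.validate()
    top = ts.topology
    if not top.ligand_heavy.any():
        raise ValueError("empty ligand-heavy mask")
    mask = binding_site_mask(top, ts.reference) if fit_mask is None else fit_mask
    coords = ts.replicates[replicate]
    lig = top.ligand_heavy
    out = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        _, fitted = kabsch_superpose(ts.reference, coords[f], mask)
        out[f] = rmsd(fitted[lig], ts.reference[lig])
    return np.asarray(ts.times[replicate], float), out


def pose_score(ts: TrajectorySet, fit_mask: np.ndarray | None = None) -> float:
    """Mean ligand RMSD from the starting pose over all frames and replicates (Å)."""
    ts.validate()
    all_rmsd = [ligand_rmsd_series(ts, i, fit_mask)[1] for i in range(len(ts.replicates))]
    return float(np.mean(np.concatenate(all_rmsd)))


def detect_hbonds(
    coords: np.ndarray, top: Topology, criteria: HBondCriteria = HBondCriteria()
) -> set:
    """Hydrogen bonds in one frame as (donor, H, acceptor) index triples.

    A triple qualifies when the donor–acceptor distance is at or below the
    cutoff AND the donor–H–acceptor angle is at or above the angle cutoff
    (both boundaries inclusive).  Self-bonds (donor == acceptor) are skipped.
    """
    top.validate()
    donors = np.flatnonzero(top.donor)
    acceptors = np.flatnonzero(top.acceptor)
    found = set()
    if len(donors) == 0 or len(acceptors) == 0:
        return found
    for d in donors:
        h = top.donor_h[int(d)]
        dvec = coords[acceptors] - coords[d]
        dist = np.linalg.norm(dvec, axis=1)
        for a, dist_da in zip(acceptors, dist):
            if a == d or dist_da > criteria.distance_cutoff + 1e-12:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if angle >= criteria.angle_cutoff - 1e-9:
                found.add((int(d), int(h), int(a)))
    return found


def _interface_bonds(bonds: set, top: Topology) -> set:
    """Keep protein–ligand bonds only (one side protein, other side ligand)."""
    lig = set(np.flatnonzero(top.ligand_heavy))
    prot = set(np.flatnonzero(top.protein))
    out = set()
    for d, h, a in bonds:
        if (d in prot and a in lig) or (d in lig and a in prot):
            out.add((d, h, a))
    return out


def pers_score(
    ts: TrajectorySet,
    criteria: HBondCriteria = HBondCriteria(),
    final_window: float = 2.0,
    pooled: bool = True,
) -> float:
    """Persistence of the starting pose's protein–ligand hydrogen bonds.

    The initial bond set is detected in the reference pose; over the frames
    of the final ``final_window`` ns of each replicate, the score is the
    fraction of (initial bond, frame) pairs where the bond is present.
    ``pooled=False`` averages per-replicate fractions instead.  Raises when
    the reference pose has no protein–ligand hydrogen bonds, or the window
    exceeds a replicate's time span.
    """
    ts.validate()
    top = ts.topology
    initial = _interface_bonds(detect_hbonds(ts.reference, top, criteria), top)
    if not initial:
        raise ValueError("no protein-ligand hydrogen bonds in the reference pose")
    fractions = []
    hits = 0
    total = 0
    for coords, t in zip(ts.replicates, ts.times):
        t = np.asarray(t, float)
        t_end = t[-1]
        if final_window > t_end - t[0] + 1e-9:
            raise ValueError("final window longer than the trajectory")
        sel = np.flatnonzero(t >= t_end - final_window + 1e-12)
        rep_hits = 0
        for f in sel:
            present = detect_hbonds(coords[f], top, criteria)
            rep_hits += len(initial & present)
        rep_total = len(sel) * len(initial)
        hits += rep_hits
        total += rep_total
        fractions.append(rep_hits / rep_total if rep_total else 0.0)
    score = hits / total if pooled else float(np.mean(fractions))
    assert 0.0 <= score <= 1.0
    return float(score)


def evaluate_pose(
    label: str,
    ts: TrajectorySet,
    criteria: HBondCriteria = HBondCriteria(),
    final_window: float = 2.0,
) -> PoseStabilityResult:
    """PoseScore + PersScore + RMSD series for one candidate pose."""
    series = [ligand_rmsd_series(ts, i) for i in range(len(ts.replicates))]
    initial = sorted(
        _interface_bonds(detect_hbonds(ts.reference, ts.topology, criteria), ts.topology)
    )
    return PoseStabilityResult(
        label=label,
        pose_score=pose_score(ts),
        pers_score=pers_score(ts, criteria, final_window),
        rmsd_series=series,
        initial_hbonds=initial,
    )


def select_stable_pose(candidates: Sequence[tuple]) -> tuple[str, list]:
    """Pick the most stable pose among (label, PoseStabilityResult) pairs.

    Ranking: ascending PoseScore, ties by descending PersScore, then label.
    Returns (best label, full ranking).
    """
    if not candidates:
        raise ValueError("no candidates")
    ranking = sorted(
        candidates, key=lambda kv: (kv[1].pose_score, -kv[1].pers_score, kv[0])
    )
    return ranking[0][0], ranking


# --- File I/O: multi-model PDB trajectories with a JSON role sidecar -------

def load_trajectory_set(
    topology_pdb: str | Path,
    trajectory_pdbs: Sequence[str | Path],
    reference_pdb: str | Path,
    roles_json: str | Path,
    dt_ns: float = 0.1,
) -> TrajectorySet:
    """Assemble a TrajectorySet from multi-model PDB files.

    ``roles_json`` carries the atom-role masks (indices for protein, ligand
    heavy atoms, donors, acceptors, the donor->H map, and optional Cα list),
    which PDB files cannot express reliably.  Frame times are ``i * dt_ns``.
    """
    import logging as _logging
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    _logging.getLogger("MDAnalysis").setLevel(_logging.WARNING)

    roles = json.loads(Path(roles_json).read_text())
    u = mda.Universe(str(topology_pdb))
    n = len(u.atoms)

    def mask(key):
        m = np.zeros(n, dtype=bool)
        m[np.asarray(roles.get(key, []), dtype=int)] = True
        return m

    top = Topology(
        names=tuple(u.atoms.names),
        elements=tuple(getattr(u.atoms, "elements", ["X"] * n)),
        protein=mask("protein"),
        ligand_heavy=mask("ligand_heavy"),
        donor=mask("donor"),
        acceptor=mask("acceptor"),
        donor_h={int(k): int(v) for k, v in roles.get("donor_h", {}).items()},
        calpha=mask("calpha") if "calpha" in roles else None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref_u = mda.Universe(str(reference_pdb))
        reference = ref_u.atoms.positions.astype(float)
        replicates, times = [], []
        for p in trajectory_pdbs:
            tu = mda.Universe(str(topology_pdb), str(p))
            frames = np.array(
                [tu.atoms.positions.copy() for _ in tu.trajectory], dtype=float
            )
            replicates.append(frames)
            times.append((np.arange(frames.shape[0]) + 1) * dt_ns)
    ts = TrajectorySet(topology=top, reference=reference, replicates=replicates, times=times)
    ts.validate()
    return ts
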