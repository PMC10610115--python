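"""Seeded generators for every fixture the screening pipeline consumes.

These generators stand in for data that is normally external: a drug-like
molecule library with planted descriptor-linear activity labels, staged
docking score tables with controlled quantiles and rank correlation,
replicate protein–ligand trajectories with controlled ligand drift and
scheduled hydrogen-bond occupancy, and noisy 4PL dose-response curves.

Every generator is a pure function of its spec and seed: the same inputs
give byte-identical outputs.  Molecules are assembled from a fragment
grammar (ring cores, linkers, decorations) so every generated SMILES parses
and survives standardization unchanged; hydrogen-bond occupancy schedules
are deterministic frame masks, so persistence targets are hit exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .assay_analysis import DEFAULT_DOSES_NM, DoseResponseCurve, FourPLParams, four_pl_response
from .chem_io import MoleculeRecord, compute_descriptors
from .pose_stability import Topology, TrajectorySet

# --- molecule library -------------------------------------------------------

# Outer cores carry one decoration slot {d} and one attachment slot {s};
# inner cores (ring index 2) carry a terminal decoration {d}.
_CORES_OUTER = (
    "c1cc({d})cc({s})c1",     # benzene, meta pattern
    "c1c({d})ccc({s})c1",     # benzene, para pattern
    "c1nc({d})cc({s})c1",     # pyridine
    "c1nc({d})nc({s})c1",     # pyrimidine
    "c1cc({d})c({s})s1",      # thiophene
    "C1CC({d})CC({s})C1",     # cyclohexane
)
_CORES_INNER = (
    "c2ccc({d})cc2",          # benzene
    "c2ccnc({d})c2",          # pyridine
    "c2csc({d})n2",           # thiazole
    "c2ccc({d})s2",           # thiophene
    "c2cnc({d})cn2",          # pyrazine
    "C2CCN({d})CC2",          # piperidine (N-substituted)
)
_LINKERS = ("", "C", "CC", "O", "C(=O)N", "NC(=O)", "C(=O)")
_DECORATIONS = ("C", "CC", "F", "Cl", "OC", "N", "C#N", "O", "C(F)(F)F", "[H]")


@dataclass(frozen=True)
class LibrarySpec:
    """Drug-like library with a planted descriptor-linear activity signal."""

    n: int = 1000
    seed: int = 0
    coefficients: tuple = (("tpsa", 0.8), ("mw", 0.5), ("rot_bonds", -0.6))
    intercept: float = 5.8
    noise_sd: float = 0.2

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_molecule_library(n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Assemble ``n`` distinct valid molecules from the fragment grammar.

    Canonical-SMILES deduplication guarantees distinctness; a construction
    that cannot reach ``n`` distinct molecules raises.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    max_attempts = 200 * n + 10000
    attempts = 0
    while len(seen) < n and attempts < max_attempts:
        attempts += 1
        outer = _CORES_OUTER[rng.integers(len(_CORES_OUTER))]
        inner = _CORES_INNER[rng.integers(len(_CORES_INNER))]
        linker = _LINKERS[rng.integers(len(_LINKERS))]
        d_out = _DECORATIONS[rng.integers(len(_DECORATIONS))]
        d_in = _DECORATIONS[rng.integers(len(_DECORATIONS))]
        smiles = outer.format(d=d_out, s=linker + inner.format(d=d_in))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees validity; guard anyway
            continue
        canonical = Chem.MolToSmiles(mol)
        seen.setdefault(canonical, None)
    if len(seen) < n:
        raise ValueError(f"fragment grammar exhausted at {len(seen)} < {n} molecules")
    return [
        MoleculeRecord(id=f"syn{i + 1:05d}", structure=smi)
        for i, smi in enumerate(seen)
    ]


def plant_activity_labels(
    lib: Sequence[MoleculeRecord],
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float = 0.2,
    intercept: float = 5.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plant pIC50 = beta . z(descriptors) + intercept + N(0, sd^2).

    Descriptors are z-scored (population sd) over the library so the planted
    coefficients are on a common scale.  Returns the activity table
    (id, pic50) and the ground truth (beta, design matrix, descriptors) for
    recovery tests.
    """
    coefficients = dict(coefficients or dict(LibrarySpec().coefficients))
    desc_rows = {rec.id: compute_descriptors(rec).as_dict() for rec in lib}
    desc = pd.DataFrame.from_dict(desc_rows, orient="index")
    names = list(coefficients)
    X = desc[names].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    beta = np.array([coefficients[c] for c in names])
    rng = np.random.default_rng(seed)
    y = Z @ beta + intercept + rng.normal(0.0, noise_sd, size=len(lib))
    table = pd.DataFrame({"id": [r.id for r in lib], "pic50": y})
    truth = {
        "beta": dict(zip(names, beta)),
        "intercept": intercept,
        "noise_sd": noise_sd,
        "design": pd.DataFrame(Z, columns=names, index=[r.id for r in lib]),
        "descriptors": desc,
    }
    return table, truth


# --- score tables -----------------------------------------------------------

def _marginal_ppf(name: str, spec: Mapping, u: np.ndarray) -> np.ndarray:
    dist = spec.get("dist", "normal")
    if dist == "normal":
        return stats.norm.ppf(u, loc=spec.get("loc", 0.0), scale=spec.get("scale", 1.0))
    if dist == "uniform":
        low, high = spec.get("low", 0.0), spec.get("high", 1.0)
        return low + u * (high - low)
    raise ValueError(f"column {name!r}: unknown distribution {dist!r}")


def gen_score_table(
    n: int,
    columns: Mapping[str, Mapping],
    seed: int = 0,
    spearman: Mapping[tuple, float] | None = None,
) -> pd.DataFrame:
    """Synthetic score table with given marginals and rank correlations.

    ``columns`` maps a column name to a marginal spec
    ({'dist': 'normal', 'loc', 'scale'} or {'dist': 'uniform', 'low',
    'high'}).  ``spearman`` maps column pairs to target Spearman rho,
    realized through a Gaussian copula (latent Pearson rho =
    2 sin(pi rho_s / 6)).
    """
    names = list(columns)
    k = len(names)
    corr = np.eye(k)
    for (a, b), rho_s in (spearman or {}).items():
        if not (-1 < rho_s < 1):
            raise ValueError("spearman rho must be in (-1, 1)")
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        ia, ib = names.index(a), names.index(b)
        corr[ia, ib] = corr[ib, ia] = rho_p
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, k)) @ L.T
    u = stats.norm.cdf(latent)
    data = {
        name: _marginal_ppf(name, columns[name], u[:, i]) for i, name in enumerate(names)
    }
    return pd.DataFrame({"id": [f"syn{i + 1:05d}" for i in range(n)], **data}).set_index("id")


# --- trajectories -----------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Replicate trajectories with controlled motion and H-bond schedules.

    ``motion`` is 'stable' (per-atom isotropic Gaussian jitter of sd
    ``jitter_sd`` Å) or 'drifting' (whole-ligand random walk with step sd
    ``drift_step`` Å per frame).  ``occupancies`` gives, per scheduled
    protein–ligand H-bond, the exact fraction of final-window frames in
    which the bond is present (a deterministic frame mask, not a random
    draw).  Defaults mirror ten replicate 10 ns runs.
    """

    n_protein: int = 40
    n_ligand: int = 12
    n_replicates: int = 10
    n_frames: int = 100
    dt_ns: float = 0.1
    motion: str = "stable"
    jitter_sd: float = 0.3
    drift_step: float = 0.2
    occupancies: tuple = (1.0,)
    final_window_ns: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.motion not in ("stable", "drifting"):
            raise ValueError("motion must be 'stable' or 'drifting'")
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames")
        if any(not (0.0 <= o <= 1.0) for o in self.occupancies):
            raise ValueError("occupancies must lie in [0, 1]")


def gen_trajectory_set(spec: TrajectorySpec) -> TrajectorySet:
    """Build a reference pose plus replicates under the spec's motion model.

    Scheduled bonds are realized constructively: in "on" frames the ligand
    acceptor sits exactly at its reference position (donor–H–acceptor
    geometry well inside the default criteria); in "off" frames it is
    displaced 4 Å along the bond axis, breaking the distance criterion.
    """
    rng = np.random.default_rng(spec.seed)
    n_bonds = len(spec.occupancies)
    n_h = n_bonds

    # protein scaffold: seeded points in a 12 A ball, then donors on the
    # face closest to the ligand
    prot = rng.uniform(-6.0, 6.0, size=(spec.n_protein, 3))
    prot[:, 0] -= 8.0  # protein occupies x < 0 half-space
    lig = rng.uniform(-2.0, 2.0, size=(spec.n_ligand, 3))
    lig[:, 0] += 4.0   # ligand occupies x > 0 pocket

    donors = []
    hydrogens = []
    acceptors = []
    for b in range(n_bonds):
        base = np.array([-1.0, 2.5 * b, 0.0])
        donors.append(base)                       # protein donor D
        hydrogens.append(base + np.array([1.0, 0.0, 0.0]))   # D-H along +x
        acceptors.append(base + np.array([2.9, 0.0, 0.0]))   # A: D-A 2.9 A, angle 180
    donors = np.array(donors)
    hydrogens = np.array(hydrogens)
    acceptors = np.array(acceptors)

    # atom layout: [protein scaffold | donors | hydrogens | ligand body | acceptors]
    coords = np.vstack([prot, donors, hydrogens, lig, acceptors])
    n_atoms = coords.shape[0]
    i_prot_end = spec.n_protein
    i_don = np.arange(i_prot_end, i_prot_end + n_bonds)
    i_h = np.arange(i_prot_end + n_bonds, i_prot_end + 2 * n_bonds)
    i_lig = np.arange(i_prot_end + 2 * n_bonds, i_prot_end + 2 * n_bonds + spec.n_ligand)
    i_acc = np.arange(n_atoms - n_bonds, n_atoms)

    protein_mask = np.zeros(n_atoms, bool)
    protein_mask[:i_prot_end] = True
    protein_mask[i_don] = True
    ligand_mask = np.zeros(n_atoms, bool)
    ligand_mask[i_lig] = True
    ligand_mask[i_acc] = True
    donor_mask = np.zeros(n_atoms, bool)
    donor_mask[i_don] = True
    acceptor_mask = np.zeros(n_atoms, bool)
    acceptor_mask[i_acc] = True

    top = Topology(
        names=tuple(
            [f"P{i}" for i in range(i_prot_end)]
            + [f"D{i}" for i in range(n_bonds)]
            + [f"H{i}" for i in range(n_h)]
            + [f"L{i}" for i in range(spec.n_ligand)]
            + [f"A{i}" for i in range(n_bonds)]
        ),
        elements=tuple(
            ["C"] * i_prot_end + ["N"] * n_bonds + ["H"] * n_h
            + ["C"] * spec.n_ligand + ["O"] * n_bonds
        ),
        protein=protein_mask,
        ligand_heavy=ligand_mask,
        donor=donor_mask,
        acceptor=acceptor_mask,
        donor_h={int(d): int(h) for d, h in zip(i_don, i_h)},
    )

    times = (np.arange(spec.n_frames) + 1) * spec.dt_ns
    t_end = times[-1]
    in_window = times >= t_end - spec.final_window_ns + 1e-12
    window_idx = np.flatnonzero(in_window)
    n_window = len(window_idx)
    on_masks = []
    for occ in spec.occupancies:
        n_on = int(round(occ * n_window))
        mask = np.ones(spec.n_frames, dtype=bool)  # present outside the window
        mask[window_idx] = False
        mask[window_idx[:n_on]] = True             # deterministic: first n_on frames on
        on_masks.append(mask)

    replicates = []
    time_arrays = []
    movable = np.concatenate([i_lig])  # acceptors handled by the schedule
    for _ in range(spec.n_replicates):
        frames = np.tile(coords, (spec.n_frames, 1, 1))
        if spec.motion == "stable":
            if spec.jitter_sd > 0:
                frames[:, movable, :] += rng.normal(
                    0.0, spec.jitter_sd, size=(spec.n_frames, len(movable), 3)
                )
        else:
            steps = rng.normal(0.0, spec.drift_step, size=(spec.n_frames, 3))
            walk = np.cumsum(steps, axis=0)
            frames[:, movable, :] += walk[:, None, :]
        for b, mask in enumerate(on_masks):
            off = ~mask
            frames[off, i_acc[b], :] = coords[i_acc[b]] + np.array([4.0, 0.0, 0.0])
            frames[mask, i_acc[b], :] = coords[i_acc[b]]
        replicates.append(frames)
        time_arrays.append(times.copy())

    ts = TrajectorySet(topology=top, reference=coords, replicates=replicates, times=time_arrays)
    ts.validate()
    return ts


def write_trajectory_files(ts: TrajectorySet, outdir: str | Path, dt_ns: float = 0.1) -> dict:
    """Emit topology/reference/replicate multi-model PDBs plus a roles JSON.

    Returns the path map consumed by ``pose_stability.load_trajectory_set``.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top = ts.topology
    n = top.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", list(top.names))
    u.add_TopologyAttr("elements", [e if e != "X" else "C" for e in top.elements])

    def write_pdb(path, frames):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n, multiframe=len(frames) > 1) as w:
                for f in frames:
                    u.atoms.positions = np.asarray(f, dtype=np.float32)
                    w.write(u.atoms)

    paths = {
        "topology": outdir / "topology.pdb",
        "reference": outdir / "reference.pdb",
        "roles": outdir / "roles.json",
        "replicates": [],
    }
    write_pdb(paths["topology"], [ts.reference])
    write_pdb(paths["reference"], [ts.reference])
    for i, rep in enumerate(ts.replicates):
        p = outdir / f"replicate_{i:02d}.pdb"
        write_pdb(p, rep)
        paths["replicates"].append(p)
    roles = {
        "protein": np.flatnonzero(top.protein).tolist(),
        "ligand_heavy": np.flatnonzero(top.ligand_heavy).tolist(),
        "donor": np.flatnonzero(top.donor).tolist(),
        "acceptor": np.flatnonzero(top.acceptor).tolist(),
        "donor_h": {str(k): int(v) for k, v in top.donor_h.items()},
    }
    paths["roles"].write_text(json.dumps(roles, indent=1))
    return paths


# --- dose-response ----------------------------------------------------------

def gen_dose_response(
    params: FourPLParams,
    doses_nm: Sequence[float] = DEFAULT_DOSES_NM,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> DoseResponseCurve:
    """Noisy 4PL curve at the given doses (nM); noise in response units."""
    params.validate()
    x = np.log10(np.asarray(doses_nm, dtype=float))
    x = np.repeat(x, replicates)
    rng = np.random.default_rng(seed)
    y = four_pl_response(x, params) + rng.normal(0.0, noise_sd, size=x.shape)
    rep = np.tile(np.arange(replicates), len(doses_nm))
    return DoseResponseCurve(x=x, y=y, replicate=rep)
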