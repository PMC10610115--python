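"""Staged score-threshold screening (funnel) and consensus tables.

A funnel is an ordered list of stages.  Each stage filters a score table on
one column: rows at or below the threshold survive (docking conventions —
more negative is better), optionally capped to the best ``max_retained``
rows.  Scores from different methods (staged docking tiers, MM/GBSA,
external surface score, predicted pIC50) are then joined into one consensus
table per molecule and ranked by a transparent weighted-z composite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Consensus table column order (staged docking tiers first, then rescores).
CONSENSUS_COLUMNS = (
    "score_htvs",
    "score_sp",
    "score_xp",
    "mmgbsa_dg",
    "external_score",
    "pic50_pred",
)


@dataclass(frozen=True)
class FunnelStage:
    """One filtering stage: keep rows with ``score <= threshold``.

    ``max_retained`` keeps only the best (most negative) rows after the
    threshold, ties broken by id.  ``poses_per_ligand`` is provenance
    metadata (how many poses the upstream docking emitted per ligand).
    """

    name: str
    score_column: str
    threshold: float
    max_retained: int | None = None
    poses_per_ligand: int = 1

    def __post_init__(self):
        if self.max_retained is not None and self.max_retained < 1:
            raise ValueError("max_retained must be >= 1")


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    n_missing_score: int
    survivors: tuple


@dataclass
class FunnelReport:
    stages: list
    provenance: dict

    @property
    def final_survivors(self) -> tuple:
        return self.stages[-1].survivors if self.stages else ()

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [
                    {
                        "name": s.name,
                        "n_in": s.n_in,
                        "n_out": s.n_out,
                        "n_missing_score": s.n_missing_score,
                        "survivors": list(s.survivors),
                    }
                    for s in self.stages
                ],
                "provenance": self.provenance,
            },
            indent=1,
        )


def _check_table(t: pd.DataFrame) -> pd.DataFrame:
    if "id" in t.columns:
        t = t.set_index("id")
    if t.index.has_duplicates:
        dupes = t.index[t.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids: {dupes[:5]}")
    return t


def collapse_best_pose(t: pd.DataFrame, score_column: str) -> pd.DataFrame:
    """Collapse multiple poses per ligand to the best (most negative) score.

    Expects a ``ligand_id`` column; all other columns take the value of the
    best-scoring pose row.
    """
    if "ligand_id" not in t.columns:
        raise ValueError("pose table needs a 'ligand_id' column")
    idx = t.groupby("ligand_id")[score_column].idxmin()
    return t.loc[idx].set_index("ligand_id").sort_index()


def apply_stage(t: pd.DataFrame, s: FunnelStage) -> tuple[pd.DataFrame, StageResult]:
    """Apply one stage; returns (surviving table, stage bookkeeping).

    The threshold is inclusive (score <= threshold survives).  Rows with a
    missing score are dropped and counted separately.
    """
    t = _check_table(t)
    if s.score_column not in t.columns:
        raise KeyError(f"stage {s.name!r}: column {s.score_column!r} not in table")
    scores = pd.to_numeric(t[s.score_column], errors="coerce")
    missing = int(scores.isna().sum())
    kept = t[scores <= s.threshold]
    if s.max_retained is not None and len(kept) > s.max_retained:
        order = np.lexsort(
            (kept.index.to_numpy(), scores.loc[kept.index].to_numpy())
        )
        kept = kept.iloc[order[: s.max_retained]]
    result = StageResult(
        name=s.name,
        n_in=len(t),
        n_out=len(kept),
        n_missing_score=missing,
        survivors=tuple(kept.index),
    )
    return kept, result


def run_funnel(t: pd.DataFrame, stages: Sequence[FunnelStage]) -> FunnelReport:
    """Apply stages in order, recording counts and survivors at each stage."""
    if not stages:
        raise ValueError("need at least one stage")
    t = _check_table(t)
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(t.sort_index(), index=True).values.tobytes()
    ).hexdigest()[:16]
    results = []
    current = t
    for s in stages:
        current, res = apply_stage(current, s)
        results.append(res)
    provenance = {
        "input_rows": len(t),
        "input_hash": digest,
        "stages": [
            {
                "name": s.name,
                "score_column": s.score_column,
                "threshold": s.threshold,
                "max_retained": s.max_retained,
                "poses_per_ligand": s.poses_per_ligand,
            }
            for s in stages
        ],
    }
    return FunnelReport(stages=results, provenance=provenance)


def assemble_consensus(
    tables: Mapping[str, pd.DataFrame], join: str = "inner"
) -> pd.DataFrame:
    """Join score tables by molecule id into one consensus table.

    ``tables`` maps a label to a table keyed by id.  Default inner join;
    ``join='outer'`` keeps all ids and leaves missing scores as NaN.  Columns
    are reordered to the canonical consensus layout where present.
    """
    if join not in ("inner", "outer"):
        raise ValueError("join must be 'inner' or 'outer'")
    frames = [_check_table(t) for t in tables.values()]
    out = pd.concat(frames, axis=1, join=join)
    if out.columns.has_duplicates:
        raise ValueError("overlapping column names across source tables")
    known = [c for c in CONSENSUS_COLUMNS if c in out.columns]
    rest = [c for c in out.columns if c not in CONSENSUS_COLUMNS]
    return out[known + rest].sort_index()


#: Default composite weights: equal weight on the final docking tier, the
#: free-energy rescore, the external surface score, and the predicted pIC50.
DEFAULT_RANK_WEIGHTS = {
    "score_xp": 1.0,
    "mmgbsa_dg": 1.0,
    "external_score": 1.0,
    "pic50_pred": 1.0,
}

#: Sign conventions: larger composite = better.  Energy-like scores (more
#: negative better) enter negated; pIC50 (larger better) enters as-is.
_SIGNS = {
    "score_htvs": -1.0,
    "score_sp": -1.0,
    "score_xp": -1.0,
    "mmgbsa_dg": -1.0,
    "external_score": -1.0,
    "pic50_pred": +1.0,
}


def rank_candidates(
    t: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Rank molecules by a weighted sum of z-scored, sign-aligned columns.

    This is a reproducible surrogate for expert triage: each weighted column
    is z-scored over the table, flipped so larger is better, weighted and
    summed.  Returns the table with ``composite`` and ``rank`` columns,
    ordered best-first, ties broken by id.
    """
    t = _check_table(t)
    weights = dict(weights or DEFAULT_RANK_WEIGHTS)
    missing = [c for c in weights if c not in t.columns]
    if missing:
        raise KeyError(f"weighted columns absent: {missing}")
    composite = np.zeros(len(t))
    for col, w in weights.items():
        v = pd.to_numeric(t[col], errors="coerce")
        if v.isna().all():
            raise ValueError(f"column {col!r} has no values")
        sd = v.std(ddof=0)
        z = (v - v.mean()) / (sd if sd > 0 else 1.0)
        composite += w * _SIGNS.get(col, 1.0) * z.fillna(0.0).to_numpy()
    out = t.copy()
    out["composite"] = composite
    order = np.lexsort((out.index.to_numpy(), -out["composite"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def load_stages(path: str | Path) -> list[FunnelStage]:
    """Read stage definitions from a YAML file (list of stage mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of stages")
    allowed = {"name", "score_column", "threshold", "max_retained", "poses_per_ligand"}
    stages = []
    for entry in raw:
        unknown = set(entry) - allowed
        if unknown:
            raise ValueError(f"unknown stage keys: {sorted(unknown)}")
        stages.append(FunnelStage(**entry))
    return stages
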