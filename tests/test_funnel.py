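"""Funnel stage filtering, consensus assembly and ranking tests."""

import io

import numpy as np
import pandas as pd
import pytest

from vsfunnel.funnel import (
    FunnelStage,
    apply_stage,
    assemble_consensus,
    collapse_best_pose,
    load_stages,
    rank_candidates,
    run_funnel,
)
from vsfunnel.synthetic_data import gen_score_table

from conftest import HIT_SCORES


def _table(scores, col="score"):
    return pd.DataFrame({"id": [f"m{i}" for i in range(len(scores))], col: scores})


class TestApplyStage:
    def test_inclusive_threshold(self):
        t = _table([-10.0, -9.5, -8.2, -8.101, -7.0])
        kept, res = apply_stage(t, FunnelStage("xp", "score", -8.101))
        assert res.n_out == 4
        assert "m4" not in kept.index  # only the -7.0 row fails

    def test_max_retained_keeps_most_negative(self):
        t = _table([-10.0, -9.5, -8.2, -8.101, -7.0])
        kept, _ = apply_stage(t, FunnelStage("xp", "score", -8.101, max_retained=3))
        assert sorted(kept["score"]) == [-10.0, -9.5, -8.2]

    def test_empty_table(self):
        t = _table([])
        kept, res = apply_stage(t, FunnelStage("s", "score", -1.0))
        assert (res.n_in, res.n_out) == (0, 0)
        assert kept.empty

    def test_missing_scores_dropped_and_counted(self):
        t = _table([-9.0, np.nan, -8.5])
        kept, res = apply_stage(t, FunnelStage("s", "score", -8.0))
        assert res.n_missing_score == 1
        assert res.n_out == 2

    def test_unknown_column(self):
        with pytest.raises(KeyError):
            apply_stage(_table([-9.0]), FunnelStage("s", "nope", -8.0))

    def test_idempotent(self):
        t = _table(list(np.linspace(-12, -5, 50)))
        s = FunnelStage("s", "score", -8.0)
        once, _ = apply_stage(t, s)
        twice, _ = apply_stage(once.reset_index(), s)
        assert list(once.index) == list(twice.index)

    def test_matches_bruteforce_on_random_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(-8, 1.5, 500)
        t = _table(list(scores))
        s = FunnelStage("s", "score", -8.3, max_retained=40)
        kept, _ = apply_stage(t, s)
        # oracle: explicit sort-and-cut
        pairs = sorted(
            [(v, f"m{i}") for i, v in enumerate(scores) if v <= -8.3]
        )[:40]
        assert set(kept.index) == {i for _, i in pairs}


class TestRunFunnel:
    def test_counts_non_increasing(self):
        t = gen_score_table(
            2000,
            {"a": {"dist": "normal", "loc": -8, "scale": 1},
             "b": {"dist": "normal", "loc": -8, "scale": 1}},
            seed=1,
        ).reset_index()
        stages = [FunnelStage("s1", "a", -8.0), FunnelStage("s2", "b", -8.5)]
        rep = run_funnel(t, stages)
        counts = [c for _, n_in, c in rep.counts()]
        assert counts[0] >= counts[1]
        assert rep.counts()[0][1] == 2000

    def test_order_statistic_thresholds_give_exact_counts(self):
        """Thresholds placed at empirical order statistics reproduce the
        requested survivor counts exactly."""
        t = gen_score_table(10000, {"s1": {"dist": "normal", "loc": -8, "scale": 1.5},
                                    "s2": {"dist": "normal", "loc": -9, "scale": 1.0}},
                            seed=7).reset_index()
        thr1 = np.sort(t["s1"])[4999]  # 5000th smallest
        survivors = t.nsmallest(5000, "s1")
        thr2 = np.sort(survivors["s2"])[1999]
        rep = run_funnel(t, [FunnelStage("one", "s1", thr1), FunnelStage("two", "s2", thr2)])
        assert [c[2] for c in rep.counts()] == [5000, 2000]

    def test_minus_infinity_threshold_removes_all(self):
        t = _table([-9.0, -8.0])
        rep = run_funnel(t, [FunnelStage("s", "score", -np.inf)])
        assert rep.counts()[0][2] == 0

    def test_survivors_invariant_to_row_order(self):
        rng = np.random.default_rng(11)
        t = _table(list(rng.normal(-8, 1, 300)))
        shuffled = t.sample(frac=1.0, random_state=4)
        stages = [FunnelStage("s", "score", -8.2, max_retained=50)]
        assert set(run_funnel(t, stages).final_survivors) == set(
            run_funnel(shuffled, stages).final_survivors
        )

    def test_duplicate_ids_rejected(self):
        t = pd.DataFrame({"id": ["a", "a"], "score": [-9.0, -8.0]})
        with pytest.raises(ValueError, match="duplicate"):
            run_funnel(t, [FunnelStage("s", "score", -8.0)])


class TestConsensus:
    def test_inner_join_shared_ids(self):
        t1 = pd.DataFrame({"id": ["a", "b", "c"], "score_xp": [-9, -8, -7]})
        t2 = pd.DataFrame({"id": ["a", "b"], "mmgbsa_dg": [-80, -70]})
        t3 = pd.DataFrame({"id": ["b", "a", "z"], "pic50_pred": [5.5, 6.0, 4.0]})
        c = assemble_consensus({"xp": t1, "mm": t2, "ml": t3})
        assert list(c.index) == ["a", "b"]
        assert list(c.columns) == ["score_xp", "mmgbsa_dg", "pic50_pred"]

    def test_outer_join_flags_missing(self):
        t1 = pd.DataFrame({"id": ["a", "b"], "score_xp": [-9, -8]})
        t2 = pd.DataFrame({"id": ["a"], "mmgbsa_dg": [-80]})
        c = assemble_consensus({"xp": t1, "mm": t2}, join="outer")
        assert len(c) == 2
        assert np.isnan(c.loc["b", "mmgbsa_dg"])

    def test_published_hit_row_csv_round_trip(self):
        """A published consensus row survives CSV write/read unchanged."""
        row = pd.DataFrame([{"id": "hit", **HIT_SCORES}])
        c = assemble_consensus({"all": row})
        buf = io.StringIO()
        c.to_csv(buf)
        buf.seek(0)
        back = pd.read_csv(buf).set_index("id")
        pd.testing.assert_frame_equal(back, c)

    def test_project_back_recovers_source_columns(self):
        t1 = pd.DataFrame({"id": ["a", "b"], "score_xp": [-9.0, -8.0]})
        t2 = pd.DataFrame({"id": ["b", "a"], "mmgbsa_dg": [-70.0, -80.0]})
        c = assemble_consensus({"xp": t1, "mm": t2})
        back = c[["score_xp"]].reset_index()
        pd.testing.assert_frame_equal(
            back.sort_values("id").reset_index(drop=True),
            t1.sort_values("id").reset_index(drop=True),
        )


class TestRanking:
    def test_dominating_row_ranks_first(self):
        t = pd.DataFrame(
            {
                "id": ["worse", "better"],
                "score_xp": [-8.0, -12.0],
                "mmgbsa_dg": [-60.0, -85.0],
                "external_score": [-100.0, -180.0],
                "pic50_pred": [5.0, 6.5],
            }
        )
        ranked = rank_candidates(t)
        assert list(ranked.index) == ["better", "worse"]

    def test_single_row_rank_one(self):
        t = pd.DataFrame([{"id": "only", **HIT_SCORES}])
        ranked = rank_candidates(t, weights={"score_xp": 1.0})
        assert ranked.loc["only", "rank"] == 1

    def test_order_matches_bruteforce_composite(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(
            {
                "id": [f"m{i}" for i in range(5)],
                "score_xp": rng.normal(-10, 2, 5),
                "pic50_pred": rng.normal(6, 0.5, 5),
            }
        )
        ranked = rank_candidates(t, weights={"score_xp": 1.0, "pic50_pred": 2.0})
        # brute force: z-score by hand, negate energies, weight, sum
        z = lambda v: (v - v.mean()) / v.std(ddof=0)
        comp = -1.0 * z(t.set_index("id")["score_xp"]) + 2.0 * z(t.set_index("id")["pic50_pred"])
        expected = list(comp.sort_values(ascending=False).index)
        assert list(ranked.index) == expected
        np.testing.assert_allclose(ranked["composite"], comp.loc[ranked.index], atol=1e-12)

    def test_all_missing_column_rejected(self):
        t = pd.DataFrame({"id": ["a"], "score_xp": [np.nan]})
        with pytest.raises(ValueError):
            rank_candidates(t, weights={"score_xp": 1.0})


class TestPoseCollapseAndConfig:
    def test_best_pose_per_ligand(self):
        t = pd.DataFrame(
            {"ligand_id": ["a", "a", "b"], "score_sp": [-9.0, -10.5, -8.0]}
        )
        out = collapse_best_pose(t, "score_sp")
        assert out.loc["a", "score_sp"] == -10.5
        assert len(out) == 2

    def test_yaml_stage_loading(self, tmp_path):
        p = tmp_path / "stages.yaml"
        p.write_text(
            "- name: htvs\n  score_column: score_htvs\n  threshold: -6.532\n"
            "  poses_per_ligand: 5\n"
            "- name: sp\n  score_column: score_sp\n  threshold: -8.689\n"
            "  poses_per_ligand: 20\n"
            "- name: xp\n  score_column: score_xp\n  threshold: -8.101\n"
            "  poses_per_ligand: 20\n"
        )
        stages = load_stages(p)
        assert [s.threshold for s in stages] == [-6.532, -8.689, -8.101]
        assert stages[0].poses_per_ligand == 5

    def test_unknown_stage_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("- name: a\n  score_column: s\n  threshold: -1\n  bogus: 2\n")
        with pytest.raises(ValueError, match="unknown"):
            load_stages(p)
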