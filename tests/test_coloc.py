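"""Colocalization: nearest-neighbor exactness vs a brute-force oracle,
interbouton arithmetic and the strict overlap criterion, CI identities and
monotonicity, group comparison."""

import logging

import numpy as np
import pandas as pd
import pytest

from coloc3d import (
    compare_ci_groups,
    compute_ci,
    interbouton_distance,
    nearest_cross_channel,
    percent_colocalized,
    summarize_image,
)
from coloc3d.coloc import ImageColocSummary


def _table(points, radii=None, ids=None, channel="candidate"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    radii = np.full(n, 0.5) if radii is None else np.asarray(radii, dtype=float)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    return pd.DataFrame(
        {
            "object_id": ids,
            "channel": channel,
            "voxel_count": 100,
            "volume_um3": 4 / 3 * np.pi * radii**3,
            "x_um": points[:, 0],
            "y_um": points[:, 1],
            "z_um": points[:, 2],
            "radius_um": radii,
        }
    )


class TestNearestCrossChannel:
    def test_simple_assignment(self):
        cand = _table([(0, 0, 0)])
        ref = _table([(1, 0, 0), (3, 0, 0)], ids=[10, 11], channel="reference")
        cand_nn, ref_nn = nearest_cross_channel(cand, ref)
        assert cand_nn.loc[0, "neighbor_id"] == 10
        assert cand_nn.loc[0, "center_distance_um"] == pytest.approx(1.0)
        assert list(ref_nn["neighbor_id"]) == [0, 0]

    def test_single_objects_are_mutual(self):
        cand = _table([(1, 2, 3)])
        ref = _table([(4, 5, 6)], channel="reference")
        cand_nn, ref_nn = nearest_cross_channel(cand, ref)
        assert cand_nn.loc[0, "neighbor_id"] == ref_nn.loc[0, "object_id"]
        assert ref_nn.loc[0, "neighbor_id"] == cand_nn.loc[0, "object_id"]

    def test_empty_channel_named_in_error(self):
        cand = _table([(0, 0, 0)])
        with pytest.raises(ValueError, match="reference"):
            nearest_cross_channel(cand, cand.iloc[:0])

    def test_tie_breaks_to_lowest_id(self):
        cand = _table([(0, 0, 0)])
        # two references exactly equidistant; the lower id must win
        ref = _table([(2, 0, 0), (-2, 0, 0)], ids=[7, 3], channel="reference")
        cand_nn, _ = nearest_cross_channel(cand, ref)
        assert cand_nn.loc[0, "neighbor_id"] == 3

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            cand = _table(rng.uniform(0, 20, size=(20, 3)))
            ref = _table(rng.uniform(0, 20, size=(20, 3)), channel="reference")
            cand_nn, ref_nn = nearest_cross_channel(cand, ref)
            oracle = _brute_force_nn(cand, ref)
            assert list(cand_nn["neighbor_id"]) == oracle[0]
            oracle_rev = _brute_force_nn(ref, cand)
            assert list(ref_nn["neighbor_id"]) == oracle_rev[0]


def _brute_force_nn(table, other):
    """Independent O(n²) scan with explicit lowest-id tie-breaking."""
    ids, dists = [], []
    for a in table.sort_values("object_id").itertuples():
        best_id, best_d = None, np.inf
        for b in other.sort_values("object_id").itertuples():
            d = np.sqrt(
                (a.x_um - b.x_um) ** 2 + (a.y_um - b.y_um) ** 2 + (a.z_um - b.z_um) ** 2
            )
            if d < best_d or (d == best_d and b.object_id < best_id):
                best_id, best_d = b.object_id, d
        ids.append(best_id)
        dists.append(best_d)
    return ids, dists


class TestInterboutonDistance:
    @pytest.mark.parametrize(
        "d, ra, rb, expected, coloc",
        [
            (1.0, 0.6, 0.5, -0.1, True),
            (1.0, 0.4, 0.5, 0.1, False),
            (1.1, 0.6, 0.5, 0.0, False),  # exactly touching is NOT colocalized
        ],
    )
    def test_arithmetic_and_strict_criterion(self, d, ra, rb, expected, coloc):
        dist = interbouton_distance(d, ra, rb)
        assert dist == pytest.approx(expected)
        assert (dist < 0) is coloc

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            interbouton_distance(1.0, -0.1, 0.5)


class TestPercentAndCI:
    def test_percent(self):
        assert percent_colocalized([True] * 4 + [False] * 6) == 40.0
        assert percent_colocalized([True] * 3) == 100.0
        assert percent_colocalized([False] * 3) == 0.0
        with pytest.raises(ValueError):
            percent_colocalized([])

    def test_ci(self):
        assert compute_ci(50, 50) == 1.0
        assert compute_ci(40, 80) == 0.5
        with pytest.raises(ZeroDivisionError):
            compute_ci(30, 0)
        with pytest.raises(ValueError):
            compute_ci(120, 50)


class TestSummarizeImage:
    def test_identical_tables_give_ci_one(self):
        t = _table(np.random.default_rng(0).uniform(0, 10, size=(30, 3)))
        ref = t.copy()
        ref["channel"] = "reference"
        s = summarize_image(t, ref, min_objects_warn=0)
        assert s.ci == 1.0
        assert s.pct_candidate_coloc == 100.0

    def test_ground_truth_scene_ci(self, small_scene):
        cand, ref = small_scene.to_object_tables()
        s = summarize_image(cand, ref, min_objects_warn=0)
        # 10 paired of 15 candidates; all 10 references paired
        assert s.pct_reference_coloc == 100.0
        assert s.ci == pytest.approx(small_scene.true_candidate_fraction, abs=1e-12)

    def test_warning_below_min_objects(self, caplog):
        t = _table([(0, 0, 0), (5, 5, 5)])
        ref = _table([(0, 0, 0), (5, 5, 5)], channel="reference")
        with caplog.at_level(logging.WARNING, logger="coloc3d.coloc"):
            summarize_image(t, ref, min_objects_warn=200)
        assert "candidate channel has 2 objects" in caplog.text

    def test_duplication_leaves_ci_unchanged(self, small_scene):
        cand, ref = small_scene.to_object_tables()
        s1 = summarize_image(cand, ref, min_objects_warn=0)
        cand2 = pd.concat(
            [cand, cand.assign(object_id=cand.object_id + 10_000)], ignore_index=True
        )
        ref2 = pd.concat(
            [ref, ref.assign(object_id=ref.object_id + 10_000)], ignore_index=True
        )
        s2 = summarize_image(cand2, ref2, min_objects_warn=0)
        assert s2.pct_candidate_coloc == pytest.approx(s1.pct_candidate_coloc)
        assert s2.ci == pytest.approx(s1.ci)

    def test_adding_unpaired_candidates_decreases_ci(self, small_scene):
        cand, ref = small_scene.to_object_tables()
        base = summarize_image(cand, ref, min_objects_warn=0)
        # far-away candidates colocalize with nothing
        extra = _table(
            [(200 + i, 200, 200) for i in range(5)],
            ids=np.arange(5) + 90_000,
        )
        more = pd.concat([cand, extra], ignore_index=True)
        worse = summarize_image(more, ref, min_objects_warn=0)
        assert worse.ci < base.ci


class TestCompareCIGroups:
    @staticmethod
    def _summary(image_id, group, ci):
        return ImageColocSummary(
            image_id=image_id, group=group, n_candidate=200, n_reference=200,
            pct_candidate_coloc=ci * 100, pct_reference_coloc=100.0, ci=ci,
        )

    def test_identical_groups(self):
        summaries = [self._summary(f"a{i}", "A", 0.8) for i in range(3)] + [
            self._summary(f"b{i}", "B", 0.8) for i in range(3)
        ]
        out = compare_ci_groups(summaries)
        assert out["test"]["statistic"] == 0.0
        assert out["test"]["p_value"] == 1.0

    def test_matches_welch_formula_oracle(self):
        x, y = [1.0, 1.1, 1.0], [0.6, 0.7, 0.65]
        summaries = [self._summary(f"a{i}", "A", v) for i, v in enumerate(x)] + [
            self._summary(f"b{i}", "B", v) for i, v in enumerate(y)
        ]
        out = compare_ci_groups(summaries)
        # independent Welch evaluation
        x, y = np.array(x), np.array(y)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df)
        assert out["test"]["statistic"] == pytest.approx(t)
        assert out["test"]["df"] == pytest.approx(df)
        assert out["test"]["p_value"] == pytest.approx(p)

    def test_single_image_group_rejected(self):
        summaries = [
            self._summary("a0", "A", 1.0),
            self._summary("b0", "B", 0.6),
            self._summary("b1", "B", 0.7),
        ]
        with pytest.raises(ValueError, match="A"):
            compare_ci_groups(summaries)
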