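"""Lineage forests, fate classes and family summaries."""
import numpy as np
import pandas as pd
import pytest

import blastoquant as bq
from blastoquant.lineage import ForestError, read_trackmate_xml


def _manual_movie():
    """One founder, one division at frame 5, 20 frames."""
    rows = []
    for t in range(5):
        rows.append(("E00", 0, t))
    for t in range(5, 20):
        rows.append(("E00", 1, t))
        rows.append(("E00", 2, t))
    nuclei = pd.DataFrame(rows, columns=["embryo_id", "cell_id", "frame"])
    nuclei[["x_um", "y_um", "z_um", "ch1"]] = 0.0
    edges = []
    for t in range(1, 5):
        edges.append(("E00", 0, 0, t))
    edges.append(("E00", 1, 0, 5))
    edges.append(("E00", 2, 0, 5))
    for t in range(6, 20):
        edges.append(("E00", 1, 1, t))
        edges.append(("E00", 2, 2, t))
    tracks = pd.DataFrame(
        edges, columns=["embryo_id", "child_id", "parent_id", "frame"]
    )
    return nuclei, tracks


class TestBuildForest:
    def test_single_division_one_family_two_leaves(self):
        nuclei, tracks = _manual_movie()
        forest = bq.build_forest(tracks, nuclei)
        assert len(forest.founders) == 1
        founder = forest.founders[0]
        assert len(forest.leaves(founder)) == 2
        assert len(forest.families()[founder]) == len(nuclei)

    def test_family_partition_matches_generator(self, small_movie):
        _, nuclei, tracks, truth = small_movie
        forest = bq.build_forest(tracks, nuclei)
        lut = truth.labels.set_index(
            ["embryo_id", "cell_id", "frame"]
        )["family_id"]
        for node, founder in forest.family_of.items():
            assert lut.loc[node] == lut.loc[founder]

    def test_missing_cell_reference_names_the_id(self):
        nuclei, tracks = _manual_movie()
        bad = pd.concat(
            [tracks,
             pd.DataFrame([("E00", 99, 0, 3)], columns=tracks.columns)],
            ignore_index=True,
        )
        with pytest.raises(ForestError, match="99"):
            bq.build_forest(bad, nuclei)

    def test_multiple_parents_rejected(self):
        nuclei, tracks = _manual_movie()
        bad = pd.concat(
            [tracks,
             pd.DataFrame([("E00", 1, 2, 7)], columns=tracks.columns)],
            ignore_index=True,
        )
        with pytest.raises(ForestError, match="multiple parents"):
            bq.build_forest(bad, nuclei)

    def test_three_children_rejected(self):
        nuclei, tracks = _manual_movie()
        extra_nucleus = pd.DataFrame(
            [("E00", 3, 5, 0.0, 0.0, 0.0, 0.0)], columns=nuclei.columns
        )
        bad = pd.concat(
            [tracks, pd.DataFrame([("E00", 3, 0, 5)], columns=tracks.columns)],
            ignore_index=True,
        )
        with pytest.raises(ForestError, match="successors"):
            bq.build_forest(bad, pd.concat([nuclei, extra_nucleus],
                                           ignore_index=True))

    def test_orphans_reported_and_excluded(self):
        nuclei, tracks = _manual_movie()
        orphan = pd.DataFrame(
            [("E00", 50, 8, 0.0, 0.0, 0.0, 0.0)], columns=nuclei.columns
        )
        forest = bq.build_forest(
            tracks, pd.concat([nuclei, orphan], ignore_index=True)
        )
        assert ("E00", 50, 8) in forest.orphans
        assert ("E00", 50, 8) not in forest.family_of


class TestClassifyFamilies:
    @pytest.mark.parametrize(
        "start, leaves, expected, flagged",
        [
            ("outer", ["outer", "outer"], "OUT-TE", False),
            ("inner", ["inner", "outer"], "IN-TE+ICM", False),
            ("inner", ["inner", "inner"], "IN-ICM", False),
            ("outer", ["inner", "outer"], "OUT-TE+ICM", False),
            ("inner", ["outer", "outer"], "OTHER", True),
            ("outer", ["inner", "inner"], "OTHER", True),
        ],
    )
    def test_rule_table(self, start, leaves, expected, flagged):
        nuclei, tracks = _manual_movie()
        labels = []
        for r in nuclei.itertuples():
            if r.frame == 0:
                labels.append((r.embryo_id, r.cell_id, r.frame, start))
            elif r.frame == 19:
                labels.append(
                    (r.embryo_id, r.cell_id, r.frame, leaves[r.cell_id - 1])
                )
            else:
                labels.append((r.embryo_id, r.cell_id, r.frame, start))
        ldf = pd.DataFrame(
            labels, columns=["embryo_id", "cell_id", "frame", "label"]
        )
        forest = bq.build_forest(tracks, nuclei)
        out = bq.classify_families(forest, ldf)
        assert out.family_class.iloc[0] == expected
        assert out.flagged.iloc[0] == flagged

    def test_unlabeled_founder_rejected(self):
        nuclei, tracks = _manual_movie()
        forest = bq.build_forest(tracks, nuclei)
        ldf = pd.DataFrame(
            columns=["embryo_id", "cell_id", "frame", "label"]
        )
        with pytest.raises(ValueError, match="unlabeled founder"):
            bq.classify_families(forest, ldf)


class TestFamilySummaries:
    def test_single_cell_family_constant_trajectory(self):
        nuclei = pd.DataFrame(
            {
                "embryo_id": "E00",
                "cell_id": 0,
                "frame": range(4),
                "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
                "ch1_std": 1.3,
            }
        )
        tracks = pd.DataFrame(
            [("E00", 0, 0, t) for t in range(1, 4)],
            columns=["embryo_id", "child_id", "parent_id", "frame"],
        )
        forest = bq.build_forest(tracks, nuclei)
        traj = bq.family_mean_trajectory(forest, nuclei, "ch1_std")
        np.testing.assert_allclose(traj["per_family"].values, 1.3)
        init = bq.initial_intensity(forest, nuclei, "ch1_std")
        assert init.initial.iloc[0] == pytest.approx(1.3)

    def test_family_means_equal_groupby_oracle(self, small_movie):
        _, nuclei, tracks, truth = small_movie
        forest = bq.build_forest(tracks, nuclei)
        df = bq.standardize_embryo(nuclei, "ch1", source="ch1")
        traj = bq.family_mean_trajectory(forest, df, "ch1_std")
        # brute-force oracle via the generator's family ids
        joined = df.merge(
            truth.labels[["embryo_id", "cell_id", "frame", "family_id"]],
            on=["embryo_id", "cell_id", "frame"],
        )
        oracle = joined.groupby(["embryo_id", "family_id", "frame"])[
            "ch1_std"
        ].mean()
        ours = traj["per_family"].stack()
        assert len(ours) == len(oracle)
        for (e, f, t), v in oracle.items():
            assert ours.loc[(e, f, t)] == pytest.approx(v)

    def test_class_means_ordered_outer_above_inner(self):
        params = bq.SimParams(seed=17, reposition_prob=0.0)
        nuclei, tracks, truth = bq.simulate_embryo_series(params)
        forest = bq.build_forest(tracks, nuclei)
        classes = bq.classify_families(forest, truth.labels)
        df = bq.correct_z_attenuation(nuclei, "ch1")
        df = bq.standardize_embryo(df, "ch1")
        traj = bq.family_mean_trajectory(forest, df, "ch1_std", classes)
        per_class = traj["per_class"]
        assert (
            per_class.loc["OUT-TE"] > per_class.loc["IN-ICM"]
        ).all()

    def test_initial_intensity_recovers_group_offset(self):
        params = bq.SimParams(seed=23, n_embryos=10, reposition_prob=0.0)
        nuclei, tracks, truth = bq.simulate_embryo_series(params)
        forest = bq.build_forest(tracks, nuclei)
        classes = bq.classify_families(forest, truth.labels)
        df = bq.correct_z_attenuation(nuclei, "ch1")
        df = bq.standardize_embryo(df, "ch1")
        init = bq.initial_intensity(forest, df, "ch1_std", classes)
        g = init.groupby("family_class").initial.mean()
        assert g["OUT-TE"] > g["IN-ICM"]


class TestPositionChanges:
    def test_no_repositioning_gives_zero_fraction(self, clean_movie):
        _, nuclei, tracks, truth = clean_movie
        forest = bq.build_forest(tracks, nuclei)
        out = bq.position_change_summary(forest, truth.labels)
        assert out["overall_fraction"] == 0.0

    def test_fraction_matches_generator_bookkeeping(self, small_movie):
        _, nuclei, tracks, truth = small_movie
        forest = bq.build_forest(tracks, nuclei)
        out = bq.position_change_summary(forest, truth.labels)
        # with true labels, flips are exactly the realized shell switches
        assert out["n_flips"] == truth.families.n_switches.sum()
        assert out["overall_fraction"] == pytest.approx(
            out["n_flips"] / out["n_transitions"]
        )

    def test_single_frame_movie_has_no_transitions(self):
        nuclei = pd.DataFrame(
            {
                "embryo_id": "E00", "cell_id": [0, 1], "frame": 0,
                "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
            }
        )
        tracks = pd.DataFrame(
            columns=["embryo_id", "child_id", "parent_id", "frame"]
        )
        forest = bq.build_forest(tracks, nuclei)
        labels = pd.DataFrame(
            {"embryo_id": "E00", "cell_id": [0, 1], "frame": 0,
             "label": ["inner", "outer"]}
        )
        out = bq.position_change_summary(forest, labels)
        assert np.isnan(out["overall_fraction"])
        assert out["n_transitions"] == 0


def test_trackmate_xml_round_trip(tmp_path):
    xml = """<?xml version="1.0"?>
    <TrackMate>
      <Model>
        <AllSpots>
          <Spot ID="10" FRAME="0"/>
          <Spot ID="11" FRAME="1"/>
          <Spot ID="12" FRAME="1"/>
        </AllSpots>
        <AllTracks>
          <Track>
            <Edge SPOT_SOURCE_ID="10" SPOT_TARGET_ID="11"/>
            <Edge SPOT_SOURCE_ID="10" SPOT_TARGET_ID="12"/>
          </Track>
        </AllTracks>
      </Model>
    </TrackMate>
    """
    p = tmp_path / "tracks.xml"
    p.write_text(xml)
    tracks = read_trackmate_xml(p, embryo_id="E01")
    assert len(tracks) == 2
    assert set(tracks.child_id) == {"11", "12"}
    nuclei = pd.DataFrame(
        {
            "embryo_id": "E01",
            "cell_id": ["10", "11", "12"],
            "frame": [0, 1, 1],
            "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
        }
    )
    forest = bq.build_forest(tracks, nuclei)
    assert len(forest.leaves(forest.founders[0])) == 2
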