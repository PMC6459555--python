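"""Canny puncta segmentation, cell assignment, colocalization counting, CSV."""

import numpy as np
import pandas as pd
import pytest

from autoflux import puncta
from autoflux.errors import InvalidParameterError
from autoflux.stacks import ImageStack, LabelVolume

ABS_PARAMS = puncta.CannyParams(
    sigma=1.0, low_threshold=100.0, high_threshold=180.0, use_quantiles=False
)


def _spot_stack(centers, shape=(12, 160, 160), amplitude=400.0, sigma=1.2,
                bg=100.0, noise_sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float32)
    for cz, cy, cx in centers:
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        img += amplitude * np.exp(-0.5 * d2 / sigma**2)
    return ImageStack(bg + img + rng.normal(0, noise_sd, shape).astype(np.float32))


class TestSegmentPuncta:
    def test_blank_stack_gives_zero_punctae(self):
        rng = np.random.default_rng(1)
        stack = ImageStack(100 + rng.normal(0, 5, (8, 64, 64)).astype(np.float32))
        out = puncta.segment_puncta(stack, None, ABS_PARAMS)
        assert out.n_objects == 0

    def test_twenty_high_snr_spots_recovered_exactly(self):
        centers = [(6, 20 + 30 * i, 20 + 30 * j) for i in range(5) for j in range(4)]
        stack = _spot_stack(centers)
        out = puncta.segment_puncta(stack, None, ABS_PARAMS)
        assert out.n_objects == 20
        from scipy import ndimage as ndi

        found = ndi.center_of_mass(np.ones(out.shape), out.labels, out.label_ids())
        for cz, cy, cx in found:
            best = min(
                np.hypot(np.hypot(cz - z, cy - y), cx - x) for z, y, x in centers
            )
            assert best <= 1.0

    def test_raising_high_threshold_never_adds_punctae(self):
        centers = [(6, 30 + 25 * i, 40 + 25 * j) for i in range(3) for j in range(3)]
        stack = _spot_stack(centers, noise_sd=8.0, seed=2)
        counts = []
        for hi in (150.0, 300.0, 600.0):
            params = puncta.CannyParams(
                sigma=1.0, low_threshold=100.0, high_threshold=hi, use_quantiles=False
            )
            counts.append(puncta.segment_puncta(stack, None, params).n_objects)
        assert counts[0] >= counts[1] >= counts[2]

    def test_low_ge_high_rejected(self):
        with pytest.raises(InvalidParameterError):
            puncta.CannyParams(low_threshold=0.9, high_threshold=0.5).validate()


class TestAssignment:
    def test_full_containment_and_plurality(self):
        cells = np.zeros((4, 12, 12), np.int32)
        cells[:, :, :6] = 1
        cells[:, :, 6:] = 2
        p = np.zeros_like(cells)
        p[1, 2:4, 2:4] = 1            # fully inside cell 1
        p[1, 6:8, 4:9] = 2            # 2 cols in cell 1, 3 cols in cell 2
        p[2, 10:12, 0:2] = 3
        out = puncta.assign_puncta_to_cells(
            LabelVolume(p, "punctae"), LabelVolume(cells)
        )
        assert out[1] == 1 and out[2] == 2 and out[3] == 1

    def test_tie_breaks_to_smaller_label_and_outside_is_unassigned(self):
        cells = np.zeros((2, 4, 8), np.int32)
        cells[:, :, 1:3] = 7
        cells[:, :, 3:5] = 4
        p = np.zeros_like(cells)
        p[0, 1, 2:4] = 1              # one voxel in 7, one in 4 -> tie -> 4
        p[1, 2, 6:8] = 2              # entirely outside cells
        out = puncta.assign_puncta_to_cells(
            LabelVolume(p, "punctae"), LabelVolume(cells)
        )
        assert out[1] == 4
        assert out[2] is None

    def test_matches_brute_force_vote(self):
        rng = np.random.default_rng(5)
        cells = rng.integers(0, 4, (5, 20, 20)).astype(np.int32)
        p = np.zeros_like(cells)
        for k in range(1, 11):
            z, y, x = rng.integers(0, 4), rng.integers(0, 17), rng.integers(0, 17)
            p[z, y : y + 3, x : x + 3] = k
        out = puncta.assign_puncta_to_cells(LabelVolume(p, "punctae"), LabelVolume(cells))
        for k in range(1, 11):
            votes = cells[p == k]
            votes = votes[votes > 0]
            if votes.size == 0:
                assert out[k] is None
            else:
                counts = np.bincount(votes)
                best = counts.max()
                assert out[k] == int(np.flatnonzero(counts == best)[0])


def _two_channel_fixture():
    cells = np.ones((3, 10, 10), np.int32)
    g = np.zeros_like(cells)
    r = np.zeros_like(cells)
    g[1, 1:3, 1:3] = 1  # overlaps red 1
    g[1, 5:7, 5:7] = 2  # disjoint
    r[1, 2:4, 2:4] = 1
    r[1, 8:10, 8:10] = 2
    gv, rv = LabelVolume(g, "punctae"), LabelVolume(r, "punctae")
    cellsv = LabelVolume(cells)
    ga = puncta.assign_puncta_to_cells(gv, cellsv)
    ra = puncta.assign_puncta_to_cells(rv, cellsv)
    return gv, rv, ga, ra, cellsv


class TestColocalization:
    def test_identical_volumes_give_full_overlap(self):
        lab = np.zeros((2, 8, 8), np.int32)
        lab[0, 1:3, 1:3] = 1
        lab[1, 5:7, 5:7] = 2
        v = LabelVolume(lab, "punctae")
        cells = LabelVolume(np.ones_like(lab))
        a = puncta.assign_puncta_to_cells(v, cells)
        table = puncta.count_colocalization(v, v, a, a, cells)
        row = table.per_cell.iloc[0]
        assert row.frac_green_overlapping == 1.0
        assert row.frac_red_overlapping == 1.0

    def test_disjoint_volumes_give_zero_overlap(self):
        gv, rv, ga, ra, cells = _two_channel_fixture()
        rv_far = LabelVolume(np.roll(rv.labels, 5, axis=2), "punctae")
        ra_far = puncta.assign_puncta_to_cells(rv_far, cells)
        table = puncta.count_colocalization(gv, rv_far, ga, ra_far, cells)
        assert table.per_cell.n_green_overlapping_red.sum() == 0

    def test_min_overlap_and_symmetric_pair_accounting(self):
        gv, rv, ga, ra, cells = _two_channel_fixture()
        t1 = puncta.count_colocalization(gv, rv, ga, ra, cells, min_overlap_vox=1)
        row = t1.per_cell.iloc[0]
        assert (row.n_green, row.n_red) == (2, 2)
        assert row.n_green_overlapping_red == 1 == row.n_red_overlapping_green
        # overlap of exactly 1 voxel disappears at min_overlap_vox=2
        t2 = puncta.count_colocalization(gv, rv, ga, ra, cells, min_overlap_vox=2)
        assert t2.per_cell.iloc[0].n_green_overlapping_red == 0

    def test_count_conservation_assigned_plus_unassigned(self, default_pipeline_result):
        result, _ = default_pipeline_result
        table = result["table"]
        s = table.field_summary.iloc[0]
        assert (
            table.per_cell.n_green.sum() + s.unassigned_green
            <= s.total_green
        )
        # every punctum is assigned to at most one cell
        assigned = sum(1 for c in result["green_assignment"].values() if c is not None)
        assert assigned + s.unassigned_green == s.total_green

    def test_empty_cells_reported_as_missing_fraction(self):
        cells = LabelVolume(np.ones((2, 6, 6), np.int32))
        empty = LabelVolume(np.zeros((2, 6, 6), np.int32), "punctae")
        table = puncta.count_colocalization(empty, empty, {}, {}, cells)
        assert np.isnan(table.per_cell.iloc[0].frac_green_overlapping)


class TestPunctaCsv:
    def test_round_trip_is_lossless(self, tmp_path, default_pipeline_result):
        result, _ = default_pipeline_result
        path = tmp_path / "puncta.csv"
        puncta.write_puncta_csv(result["table"], path)
        back = puncta.read_puncta_csv(path)
        pd.testing.assert_frame_equal(
            back.per_cell, result["table"].per_cell, check_dtype=False
        )
        pd.testing.assert_frame_equal(
            back.field_summary, result["table"].field_summary, check_dtype=False
        )

    def test_empty_table_is_header_only(self, tmp_path):
        table = puncta.PunctaTable(
            per_cell=pd.DataFrame(columns=puncta._CELL_COLS),
            field_summary=pd.DataFrame(columns=puncta._FIELD_COLS),
        )
        path = tmp_path / "empty.csv"
        puncta.write_puncta_csv(table, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("scope,")

    def test_counts_are_integers_fractions_are_decimals(self, tmp_path):
        gv, rv, ga, ra, cells = _two_channel_fixture()
        table = puncta.count_colocalization(gv, rv, ga, ra, cells)
        path = tmp_path / "fmt.csv"
        puncta.write_puncta_csv(table, path)
        cell_line = path.read_text().splitlines()[1].split(",")
        header = path.read_text().splitlines()[0].split(",")
        n_green = cell_line[header.index("n_green")]
        frac = cell_line[header.index("frac_green_overlapping")]
        assert n_green == "2"
        assert frac == "0.5"
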