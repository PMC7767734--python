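import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicyto import (
    MultiChannelImage,
    gate_cells,
    measure_cells,
    scatter_summary,
    stratum_distribution,
)
from epicyto.cells import CellMasks
from epicyto.nuclei import nuclei_set_from_labels
from conftest import match_to_truth


def _two_cell_setup():
    """Tiny hand-enumerable scene: 2 cells of 3x3, nuclei of 1 px."""
    cell_labels = np.zeros((6, 10), dtype=np.int32)
    cell_labels[1:4, 1:4] = 1
    cell_labels[1:4, 5:8] = 2
    nuc_labels = np.zeros_like(cell_labels)
    nuc_labels[2, 2] = 1
    nuc_labels[2, 6] = 2
    k14 = np.arange(60, dtype=float).reshape(6, 10)
    bf = np.full((6, 10), 200.0)
    bf[1:4, 1:4] = 150.0   # cell 1 attenuated by 50
    bf[2, 2] = 140.0       # nuclear pixel (excluded from cytoplasm)
    image = MultiChannelImage({"k14": k14, "brightfield": bf}, 1.0)
    nuclei = nuclei_set_from_labels(nuc_labels, k14, 1.0)
    table = pd.DataFrame({"cell_id": [1, 2], "row": [2.0, 2.0],
                          "col": [2.0, 6.0],
                          "stratum": ["basal", "low_suprabasal"]})
    cells = CellMasks(labels=cell_labels, nuclei=nuclei, table=table)
    return cells, nuclei, image


class TestMeasureCells:
    def test_uniform_channel_exact(self):
        cells, nuclei, image = _two_cell_setup()
        uniform = MultiChannelImage(
            {"k14": np.full((6, 10), 7.0), "brightfield": np.full((6, 10), 3.0)},
            1.0)
        tab = measure_cells(cells, nuclei, uniform)
        assert (tab["k14_nuc_mean"] == 7.0).all()
        assert (tab["k14_cyto_mean"] == 7.0).all()
        assert (tab["k14_cell_mean"] == 7.0).all()

    def test_hand_computed_means(self):
        cells, nuclei, image = _two_cell_setup()
        tab = measure_cells(cells, nuclei, image).set_index("cell_id")
        k14 = image.planes["k14"]
        # cell 1: block rows 1..3, cols 1..3; nucleus at (2,2)
        block = k14[1:4, 1:4]
        assert tab.loc[1, "k14_nuc_mean"] == k14[2, 2]
        assert tab.loc[1, "k14_cell_mean"] == pytest.approx(block.mean())
        cyto = (block.sum() - k14[2, 2]) / 8
        assert tab.loc[1, "k14_cyto_mean"] == pytest.approx(cyto)
        # activity: background anchor is the modal value 200
        assert tab.attrs["od_anchor"] == 200.0
        assert tab.loc[1, "activity_od"] == pytest.approx(50.0)
        # cell 2 sits at background level -> OD contribution 0
        assert tab.loc[2, "activity_od"] == pytest.approx(0.0)

    def test_mask_locality(self):
        cells, nuclei, image = _two_cell_setup()
        before = measure_cells(cells, nuclei, image).set_index("cell_id")
        planes = {k: v.copy() for k, v in image.planes.items()}
        planes["k14"][1:4, 5:8] = 999.0   # edit only cell 2's pixels
        edited = MultiChannelImage(planes, 1.0)
        after = measure_cells(cells, nuclei, edited).set_index("cell_id")
        for col in ("k14_nuc_mean", "k14_cyto_mean", "k14_cell_mean",
                    "activity_od"):
            assert after.loc[1, col] == before.loc[1, col]
        assert after.loc[2, "k14_cell_mean"] != before.loc[2, "k14_cell_mean"]

    def test_nucleus_filling_mask_flags_missing_cytoplasm(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[1:4, 1:4] = 1
        nuclei = nuclei_set_from_labels(labels.copy(), np.ones((5, 5)), 1.0)
        table = pd.DataFrame({"cell_id": [1], "row": [2.0], "col": [2.0],
                              "stratum": ["basal"]})
        cells = CellMasks(labels=labels, nuclei=nuclei, table=table)
        img = MultiChannelImage({"k14": np.ones((5, 5))}, 1.0)
        tab = measure_cells(cells, nuclei, img)
        assert tab["cyto_missing"].all()
        assert np.isnan(tab["k14_cyto_mean"]).all()

    def test_activity_ordering_on_section(self, default_result):
        med = default_result.table.groupby("stratum")["activity_od"].median()
        assert med["basal"] < med["low_suprabasal"] < med["high_suprabasal"]


class TestGating:
    def test_threshold_above_max_zero_positives(self, default_result):
        tab = gate_cells(default_result.table, "k14", rule=1e9)
        assert tab["k14_pos"].sum() == 0
        assert tab.attrs["gates"]["k14"]["rule"] == "absolute"

    def test_otsu_matches_ground_truth(self, default_section, default_result):
        _, gt = default_section
        tab = gate_cells(default_result.table, "k14", "otsu")
        matched, idx = match_to_truth(tab[["row", "col"]].to_numpy(),
                                      gt.cells[["row", "col"]].to_numpy())
        truth = gt.cells["k14_pos"].to_numpy()[idx]
        acc = (tab["k14_pos"].to_numpy()[matched] == truth[matched]).mean()
        assert acc >= 0.98

    def test_bg_sd_rule_requires_control(self, default_result):
        with pytest.raises(ValueError, match="control"):
            gate_cells(default_result.table, "gh2ax", "bg+k*sd",
                       compartment="nuc")
        ctrl = default_result.table["stratum"] == "basal"
        tab = gate_cells(default_result.table, "gh2ax", "bg+k*sd",
                         compartment="nuc", control=ctrl)
        assert "gh2ax_pos" in tab.columns


class TestStratumDistribution:
    def test_all_basal(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 5})
        dist = stratum_distribution(tab)
        assert dist["basal"] == 1.0
        assert dist["low_suprabasal"] == 0.0
        assert dist["high_suprabasal"] == 0.0

    def test_empty_subset_flagged(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 5})
        dist = stratum_distribution(tab, subset=np.zeros(5, bool))
        assert dist.attrs["empty"]
        assert (dist == 0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        ["basal", "low_suprabasal", "high_suprabasal"]),
        min_size=1, max_size=40))
    def test_fractions_sum_to_one(self, strata):
        tab = pd.DataFrame({"stratum": strata})
        assert stratum_distribution(tab).sum() == pytest.approx(1.0, abs=1e-12)


class TestScatterSummary:
    def test_identical_points_single_bin_contour(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 20,
                            "x": [5.0] * 20, "y": [3.0] * 20})
        out = scatter_summary(tab, "x", "y")["basal"]
        assert out.contour.sum() == 1
        assert out.coverage == 1.0

    def test_contour_definitional_minimality(self, default_result):
        tab = default_result.table
        out = scatter_summary(tab, "k14_cyto_mean", "k10_cyto_mean")
        for s in out.values():
            if s.contour is None:
                continue
            assert s.coverage >= 0.95
            inside = s.hist[s.contour]
            # dropping the least-populated contour bin goes below 95 %
            assert (inside.sum() - inside.min()) < 0.95 * s.hist.sum()

    def test_basal_low_regions_disjoint(self, default_result):
        out = scatter_summary(default_result.table, "k14_cyto_mean",
                              "k10_cyto_mean")
        overlap = out["basal"].contour & out["low_suprabasal"].contour
        assert overlap.sum() == 0

    def test_small_group_omits_contour(self):
        tab = pd.DataFrame({"stratum": ["basal"] * 3,
                            "x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        out = scatter_summary(tab, "x", "y")["basal"]
        assert out.contour is None
        assert out.hist.sum() == 3
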