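import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import pulsekinetics as pk
from pulsekinetics import subcellular as sub
from pulsekinetics.datamodel import empty_reads


def _toy_seg():
    """One hand-built cell in a 16^3 grid: cube cell, cube nucleus."""
    grid = pk.VoxelGrid((16, 16, 16))
    cells = np.zeros(grid.shape, np.int32)
    nuc = np.zeros(grid.shape, np.int32)
    cells[3:13, 3:13, 4:12] = 1
    nuc[6:10, 6:10, 6:10] = 1
    return pk.SegmentationSet(grid=grid, nucleus_labels=nuc, cell_labels=cells)


class TestComputeDr:
    def test_periphery_cutoff_identity(self):
        # d_n/d_c = 10 corresponds to the 0.909 middle/periphery cutoff
        assert sub.compute_dr(10.0, 1.0) == pytest.approx(0.909, abs=5e-4)

    def test_nuclear_surface_is_zero(self):
        assert sub.compute_dr(0.0, 5.0) == 0.0

    def test_symmetry_midpoint(self):
        assert sub.compute_dr(3.0, 3.0) == 0.5

    def test_degenerate_geometry_warns_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = sub.compute_dr(0.0, 0.0)
        assert np.isnan(out)

    def test_monotone_in_dn_for_fixed_dc(self):
        dn = np.linspace(0, 50, 20)
        dr = sub.compute_dr(dn, np.full_like(dn, 7.0))
        assert (np.diff(dr) > 0).all()
        assert ((dr >= 0) & (dr <= 1)).all()


class TestDistanceFields:
    def test_brute_force_oracle_small_volume(self):
        # exhaustive all-pairs distances to the surface shells on a
        # <= 20^3 volume must match the EDT implementation exactly
        seg = _toy_seg()
        fields = sub.distance_fields(seg, physical=True)
        sp = np.array(seg.grid.spacing)
        cell = seg.cell_labels == 1
        nucleus = seg.nucleus_labels == 1
        cyto = cell & ~nucleus

        # surface shells by brute-force 26-neighborhood scan
        def shell_of(mask):
            out = np.zeros_like(mask)
            idx = np.argwhere(mask)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        shifted = idx + (dx, dy, dz)
                        ok = ((shifted >= 0) & (shifted < mask.shape)).all(axis=1)
                        s = shifted[ok]
                        out[s[:, 0], s[:, 1], s[:, 2]] = True
            return out

        nuc_zero = shell_of(nucleus)
        bg_zero = shell_of(~cell)
        nz = np.argwhere(nuc_zero) * sp
        bz = np.argwhere(bg_zero) * sp
        for p in np.argwhere(cyto)[::7]:  # subsample for speed
            pos = p * sp
            dn = np.sqrt(((nz - pos) ** 2).sum(axis=1)).min()
            dc = np.sqrt(((bz - pos) ** 2).sum(axis=1)).min()
            # fields store float32; 0.1 nm slack covers the rounding
            assert fields.d_n[tuple(p)] == pytest.approx(dn, abs=0.1)
            assert fields.d_c[tuple(p)] == pytest.approx(dc, abs=0.1)

    def test_dn_zero_on_nucleus_adjacent_voxels(self):
        seg = _toy_seg()
        fields = sub.distance_fields(seg)
        nucleus = seg.nucleus_labels == 1
        adjacent = ndimage.binary_dilation(nucleus, np.ones((3, 3, 3), bool)) & ~nucleus
        adjacent &= (seg.cell_labels == 1)
        assert (fields.d_n[adjacent] == 0).all()

    def test_dr_in_unit_interval(self, small_fields):
        dr = small_fields.dr
        vals = dr[np.isfinite(dr)]
        assert vals.min() >= 0 and vals.max() <= 1

    def test_dn_only_to_own_nucleus(self, small_geometry, small_fields):
        # no cytoplasmic voxel's d_n can beat the distance to its own
        # cell's nearest nucleus voxel computed per cell
        seg = small_geometry
        label = int(seg.labels[0])
        cyto = (seg.cell_labels == label) & (seg.nucleus_labels == 0)
        assert np.isfinite(small_fields.d_n[cyto]).all()


class TestAssignReads:
    def test_nucleus_and_background_assignment(self):
        seg = _toy_seg()
        reads = empty_reads()
        reads = pd.concat(
            [
                reads,
                pd.DataFrame(
                    {
                        "gene": ["A", "A"],
                        "x": [7, 0],
                        "y": [7, 0],
                        "z": [7, 0],
                        "timepoint_h": [0.0, 0.0],
                        "cell_id": [0, 0],
                        "compartment": ["unassigned"] * 2,
                        "dr": [np.nan] * 2,
                        "quality": [np.nan] * 2,
                    }
                ),
            ],
            ignore_index=True,
        )
        out = sub.assign_reads(reads, seg)
        assert out.loc[0, "cell_id"] == 1 and out.loc[0, "compartment"] == "nucleus"
        assert out.loc[1, "cell_id"] == 0 and out.loc[1, "compartment"] == "unassigned"

    def test_counts_match_brute_force_membership(self, small_geometry, small_experiment):
        # per-cell counts after assignment equal direct voxel lookups
        _, reads, _ = small_experiment
        out = sub.assign_reads(reads, small_geometry)
        for _, row in out.head(200).iterrows():
            expected = small_geometry.cell_labels[row.x, row.y, row.z]
            assert row.cell_id == expected

    def test_shape_mismatch_raises(self, small_geometry):
        reads = empty_reads()
        bad = pk.SegmentationSet(
            grid=pk.VoxelGrid((4, 4, 4)),
            nucleus_labels=np.zeros((4, 4, 4), np.int32),
            cell_labels=np.zeros((4, 4, 4), np.int32),
        )
        # a read outside the tiny grid triggers the coordinate check
        reads = pd.concat(
            [reads, pd.DataFrame({"gene": ["A"], "x": [10], "y": [0], "z": [0],
                                  "timepoint_h": [0.0], "cell_id": [0],
                                  "compartment": ["unassigned"], "dr": [np.nan],
                                  "quality": [np.nan]})],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="outside grid"):
            sub.assign_reads(reads, bad)


class TestSplitCytoplasm:
    @pytest.mark.parametrize("dr, expected", [(0.95, "periphery"), (0.5, "middle")])
    def test_cutoff_rule(self, dr, expected, small_geometry, small_fields):
        # pick a real cytoplasmic voxel, then force its DR via cutoff choice
        seg = small_geometry
        cyto = np.argwhere((seg.cell_labels > 0) & (seg.nucleus_labels == 0))[0]
        reads = pd.DataFrame(
            {"gene": ["A"], "x": [cyto[0]], "y": [cyto[1]], "z": [cyto[2]],
             "timepoint_h": [0.0], "cell_id": [0], "compartment": ["unassigned"],
             "dr": [np.nan], "quality": [np.nan]}
        )
        out = sub.assign_reads(reads, seg)
        actual_dr = small_fields.dr[cyto[0], cyto[1], cyto[2]]
        split = sub.split_cytoplasm(out, small_fields, cutoff=0.909)
        want = "periphery" if actual_dr > 0.909 else "middle"
        assert split.loc[0, "compartment"] == want

    def test_cutoff_zero_sends_all_to_periphery(self, small_geometry, small_fields, small_experiment):
        _, reads, _ = small_experiment
        out = sub.assign_reads(reads.head(300), small_geometry)
        split = sub.split_cytoplasm(out, small_fields, cutoff=0.0)
        cyto = split[split["dr"].notna() & (split["dr"] > 0)]
        assert (cyto["compartment"] == "periphery").all()

    def test_invalid_cutoff(self, small_fields, toy_reads):
        with pytest.raises(ValueError):
            sub.split_cytoplasm(toy_reads, small_fields, cutoff=1.5)


class TestCellVolumes:
    def test_additivity_and_brute_force(self, small_geometry):
        vols = sub.cell_volumes(small_geometry)
        assert (vols["total_voxels"] == vols["nucleus_voxels"] + vols["cytoplasm_voxels"]).all()
        for label in small_geometry.labels:
            assert vols.loc[label, "total_voxels"] == int(
                (small_geometry.cell_labels == label).sum()
            )
            assert vols.loc[label, "nucleus_voxels"] == int(
                (small_geometry.nucleus_labels == label).sum()
            )

    def test_empty_segmentation_warns(self):
        grid = pk.VoxelGrid((4, 4, 4))
        seg = pk.SegmentationSet(
            grid=grid,
            nucleus_labels=np.zeros(grid.shape, np.int32),
            cell_labels=np.zeros(grid.shape, np.int32),
        )
        with pytest.warns(UserWarning, match="no labels"):
            vols = sub.cell_volumes(seg)
        assert len(vols) == 0


class TestCompartmentFractions:
    def test_fractions_sum_to_one_and_invert(self, small_matrix):
        cm, _, _ = small_matrix
        frac = sub.compartment_fractions(cm)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)
        # fractions x group totals reconstruct counts
        for t, row in frac.iterrows():
            cols = np.nonzero((cm.cells["timepoint_h"] == t).to_numpy())[0]
            total = sum(float(cm.counts[c][:, cols].sum()) for c in pk.COMPARTMENTS)
            for comp in pk.COMPARTMENTS:
                assert row[comp] * total == pytest.approx(
                    float(cm.counts[comp][:, cols].sum())
                )
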