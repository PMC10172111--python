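"""Read-to-cell assignment and 3D subcellular partitioning.

A cytoplasmic read's radial position is summarized by its distance
ratio ``DR = d_n / (d_n + d_c)``, where ``d_n`` is the shortest
distance to the nuclear surface and ``d_c`` the shortest distance to
the cell membrane.  DR is 0 at the nuclear surface and approaches 1 at
the membrane; a cutoff of 0.909 (``d_n/d_c = 10``) splits the
cytoplasm into a 'middle' and a thin 'periphery' shell.

Surface convention: distances are Euclidean distance transforms whose
zero set is the first cytoplasmic voxel shell of each surface — the
cytoplasmic voxels 26-adjacent to the nucleus (for ``d_n``) and those
adjacent to the background (for ``d_c``).  Both shells therefore sit
exactly at distance 0, so DR spans the full [0, 1] range on the
discrete grid.  ``d_n`` is measured to the read's *own* cell's nucleus
only.  Distances use physical anisotropic voxel spacing by default;
``physical=False`` switches to index units for replicating isotropic
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .datamodel import (
    COMPARTMENTS,
    CompartmentMatrix,
    PulseChaseDesign,
    SegmentationSet,
    validate_reads,
)

__all__ = [
    "DistanceFields",
    "distance_fields",
    "compute_dr",
    "assign_reads",
    "split_cytoplasm",
    "assign_and_partition",
    "cell_volumes",
    "count_matrix",
    "compartment_fractions",
    "DEFAULT_DR_CUTOFF",
]

#: DR above which a cytoplasmic read is 'periphery' (d_n/d_c = 10)
DEFAULT_DR_CUTOFF = 0.909

_STRUCT = np.ones((3, 3, 3), bool)  # 26-connectivity for surface shells


@dataclass
class DistanceFields:
    """Per-voxel distances (nm) to nuclear surface and cell membrane.

    ``d_n``/``d_c`` are full-volume float32 arrays, NaN outside the
    cytoplasm; ``dr`` is their precomputed ratio.
    """

    grid_shape: tuple[int, int, int]
    d_n: np.ndarray
    d_c: np.ndarray
    dr: np.ndarray


def compute_dr(d_n, d_c):
    """Distance ratio ``d_n / (d_n + d_c)``, elementwise.

    Returns NaN (with a warning) where ``d_n + d_c == 0`` — a voxel
    adjacent to both surfaces, i.e. degenerately thin cytoplasm.
    """
    d_n = np.asarray(d_n, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    if (d_n < 0).any() or (d_c < 0).any():
        raise ValueError("distances must be nonnegative")
    total = d_n + d_c
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(
            f"{int(np.sum(degenerate))} degenerate voxel(s) with d_n + d_c = 0; DR set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(degenerate, np.nan, d_n / np.where(degenerate, 1.0, total))
    if out.ndim == 0:
        return float(out)
    return out


def distance_fields(seg: SegmentationSet, physical: bool = True) -> DistanceFields:
    """Compute ``d_n``, ``d_c`` and DR for every cytoplasmic voxel.

    Each cell is processed in its padded bounding box; ``d_n`` uses only
    that cell's nucleus, so reads never measure distance to a
    neighboring cell's nucleus.
    """
    sampling = seg.grid.spacing if physical else (1.0, 1.0, 1.0)
    shape = seg.grid.shape
    d_n = np.full(shape, np.nan, dtype=np.float32)
    d_c = np.full(shape, np.nan, dtype=np.float32)

    slices = ndimage.find_objects(seg.cell_labels)
    for label, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        slc = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(slc, shape)
        )
        cell = seg.cell_labels[slc] == label
        nuc = seg.nucleus_labels[slc] == label
        cyto = cell & ~nuc
        if not cyto.any():
            continue
        # zero sets: one-voxel shells just outside each surface
        nuc_shell = ndimage.binary_dilation(nuc, _STRUCT)
        bg_shell = ndimage.binary_dilation(~cell, _STRUCT)
        dn = ndimage.distance_transform_edt(~nuc_shell, sampling=sampling) if nuc.any() else np.zeros(cell.shape)
        dc = ndimage.distance_transform_edt(~bg_shell, sampling=sampling)
        d_n[slc] = np.where(cyto, dn, d_n[slc])
        d_c[slc] = np.where(cyto, dc, d_c[slc])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate voxels surface later, per read
        total = d_n + d_c
        dr = np.where(total > 0, d_n / np.where(total > 0, total, 1.0), np.nan).astype(np.float32)
    return DistanceFields(grid_shape=shape, d_n=d_n, d_c=d_c, dr=dr)


def assign_reads(reads: pd.DataFrame, seg: SegmentationSet) -> pd.DataFrame:
    """Assign each read to the cell and gross compartment at its voxel.

    ``cell_id`` becomes the cell label at the read's position (0 for
    background); ``compartment`` becomes ``nucleus``, ``cytoplasm``
    (pending the DR split) or ``unassigned``.
    """
    validate_reads(reads, grid=seg.grid)
    out = reads.copy()
    xi = out["x"].to_numpy(dtype=np.intp)
    yi = out["y"].to_numpy(dtype=np.intp)
    zi = out["z"].to_numpy(dtype=np.intp)
    cell = seg.cell_labels[xi, yi, zi]
    nuc = seg.nucleus_labels[xi, yi, zi]
    out["cell_id"] = cell.astype(np.int64)
    comp = np.where(cell == 0, "unassigned", np.where(nuc > 0, "nucleus", "cytoplasm"))
    out["compartment"] = comp
    out["dr"] = np.nan
    return out


def split_cytoplasm(
    reads: pd.DataFrame,
    fields: DistanceFields,
    cutoff: float = DEFAULT_DR_CUTOFF,
) -> pd.DataFrame:
    """Resolve cytoplasmic reads into middle vs periphery by DR.

    Strictly ``DR > cutoff`` is periphery; ties go to middle.  Reads at
    degenerate voxels (``d_n + d_c = 0``) keep ``dr = NaN`` and fall to
    middle with a warning.
    """
    if not (0 <= cutoff < 1):
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    out = reads.copy()
    is_cyto = out["compartment"].isin(["cytoplasm", "middle", "periphery"]).to_numpy()
    if not is_cyto.any():
        return out
    xi = out["x"].to_numpy(dtype=np.intp)[is_cyto]
    yi = out["y"].to_numpy(dtype=np.intp)[is_cyto]
    zi = out["z"].to_numpy(dtype=np.intp)[is_cyto]
    dr = fields.dr[xi, yi, zi].astype(float)
    n_degen = int(np.isnan(dr).sum())
    if n_degen:
        warnings.warn(
            f"{n_degen} cytoplasmic read(s) at degenerate voxels (d_n + d_c = 0); DR missing",
            stacklevel=2,
        )
    comp = np.where(dr > cutoff, "periphery", "middle")
    out.loc[is_cyto, "dr"] = dr
    out.loc[is_cyto, "compartment"] = comp
    return out


def assign_and_partition(
    reads: pd.DataFrame,
    seg: SegmentationSet,
    cutoff: float = DEFAULT_DR_CUTOFF,
    physical: bool = True,
    fields: DistanceFields | None = None,
) -> pd.DataFrame:
    """Full spatial assignment: cell, nucleus/middle/periphery, DR."""
    if fields is None:
        fields = distance_fields(seg, physical=physical)
    return split_cytoplasm(assign_reads(reads, seg), fields, cutoff=cutoff)


def cell_volumes(seg: SegmentationSet) -> pd.DataFrame:
    """Voxel counts per cell: nucleus, cytoplasm and total.

    Indexed by cell label; an absent label queried downstream simply has
    no row.
    """
    labels = seg.labels
    if labels.size == 0:
        warnings.warn("segmentation contains no labels", stacklevel=2)
        return pd.DataFrame(columns=["nucleus_voxels", "cytoplasm_voxels", "total_voxels"])
    nmax = int(labels.max())
    total = np.bincount(seg.cell_labels.ravel(), minlength=nmax + 1)
    nuc = np.bincount(seg.nucleus_labels.ravel(), minlength=nmax + 1)
    df = pd.DataFrame(
        {
            "nucleus_voxels": nuc[labels],
            "cytoplasm_voxels": total[labels] - nuc[labels],
            "total_voxels": total[labels],
        },
        index=pd.Index(labels, name="cell_id"),
    )
    return df


def count_matrix(
    reads: pd.DataFrame,
    seg: SegmentationSet,
    design: PulseChaseDesign | None = None,
    genes: list[str] | None = None,
) -> CompartmentMatrix:
    """Build the compartment-resolved gene-by-cell count matrix.

    A "cell" is a (cell label, timepoint) pair — each chase timepoint is
    an independent cohort sharing the segmentation.  Unassigned reads
    are dropped.
    """
    validate_reads(reads, design=design)
    assigned = reads[(reads["cell_id"] > 0) & reads["compartment"].isin(COMPARTMENTS)]
    if genes is None:
        genes = sorted(assigned["gene"].unique())
    gene_idx = {g: i for i, g in enumerate(genes)}
    vols = cell_volumes(seg)

    tps = sorted(assigned["timepoint_h"].unique()) if design is None else list(design.chase_hours)
    if design is not None and design.steady_state_hours is not None:
        tps.append(-1.0)
    cell_keys = [(t, int(c)) for t in tps for c in vols.index]
    key_idx = {k: i for i, k in enumerate(cell_keys)}
    cells = pd.DataFrame(
        {
            "cell_id": [c for _, c in cell_keys],
            "timepoint_h": [t for t, _ in cell_keys],
            "volume_voxels": [int(vols.loc[c, "total_voxels"]) for _, c in cell_keys],
            "nucleus_voxels": [int(vols.loc[c, "nucleus_voxels"]) for _, c in cell_keys],
            "phase": pd.array([pd.NA] * len(cell_keys), dtype=object),
            "batch": 0,
        }
    )

    counts = {}
    for comp in COMPARTMENTS:
        sub = assigned[assigned["compartment"] == comp]
        rows = sub["gene"].map(gene_idx).to_numpy(dtype=np.intp)
        cols = np.fromiter(
            (key_idx[(t, int(c))] for t, c in zip(sub["timepoint_h"], sub["cell_id"])),
            dtype=np.intp,
            count=len(sub),
        )
        counts[comp] = sparse.coo_matrix(
            (np.ones(len(sub), dtype=np.int64), (rows, cols)),
            shape=(len(genes), len(cell_keys)),
        ).tocsr()
    return CompartmentMatrix(genes=list(genes), cells=cells, counts=counts)


def compartment_fractions(cm: CompartmentMatrix, by: str = "timepoint_h") -> pd.DataFrame:
    """Fraction of reads in each compartment, per group of cells.

    Fractions sum to 1 per group; an empty group raises.
    """
    groups = cm.cells.groupby(by).indices
    rows = []
    for key, idx in sorted(groups.items()):
        totals = {comp: float(cm.counts[comp][:, idx].sum()) for comp in COMPARTMENTS}
        denom = sum(totals.values())
        if denom == 0:
            raise ValueError(f"group {by}={key} has no reads")
        rows.append({by: key, **{c: totals[c] / denom for c in COMPARTMENTS}})
    return pd.DataFrame(rows).set_index(by)
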