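"""Shared data model and on-disk formats.

The pipeline's central currency is the *read table*: one row per decoded
amplicon (a single detected RNA molecule) carrying its gene identity, 3D
voxel position, pulse-chase timepoint, and — once assigned — its cell,
subcellular compartment and distance ratio (DR).

Conventions fixed here, once, for the whole package:

* voxel coordinates are 0-based integer indices ``(x, y, z)``;
* in-memory label volumes are numpy arrays indexed ``[x, y, z]``;
* on disk, label volumes are multi-page TIFFs with one page per z-plane
  (page layout ``(y, x)``, z slowest) plus a JSON sidecar with spacing;
* ``timepoint_h = -1`` encodes a steady-state long-pulse sample so it can
  never silently enter a kinetic regression;
* gene-by-cell count matrices go to Matrix Market files with gene/cell
  TSV sidecars.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "VoxelGrid",
    "SegmentationSet",
    "PulseChaseDesign",
    "GeneSets",
    "CompartmentMatrix",
    "COMPARTMENTS",
    "READ_COLUMNS",
    "STEADY_STATE_TIMEPOINT",
    "empty_reads",
    "validate_reads",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_label_tiff",
    "write_label_tiff",
    "write_matrix_market",
    "read_matrix_market",
]

#: compartments a read can be assigned to, in canonical order
COMPARTMENTS = ("nucleus", "middle", "periphery")

#: sentinel chase time for the steady-state (long-pulse) sample
STEADY_STATE_TIMEPOINT = -1.0

#: required columns of a read table, in canonical order
READ_COLUMNS = (
    "gene",
    "x",
    "y",
    "z",
    "timepoint_h",
    "cell_id",
    "compartment",
    "dr",
    "quality",
)

_INT_COLUMNS = ("x", "y", "z", "cell_id")
_VALID_COMPARTMENTS = frozenset(COMPARTMENTS) | {"unassigned", "cytoplasm"}


@dataclass(frozen=True)
class VoxelGrid:
    """Anisotropic voxel grid: shape in voxels, spacing in nm.

    Default spacing (200, 200, 350) nm matches confocal in situ
    sequencing stacks with 350 nm z-steps.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (200.0, 200.0, 350.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class SegmentationSet:
    """Paired nucleus / whole-cell 3D label volumes on one grid.

    Label ``k``'s nucleus voxels must be a subset of label ``k``'s cell
    voxels; 0 is background.  The cytoplasm of cell ``k`` is its cell
    mask minus its nucleus mask.
    """

    grid: VoxelGrid
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray

    def __post_init__(self) -> None:
        for name, vol in (("nucleus_labels", self.nucleus_labels), ("cell_labels", self.cell_labels)):
            if tuple(vol.shape) != self.grid.shape:
                raise ValueError(
                    f"{name} shape {vol.shape} does not match grid shape {self.grid.shape}"
                )
        nuc = self.nucleus_labels
        mismatch = (nuc > 0) & (self.cell_labels != nuc)
        if mismatch.any():
            raise ValueError(
                f"{int(mismatch.sum())} nucleus voxels fall outside their cell mask"
            )

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero cell labels present in the volume."""
        out = np.unique(self.cell_labels)
        return out[out > 0]


@dataclass(frozen=True)
class PulseChaseDesign:
    """Pulse-chase experimental design.

    ``excluded_chase_hours`` are timepoints dropped from every kinetic
    regression (default {1}: the 1 h chase sample is contaminated by
    residual label after washing and behaves as an outlier of the decay
    model).
    """

    pulse_hours: float = 1.0
    chase_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)
    excluded_chase_hours: frozenset[float] = frozenset({1.0})
    steady_state_hours: float | None = None

    def __post_init__(self) -> None:
        ch = tuple(float(t) for t in self.chase_hours)
        if any(t < 0 for t in ch):
            raise ValueError("chase hours must be nonnegative")
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError(f"chase hours must be strictly increasing, got {ch}")
        exc = frozenset(float(t) for t in self.excluded_chase_hours)
        if not exc <= set(ch):
            raise ValueError(f"excluded timepoints {sorted(exc - set(ch))} not in design")
        if self.pulse_hours <= 0:
            raise ValueError("pulse duration must be positive")
        object.__setattr__(self, "chase_hours", ch)
        object.__setattr__(self, "excluded_chase_hours", exc)

    @property
    def usable_chase_hours(self) -> tuple[float, ...]:
        """Chase timepoints entering the kinetic regressions."""
        return tuple(t for t in self.chase_hours if t not in self.excluded_chase_hours)

    @property
    def valid_timepoints(self) -> frozenset[float]:
        tps = set(self.chase_hours)
        if self.steady_state_hours is not None:
            tps.add(STEADY_STATE_TIMEPOINT)
        return frozenset(tps)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "pulse_hours": self.pulse_hours,
            "chase_hours": list(self.chase_hours),
            "excluded_chase_hours": sorted(self.excluded_chase_hours),
            "steady_state_hours": self.steady_state_hours,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PulseChaseDesign":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            pulse_hours=doc["pulse_hours"],
            chase_hours=tuple(doc["chase_hours"]),
            excluded_chase_hours=frozenset(doc.get("excluded_chase_hours", ())),
            steady_state_hours=doc.get("steady_state_hours"),
        )


@dataclass(frozen=True)
class GeneSets:
    """Gene annotations consumed by the pipeline.

    ``reference_genes`` are probed for *total* (not just pulse-labeled)
    RNA, assumed time-invariant, and anchor the cross-timepoint count
    normalization.  The marker lists drive cell-cycle phase scoring;
    ``m6a_labels`` maps gene -> {'m6a', 'non_m6a', 'unknown'}.
    """

    reference_genes: tuple[str, ...] = ()
    g1s_markers: tuple[str, ...] = ()
    g2m_markers: tuple[str, ...] = ()
    m6a_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.g1s_markers) & set(self.g2m_markers)
        if overlap:
            raise ValueError(f"marker lists must be disjoint; shared genes: {sorted(overlap)}")
        bad = {v for v in self.m6a_labels.values()} - {"m6a", "non_m6a", "unknown"}
        if bad:
            raise ValueError(f"invalid m6a labels: {sorted(bad)}")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "reference_genes": list(self.reference_genes),
            "g1s_markers": list(self.g1s_markers),
            "g2m_markers": list(self.g2m_markers),
            "m6a_labels": dict(sorted(self.m6a_labels.items())),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneSets":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            reference_genes=tuple(doc.get("reference_genes", ())),
            g1s_markers=tuple(doc.get("g1s_markers", ())),
            g2m_markers=tuple(doc.get("g2m_markers", ())),
            m6a_labels=dict(doc.get("m6a_labels", {})),
        )


@dataclass
class CompartmentMatrix:
    """Gene-by-cell counts resolved by subcellular compartment.

    ``counts`` holds one sparse genes x cells matrix per compartment;
    ``total`` is their elementwise sum.  ``cells`` carries per-cell
    metadata (cell_id, timepoint_h, volume_voxels, phase, batch) indexed
    like the matrix columns.  Raw counts are integers; normalized copies
    (see :func:`pulsekinetics.kinetics.normalize_counts`) are floats.
    """

    genes: list[str]
    cells: pd.DataFrame
    counts: dict[str, sparse.csr_matrix]

    def __post_init__(self) -> None:
        missing = set(COMPARTMENTS) - set(self.counts)
        if missing:
            raise ValueError(f"missing compartment matrices: {sorted(missing)}")
        n_g, n_c = len(self.genes), len(self.cells)
        for comp, m in self.counts.items():
            if m.shape != (n_g, n_c):
                raise ValueError(
                    f"{comp} matrix shape {m.shape} != (genes={n_g}, cells={n_c})"
                )
            if (m.data < 0).any():
                raise ValueError(f"negative counts in {comp} matrix")

    @property
    def total(self) -> sparse.csr_matrix:
        out = self.counts[COMPARTMENTS[0]].copy()
        for comp in COMPARTMENTS[1:]:
            out = out + self.counts[comp]
        return out.tocsr()

    @property
    def cytoplasm(self) -> sparse.csr_matrix:
        return (self.counts["middle"] + self.counts["periphery"]).tocsr()

    def copy(self) -> "CompartmentMatrix":
        return CompartmentMatrix(
            genes=list(self.genes),
            cells=self.cells.copy(),
            counts={k: v.copy() for k, v in self.counts.items()},
        )


# ---------------------------------------------------------------------------
# read table


def empty_reads() -> pd.DataFrame:
    """A 0-row read table with the canonical schema."""
    return pd.DataFrame(
        {
            "gene": pd.Series(dtype=object),
            "x": pd.Series(dtype=np.int64),
            "y": pd.Series(dtype=np.int64),
            "z": pd.Series(dtype=np.int64),
            "timepoint_h": pd.Series(dtype=float),
            "cell_id": pd.Series(dtype=np.int64),
            "compartment": pd.Series(dtype=object),
            "dr": pd.Series(dtype=float),
            "quality": pd.Series(dtype=float),
        }
    )


def validate_reads(
    reads: pd.DataFrame,
    design: PulseChaseDesign | None = None,
    grid: VoxelGrid | None = None,
    strict_compartments: bool = False,
) -> pd.DataFrame:
    """Check a read table against the schema; return it unchanged.

    Raises ``ValueError`` naming the first offending row.  When a design
    is given, every ``timepoint_h`` must belong to it; when a grid is
    given, coordinates must lie inside it.
    """
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing required columns: {missing}")
    for c in _INT_COLUMNS:
        vals = reads[c]
        if len(vals) and not np.issubdtype(vals.dtype, np.integer):
            as_float = vals.to_numpy(dtype=float)
            if not np.all(as_float == np.round(as_float)):
                bad = int(np.nonzero(as_float != np.round(as_float))[0][0])
                raise ValueError(f"non-integer value in column {c!r} at row {bad}")
    if grid is not None and len(reads):
        for axis, c in enumerate(("x", "y", "z")):
            vals = reads[c].to_numpy()
            bad = (vals < 0) | (vals >= grid.shape[axis])
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise ValueError(
                    f"coordinate {c}={vals[row]} at row {row} outside grid extent {grid.shape[axis]}"
                )
    if design is not None and len(reads):
        ok = reads["timepoint_h"].isin(design.valid_timepoints)
        if not ok.all():
            row = int(np.nonzero(~ok.to_numpy())[0][0])
            raise ValueError(
                f"timepoint {reads['timepoint_h'].iat[row]} at row {row} not in design "
                f"{sorted(design.valid_timepoints)}"
            )
    if len(reads):
        allowed = frozenset(COMPARTMENTS) | {"unassigned"}
        if not strict_compartments:
            allowed = _VALID_COMPARTMENTS
        ok = reads["compartment"].isin(allowed) | reads["compartment"].isna()
        if not ok.all():
            row = int(np.nonzero(~ok.to_numpy())[0][0])
            raise ValueError(
                f"invalid compartment {reads['compartment'].iat[row]!r} at row {row}"
            )
    return reads


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a read table as TSV with canonical column order.

    Unknown columns are preserved after the schema columns.  Output is
    deterministic given the input row order.
    """
    extra = [c for c in reads.columns if c not in READ_COLUMNS]
    cols = list(READ_COLUMNS) + extra
    reads[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_reads_tsv(
    path: str | Path,
    design: PulseChaseDesign | None = None,
    grid: VoxelGrid | None = None,
) -> pd.DataFrame:
    """Read a TSV read table, validate, and return a DataFrame."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene": object})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df):
        for c in _INT_COLUMNS:
            as_float = df[c].to_numpy(dtype=float)
            if np.isnan(as_float).any():
                row = int(np.nonzero(np.isnan(as_float))[0][0])
                raise ValueError(f"{path}: missing {c} at row {row}")
            if not np.all(as_float == np.round(as_float)):
                row = int(np.nonzero(as_float != np.round(as_float))[0][0])
                raise ValueError(f"{path}: non-integer {c}={as_float[row]} at row {row}")
            df[c] = as_float.astype(np.int64)
    else:
        df = empty_reads()
    return validate_reads(df, design=design, grid=grid)


# ---------------------------------------------------------------------------
# label volumes


def write_label_tiff(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write an ``[x, y, z]`` label volume as a z-paged 16-bit TIFF + sidecar.

    The JSON sidecar ``<stem>.json`` records voxel spacing and axis
    order, removing the on-disk orientation ambiguity.
    """
    if volume.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    pages = np.ascontiguousarray(volume.astype(np.uint16).transpose(2, 1, 0))  # (z, y, x)
    path = Path(path)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "axis_order": "zyx (page, row, col)",
        "shape_xyz": list(grid.shape),
        "spacing_nm_xyz": list(grid.spacing),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_label_tiff(path: str | Path, sidecar: str | Path | None = None) -> tuple[np.ndarray, VoxelGrid]:
    """Read a z-paged label TIFF back into an ``[x, y, z]`` volume.

    ``sidecar`` defaults to ``<stem>.json`` next to the TIFF; it must
    declare the voxel spacing.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    volume = pages.transpose(2, 1, 0).astype(np.int32)  # back to (x, y, z)
    grid = VoxelGrid(shape=tuple(volume.shape), spacing=tuple(meta["spacing_nm_xyz"]))
    if tuple(meta.get("shape_xyz", volume.shape)) != tuple(volume.shape):
        raise ValueError(
            f"sidecar shape {meta['shape_xyz']} does not match TIFF shape {volume.shape}"
        )
    if volume.max() == 0:
        warnings.warn(f"{path}: no labels (volume is all zeros)", stacklevel=2)
    return volume, grid


# ---------------------------------------------------------------------------
# count matrices


def write_matrix_market(cm: CompartmentMatrix, outdir: str | Path) -> None:
    """Write one .mtx per compartment (plus total) with TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for comp in COMPARTMENTS:
        mmwrite(str(outdir / f"counts_{comp}.mtx"), sparse.coo_matrix(cm.counts[comp]))
    mmwrite(str(outdir / "counts_total.mtx"), sparse.coo_matrix(cm.total))
    pd.Series(cm.genes, name="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cm.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False, na_rep="NA")


def read_matrix_market(indir: str | Path) -> CompartmentMatrix:
    indir = Path(indir)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", na_values=["NA"])
    counts = {
        comp: sparse.csr_matrix(mmread(str(indir / f"counts_{comp}.mtx")))
        for comp in COMPARTMENTS
    }
    return CompartmentMatrix(genes=genes, cells=cells, counts=counts)
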