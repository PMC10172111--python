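"""Pulse-chase simulator with known ground truth.

Generates the inputs the estimation pipeline expects — a decoded read
table on a segmented 3D voxel grid — from per-gene kinetic parameters,
so that parameter recovery can be tested against truth:

* molecules are born in the nucleus during the pulse as a homogeneous
  Poisson process with rate ``alpha * phase multiplier * cell volume``
  (zero-order synthesis; alpha is a concentration in copies/voxel/h, so
  rate x volume gives expected copies);
* no synthesis after the pulse ends;
* each molecule decays with constant hazard ``beta`` (first-order);
* nuclear -> cytoplasmic export follows one of two modes: a constant
  first-order hazard, or a *linear fraction schedule* in which the
  expected nuclear fraction at chase time t is exactly
  ``max(0, f0 - lam * t)`` — the latter exists because a constant
  hazard does not produce an exactly linear nuclear fraction, and the
  export-rate estimator's target is the linear slope;
* a cytoplasmic molecule's DR drifts deterministically at rate
  ``gamma`` (clipped to [0, 1]); the estimator only uses the mean DR,
  so the mean model is what the simulator controls;
* each surviving molecule is detected independently with probability
  ``detection_efficiency`` at its (single) sampled timepoint;
* reference genes emit time-constant expected counts uniformly over
  the whole cell (they emulate probes against total, not pulse-labeled,
  RNA).

Each chase timepoint is an independent cohort of cells — as in the
experiment, where each timepoint is a separate fixed sample — sharing
one segmented geometry; a cell is identified by (label, timepoint)
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import SegmentationSet, VoxelGrid
from .subcellular import DistanceFields, distance_fields

__all__ = [
    "GeneTruth",
    "SimConfig",
    "SimTruth",
    "make_cell_geometry",
    "simulate_experiment",
    "simulate_intensities",
    "simulate_marker_expression",
    "make_blob_parameters",
    "random_gene_truths",
]

PHASES = ("G1", "G1/S", "G2/M")


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth kinetic constants for one gene.

    alpha: synthesis rate, copies/voxel/h (for reference genes, the
    steady abundance in copies/voxel); beta: degradation, 1/h; lam:
    export (decline of nuclear fraction), 1/h; gamma: cytoplasmic DR
    drift, DR units/h.  ``phase_multipliers`` scale alpha per cell-cycle
    phase (G1, G1/S, G2/M).
    """

    gene: str
    alpha: float
    beta: float
    lam: float = 0.05
    gamma: float = 0.0
    is_reference: bool = False
    phase_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"{self.gene}: alpha must be >= 0")
        if self.beta < 0:
            raise ValueError(f"{self.gene}: beta must be >= 0")
        if self.is_reference and self.beta != 0:
            raise ValueError(f"{self.gene}: reference genes must have beta = 0")
        if any(m <= 0 for m in self.phase_multipliers):
            raise ValueError(f"{self.gene}: phase multipliers must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study design for one simulated pulse-chase experiment.

    Defaults mirror a 1 h pulse with chases at 0/1/2/4/6 h.  The
    default detection efficiency of 0.2 reflects realistic per-molecule
    capture of amplicon-based in situ sequencing; recovery tests also
    run at 1.0 to isolate estimator error from sampling noise.
    ``nuclear_fraction_t0`` (f0) is the expected nuclear fraction at
    chase 0; ``dr_start_mean``/``dr_start_sd`` set where exported
    molecules start in DR units before gamma drift.
    """

    n_cells: int
    genes: tuple[GeneTruth, ...]
    pulse_hours: float = 1.0
    chase_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)
    detection_efficiency: float = 0.2
    export_mode: str = "linear_fraction_schedule"
    translocation_mode: str = "dr_drift"
    seed: int = 0
    phase_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    nuclear_fraction_t0: float = 0.8
    dr_start_mean: float = 0.3
    dr_start_sd: float = 0.05
    chase_inflation: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.detection_efficiency <= 1):
            raise ValueError("detection_efficiency must be in (0, 1]")
        ch = tuple(float(t) for t in self.chase_hours)
        if any(t < 0 for t in ch) or any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError("chase_hours must be nonnegative and strictly increasing")
        if self.export_mode not in ("first_order_hazard", "linear_fraction_schedule"):
            raise ValueError(f"unknown export_mode {self.export_mode!r}")
        if self.translocation_mode not in ("dr_drift", "none"):
            raise ValueError(f"unknown translocation_mode {self.translocation_mode!r}")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if self.pulse_hours <= 0:
            raise ValueError("pulse_hours must be positive")
        object.__setattr__(self, "chase_hours", ch)
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def reference_genes(self) -> tuple[str, ...]:
        return tuple(g.gene for g in self.genes if g.is_reference)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated reads.

    ``tallies`` has one row per gene x timepoint with born / degraded /
    alive / detected molecule counts (before and after thinning);
    born = alive + degraded holds exactly.  ``cell_phase`` maps
    (timepoint_h, cell_id) to the drawn cell-cycle phase.
    """

    gene_truth: tuple[GeneTruth, ...]
    cell_phase: pd.DataFrame
    cell_volume_voxels: pd.DataFrame
    tallies: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        """Per-gene true parameters as a DataFrame indexed by gene."""
        return pd.DataFrame(
            [
                {
                    "gene": g.gene,
                    "alpha": g.alpha,
                    "beta": g.beta,
                    "lam": g.lam,
                    "gamma": g.gamma,
                    "is_reference": g.is_reference,
                }
                for g in self.gene_truth
            ]
        ).set_index("gene")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "gene_truth": [vars(g) | {"phase_multipliers": list(g.phase_multipliers)} for g in self.gene_truth],
            "cell_phase": self.cell_phase.to_dict(orient="list"),
            "cell_volume_voxels": self.cell_volume_voxels.reset_index().to_dict(orient="list"),
            "tallies": self.tallies.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(doc, indent=1, default=float))


# ---------------------------------------------------------------------------
# geometry


def make_cell_geometry(
    grid: VoxelGrid,
    n_cells: int,
    seed: int = 0,
    cell_radius_xy: tuple[float, float] = (8.0, 11.0),
    cell_radius_z: tuple[float, float] = (4.0, 5.5),
    nucleus_scale: float = 0.55,
) -> SegmentationSet:
    """Place ``n_cells`` non-overlapping ellipsoid cells with interior nuclei.

    Cells sit on a jittered lattice whose pitch exceeds the maximum cell
    diameter, so non-overlap is guaranteed by construction.  Raises if
    the grid cannot hold the requested number of cells, naming how many
    would fit.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid.shape
    nucleus = np.zeros(grid.shape, dtype=np.int32)
    cells = np.zeros(grid.shape, dtype=np.int32)
    if n_cells == 0:
        return SegmentationSet(grid=grid, nucleus_labels=nucleus, cell_labels=cells)
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")

    rmax_xy = cell_radius_xy[1]
    rmax_z = cell_radius_z[1]
    pitch_xy = int(np.ceil(2 * rmax_xy + 2))
    pitch_z = int(np.ceil(2 * rmax_z + 2))
    slots_x = nx // pitch_xy
    slots_y = ny // pitch_xy
    slots_z = max(nz // pitch_z, 1 if nz >= 2 * rmax_z + 1 else 0)
    capacity = slots_x * slots_y * slots_z
    if capacity < n_cells:
        raise ValueError(
            f"grid {grid.shape} holds at most {capacity} cells of radius "
            f"~{rmax_xy}x{rmax_xy}x{rmax_z} voxels; {n_cells} requested"
        )

    if nz // pitch_z >= 1:
        z_centers = [iz * pitch_z + pitch_z / 2 for iz in range(slots_z)]
    else:  # single squeezed layer in a thin stack
        z_centers = [nz / 2]
    slots = [
        (ix * pitch_xy + pitch_xy / 2, iy * pitch_xy + pitch_xy / 2, cz)
        for cz in z_centers
        for iy in range(slots_y)
        for ix in range(slots_x)
    ]

    xs = np.arange(nx)[:, None, None]
    ys = np.arange(ny)[None, :, None]
    zs = np.arange(nz)[None, None, :]
    for label in range(1, n_cells + 1):
        cx, cy, cz = slots[label - 1]
        cx += rng.uniform(-1, 1)
        cy += rng.uniform(-1, 1)
        rx = rng.uniform(*cell_radius_xy)
        ry = rng.uniform(*cell_radius_xy)
        rz = rng.uniform(*cell_radius_z)
        rz = min(rz, cz - 0.5, nz - 1 - cz - 0.5) if nz > 2 else rz
        lo = (
            max(int(cx - rx) - 1, 0),
            max(int(cy - ry) - 1, 0),
            max(int(cz - rz) - 1, 0),
        )
        hi = (
            min(int(cx + rx) + 2, nx),
            min(int(cy + ry) + 2, ny),
            min(int(cz + rz) + 2, nz),
        )
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        dx = (xs[box[0]] - cx) / rx
        dy = (ys[:, box[1]] - cy) / ry
        dz = (zs[:, :, box[2]] - cz) / rz
        cell_mask = dx**2 + dy**2 + dz**2 <= 1.0
        nuc_mask = dx**2 + dy**2 + dz**2 <= nucleus_scale**2
        if not nuc_mask.any():  # degenerate tiny cell: keep the center voxel as nucleus
            center = (int(round(cx)) - lo[0], int(round(cy)) - lo[1], int(round(cz)) - lo[2])
            nuc_mask = np.zeros_like(cell_mask)
            nuc_mask[center] = True
            cell_mask |= nuc_mask
        cells[box][cell_mask] = label
        nucleus[box][nuc_mask] = label
    return SegmentationSet(grid=grid, nucleus_labels=nucleus, cell_labels=cells)


# ---------------------------------------------------------------------------
# pulse-chase experiment


def random_gene_truths(
    n_genes: int,
    seed: int = 0,
    alpha_range: tuple[float, float] = (0.005, 0.05),
    beta_range: tuple[float, float] = (0.1, 1.0),
    lam_range: tuple[float, float] = (0.02, 0.10),
    gamma_range: tuple[float, float] = (-0.03, 0.07),
    n_reference: int = 5,
    reference_level: float = 0.01,
) -> tuple[GeneTruth, ...]:
    """Draw a realistic spread of per-gene kinetic constants.

    alpha and beta are log-uniform (rates span decades in real data);
    lam and gamma are uniform.  ``n_reference`` constant-expression
    control genes are appended.
    """
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_genes):
        truths.append(
            GeneTruth(
                gene=f"GENE{i:03d}",
                alpha=float(np.exp(rng.uniform(np.log(alpha_range[0]), np.log(alpha_range[1])))),
                beta=float(np.exp(rng.uniform(np.log(beta_range[0]), np.log(beta_range[1])))),
                lam=float(rng.uniform(*lam_range)),
                gamma=float(rng.uniform(*gamma_range)),
            )
        )
    for j in range(n_reference):
        truths.append(
            GeneTruth(gene=f"REF{j:02d}", alpha=reference_level, beta=0.0, lam=0.0, gamma=0.0, is_reference=True)
        )
    return tuple(truths)


def _cell_site_cache(seg: SegmentationSet, fields: DistanceFields):
    """Per-cell voxel index arrays for molecule placement.

    For each label: nucleus voxel coordinates, whole-cell coordinates,
    and cytoplasmic coordinates sorted by voxel DR (for nearest-DR
    placement via searchsorted).
    """
    cache = {}
    for label in seg.labels:
        nuc_idx = np.argwhere(seg.nucleus_labels == label)
        cell_idx = np.argwhere(seg.cell_labels == label)
        cyto_mask = (seg.cell_labels == label) & (seg.nucleus_labels == 0)
        cyto_idx = np.argwhere(cyto_mask)
        drs = fields.dr[cyto_idx[:, 0], cyto_idx[:, 1], cyto_idx[:, 2]]
        ok = ~np.isnan(drs)
        cyto_idx, drs = cyto_idx[ok], drs[ok]
        order = np.argsort(drs, kind="stable")
        cache[int(label)] = {
            "nucleus": nuc_idx,
            "cell": cell_idx,
            "cyto_sorted": cyto_idx[order],
            "dr_sorted": drs[order].astype(float),
            "volume": len(cell_idx),
        }
    return cache


def _place_by_dr(target_dr: np.ndarray, dr_sorted: np.ndarray, cyto_sorted: np.ndarray) -> np.ndarray:
    """Map target DR values to the cytoplasmic voxel with nearest DR."""
    pos = np.searchsorted(dr_sorted, target_dr)
    pos = np.clip(pos, 0, len(dr_sorted) - 1)
    left = np.clip(pos - 1, 0, len(dr_sorted) - 1)
    use_left = np.abs(dr_sorted[left] - target_dr) < np.abs(dr_sorted[pos] - target_dr)
    return cyto_sorted[np.where(use_left, left, pos)]


def simulate_experiment(
    cfg: SimConfig,
    geometry: SegmentationSet,
    fields: DistanceFields | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one pulse-chase experiment on the given geometry.

    Returns a read table (with generative cell/compartment/DR filled
    in — the spatial pipeline recomputes these from the masks) and the
    ground truth.  Byte-identical output for identical config + seed.
    """
    labels = geometry.labels
    if labels.size == 0:
        raise ValueError("geometry contains no cells")
    if fields is None:
        fields = distance_fields(geometry)
    sites = _cell_site_cache(geometry, fields)
    rng = np.random.default_rng(cfg.seed)
    tau = cfg.pulse_hours
    genes = cfg.genes
    n_genes = len(genes)
    alpha = np.array([g.alpha for g in genes])
    beta = np.array([g.beta for g in genes])
    lam = np.array([g.lam for g in genes])
    gamma = np.array([g.gamma for g in genes])
    is_ref = np.array([g.is_reference for g in genes])
    mult = np.array([g.phase_multipliers for g in genes])  # (n_genes, 3)

    if cfg.n_cells > len(labels):
        raise ValueError(
            f"cfg.n_cells={cfg.n_cells} exceeds the {len(labels)} labeled cells in the geometry"
        )
    use_labels = labels[: cfg.n_cells]

    recs: list[pd.DataFrame] = []
    phase_rows = []
    born_tab = np.zeros((n_genes, len(cfg.chase_hours)), dtype=np.int64)
    dead_tab = np.zeros_like(born_tab)
    alive_tab = np.zeros_like(born_tab)
    det_tab = np.zeros_like(born_tab)
    ref_idx = np.nonzero(is_ref)[0]

    for ti, t_chase in enumerate(cfg.chase_hours):
        inflation = float(cfg.chase_inflation.get(t_chase, 1.0))
        for label in use_labels:
            site = sites[int(label)]
            vol = site["volume"]
            phase_i = int(rng.choice(3, p=cfg.phase_fractions))
            phase_rows.append({"timepoint_h": t_chase, "cell_id": int(label), "phase": PHASES[phase_i]})

            # births over the pulse window, per gene
            rate = np.where(is_ref, 0.0, alpha * mult[:, phase_i] * vol * tau)
            n_born = rng.poisson(rate)
            born_tab[:, ti] += n_born
            total = int(n_born.sum())
            gidx = np.repeat(np.arange(n_genes), n_born)
            # age at sampling = (pulse - birth time) + chase
            birth = rng.uniform(0.0, tau, size=total)
            age = (tau - birth) + t_chase
            survive = rng.random(total) < np.exp(-beta[gidx] * age)
            np.add.at(dead_tab[:, ti], gidx[~survive], 1)
            np.add.at(alive_tab[:, ti], gidx[survive], 1)
            gidx, age = gidx[survive], age[survive]

            # nuclear vs cytoplasmic split
            if cfg.export_mode == "linear_fraction_schedule":
                p_nuc = np.clip(cfg.nuclear_fraction_t0 - lam[gidx] * t_chase, 0.0, 1.0)
                nuclear = rng.random(len(gidx)) < p_nuc
                t_drift = np.full(len(gidx), t_chase)
            else:  # first_order_hazard
                export_t = rng.exponential(1.0, size=len(gidx)) / np.maximum(lam[gidx], 1e-12)
                nuclear = export_t > age
                t_drift = np.maximum(age - export_t, 0.0)

            # detection thinning (tally alive before thinning)
            keep = rng.random(len(gidx)) < cfg.detection_efficiency
            if inflation != 1.0:
                # residual-label artifact: extra multiplicative detection at this chase
                extra = rng.random(len(gidx)) < min(cfg.detection_efficiency * (inflation - 1.0), 1.0)
                keep |= extra
            det_g, det_nuc, det_drift = gidx[keep], nuclear[keep], t_drift[keep]
            np.add.at(det_tab[:, ti], det_g, 1)

            coords = np.empty((len(det_g), 3), dtype=np.int64)
            dr_out = np.full(len(det_g), np.nan)
            # nuclear molecules: uniform over nucleus voxels
            n_nuc = int(det_nuc.sum())
            if n_nuc:
                pick = rng.integers(0, len(site["nucleus"]), size=n_nuc)
                coords[det_nuc] = site["nucleus"][pick]
            # cytoplasmic molecules: place at voxel nearest the target DR
            cyto = ~det_nuc
            n_cyt = int(cyto.sum())
            if n_cyt:
                if cfg.export_mode == "first_order_hazard":
                    dr0 = np.zeros(n_cyt)  # exported molecules land just outside the nucleus
                else:
                    dr0 = np.clip(
                        rng.normal(cfg.dr_start_mean, cfg.dr_start_sd, size=n_cyt), 0.0, 1.0
                    )
                if cfg.translocation_mode == "dr_drift":
                    target = np.clip(dr0 + gamma[det_g[cyto]] * det_drift[cyto], 0.0, 1.0)
                else:
                    target = dr0
                vox = _place_by_dr(target, site["dr_sorted"], site["cyto_sorted"])
                coords[cyto] = vox
                dr_out[cyto] = fields.dr[vox[:, 0], vox[:, 1], vox[:, 2]]

            # reference genes: time-constant Poisson counts, uniform over the cell
            ref_n = rng.poisson(alpha[ref_idx] * vol)
            born_tab[ref_idx, ti] += ref_n
            alive_tab[ref_idx, ti] += ref_n  # beta = 0: nothing degrades
            ref_keep = rng.binomial(ref_n, cfg.detection_efficiency)
            det_tab[ref_idx, ti] += ref_keep
            r_total = int(ref_keep.sum())
            r_gidx = np.repeat(ref_idx, ref_keep)
            r_coords = site["cell"][rng.integers(0, len(site["cell"]), size=r_total)]
            r_nuc = geometry.nucleus_labels[r_coords[:, 0], r_coords[:, 1], r_coords[:, 2]] > 0
            r_dr = np.where(
                r_nuc, np.nan, fields.dr[r_coords[:, 0], r_coords[:, 1], r_coords[:, 2]]
            )

            all_g = np.concatenate([det_g, r_gidx])
            all_coords = np.vstack([coords, r_coords])
            all_nuc = np.concatenate([det_nuc, r_nuc])
            all_dr = np.concatenate([dr_out, r_dr])
            recs.append(
                pd.DataFrame(
                    {
                        "gene": np.array([g.gene for g in genes], dtype=object)[all_g],
                        "x": all_coords[:, 0],
                        "y": all_coords[:, 1],
                        "z": all_coords[:, 2],
                        "timepoint_h": float(t_chase),
                        "cell_id": int(label),
                        "compartment": np.where(all_nuc, "nucleus", "cytoplasm"),
                        "dr": all_dr,
                        "quality": np.nan,
                    }
                )
            )

    reads = (
        pd.concat(recs, ignore_index=True)
        if recs
        else pd.DataFrame(columns=["gene", "x", "y", "z", "timepoint_h", "cell_id", "compartment", "dr", "quality"])
    )
    vols = pd.DataFrame(
        {"total_voxels": [sites[int(c)]["volume"] for c in labels]},
        index=pd.Index(labels, name="cell_id"),
    )
    tallies = pd.DataFrame(
        {
            "gene": np.repeat([g.gene for g in genes], len(cfg.chase_hours)),
            "timepoint_h": np.tile(cfg.chase_hours, n_genes),
            "born": born_tab.ravel(),
            "degraded": dead_tab.ravel(),
            "alive": alive_tab.ravel(),
            "detected": det_tab.ravel(),
        }
    )
    truth = SimTruth(
        gene_truth=genes,
        cell_phase=pd.DataFrame(phase_rows),
        cell_volume_voxels=vols,
        tallies=tallies,
    )
    return reads, truth


# ---------------------------------------------------------------------------
# decoding-layer intensities


def simulate_intensities(
    reads: pd.DataFrame,
    codebook,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit per-dot per-round 4-channel intensities for the decoder.

    Each read becomes one dot; at round r the channel matching the
    gene's color gets intensity 1 and the others 0, then Gaussian noise
    of sd ``noise_sd`` is added and truncated at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = reads["gene"].to_numpy()
    missing = sorted(set(genes) - set(codebook.color_sequences))
    if missing:
        raise KeyError(f"genes absent from codebook: {missing[:5]}")
    colors = np.array([codebook.color_sequences[g] for g in genes])  # (n, R)
    n, R = colors.shape
    intens = np.zeros((n, R, 4))
    np.put_along_axis(intens, colors[:, :, None], 1.0, axis=2)
    if noise_sd > 0:
        intens = np.clip(intens + rng.normal(0.0, noise_sd, size=intens.shape), 0.0, None)
    rows = {
        "dot_id": np.repeat(np.arange(n), R),
        "round": np.tile(np.arange(1, R + 1), n),
    }
    flat = intens.reshape(n * R, 4)
    for ch in range(4):
        rows[f"ch{ch + 1}"] = flat[:, ch]
    out = pd.DataFrame(rows)
    out.attrs["true_gene"] = genes
    return out


# ---------------------------------------------------------------------------
# light-weight generators for specific validation studies


def simulate_marker_expression(
    n_cells: int,
    g1s_markers: tuple[str, ...],
    g2m_markers: tuple[str, ...],
    n_background: int = 150,
    base_mean: float = 5.0,
    inflation: float = 3.0,
    phase_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson expression with phase-dependent marker inflation.

    Cells in G1/S have their G1/S marker means multiplied by
    ``inflation`` (likewise G2/M); G1 cells are uninflated.  Returns
    (genes x cells counts, true phase per cell).  This bypasses the
    spatial layer: phase calling consumes expression only.
    """
    rng = np.random.default_rng(seed)
    background = [f"BG{i:03d}" for i in range(n_background)]
    genes = list(g1s_markers) + list(g2m_markers) + background
    phases = rng.choice(3, size=n_cells, p=phase_fractions)
    means = np.full((len(genes), n_cells), base_mean)
    g1s_rows = np.arange(len(g1s_markers))
    g2m_rows = np.arange(len(g1s_markers), len(g1s_markers) + len(g2m_markers))
    means[np.ix_(g1s_rows, np.nonzero(phases == 1)[0])] *= inflation
    means[np.ix_(g2m_rows, np.nonzero(phases == 2)[0])] *= inflation
    counts = rng.poisson(means)
    expr = pd.DataFrame(counts, index=genes, columns=[f"cell{i}" for i in range(n_cells)])
    truth = pd.Series([PHASES[p] for p in phases], index=expr.columns, name="phase")
    return expr, truth


def make_blob_parameters(
    n_per_blob: int = 50,
    n_params: int = 4,
    separation: float = 10.0,
    sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two well-separated Gaussian blobs in kinetic-parameter space.

    A fixture for cluster-recovery tests: blob centers ``separation``
    apart along every axis, isotropic sd ``sd``.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_per_blob, n_params))
    b = rng.normal(separation, sd, size=(n_per_blob, n_params))
    values = np.vstack([a, b])
    genes = [f"GENE{i:03d}" for i in range(2 * n_per_blob)]
    pm = pd.DataFrame(values, index=genes, columns=[f"p{j}" for j in range(n_params)])
    labels = pd.Series([0] * n_per_blob + [1] * n_per_blob, index=genes, name="blob")
    return pm, labels
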