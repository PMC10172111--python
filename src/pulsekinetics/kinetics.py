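"""Per-gene RNA kinetic constants from pulse-chase timecourses.

Model: during a pulse of length tau, labeled RNA concentration X(t)
(copies per voxel of cell volume) obeys

    dX/dt = alpha - beta * X,        X(0) = 0        (pulse)
    dX/dt = -beta * X                                (chase)

with zero-order synthesis alpha and first-order degradation beta, and
no synthesis of labeled RNA after the pulse.  Hence over the chase
X(t) = X0 * exp(-beta * t), and the pulse solution inverts to

    alpha = beta * X0 / (1 - exp(-beta * tau)).

Nuclear export lam is the (negated) slope of the nuclear read fraction
y(t) = nuclear / (nuclear + cytoplasmic) regressed on chase time, and
cytoplasmic translocation gamma is the slope of the mean DR of pooled
cytoplasmic reads regressed on chase time (negative gamma = inward
movement).  All regressions are unweighted OLS over the non-excluded
chase timepoints (the 1 h chase is excluded by default as a
residual-label outlier).  A gene passes QC when alpha > 0, beta > 0
and the beta fit's R^2 >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .datamodel import COMPARTMENTS, CompartmentMatrix, GeneSets, PulseChaseDesign

__all__ = [
    "GeneTimecourse",
    "normalize_counts",
    "to_concentration",
    "fit_beta",
    "estimate_alpha",
    "fit_lambda",
    "fit_gamma",
    "build_timecourses",
    "estimate_all",
    "R2_THRESHOLD",
]

#: minimum R^2 of the degradation fit for a gene to pass QC
R2_THRESHOLD = 0.5

_MIN_TIMEPOINTS = 3


@dataclass
class GeneTimecourse:
    """Aggregated per-gene series over usable chase timepoints.

    ``X``: mean concentration across cells; ``y``: nuclear read
    fraction (ratio of summed nuclear to summed total reads);
    ``dr_mean``: mean DR of cytoplasmic reads pooled across cells.
    Entries may be NaN where a timepoint had no reads.
    """

    gene: str
    t: np.ndarray
    X: np.ndarray
    y: np.ndarray
    dr_mean: np.ndarray
    n_cells: np.ndarray
    n_reads: np.ndarray


# ---------------------------------------------------------------------------
# normalization and concentrations


def normalize_counts(cm: CompartmentMatrix, reference_genes) -> CompartmentMatrix:
    """Rescale counts per timepoint against reference-gene means.

    The scale for timepoint t is (grand mean of per-timepoint reference
    reads per cell) / (reference reads per cell at t), so after
    normalization every timepoint has the same mean reference signal.
    Reference genes are probed for total RNA and assumed
    time-invariant, which anchors the labeled counts on a common scale.
    Idempotent: a second application is the identity.
    """
    ref = [g for g in reference_genes if g in cm.genes]
    if not ref:
        raise ValueError("no reference genes present in the matrix")
    ridx = [cm.genes.index(g) for g in ref]
    total = cm.total
    tps = sorted(cm.cells["timepoint_h"].unique())
    means = {}
    for t in tps:
        cols = np.nonzero((cm.cells["timepoint_h"] == t).to_numpy())[0]
        if cols.size == 0:
            raise ValueError(f"no cells at timepoint {t}")
        m = float(total[np.ix_(ridx, cols)].sum()) / cols.size
        if m == 0:
            raise ValueError(f"zero reference-gene signal at timepoint {t}")
        means[t] = m
    grand = float(np.mean(list(means.values())))
    out = cm.copy()
    scale = np.empty(len(cm.cells))
    for t in tps:
        cols = (cm.cells["timepoint_h"] == t).to_numpy()
        scale[cols] = grand / means[t]
    scaler = sparse.diags(scale)
    for comp in COMPARTMENTS:
        out.counts[comp] = (out.counts[comp].astype(float) @ scaler).tocsr()
    return out


def to_concentration(cm: CompartmentMatrix, volumes: np.ndarray | None = None) -> pd.DataFrame:
    """Counts per voxel of total cell volume: genes x cells DataFrame.

    ``volumes`` defaults to the ``volume_voxels`` column of the cell
    metadata.
    """
    if volumes is None:
        volumes = cm.cells["volume_voxels"].to_numpy(dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any():
        raise ValueError("cell volumes must be positive")
    dense = np.asarray(cm.total.todense(), dtype=float)
    return pd.DataFrame(dense / volumes[None, :], index=cm.genes, columns=cm.cells.index)


# ---------------------------------------------------------------------------
# the four fits


def _ols(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of an unweighted least-squares line."""
    if np.allclose(v, v[0]):
        # flat series: slope 0, R^2 undefined
        return 0.0, float(v[0]), np.nan
    res = stats.linregress(t, v)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_beta(t, X, mode: str = "loglinear") -> tuple[float, float]:
    """Degradation rate from the chase decay of mean concentration.

    ``loglinear`` (default): OLS of ln X on t, beta = -slope.
    ``nls``: nonlinear least squares on X = X0 exp(-beta t); R^2 is
    then 1 - SS_res/SS_tot on the natural scale.
    Timepoints with X <= 0 or NaN are dropped; fewer than 3 usable
    points returns (NaN, NaN).
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = np.isfinite(X) & (X > 0) & np.isfinite(t)
    t, X = t[ok], X[ok]
    if len(t) < _MIN_TIMEPOINTS:
        return np.nan, np.nan
    if mode == "loglinear":
        slope, _, r2 = _ols(t, np.log(X))
        return -slope, r2
    if mode == "nls":
        slope0, icpt0, _ = _ols(t, np.log(X))
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, x0, b: x0 * np.exp(-b * tt),
                t,
                X,
                p0=(float(np.exp(icpt0)), max(-slope0, 1e-6)),
                maxfev=10000,
            )
        except RuntimeError:
            return np.nan, np.nan
        x0, b = popt
        resid = X - x0 * np.exp(-b * t)
        sstot = float(np.sum((X - X.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else np.nan
        return float(b), r2
    raise ValueError(f"unknown beta fit mode {mode!r}")


def estimate_alpha(X0: float, beta: float, pulse_hours: float, mode: str = "closed_form") -> float:
    """Synthesis rate from the chase-0 concentration.

    Closed form inverts the pulse solution
    X0 = (alpha/beta)(1 - exp(-beta tau)); as beta -> 0 this tends to
    the zero-degradation limit X0/tau, which is also the ``linear``
    fallback used when beta <= 0.
    """
    if pulse_hours <= 0:
        raise ValueError("pulse duration must be positive")
    if not np.isfinite(X0) or X0 == 0:
        return 0.0 if X0 == 0 else np.nan
    if mode == "linear" or not np.isfinite(beta) or beta <= 0:
        return float(X0 / pulse_hours)
    if mode != "closed_form":
        raise ValueError(f"unknown alpha mode {mode!r}")
    return float(beta * X0 / (1.0 - np.exp(-beta * pulse_hours)))


def fit_lambda(t, y) -> tuple[float, float, float]:
    """Export rate: negated OLS slope of nuclear fraction on chase time.

    Returns (lam, f0, r2) where f0 is the fitted intercept (nuclear
    fraction at chase 0).  The fraction is assumed to decline linearly
    with constant export.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    if len(t) < _MIN_TIMEPOINTS:
        return np.nan, np.nan, np.nan
    slope, icpt, r2 = _ols(t, y)
    return -slope, icpt, r2


def fit_gamma(t, dr_mean) -> tuple[float, float]:
    """Translocation rate: OLS slope of mean DR on chase time.

    The sign is kept: a small set of genes genuinely moves inward
    (gamma < 0).
    """
    t = np.asarray(t, dtype=float)
    dr = np.asarray(dr_mean, dtype=float)
    ok = np.isfinite(dr) & np.isfinite(t)
    t, dr = t[ok], dr[ok]
    if len(t) < _MIN_TIMEPOINTS:
        return np.nan, np.nan
    slope, _, r2 = _ols(t, dr)
    return slope, r2


# ---------------------------------------------------------------------------
# end-to-end estimation


def build_timecourses(
    cm: CompartmentMatrix,
    design: PulseChaseDesign,
    reads: pd.DataFrame | None = None,
    cell_mask: np.ndarray | None = None,
) -> dict[str, GeneTimecourse]:
    """Aggregate the matrix (and reads, for DR) into per-gene series.

    Uses only non-excluded chase timepoints.  ``y`` is the ratio of
    summed nuclear to summed total reads across the cells at each
    timepoint (ratio of means, which is robust to empty cells);
    ``dr_mean`` pools cytoplasmic reads across those cells.  A boolean
    ``cell_mask`` restricts to a cell subset (e.g. one cell-cycle
    phase).
    """
    tps = np.array(design.usable_chase_hours)
    if len(tps) < _MIN_TIMEPOINTS:
        raise ValueError(
            f"design leaves {len(tps)} usable chase timepoints; >= {_MIN_TIMEPOINTS} required"
        )
    if cell_mask is None:
        cell_mask = np.ones(len(cm.cells), dtype=bool)
    conc = to_concentration(cm)
    nuc = cm.counts["nucleus"]
    cyt = cm.cytoplasm

    col_sets = []
    for t in tps:
        col_sets.append(np.nonzero(((cm.cells["timepoint_h"] == t).to_numpy()) & cell_mask)[0])

    dr_lookup: dict[tuple[str, float], float] = {}
    if reads is not None:
        sel = reads[
            reads["compartment"].isin(["middle", "periphery", "cytoplasm"])
            & reads["dr"].notna()
            & (reads["cell_id"] > 0)
        ]
        if cell_mask is not None and not cell_mask.all():
            keep_keys = set(
                zip(
                    cm.cells.loc[cell_mask, "timepoint_h"].tolist(),
                    cm.cells.loc[cell_mask, "cell_id"].tolist(),
                )
            )
            pair = list(zip(sel["timepoint_h"], sel["cell_id"]))
            sel = sel[[p in keep_keys for p in pair]]
        grouped = sel.groupby(["gene", "timepoint_h"])["dr"].mean()
        dr_lookup = grouped.to_dict()

    out: dict[str, GeneTimecourse] = {}
    for gi, gene in enumerate(cm.genes):
        X = np.empty(len(tps))
        y = np.empty(len(tps))
        dr = np.empty(len(tps))
        ncells = np.empty(len(tps), dtype=int)
        nreads = np.empty(len(tps), dtype=int)
        for k, (t, cols) in enumerate(zip(tps, col_sets)):
            ncells[k] = len(cols)
            if len(cols) == 0:
                X[k] = y[k] = dr[k] = np.nan
                nreads[k] = 0
                continue
            X[k] = float(conc.iloc[gi, cols].mean())
            n_nuc = float(nuc[gi, cols].sum())
            n_cyt = float(cyt[gi, cols].sum())
            tot = n_nuc + n_cyt
            y[k] = n_nuc / tot if tot > 0 else np.nan
            nreads[k] = int(tot)
            dr[k] = dr_lookup.get((gene, float(t)), np.nan)
        out[gene] = GeneTimecourse(
            gene=gene, t=tps.copy(), X=X, y=y, dr_mean=dr, n_cells=ncells, n_reads=nreads
        )
    return out


def estimate_all(
    cm: CompartmentMatrix,
    design: PulseChaseDesign,
    genesets: GeneSets | None = None,
    reads: pd.DataFrame | None = None,
    phase_partition: pd.Series | None = None,
    beta_mode: str = "loglinear",
    alpha_mode: str = "closed_form",
    r2_min: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Estimate (alpha, beta, lam, gamma) per gene, optionally per phase.

    ``phase_partition`` maps matrix cell positions to phase labels; when
    given, each phase is estimated separately ('all' rows are always
    emitted too).  Reference genes are skipped (their counts anchor the
    normalization, they have no labeled kinetics).  No gene is dropped:
    failures surface as NaN estimates and ``qc_pass = False`` —
    filtering is the caller's choice.
    """
    ref = set(genesets.reference_genes) if genesets is not None else set()
    partitions: list[tuple[str, np.ndarray | None]] = [("all", None)]
    if phase_partition is not None:
        phases = pd.Series(phase_partition)
        if phases.isna().any():
            raise ValueError("every cell needs a phase when partitioning")
        for ph in sorted(phases.unique()):
            partitions.append((str(ph), (phases == ph).to_numpy()))

    rows = []
    X0_t = 0.0
    if 0.0 not in design.usable_chase_hours:
        raise ValueError("chase 0 must be a usable timepoint (needed for alpha)")
    for phase_name, mask in partitions:
        tcs = build_timecourses(cm, design, reads=reads, cell_mask=mask)
        for gene, tc in tcs.items():
            if gene in ref:
                continue
            beta, r2_beta = fit_beta(tc.t, tc.X, mode=beta_mode)
            X0 = tc.X[tc.t == X0_t]
            X0 = float(X0[0]) if len(X0) and np.isfinite(X0[0]) else np.nan
            alpha = estimate_alpha(X0, beta, design.pulse_hours, mode=alpha_mode)
            lam, f0, r2_lam = fit_lambda(tc.t, tc.y)
            gamma, r2_gam = fit_gamma(tc.t, tc.dr_mean)
            qc = bool(
                np.isfinite(alpha)
                and np.isfinite(beta)
                and alpha > 0
                and beta > 0
                and np.isfinite(r2_beta)
                and r2_beta >= r2_min
            )
            rows.append(
                {
                    "gene": gene,
                    "phase": phase_name,
                    "alpha": alpha,
                    "beta": beta,
                    "lam": lam,
                    "gamma": gamma,
                    "f0": f0,
                    "r2_beta": r2_beta,
                    "r2_lambda": r2_lam,
                    "r2_gamma": r2_gam,
                    "qc_pass": qc,
                    "n_cells_used": int(tc.n_cells.sum()),
                }
            )
    return pd.DataFrame(rows)
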