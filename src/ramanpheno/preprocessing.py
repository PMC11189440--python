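"""Spectral preprocessing chain.

Stages, in the order they are applied by :func:`run_preprocessing`:
despiking (running-median replacement), iterative cubic-spline baseline
subtraction, reference-peak axis calibration, silent-region excision, and
PCA/MAD outlier filtering.

The named methods come from conventional Raman chemometrics; concrete
parameter defaults (window sizes, knot spacing, thresholds) are package
conventions exposed through :class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import BSpline, CubicSpline, PchipInterpolator
from scipy.ndimage import median_filter
from sklearn.decomposition import PCA

from .errors import CalibrationError
from .spectra_io import SpectrumSet

#: Silent region bounds (closed interval), cm^-1.
SILENT_REGION = (1800.0, 2700.0)
_SILENT_EPS = 1e-9


# ---------------------------------------------------------------------------
# despiking

def remove_cosmic_rays(
    sset: SpectrumSet, window: int = 5, threshold: float = 8.0
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Replace positive single-/few-channel spikes by the running median.

    A channel is replaced when its residual above the running median exceeds
    ``threshold`` times the spectrum's robust residual scale (1.4826 x MAD).
    Returns the despiked set and a report of (cell_id, channel) replacements;
    channels not listed in the report are bit-identical to the input.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > sset.n_channels:
        raise ValueError("window larger than axis")
    y = sset.intensities.copy()
    # mirror padding: replicate padding would make a spike in the first or
    # last channel its own window median and hence undetectable
    med = median_filter(y, size=(1, window), mode="mirror")
    resid = y - med
    # robust residual scale; exact zeros (centre == window median, common on
    # steep band slopes) carry no scale information and are excluded
    absr = np.abs(resid)
    scale = np.empty((y.shape[0], 1))
    for i in range(y.shape[0]):
        nz = absr[i][absr[i] > 0]
        scale[i, 0] = 1.4826 * np.median(nz) if nz.size else 0.0
    # floor at 0.8% of the smoothed dynamic range: in a noiseless spectrum the
    # residual scale vanishes and band curvature would be flagged as spikes
    floor = 0.008 * np.ptp(med, axis=1, keepdims=True)
    scale = np.maximum(np.maximum(scale, floor), 1e-12)
    hits = resid > threshold * scale
    rows, cols = np.nonzero(hits)
    y[rows, cols] = med[rows, cols]
    ids = sset.meta["cell_id"].to_numpy()
    report = pd.DataFrame({"cell_id": ids[rows], "channel": cols})
    return SpectrumSet(sset.axis.copy(), y, sset.meta.copy()), report


# ---------------------------------------------------------------------------
# baseline

def _segment_edges(x: np.ndarray, spacing: float) -> np.ndarray:
    n_seg = max(int(np.ceil((x[-1] - x[0]) / spacing)), 1)
    return np.linspace(x[0], x[-1], n_seg + 1)


def _spline_baseline(
    x: np.ndarray, y: np.ndarray, edges: np.ndarray, n_iterations: int
) -> np.ndarray:
    """Baseline of one spectrum: cubic spline through per-segment minima.

    Anchors are the lowest point of each ``spacing``-wide segment; the spline
    is iteratively re-anchored against min(original, previous fit) so that
    segments fully covered by a peak settle onto the interpolated baseline.
    """
    y = y.astype(float)
    work = y.copy()
    fit = work
    prev_anchors: tuple | None = None
    for _ in range(n_iterations):
        ax: list[float] = []
        ay: list[float] = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (x >= lo) & (x < hi) if hi < edges[-1] else (x >= lo)
            if not m.any():
                continue  # gap axes leave empty segments
            j = int(np.argmin(work[m]))
            ax.append(float(x[m][j]))
            ay.append(float(work[m][j]))
        # anchor the ends so the spline never extrapolates beyond data
        if ax[0] > x[0]:
            ax.insert(0, float(x[0]))
            ay.insert(0, float(work[0]))
        if ax[-1] < x[-1]:
            ax.append(float(x[-1]))
            ay.append(float(work[-1]))
        anchors = (tuple(ax), tuple(ay))
        if anchors == prev_anchors:
            break  # converged: re-anchoring is a fixed point
        prev_anchors = anchors
        prev_fit = fit
        if len(ax) >= 4:
            fit = CubicSpline(ax, ay, bc_type="not-a-knot")(x)
        else:
            fit = np.polyval(np.polyfit(ax, ay, len(ax) - 1), x)
        work = np.minimum(y, fit)
        if (
            prev_fit is not work
            and np.max(np.abs(fit - prev_fit)) < 1e-3 * max(np.ptp(y), 1e-12)
        ):
            break
    # refine: least-squares spline over every below/near-curve channel, which
    # averages out band-tail contamination of the individual minimum anchors
    resid = y - fit
    neg = resid[resid < 0]
    # noise scale from the negative residuals only: below-fit excursions are
    # noise/overshoot, never band signal
    sigma = 1.4826 * float(np.median(-neg)) if neg.size else 0.0
    support = resid <= 3.0 * max(sigma, 1e-12)
    kts = np.r_[[x[0]] * 4, edges[1:-1], [x[-1]] * 4]
    n_coef = len(kts) - 4
    if support.sum() > n_coef + 2:
        design = BSpline.design_matrix(x[support], kts, 3).toarray()
        # refit only when every basis function is well supported, else the
        # solution can swing wildly across support gaps under broad bands
        if np.all((design > 1e-12).sum(axis=0) >= 4):
            coef, _, rank, _ = np.linalg.lstsq(design, y[support], rcond=1e-6)
            refit = BSpline(kts, coef, 3)(x)
            bound = max(10.0 * sigma, 0.05 * float(np.ptp(y)))
            if rank == n_coef and np.max(np.abs(refit - fit)) <= bound:
                fit = refit
    return fit


def correct_baseline(
    sset: SpectrumSet, knot_spacing: float = 150.0, n_iterations: int = 10
) -> SpectrumSet:
    """Subtract a fluorescence-like baseline from every spectrum.

    Per spectrum, a cubic spline is interpolated through the local minimum of
    each ``knot_spacing``-wide axis segment and iteratively re-anchored
    against min(original, previous fit), so peaks are excluded from the
    baseline estimate.  Output values may be slightly negative; nothing is
    clipped.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    dx = np.diff(sset.axis).min()
    if knot_spacing <= dx:
        raise ValueError(
            f"knot_spacing ({knot_spacing}) must exceed channel spacing ({dx:.3f})"
        )
    x = sset.axis
    edges = _segment_edges(x, knot_spacing)
    out = np.empty_like(sset.intensities)
    for i in range(sset.n_cells):
        base = _spline_baseline(x, sset.intensities[i], edges, n_iterations)
        out[i] = sset.intensities[i] - base
    return SpectrumSet(x.copy(), out, sset.meta.copy())


# ---------------------------------------------------------------------------
# axis calibration

def _refine_peak(y: np.ndarray, i: int, x: np.ndarray) -> float:
    """Sub-channel peak position by parabolic interpolation around channel i."""
    if i == 0 or i == y.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[min(i + 1, x.size - 1)] - x[i - 1]) / 2.0)


def fit_axis_map(
    measured_reference: np.ndarray,
    axis: np.ndarray,
    reference_peaks: np.ndarray,
    match_window: float = 15.0,
    prominence_fraction: float = 0.02,
):
    """Fit the observed-position -> true-wavenumber calibration map.

    Peaks are detected in the measured reference spectrum, refined to
    sub-channel precision, and matched to the known band centers within
    ``match_window`` cm^-1.  With fewer than 4 matches the map is affine;
    with >= 4 it is a monotone cubic (PCHIP) with linear extrapolation.

    Returns (map_callable, diagnostics dict).
    """
    ref = np.asarray(measured_reference, dtype=float)
    known = np.sort(np.asarray(reference_peaks, dtype=float))
    span = float(ref.max() - ref.min())
    idx, _ = signal.find_peaks(ref, prominence=prominence_fraction * span)
    observed = np.array([_refine_peak(ref, int(i), axis) for i in idx])
    pairs: list[tuple[float, float]] = []
    for k in known:
        if observed.size == 0:
            continue
        j = int(np.argmin(np.abs(observed - k)))
        if abs(observed[j] - k) <= match_window:
            pairs.append((observed[j], k))
    if len(pairs) < 2:
        raise CalibrationError(
            f"only {len(pairs)} reference peak(s) matched; need >= 2"
        )
    obs = np.array([p[0] for p in pairs])
    tru = np.array([p[1] for p in pairs])
    order = np.argsort(obs)
    obs, tru = obs[order], tru[order]
    if len(pairs) >= 4:
        interp = PchipInterpolator(obs, tru, extrapolate=True)

        def mapping(w: np.ndarray) -> np.ndarray:
            w = np.asarray(w, dtype=float)
            out = interp(np.clip(w, obs[0], obs[-1]))
            d0 = interp.derivative()(obs[0])
            d1 = interp.derivative()(obs[-1])
            out = np.where(w < obs[0], tru[0] + d0 * (w - obs[0]), out)
            out = np.where(w > obs[-1], tru[-1] + d1 * (w - obs[-1]), out)
            return out

        kind = "pchip"
    else:
        slope, icpt = np.polyfit(obs, tru, 1)

        def mapping(w: np.ndarray) -> np.ndarray:
            return slope * np.asarray(w, dtype=float) + icpt

        kind = "affine"
    mapped = mapping(axis)
    if not np.all(np.diff(mapped) > 0):
        raise CalibrationError("fitted calibration map is non-monotone")
    diagnostics = {
        "kind": kind,
        "n_peaks_matched": len(pairs),
        "observed_positions": obs,
        "known_positions": tru,
        "mean_shift": float(np.mean(tru - obs)),
        "residual_rms": float(np.sqrt(np.mean((mapping(obs) - tru) ** 2))),
    }
    return mapping, diagnostics


def calibrate_axis(
    sset: SpectrumSet,
    measured_reference: np.ndarray,
    reference_peaks: np.ndarray,
    **kwargs,
) -> SpectrumSet:
    """Realign all spectra onto the canonical axis via a daily reference.

    The measured reference (acquired on the same grid as the set) defines a
    channel -> true-wavenumber map; every spectrum is then interpolated back
    onto the set's nominal axis.
    """
    mapping, _ = fit_axis_map(
        measured_reference, sset.axis, reference_peaks, **kwargs
    )
    true_w = mapping(sset.axis)
    out = np.empty_like(sset.intensities)
    for i in range(sset.n_cells):
        out[i] = np.interp(sset.axis, true_w, sset.intensities[i])
    return SpectrumSet(sset.axis.copy(), out, sset.meta.copy())


# ---------------------------------------------------------------------------
# silent region

def remove_silent_region(sset: SpectrumSet) -> SpectrumSet:
    """Drop channels inside the closed silent interval 1800-2700 cm^-1."""
    lo, hi = SILENT_REGION
    keep = ~(
        (sset.axis >= lo - _SILENT_EPS) & (sset.axis <= hi + _SILENT_EPS)
    )
    if keep.all():
        return sset.copy()
    return SpectrumSet(
        sset.axis[keep], sset.intensities[:, keep], sset.meta.copy()
    )


# ---------------------------------------------------------------------------
# outlier filtering

def pca_outlier_filter(
    sset: SpectrumSet, n_components: int = 6, mad_threshold: float = 5.0
) -> tuple[SpectrumSet, list[str]]:
    """Remove cells whose PCA scores are extreme on any retained component.

    A cell is an outlier when, for some component, |score - median| exceeds
    ``mad_threshold`` x 1.4826 x MAD of that component's scores.  Removed
    cells are returned by id; survivors keep qc_flag unchanged.
    """
    if n_components >= min(sset.n_cells, sset.n_channels):
        raise ValueError(
            f"n_components ({n_components}) must be < min(cells, channels) "
            f"({min(sset.n_cells, sset.n_channels)})"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(sset.intensities)
    med = np.median(scores, axis=0)
    mad = 1.4826 * np.median(np.abs(scores - med), axis=0)
    mad = np.maximum(mad, 1e-12)
    out_mask = (np.abs(scores - med) > mad_threshold * mad).any(axis=1)
    removed = sset.meta.loc[out_mask, "cell_id"].tolist()
    kept = sset.select(~out_mask)
    return kept, removed


# ---------------------------------------------------------------------------
# full chain

@dataclass
class PreprocessConfig:
    """Parameters and stage toggles for :func:`run_preprocessing`."""

    despike: bool = True
    despike_window: int = 5
    despike_threshold: float = 8.0
    baseline: bool = True
    baseline_knot_spacing: float = 150.0
    baseline_iterations: int = 10
    calibrate: bool = True
    silent_region: bool = True
    outlier_filter: bool = True
    outlier_components: int = 6
    outlier_mad_threshold: float = 5.0

    def to_dict(self) -> dict:
        return asdict(self)


def run_preprocessing(
    sset: SpectrumSet,
    config: PreprocessConfig | None = None,
    measured_reference: np.ndarray | None = None,
    reference_peaks: np.ndarray | None = None,
) -> tuple[SpectrumSet, dict]:
    """Apply the full chain: despike, baseline, calibrate, excise, filter.

    Calibration runs only when a measured reference and its known peak list
    are supplied (it needs a daily reference acquisition); otherwise the
    stage is reported as skipped.  Returns the processed set and a QC report.
    """
    cfg = config or PreprocessConfig()
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    cur = sset

    if cfg.despike:
        cur, spikes = remove_cosmic_rays(
            cur, cfg.despike_window, cfg.despike_threshold
        )
        report["stages"]["despike"] = {
            "n_replaced_channels": int(len(spikes)),
            "n_cells_affected": int(spikes["cell_id"].nunique()),
        }
    else:
        report["stages"]["despike"] = {"skipped": True}

    if cfg.baseline:
        cur = correct_baseline(
            cur, cfg.baseline_knot_spacing, cfg.baseline_iterations
        )
        report["stages"]["baseline"] = {
            "knot_spacing": cfg.baseline_knot_spacing,
            "iterations": cfg.baseline_iterations,
        }
    else:
        report["stages"]["baseline"] = {"skipped": True}

    if cfg.calibrate and measured_reference is not None:
        mapping, diag = fit_axis_map(
            measured_reference, cur.axis, np.asarray(reference_peaks)
        )
        true_w = mapping(cur.axis)
        y = np.empty_like(cur.intensities)
        for i in range(cur.n_cells):
            y[i] = np.interp(cur.axis, true_w, cur.intensities[i])
        cur = SpectrumSet(cur.axis.copy(), y, cur.meta.copy())
        report["stages"]["calibrate"] = {
            "kind": diag["kind"],
            "n_peaks_matched": diag["n_peaks_matched"],
            "mean_shift": diag["mean_shift"],
        }
    else:
        report["stages"]["calibrate"] = {"skipped": True}

    if cfg.silent_region:
        before = cur.n_channels
        cur = remove_silent_region(cur)
        report["stages"]["silent_region"] = {
            "n_channels_removed": before - cur.n_channels,
            "n_channels_remaining": cur.n_channels,
        }
    else:
        report["stages"]["silent_region"] = {"skipped": True}

    if cfg.outlier_filter:
        cur, removed = pca_outlier_filter(
            cur, cfg.outlier_components, cfg.outlier_mad_threshold
        )
        report["stages"]["outlier_filter"] = {
            "n_removed": len(removed),
            "removed_ids": removed,
        }
    else:
        report["stages"]["outlier_filter"] = {"skipped": True}

    report["n_cells_in"] = sset.n_cells
    report["n_cells_out"] = cur.n_cells
    return cur, report
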