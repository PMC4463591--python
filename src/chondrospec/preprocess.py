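"""Raw-to-analysis spectral correction chain.

Stages, applied in acquisition-pipeline order:

1. cosmic-ray removal (despike) — rolling-MAD outlier test on second
   differences, flagged points replaced by linear interpolation;
2. background subtraction — matched PBS trace of the same specimen;
3. Savitzky-Golay smoothing — 3rd order, 9-point window by default;
4. extended multiplicative signal correction (EMSC) — least-squares fit
   s ≈ b·r + Σ c_k ν̃^k against a reference spectrum r, then baseline
   removal and division by the gain b;
5. peak normalization — divide by the maximum intensity in the
   phenylalanine window [1001, 1007] cm⁻¹.

The EMSC reference is, by convention, the mean of the background-subtracted
smoothed cell spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet, WavenumberGrid


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class DespikeParams:
    window_points: int = 11
    mad_z_threshold: float = 8.0
    max_flag_fraction: float = 0.05
    # a flagged run wider than this is a real band, not a cosmic ray
    # (spikes span 1–3 grid points; +1 shoulder each side in the second
    # difference, +1 from mask growth)
    max_spike_width_points: int = 8
    # a spike's second difference is of the order of its amplitude, which
    # dwarfs the spectrum's own intensity range; band curvature does not.
    # Expressed as a fraction of the robust (spike-free) intensity range.
    min_prominence: float = 1.0


@dataclass(frozen=True)
class SavgolParams:
    polyorder: int = 3
    window_points: int = 9

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points <= self.polyorder:
            raise PreprocessError("SG window must be odd and exceed polyorder")


@dataclass(frozen=True)
class EMSCParams:
    degree: int = 2


@dataclass(frozen=True)
class NormParams:
    anchor: float = 1004.0
    window: tuple[float, float] = (1001.0, 1007.0)


@dataclass(frozen=True)
class PreprocessParams:
    despike: DespikeParams = field(default_factory=DespikeParams)
    sg: SavgolParams = field(default_factory=SavgolParams)
    emsc: EMSCParams = field(default_factory=EMSCParams)
    norm: NormParams = field(default_factory=NormParams)


@dataclass(frozen=True)
class EMSCFit:
    """Fitted multiplicative gain and polynomial baseline coefficients."""

    gain: float
    poly_coeffs: np.ndarray  # c_0 .. c_d in the scaled variable ν̃ ∈ [−1, 1]
    residual_norm: float


# ---------------------------------------------------------------------------
# despike


def _despike_array(y: np.ndarray, params: DespikeParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (cleaned, flagged mask) for one intensity trace."""
    if params.window_points < 5:
        raise PreprocessError("despike window must be at least 5 points")
    d2 = np.zeros_like(y)
    d2[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    med = median_filter(d2, size=params.window_points, mode="nearest")
    mad = median_filter(np.abs(d2 - med), size=params.window_points, mode="nearest")
    # Floor the rolling MAD by the spectrum-wide MAD: an 11-point MAD is a
    # noisy scale estimate whose occasional collapse would flag ordinary
    # noise (and sharp real peak tops) as spikes.  Cosmic rays dwarf both
    # scales, so the floor costs no sensitivity.
    global_mad = np.median(np.abs(d2 - np.median(d2)))
    sigma = 1.4826 * np.maximum(mad, global_mad) + 1e-12
    z = np.abs(d2 - med) / sigma
    # robust intensity range from a 3-point median (immune to the spikes
    # themselves); curvature of real bands stays well below it
    med3 = median_filter(y, size=3, mode="nearest")
    rrange = float(np.percentile(med3, 99.5) - np.percentile(med3, 0.5))
    flagged = (z > params.mad_z_threshold) & (
        np.abs(d2 - med) > params.min_prominence * rrange
    )
    # a spike contaminates the second difference of its neighbours too;
    # grow the mask by one point each side so shoulders are replaced
    grown = flagged.copy()
    grown[:-1] |= flagged[1:]
    grown[1:] |= flagged[:-1]
    # width screen: cosmic rays are narrow.  A wide contiguous flagged run
    # is a genuine spectral band (the robust scale degenerates on
    # noise-free spectra, where any curvature looks anomalous); keep it.
    if grown.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], grown.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > params.max_spike_width_points:
                grown[start:stop] = False
    if grown.mean() > params.max_flag_fraction:
        raise PreprocessError(
            f"despike flagged {grown.mean():.1%} of points (> "
            f"{params.max_flag_fraction:.0%}); input looks pathological"
        )
    if not grown.any():
        return y.copy(), grown
    x = np.arange(y.size)
    cleaned = y.copy()
    cleaned[grown] = np.interp(x[grown], x[~grown], y[~grown])
    return cleaned, grown


def despike(s: Spectrum, params: DespikeParams | None = None) -> Spectrum:
    """Remove narrow cosmic-ray spikes.

    Points whose second difference deviates from the rolling median by more
    than ``mad_z_threshold`` robust standard deviations are replaced by
    linear interpolation of the nearest unflagged neighbours.  Flagging
    more than ``max_flag_fraction`` of the spectrum raises, signalling a
    pathological input rather than silently rewriting it.
    """
    cleaned, _ = _despike_array(s.intensity, params or DespikeParams())
    return s.with_intensity(cleaned)


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(s: Spectrum, bg: Spectrum) -> Spectrum:
    """Pointwise cell − matched PBS background, on a shared grid."""
    if s.grid != bg.grid:
        raise PreprocessError("cell and background grids differ")
    if bg.meta.kind != "background":
        raise PreprocessError("bg spectrum is not of kind 'background'")
    return s.with_intensity(s.intensity - bg.intensity)


# ---------------------------------------------------------------------------
# smoothing


def savgol(s: Spectrum, params: SavgolParams | None = None) -> Spectrum:
    """Savitzky-Golay smoothing (default 3rd order, 9 points).

    Edges are handled by ``mode='interp'``: a polynomial of the filter
    order is fitted to the truncated one-sided windows.
    """
    p = params or SavgolParams()
    return s.with_intensity(
        savgol_filter(s.intensity, p.window_points, p.polyorder, mode="interp")
    )


# ---------------------------------------------------------------------------
# EMSC


def _poly_basis(grid: WavenumberGrid, degree: int) -> np.ndarray:
    v = grid.values
    mid = 0.5 * (v[0] + v[-1])
    nu = (v - mid) / ((v[-1] - v[0]) / 2.0)  # rescaled to [−1, 1] for conditioning
    return np.vander(nu, degree + 1, increasing=True)


def emsc_design(reference: Spectrum, degree: int) -> np.ndarray:
    """Design matrix [r | 1 | ν̃ | … | ν̃^d] of the EMSC least-squares model."""
    return np.column_stack([reference.intensity, _poly_basis(reference.grid, degree)])


def emsc_fit(s: Spectrum, reference: Spectrum, degree: int = 2) -> EMSCFit:
    """Least-squares fit of s = b·r + Σ_{k≤d} c_k·ν̃^k."""
    if s.grid != reference.grid:
        raise PreprocessError("spectrum and reference grids differ")
    design = emsc_design(reference, degree)
    coef, _, rank, _ = np.linalg.lstsq(design, s.intensity, rcond=None)
    if rank < design.shape[1]:
        raise PreprocessError(
            "singular EMSC design: reference is collinear with the polynomial basis"
        )
    resid = s.intensity - design @ coef
    return EMSCFit(
        gain=float(coef[0]),
        poly_coeffs=coef[1:].copy(),
        residual_norm=float(np.linalg.norm(resid)),
    )


def emsc_correct(s: Spectrum, fit: EMSCFit, reference: Spectrum) -> Spectrum:
    """Apply a fitted EMSC model: remove the baseline, divide by the gain."""
    if abs(fit.gain) < 1e-10:
        raise PreprocessError(f"non-physical EMSC gain {fit.gain!r}")
    basis = _poly_basis(s.grid, fit.poly_coeffs.size - 1)
    corrected = (s.intensity - basis @ fit.poly_coeffs) / fit.gain
    return s.with_intensity(corrected)


def emsc(s: Spectrum, reference: Spectrum, degree: int = 2) -> Spectrum:
    """Fit-and-correct convenience wrapper."""
    return emsc_correct(s, emsc_fit(s, reference, degree), reference)


# ---------------------------------------------------------------------------
# normalization


def normalize_peak(s: Spectrum, params: NormParams | None = None) -> Spectrum:
    """Scale so the maximum intensity in the anchor window equals 1."""
    p = params or NormParams()
    mask = s.grid.window_mask(*p.window)
    if not mask.any():
        raise PreprocessError("normalization window outside grid")
    peak = float(s.intensity[mask].max())
    if peak <= 0:
        raise PreprocessError(
            f"non-positive maximum {peak:g} in normalization window "
            f"{p.window}; preceding corrections likely failed"
        )
    return s.with_intensity(s.intensity / peak)


# ---------------------------------------------------------------------------
# full chain


def run_chain(
    cells: SpectrumSet,
    backgrounds: SpectrumSet,
    params: PreprocessParams | None = None,
) -> SpectrumSet:
    """Apply despike → background subtraction → SG → EMSC → normalization.

    Every cell must have a background of the same specimen_id.  The EMSC
    reference is the mean of all background-subtracted smoothed cell
    spectra.  Spectrum count, order, and metadata are preserved.
    """
    params = params or PreprocessParams()
    if cells.grid != backgrounds.grid:
        raise PreprocessError("cell and background sets are on different grids")
    bg_by_specimen: dict[str, np.ndarray] = {}
    for i in range(len(backgrounds)):
        row = backgrounds.manifest.iloc[i]
        bg_by_specimen[str(row["specimen_id"])] = backgrounds.matrix[i]

    n, p = cells.matrix.shape
    stage = np.empty_like(cells.matrix)
    for i in range(n):
        specimen = str(cells.manifest.iloc[i]["specimen_id"])
        if specimen not in bg_by_specimen:
            raise PreprocessError(
                f"no background spectrum for specimen {specimen!r} "
                f"(cell {cells.manifest.iloc[i]['cell_id']!r})"
            )
        try:
            cleaned, _ = _despike_array(cells.matrix[i], params.despike)
        except PreprocessError as exc:
            raise PreprocessError(
                f"despike failed for {cells.manifest.iloc[i]['cell_id']!r}: {exc}"
            ) from exc
        stage[i] = cleaned - bg_by_specimen[specimen]

    stage = savgol_filter(
        stage, params.sg.window_points, params.sg.polyorder, axis=1, mode="interp"
    )

    reference = Spectrum(cells.grid, stage.mean(axis=0))
    design = emsc_design(reference, params.emsc.degree)
    # one factorization serves every spectrum: solve for all rows at once
    coef, _, rank, _ = np.linalg.lstsq(design, stage.T, rcond=None)
    if rank < design.shape[1]:
        raise PreprocessError("singular EMSC design on this cohort")
    basis = design[:, 1:]
    gains = coef[0]
    if np.any(np.abs(gains) < 1e-10):
        bad = int(np.argmin(np.abs(gains)))
        raise PreprocessError(
            f"non-physical EMSC gain for {cells.manifest.iloc[bad]['cell_id']!r}"
        )
    stage = (stage - (basis @ coef[1:]).T) / gains[:, None]

    mask = cells.grid.window_mask(*params.norm.window)
    peaks = stage[:, mask].max(axis=1)
    if np.any(peaks <= 0):
        bad = int(np.argmin(peaks))
        raise PreprocessError(
            f"non-positive normalization peak for {cells.manifest.iloc[bad]['cell_id']!r}"
        )
    stage = stage / peaks[:, None]
    return cells.with_matrix(stage)
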