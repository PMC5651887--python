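"""Preprocessing chain for culture-medium Raman spectra.

Stage order: cosmic-ray despiking -> wavenumber calibration against a
toluene standard -> water-background subtraction -> iterative third-order
polynomial fluorescence correction -> normalization to maximum intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import CalibrationError, NormalizationError, RamanPipelineError
from .io_formats import LabeledCohort, Spectrum
from .synthetic import TOLUENE_REFERENCE_SHIFTS


@dataclass
class CalibrationMap:
    """Polynomial map from the observed shift axis to the calibrated axis.

    ``coefficients`` are in numpy polyval order (highest degree first).
    """

    coefficients: np.ndarray
    residual_rms: float
    matched_pairs: list[tuple[float, float]]  # (observed apex, reference shift)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.matched_pairs) < 2:
            raise CalibrationError(
                f"calibration needs >= 2 matched peaks, got {len(self.matched_pairs)}"
            )
        if not np.isfinite(self.residual_rms):
            raise CalibrationError("calibration residual RMS is not finite")

    def apply(self, axis: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(axis, float))


@dataclass
class PreprocessConfig:
    """Free parameters of the preprocessing chain."""

    spike_z_threshold: float = 8.0
    calib_order: int = 1
    calib_ref_shifts: tuple[float, ...] = TOLUENE_REFERENCE_SHIFTS
    calib_match_window: float = 15.0
    water_scale_mode: str = "unit"  # {"unit", "lsq"}
    water_fit_window: tuple[float, float] | None = None  # lsq mode: signal-poor window
    baseline_order: int = 3
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6

    def validate(self) -> None:
        if self.spike_z_threshold <= 0:
            raise RamanPipelineError("spike_z_threshold must be > 0")
        if self.calib_order not in (1, 2):
            raise RamanPipelineError("calib_order must be 1 or 2")
        if self.water_scale_mode not in ("unit", "lsq"):
            raise RamanPipelineError("water_scale_mode must be 'unit' or 'lsq'")
        if self.baseline_order < 1:
            raise RamanPipelineError("baseline_order must be >= 1")


# ---------------------------------------------------------------------------
# despiking


def despike(s: Spectrum, z_threshold: float = 8.0) -> Spectrum:
    """Remove single-channel cosmic-ray spikes.

    Channels whose modified z-score (0.6745*|d - median|/MAD) of the second
    difference exceeds ``z_threshold`` are replaced by the median of a
    5-point neighborhood excluding flagged channels; every other channel is
    left bit-identical.  The MAD is floored at 1e-3 of the intensity range
    so that smooth noise-free band curvature is not mistaken for spikes.
    """
    y = s.intensity
    if y.size < 5:
        return s.with_intensity(y.copy(), "warn:despike-skipped-short-spectrum")
    d2 = np.zeros_like(y)
    d2[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    span = float(np.max(y) - np.min(y))
    scale = max(mad, 2e-3 * span)
    if scale == 0.0:  # constant spectrum: zero second difference everywhere
        return s.with_intensity(y.copy(), "despike:none")
    z = 0.6745 * np.abs(d2 - med) / scale
    candidates = set(np.flatnonzero(z > z_threshold).tolist())
    # a spike at i also inflates the second difference at i-1 and i+1, so
    # confirm each candidate against its own intensity deviation before
    # replacing; unconfirmed channels stay bit-identical
    noise_sd_est = scale / (0.6745 * np.sqrt(6.0))
    out = y.copy()
    replaced = []
    for i in sorted(candidates):
        half = 2
        neighbors = []
        while not neighbors and half <= y.size:
            lo, hi = max(0, i - half), min(y.size, i + half + 1)
            neighbors = [y[j] for j in range(lo, hi) if j != i and j not in candidates]
            half += 2
        if not neighbors:
            continue
        local_med = float(np.median(neighbors))
        if abs(y[i] - local_med) > z_threshold * noise_sd_est:
            out[i] = local_med
            replaced.append(int(i))
    tag = f"despike:z={z_threshold},replaced={replaced}"
    return s.with_intensity(out, tag)


# ---------------------------------------------------------------------------
# wavenumber calibration


def _refine_apex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic-interpolated apex position around a local maximum index."""
    if i == 0 or i == x.size - 1:
        return float(x[i])
    coef = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if coef[0] >= 0:  # not concave; keep the grid point
        return float(x[i])
    apex = -coef[1] / (2.0 * coef[0])
    if not (x[i - 1] <= apex <= x[i + 1]):
        return float(x[i])
    return float(apex)


def detect_peaks(s: Spectrum, prominence_frac: float = 0.1) -> list[float]:
    """Apex positions of prominent peaks (quadratic-interpolated)."""
    y = s.intensity
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        return []
    idx, _ = find_peaks(y, prominence=prominence_frac * span)
    return [_refine_apex(s.shift, y, i) for i in idx]


def calibrate(
    s: Spectrum, toluene: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, CalibrationMap]:
    """Calibrate the shift axis against toluene reference bands.

    Toluene peak apexes are located by quadratic interpolation, matched to
    the nearest reference shift within the match window, and a polynomial
    map observed -> reference is least-squares fitted and applied to the
    sample's axis.
    """
    config = config or PreprocessConfig()
    config.validate()
    apexes = detect_peaks(toluene)
    pairs = []
    for ref in config.calib_ref_shifts:
        cands = [a for a in apexes if abs(a - ref) <= config.calib_match_window]
        if cands:
            pairs.append((min(cands, key=lambda a: abs(a - ref)), ref))
    if len(pairs) < max(2, config.calib_order + 1):
        raise CalibrationError(
            f"matched only {len(pairs)} toluene peaks "
            f"(need >= {max(2, config.calib_order + 1)})"
        )
    obs = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    coef = np.polyfit(obs, ref, config.calib_order)
    resid = np.polyval(coef, obs) - ref
    rms = float(np.sqrt(np.mean(resid**2)))
    # monotonicity of the map over the sample's axis range
    deriv = np.polyval(np.polyder(coef), np.linspace(s.shift[0], s.shift[-1], 101))
    if not np.all(deriv > 0):
        raise CalibrationError("calibration map is non-monotone over the data range")
    cal = CalibrationMap(coef, rms, pairs)
    new_axis = cal.apply(s.shift)
    out = Spectrum(
        s.sample_id,
        new_axis,
        s.intensity.copy(),
        s.processing_log + [f"calibrate:order={config.calib_order},rms={rms:.4g}"],
    )
    return out, cal


# ---------------------------------------------------------------------------
# water subtraction


def subtract_water(
    s: Spectrum,
    water: Spectrum,
    mode: str = "unit",
    fit_window: tuple[float, float] | None = None,
) -> Spectrum:
    """Subtract the water background.

    mode="unit": plain subtraction s - water.
    mode="lsq": s - alpha*water with alpha >= 0 minimizing the squared
    residual over a signal-poor window (default: the top 15% of the axis).
    """
    w = np.interp(s.shift, water.shift, water.intensity)
    if mode == "unit":
        return s.with_intensity(s.intensity - w, "water:unit")
    if mode != "lsq":
        raise RamanPipelineError(f"unknown water subtraction mode {mode!r}")
    if fit_window is None:
        lo = s.shift[0] + 0.85 * (s.shift[-1] - s.shift[0])
        fit_window = (lo, s.shift[-1])
    mask = (s.shift >= fit_window[0]) & (s.shift <= fit_window[1])
    denom = float(np.dot(w[mask], w[mask]))
    alpha = 0.0 if denom == 0 else max(0.0, float(np.dot(s.intensity[mask], w[mask]) / denom))
    return s.with_intensity(s.intensity - alpha * w, f"water:lsq,alpha={alpha:.4g}")


# ---------------------------------------------------------------------------
# fluorescence baseline


def baseline_correct(
    s: Spectrum, order: int = 3, max_iter: int = 100, tol: float = 1e-6
) -> tuple[Spectrum, np.ndarray]:
    """Iterative modified-polyfit fluorescence correction (Lieber-style).

    An order-``order`` polynomial is fitted to the working vector; values
    above the fit are replaced by the fit; iterate until the baseline's
    maximum relative change is below ``tol`` or ``max_iter`` is reached.
    The clipping loop leaves a small bias under isolated bands (its fixed
    point is not the background polynomial), so a final refit uses only the
    channels consistent with the converged baseline — within 3 robust SDs,
    estimated from the below-baseline residuals.  On band-free polynomial
    input the refit sees every channel and is exact.  Returns the corrected
    spectrum and the final baseline.
    """
    if s.shift.size <= order + 1:
        raise RamanPipelineError(
            f"{s.sample_id}: need > order+1 points for baseline correction"
        )
    # scale axis to [-1, 1] for conditioning
    x = -1.0 + 2.0 * (s.shift - s.shift[0]) / (s.shift[-1] - s.shift[0])
    work = s.intensity.astype(float).copy()
    base = np.zeros_like(work)
    converged = False
    scale = max(float(np.max(np.abs(s.intensity))), 1e-30)
    for _ in range(max_iter):
        coef = np.polyfit(x, work, order)
        new_base = np.polyval(coef, x)
        delta = float(np.max(np.abs(new_base - base))) / scale
        base = new_base
        work = np.minimum(work, base)
        if delta < tol:
            converged = True
            break
    resid = s.intensity - base
    med = float(np.median(resid))
    sd = 1.4826 * float(np.median(np.abs(resid - med)))
    if sd > 0:
        keep = np.abs(resid - med) <= 3.0 * sd
        if keep.sum() > order + 1:
            coef = np.polyfit(x[keep], s.intensity[keep], order)
            base = np.polyval(coef, x)
    tag = f"baseline:order={order}" + ("" if converged else ",warn:not-converged")
    return s.with_intensity(s.intensity - base, tag), base


def normalize_max(s: Spectrum) -> Spectrum:
    """Divide intensities by their maximum, making max(output) exactly 1."""
    m = float(np.max(s.intensity))
    if m <= 0:
        raise NormalizationError(
            f"{s.sample_id}: non-positive maximum intensity ({m}); "
            "baseline correction likely failed"
        )
    return s.with_intensity(s.intensity / m, "normalize:max")


# ---------------------------------------------------------------------------
# full chain


def preprocess_spectrum(
    s: Spectrum,
    toluene: Spectrum | None,
    water: Spectrum | None,
    config: PreprocessConfig | None = None,
    common_axis: np.ndarray | None = None,
) -> Spectrum:
    """Apply the full chain to one spectrum.

    When a common axis is given, the calibrated spectrum is resampled back
    onto it so the cohort stays on one grid.
    """
    config = config or PreprocessConfig()
    config.validate()
    out = despike(s, config.spike_z_threshold)
    if toluene is not None:
        out, _ = calibrate(out, toluene, config)
        if common_axis is not None:
            out = out.resample(common_axis, "resample:post-calibration")
    if water is not None:
        out = subtract_water(out, water, config.water_scale_mode, config.water_fit_window)
    out, _ = baseline_correct(
        out, config.baseline_order, config.baseline_max_iter, config.baseline_tol
    )
    return normalize_max(out)


def run_chain(
    cohort: LabeledCohort,
    toluene: Spectrum | None,
    water: Spectrum | None,
    config: PreprocessConfig | None = None,
) -> tuple[LabeledCohort, dict]:
    """Preprocess every spectrum in the cohort.

    Water is calibrated with the same toluene map before subtraction.
    A stage failure aborts that sample and is recorded in the returned
    failure report; the remaining samples proceed.
    """
    config = config or PreprocessConfig()
    axis = cohort.common_axis
    cal_water = water
    if water is not None and toluene is not None:
        cal_water, _ = calibrate(despike(water, config.spike_z_threshold), toluene, config)
    processed, labels, failures = [], {}, {}
    for s in cohort.spectra:
        try:
            p = preprocess_spectrum(s, toluene, cal_water, config, common_axis=axis)
            processed.append(p)
            labels[s.sample_id] = cohort.labels[s.sample_id]
        except RamanPipelineError as exc:
            failures[s.sample_id] = str(exc)
    out_axis = axis if processed else None
    report = {"n_in": len(cohort), "n_out": len(processed), "failures": failures}
    return LabeledCohort(processed, labels, out_axis), report
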