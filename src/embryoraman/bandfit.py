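"""Gaussian band-component analysis and band-area-ratio features.

Preprocessed spectra are decomposed over two regions (defaults 815-1065 and
1140-1500 cm^-1) into sums of Gaussian components by bounded nonlinear least
squares.  Band areas come from the closed form A*sigma*sqrt(2*pi), and the
viability feature is the area ratio of the bands nearest the nominal 900 and
940 cm^-1 centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .errors import ConfigError, FittingError, MissingBandError, PipelineError
from .io_formats import LabeledCohort, Spectrum

DEFAULT_REGIONS = ((815.0, 1065.0), (1140.0, 1500.0))

#: Nominal band centers used for feature columns and (in manual mode) for
#: seeding; mirrors the default synthetic band inventory over both regions.
DEFAULT_NOMINAL_CENTERS = (830.0, 862.0, 900.0, 940.0, 1003.0, 1045.0,
                           1180.0, 1260.0, 1340.0, 1450.0)

SIGMA_BOUNDS = (2.0, 40.0)
CENTER_WINDOW = 10.0  # fitted centers stay within +/- this of their seeds


@dataclass
class Band:
    """One fitted Gaussian component with closed-form area."""

    center: float
    sigma: float
    amplitude: float
    center_err: float = math.nan
    sigma_err: float = math.nan
    amplitude_err: float = math.nan

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)

    @property
    def area_err(self) -> float:
        if math.isnan(self.amplitude_err) or math.isnan(self.sigma_err):
            return math.nan
        # first-order propagation, ignoring A-sigma covariance
        return math.sqrt(2.0 * math.pi) * math.hypot(
            self.sigma * self.amplitude_err, self.amplitude * self.sigma_err
        )


@dataclass
class BandFit:
    """Fitted Gaussian decomposition of one spectrum over one region."""

    sample_id: str
    region: tuple[float, float]
    bands: list[Band]
    residual_rms: float
    converged: bool
    message: str = ""

    def band_near(self, center: float, tol: float = 10.0) -> Band:
        cands = [b for b in self.bands if abs(b.center - center) <= tol]
        if not cands:
            raise MissingBandError(
                f"{self.sample_id}: no fitted band within {tol} cm^-1 of {center:g}"
            )
        return min(cands, key=lambda b: abs(b.center - center))


@dataclass
class FeatureTable:
    """Per-sample band areas and ratios with labels.

    ``table`` has index sample_id and columns ``label``, ``area_<center>``
    per nominal center, and one ratio column per ratio spec (``r900_940``).
    ``excluded`` maps dropped sample ids to the reason.
    """

    table: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c != "label"]

    def groups(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """(pregnant values, nonpregnant values) for one feature column."""
        t = self.table
        return (
            t.loc[t["label"] == "pregnant", column].to_numpy(float),
            t.loc[t["label"] == "nonpregnant", column].to_numpy(float),
        )


def _gauss_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for c, sig, amp in params.reshape(-1, 3):
        out += amp * np.exp(-((x - c) ** 2) / (2.0 * sig**2))
    return out


def seed_bands(
    s: Spectrum,
    region: tuple[float, float],
    n_bands: int | None = None,
    centers: list[float] | None = None,
    smooth_sigma: float = 2.0,
    min_strength: float = 0.02,
) -> list[Band]:
    """Initial band guesses for a region.

    Manual mode (``centers`` given): one seed per requested center with
    sigma = 8 cm^-1 and amplitude = local intensity.  Auto mode: candidate
    centers at minima of the smoothed second derivative (band curvature is
    most negative at a Gaussian's apex); the strongest ``n_bands`` kept, or
    all candidates above ``min_strength`` of the region maximum.
    """
    lo, hi = region
    mask = (s.shift >= lo) & (s.shift < hi)
    if mask.sum() < 5:
        raise FittingError(f"region {region} contains too few points")
    x, y = s.shift[mask], s.intensity[mask]
    if centers is not None:
        seeds = []
        for c in centers:
            if not (lo <= c < hi):
                continue
            amp = float(np.interp(c, x, y))
            seeds.append(Band(float(c), 8.0, max(amp, 0.0)))
        if not seeds:
            raise FittingError(f"no requested centers fall inside region {region}")
        return seeds
    sm = gaussian_filter1d(y, smooth_sigma)
    d2 = np.gradient(np.gradient(sm, x), x)
    cand = [
        i
        for i in range(1, x.size - 1)
        if d2[i] < 0 and d2[i] <= d2[i - 1] and d2[i] <= d2[i + 1]
    ]
    peak = float(np.max(y)) if y.size else 0.0
    if peak <= 0:
        raise FittingError(
            f"no signal in region {region}; provide manual centers"
        )
    cand = [i for i in cand if y[i] >= min_strength * peak]
    if not cand:
        raise FittingError(
            f"no band candidates found in region {region}; provide manual centers"
        )
    cand.sort(key=lambda i: y[i], reverse=True)
    if n_bands is not None:
        cand = cand[:n_bands]
    cand.sort(key=lambda i: x[i])
    return [Band(float(x[i]), 8.0, max(float(y[i]), 0.0)) for i in cand]


def fit_bands(
    s: Spectrum,
    region: tuple[float, float],
    seeds: list[Band],
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
    center_window: float = CENTER_WINDOW,
) -> BandFit:
    """Bounded nonlinear least squares over one region.

    Centers stay within ``center_window`` of their seeds, widths within
    ``sigma_bounds``, amplitudes non-negative.  Areas come from the closed
    form; per-parameter uncertainties from the Jacobian when estimable.
    """
    if not seeds:
        raise FittingError("fit_bands needs at least one seed")
    lo, hi = region
    mask = (s.shift >= lo) & (s.shift < hi)
    x, y = s.shift[mask], s.intensity[mask]
    n_par = 3 * len(seeds)
    if x.size <= n_par:
        raise FittingError(
            f"region {region}: {x.size} points cannot constrain {n_par} parameters"
        )
    p0, lb, ub = [], [], []
    for b in seeds:
        sig0 = min(max(b.sigma, sigma_bounds[0]), sigma_bounds[1])
        p0 += [b.center, sig0, max(b.amplitude, 0.0)]
        lb += [b.center - center_window, sigma_bounds[0], 0.0]
        ub += [b.center + center_window, sigma_bounds[1], np.inf]

    res = least_squares(
        lambda p: _gauss_sum(x, p) - y, p0, bounds=(lb, ub), method="trf", x_scale="jac"
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # trf keeps iterates strictly inside the bounds; snap amplitudes that
    # ended epsilon above zero back onto the bound
    snap = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    res.x[2::3] = np.where(res.x[2::3] < snap, 0.0, res.x[2::3])
    errs = np.full(len(res.x), math.nan)
    dof = x.size - len(res.x)
    if res.success and dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.pinv(jtj) * (2.0 * res.cost / dof)
            errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    bands = [
        Band(c, sig, amp, ec, es, ea)
        for (c, sig, amp), (ec, es, ea) in zip(
            res.x.reshape(-1, 3), errs.reshape(-1, 3)
        )
    ]
    bands.sort(key=lambda b: b.center)
    return BandFit(s.sample_id, region, bands, rms, bool(res.success), res.message)


def band_ratio(
    fit_or_fits, num_center: float = 900.0, den_center: float = 940.0, tol: float = 10.0
) -> float:
    """Area ratio of the bands nearest two nominal centers.

    Accepts one BandFit or a list (bands pooled across regions).  Raises
    MissingBandError when either band is absent or the denominator area is
    not positive.
    """
    fits = fit_or_fits if isinstance(fit_or_fits, (list, tuple)) else [fit_or_fits]
    pooled = BandFit(
        fits[0].sample_id,
        (min(f.region[0] for f in fits), max(f.region[1] for f in fits)),
        [b for f in fits for b in f.bands],
        0.0,
        True,
    )
    num = pooled.band_near(num_center, tol)
    den = pooled.band_near(den_center, tol)
    if den.area <= 0:
        raise MissingBandError(
            f"{pooled.sample_id}: zero-area denominator band near {den_center:g}"
        )
    return num.area / den.area


def fit_cohort(
    cohort: LabeledCohort,
    regions=DEFAULT_REGIONS,
    centers=DEFAULT_NOMINAL_CENTERS,
    n_bands: int | None = None,
    auto_seed: bool = False,
) -> dict[str, list[BandFit]]:
    """Fit every sample over every region; returns fits keyed by sample."""
    out: dict[str, list[BandFit]] = {}
    for s in cohort.spectra:
        fits = []
        for region in regions:
            region_centers = None if auto_seed else [
                c for c in centers if region[0] <= c < region[1]
            ]
            seeds = seed_bands(s, region, n_bands=n_bands, centers=region_centers)
            fits.append(fit_bands(s, region, seeds))
        out[s.sample_id] = fits
    return out


def build_features(
    fits_by_sample: dict[str, list[BandFit]],
    labels: dict[str, str],
    nominal_centers=DEFAULT_NOMINAL_CENTERS,
    ratio_specs=((900.0, 940.0),),
    tol: float = 10.0,
) -> FeatureTable:
    """Assemble the per-sample feature table of band areas and ratios.

    Samples with a non-converged fit or a missing/zero band are excluded
    and listed in ``FeatureTable.excluded``.
    """
    for num, den in ratio_specs:
        for c in (num, den):
            if not any(abs(c - nc) <= tol for nc in nominal_centers):
                raise ConfigError(
                    f"ratio spec references center {c:g} absent from nominal_centers"
                )
    rows, excluded = {}, {}
    for sid, fits in fits_by_sample.items():
        bad = [f for f in fits if not f.converged]
        if bad:
            excluded[sid] = f"non-converged fit in region {bad[0].region}"
            continue
        pooled = [b for f in fits for b in f.bands]
        helper = BandFit(sid, (0.0, np.inf), pooled, 0.0, True)
        row: dict[str, float | str] = {"label": labels[sid]}
        try:
            for nc in nominal_centers:
                row[f"area_{nc:g}"] = helper.band_near(nc, tol).area
            for num, den in ratio_specs:
                row[f"r{num:g}_{den:g}"] = band_ratio(fits, num, den, tol)
        except MissingBandError as exc:
            excluded[sid] = str(exc)
            continue
        rows[sid] = row
    if not rows:
        raise PipelineError("feature table is empty: no sample produced usable fits")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return FeatureTable(table, excluded)
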