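"""Synthetic Raman cohorts with known ground truth.

Real spent-culture-medium spectra are modeled as a sum of Gaussian bands
riding on a smooth cubic fluorescence background plus a broad, weak water
contribution, with additive detector noise and occasional single-channel
cosmic-ray spikes.  A two-group difference is planted multiplicatively on
the amplitude of the 900 cm^-1 band, so the 900/940 band-area ratio carries
the group effect — the feature the downstream screen and classifier are
built to detect.  Every stochastic draw is recorded in a GroundTruth record
so each pipeline stage can be tested against exact truth.

The band library is a stand-in: the real medium's band inventory is not
specified anywhere, so centers/widths/amplitudes here are free parameters
chosen to look like a protein-and-metabolite-bearing aqueous medium, not
claims about any particular formulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io_formats import LabeledCohort, Spectrum, write_manifest, write_spectrum

#: Canonical toluene reference Raman shifts (cm^-1) used for wavenumber
#: calibration; standard published band positions.
TOLUENE_REFERENCE_SHIFTS = (521.0, 785.8, 1003.6, 1030.6, 1210.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: A * exp(-(v - c)^2 / (2 sigma^2)).

    Area has the closed form A * sigma * sqrt(2*pi).
    """

    center: float
    sigma: float
    amplitude: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ConfigError(f"BandSpec.sigma must be > 0, got {self.sigma}")
        if self.amplitude < 0:
            raise ConfigError(f"BandSpec.amplitude must be >= 0, got {self.amplitude}")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)

    def profile(self, axis: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((axis - self.center) ** 2) / (2.0 * self.sigma**2))


def gaussian_area(amplitude: float, sigma: float) -> float:
    """Closed-form area of A*exp(-(v-c)^2/(2 sigma^2)): A*sigma*sqrt(2 pi)."""
    return amplitude * sigma * np.sqrt(2.0 * np.pi)


#: Default band library: ~10 bands spanning 815-1500 cm^-1 including the
#: nominal 900 and 940 cm^-1 bands; widths 6-15 cm^-1.  The strongest band
#: sits near 1003 cm^-1 (phenylalanine ring-breathing territory) so that
#: max-normalization is not driven by the effect-carrying 900 band.
DEFAULT_BAND_LIBRARY = (
    BandSpec(830.0, 9.0, 0.35),
    BandSpec(862.0, 8.0, 0.25),
    BandSpec(900.0, 9.0, 0.30),
    BandSpec(940.0, 10.0, 0.50),
    BandSpec(1003.0, 6.0, 1.00),
    BandSpec(1045.0, 8.0, 0.40),
    BandSpec(1180.0, 12.0, 0.30),
    BandSpec(1260.0, 14.0, 0.45),
    BandSpec(1340.0, 13.0, 0.35),
    BandSpec(1450.0, 15.0, 0.60),
)

#: Water contribution: two very broad (sigma > 100 cm^-1), weak Gaussians.
DEFAULT_WATER_PROFILE = (
    BandSpec(1640.0, 180.0, 0.25),
    BandSpec(760.0, 260.0, 0.15),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the study's design: 15 pregnant / 16 non-pregnant
    samples, a group effect doubling the 900 cm^-1 band amplitude in the
    pregnant group, detector noise at 1% of the strongest band, and on
    average one cosmic-ray spike per spectrum.

    ``baseline_coeffs`` are cubic-polynomial coefficients (constant first)
    in the normalized coordinate t = (v - v_min)/(v_max - v_min), so their
    magnitudes are on the intensity scale regardless of the axis range.
    ``pixel_map`` (gain, offset) optionally distorts the recorded shift
    axis: a feature truly at v appears at gain*v + offset, for exercising
    the wavenumber-calibration stage.
    """

    axis_range: tuple[float, float] = (600.0, 1800.0)
    n_points: int = 1201
    band_library: tuple[BandSpec, ...] = DEFAULT_BAND_LIBRARY
    baseline_coeffs: tuple[float, float, float, float] = (2.0, -1.5, 0.8, -0.3)
    water_profile: tuple[BandSpec, ...] = DEFAULT_WATER_PROFILE
    noise_sd: float = 0.01
    spike_rate: float = 1.0
    spike_amplitude_range: tuple[float, float] = (10.0, 50.0)
    effect_size: float = 2.0
    n_pregnant: int = 15
    n_nonpregnant: int = 16
    seed: int = 0
    # per-sample band variability (multiplicative amp jitter SD, additive
    # center jitter SD in cm^-1, multiplicative width jitter SD); the 900
    # band is exempt so the planted group effect on its area is exact
    amplitude_jitter_sd: float = 0.05
    center_jitter_sd: float = 0.5
    sigma_jitter_sd: float = 0.02
    pixel_map: tuple[float, float] = (1.0, 0.0)
    toluene_sigma: float = 3.0

    def validate(self) -> None:
        lo, hi = self.axis_range
        if not hi > lo:
            raise ConfigError(f"axis_range: max must exceed min, got {self.axis_range}")
        if self.n_points < 200:
            raise ConfigError(f"n_points must be >= 200, got {self.n_points}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.spike_rate < 0:
            raise ConfigError(f"spike_rate must be >= 0, got {self.spike_rate}")
        if self.n_pregnant < 1 or self.n_nonpregnant < 1:
            raise ConfigError(
                f"group sizes must be >= 1, got n_pregnant={self.n_pregnant}, "
                f"n_nonpregnant={self.n_nonpregnant}"
            )
        if self.effect_size <= 0:
            raise ConfigError(f"effect_size must be > 0, got {self.effect_size}")
        if len(self.baseline_coeffs) != 4:
            raise ConfigError("baseline_coeffs must have exactly 4 coefficients")
        for b in self.band_library:
            if not (lo <= b.center <= hi):
                raise ConfigError(
                    f"band_library: center {b.center} outside axis_range {self.axis_range}"
                )
        if self.effect_size != 1.0 and not any(
            abs(b.center - 900.0) <= 1.0 for b in self.band_library
        ):
            raise ConfigError(
                "band_library must include a band at 900 cm^-1 to carry "
                f"effect_size={self.effect_size}"
            )
        if self.pixel_map[0] <= 0:
            raise ConfigError(f"pixel_map gain must be > 0, got {self.pixel_map[0]}")

    @property
    def axis(self) -> np.ndarray:
        lo, hi = self.axis_range
        return np.linspace(lo, hi, self.n_points)

    def distort(self, v):
        """Map a true shift to its recorded position under pixel_map."""
        gain, offset = self.pixel_map
        return gain * np.asarray(v, float) + offset


@dataclass
class GroundTruth:
    """Every stochastic draw behind one generated spectrum."""

    sample_id: str
    label: str
    bands: list[BandSpec]
    spike_indices: list[int]
    spike_amplitudes: list[float]
    baseline_coeffs: tuple[float, float, float, float]
    noise_sd: float

    def band_near(self, center: float, tol: float = 10.0) -> BandSpec:
        cands = [b for b in self.bands if abs(b.center - center) <= tol]
        if not cands:
            raise KeyError(f"no true band within {tol} cm^-1 of {center}")
        return min(cands, key=lambda b: abs(b.center - center))

    def true_area(self, center: float, tol: float = 10.0) -> float:
        return self.band_near(center, tol).area

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d


def _baseline(config: SimConfig) -> np.ndarray:
    lo, hi = config.axis_range
    t = (config.axis - lo) / (hi - lo)
    c0, c1, c2, c3 = config.baseline_coeffs
    return c0 + c1 * t + c2 * t**2 + c3 * t**3


def _water(config: SimConfig) -> np.ndarray:
    axis = config.axis
    out = np.zeros_like(axis)
    for b in config.water_profile:
        out += BandSpec(config.distort(b.center), b.sigma * config.pixel_map[0], b.amplitude).profile(axis)
    return out


def _realize_bands(config: SimConfig, label: str, rng: np.random.Generator) -> list[BandSpec]:
    """Per-sample band parameters.

    All bands except the 900 cm^-1 band get multiplicative amplitude and
    width jitter plus small center jitter.  The 900 band is deterministic:
    its amplitude is exactly base * effect_size in the pregnant group, so
    the ratio of group means of true 900-band areas equals effect_size.
    """
    realized = []
    for b in config.band_library:
        is_effect_band = abs(b.center - 900.0) <= 1.0
        if is_effect_band:
            amp = b.amplitude * (config.effect_size if label == "pregnant" else 1.0)
            realized.append(BandSpec(b.center, b.sigma, amp))
        else:
            amp = b.amplitude * max(0.0, 1.0 + config.amplitude_jitter_sd * rng.standard_normal())
            sigma = b.sigma * max(0.1, 1.0 + config.sigma_jitter_sd * rng.standard_normal())
            center = b.center + config.center_jitter_sd * rng.standard_normal()
            realized.append(BandSpec(center, sigma, amp))
    return realized


def generate_spectrum(
    config: SimConfig,
    label: str,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> tuple[Spectrum, GroundTruth]:
    """Generate one spectrum: bands + cubic baseline + water + noise + spikes."""
    config.validate()
    if label not in ("pregnant", "nonpregnant"):
        raise ConfigError(f"label must be 'pregnant' or 'nonpregnant', got {label!r}")
    axis = config.axis
    bands = _realize_bands(config, label, rng)
    gain = config.pixel_map[0]
    clean = _baseline(config) + _water(config)
    for b in bands:
        # under a distorted pixel map a band truly at c appears at distort(c)
        clean = clean + BandSpec(config.distort(b.center), b.sigma * gain, b.amplitude).profile(axis)
    intensity = clean + rng.normal(0.0, config.noise_sd, size=axis.size)

    n_spikes = rng.poisson(config.spike_rate)
    spike_idx = sorted(rng.choice(axis.size, size=min(n_spikes, axis.size), replace=False).tolist())
    spike_amps = []
    lo_f, hi_f = config.spike_amplitude_range
    floor = 0.05 * float(np.max(np.abs(clean))) if np.any(clean) else 1.0
    for i in spike_idx:
        factor = rng.uniform(lo_f, hi_f)
        amp = factor * max(abs(clean[i]), floor)
        intensity[i] += amp
        spike_amps.append(float(amp))

    spectrum = Spectrum(sample_id, axis, intensity, [f"synthetic:label={label}"])
    truth = GroundTruth(
        sample_id, label, bands, list(spike_idx), spike_amps,
        tuple(config.baseline_coeffs), config.noise_sd,
    )
    return spectrum, truth


def generate_cohort(config: SimConfig) -> tuple[LabeledCohort, list[GroundTruth]]:
    """Generate the full labeled cohort (default 15 pregnant / 16 non-pregnant)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    spectra, labels = [], {}
    plan = [("P{:02d}".format(i + 1), "pregnant") for i in range(config.n_pregnant)]
    plan += [("N{:02d}".format(i + 1), "nonpregnant") for i in range(config.n_nonpregnant)]
    truth_list = []
    for sid, label in plan:
        s, t = generate_spectrum(config, label, rng, sample_id=sid)
        spectra.append(s)
        truth_list.append(t)
        labels[sid] = label
    return LabeledCohort(spectra, labels, config.axis), truth_list


def generate_references(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Spectrum, Spectrum]:
    """Session reference spectra: a toluene calibration standard and water.

    Toluene carries narrow bands at the canonical reference shifts that fall
    inside the axis range (recorded at their pixel-map-distorted positions);
    water is the configured water profile.  Both share the cohort axis and
    carry the configured noise level.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    axis = config.axis
    lo, hi = config.axis_range
    tol_intensity = np.zeros_like(axis)
    gain = config.pixel_map[0]
    for ref in TOLUENE_REFERENCE_SHIFTS:
        pos = config.distort(ref)
        if lo + 5 <= pos <= hi - 5:
            tol_intensity += BandSpec(pos, config.toluene_sigma * gain, 1.0).profile(axis)
    tol_intensity += rng.normal(0.0, config.noise_sd, size=axis.size)
    toluene = Spectrum("toluene_reference", axis, tol_intensity, ["synthetic:toluene"])

    water_intensity = _water(config) + rng.normal(0.0, config.noise_sd, size=axis.size)
    water = Spectrum("water_background", axis, water_intensity, ["synthetic:water"])
    return toluene, water


def write_cohort(
    config: SimConfig,
    out_dir,
    cohort: LabeledCohort | None = None,
    truths: list[GroundTruth] | None = None,
) -> Path:
    """Write spectra CSVs, manifest, references, and ground-truth JSON.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None or truths is None:
        cohort, truths = generate_cohort(config)
    rows = []
    for s in cohort.spectra:
        rel = f"{s.sample_id}.csv"
        write_spectrum(s, out_dir / rel)
        rows.append({"sample_id": s.sample_id, "path": rel, "label": cohort.labels[s.sample_id]})
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    toluene, water = generate_references(config)
    write_spectrum(toluene, out_dir / "toluene.csv")
    write_spectrum(water, out_dir / "water.csv")
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1)
    return manifest_path
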