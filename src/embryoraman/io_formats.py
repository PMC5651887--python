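"""Spectrum/cohort containers and file I/O (two-column CSV, JCAMP-DX, manifests).

A :class:`Spectrum` is one sample's Raman shift axis (cm^-1) plus intensity
vector (arbitrary units) with a processing log.  A :class:`LabeledCohort`
bundles spectra with binary clinical-pregnancy labels and, after assembly,
a shared uniform shift grid so that downstream band fitting and PCA operate
on comparable channels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import AssemblyError, FormatError

CSV_HEADER = ("wavenumber_cm1", "intensity")
VALID_LABELS = ("pregnant", "nonpregnant")
POSITIVE_LABEL = "pregnant"


@dataclass
class Spectrum:
    """A single Raman spectrum on a strictly increasing shift axis.

    Parameters
    ----------
    sample_id : str
        Identifier joining the spectrum to manifest rows and labels.
    shift : ndarray
        Raman shift axis in cm^-1, strictly increasing, length >= 2.
    intensity : ndarray
        Intensity in arbitrary units, same length as ``shift``, all finite.
    processing_log : list of str
        Ordered tags of processing steps already applied.
    """

    sample_id: str
    shift: np.ndarray
    intensity: np.ndarray
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError(f"{self.sample_id}: shift and intensity must be 1-D")
        if self.shift.size != self.intensity.size:
            raise FormatError(
                f"{self.sample_id}: axis length {self.shift.size} != "
                f"intensity length {self.intensity.size}"
            )
        if self.shift.size < 2:
            raise FormatError(f"{self.sample_id}: need at least 2 points")
        if not np.all(np.isfinite(self.shift)):
            raise FormatError(f"{self.sample_id}: non-finite shift values")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError(f"{self.sample_id}: non-finite intensity values")
        if not np.all(np.diff(self.shift) > 0):
            raise FormatError(
                f"{self.sample_id}: shift axis must be strictly increasing "
                "(use Spectrum.from_unsorted to sort/deduplicate)"
            )

    @classmethod
    def from_unsorted(
        cls,
        sample_id: str,
        shift: np.ndarray,
        intensity: np.ndarray,
        processing_log: list[str] | None = None,
    ) -> "Spectrum":
        """Build a Spectrum from possibly unsorted data.

        Non-monotone axes are sorted (logged with a warning tag) and exact
        duplicate shifts are averaged.
        """
        log = list(processing_log or [])
        shift = np.asarray(shift, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if shift.size and not np.all(np.diff(shift) > 0):
            order = np.argsort(shift, kind="stable")
            if not np.array_equal(order, np.arange(shift.size)):
                log.append("warn:axis-sorted-on-read")
            shift, intensity = shift[order], intensity[order]
            uniq, inverse, counts = np.unique(
                shift, return_inverse=True, return_counts=True
            )
            if uniq.size != shift.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, intensity)
                shift, intensity = uniq, summed / counts
                log.append("warn:duplicate-shifts-averaged")
        return cls(sample_id, shift, intensity, log)

    def with_intensity(self, intensity: np.ndarray, log_entry: str | None = None) -> "Spectrum":
        """Copy with new intensities (same axis), appending a log entry."""
        log = self.processing_log + ([log_entry] if log_entry else [])
        return Spectrum(self.sample_id, self.shift.copy(), np.asarray(intensity, float), log)

    def with_shift(self, shift: np.ndarray, log_entry: str | None = None) -> "Spectrum":
        log = self.processing_log + ([log_entry] if log_entry else [])
        return Spectrum(self.sample_id, np.asarray(shift, float), self.intensity.copy(), log)

    def resample(self, axis: np.ndarray, log_entry: str | None = None) -> "Spectrum":
        """Linearly interpolate onto ``axis``; exact at shared grid points."""
        axis = np.asarray(axis, dtype=float)
        y = np.interp(axis, self.shift, self.intensity)
        log = self.processing_log + ([log_entry] if log_entry else [])
        return Spectrum(self.sample_id, axis, y, log)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.sample_id, self.shift.copy(), self.intensity.copy(), list(self.processing_log)
        )


@dataclass
class LabeledCohort:
    """A set of spectra with binary pregnancy labels.

    After :func:`assemble_cohort`, all spectra share ``common_axis``.
    """

    spectra: list[Spectrum]
    labels: dict[str, str]
    common_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for s in self.spectra:
            if s.sample_id not in self.labels:
                raise AssemblyError(f"sample {s.sample_id!r} has no label")
        for sid, lab in self.labels.items():
            if lab not in VALID_LABELS:
                raise AssemblyError(f"sample {sid!r}: unknown label {lab!r}")
        if self.common_axis is not None:
            self.common_axis = np.asarray(self.common_axis, dtype=float)
            for s in self.spectra:
                if s.shift.size != self.common_axis.size or not np.allclose(
                    s.shift, self.common_axis
                ):
                    raise AssemblyError(f"sample {s.sample_id!r} not on the common axis")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    def label_array(self) -> np.ndarray:
        """Boolean vector in manifest order; True = pregnant (positive class)."""
        return np.array([self.labels[s.sample_id] == POSITIVE_LABEL for s in self.spectra])

    def intensity_matrix(self) -> np.ndarray:
        """(n_samples, n_channels) matrix; requires a common axis."""
        if self.common_axis is None:
            raise AssemblyError("cohort has no common axis; assemble/resample first")
        return np.vstack([s.intensity for s in self.spectra])

    def subset(self, indices) -> "LabeledCohort":
        spectra = [self.spectra[i] for i in indices]
        labels = {s.sample_id: self.labels[s.sample_id] for s in spectra}
        return LabeledCohort(spectra, labels, self.common_axis)


# ---------------------------------------------------------------------------
# spectrum files


def _infer_format(path: Path) -> str:
    return "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"


def read_spectrum(path, fmt: str | None = None, sample_id: str | None = None) -> Spectrum:
    """Read a spectrum from a two-column CSV or JCAMP-DX file.

    Parameters
    ----------
    path : path-like
    fmt : {"csv", "jcamp"}, optional
        Inferred from the suffix when omitted (``.jdx``/``.dx`` -> jcamp).
    sample_id : str, optional
        Defaults to the file stem (CSV) or ##TITLE (JCAMP).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spectrum file not found: {path}")
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path, sample_id)
    if fmt == "jcamp":
        return _read_jcamp(path, sample_id)
    raise FormatError(f"unknown spectrum format {fmt!r}")


def _read_csv(path: Path, sample_id: str | None) -> Spectrum:
    xs, ys = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1:
                # header line is required; tolerate any names but 2 columns
                if len(row) < 2:
                    raise FormatError(f"{path}:{lineno}: header must have 2 columns")
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                xs.append(float(row[0]))
                ys.append(float(row[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric row: {exc}") from exc
    if len(xs) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    return Spectrum.from_unsorted(sample_id or path.stem, np.array(xs), np.array(ys))


def write_spectrum(spectrum: Spectrum, path, fmt: str | None = None) -> None:
    """Write a spectrum as two-column CSV or JCAMP-DX (XY..XY)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for x, y in zip(spectrum.shift, spectrum.intensity):
                writer.writerow([f"{x:.12g}", f"{y:.12g}"])
    elif fmt == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise FormatError(f"unknown spectrum format {fmt!r}")


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    lines = [
        f"##TITLE={spectrum.sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##NPOINTS={spectrum.shift.size}",
        f"##FIRSTX={spectrum.shift[0]:.10g}",
        f"##LASTX={spectrum.shift[-1]:.10g}",
        "##XYDATA=(XY..XY)",
    ]
    for x, y in zip(spectrum.shift, spectrum.intensity):
        lines.append(f"{x:.10g}, {y:.10g}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_jcamp(path: Path, sample_id: str | None) -> Spectrum:
    title = None
    xfactor = yfactor = 1.0
    xs, ys = [], []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "TITLE":
                    title = value
                elif key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key in {"XYDATA", "XYPOINTS"}:
                    in_data = True
                elif key == "END":
                    in_data = False
                else:
                    in_data = False
                continue
            if in_data:
                tokens = [t for t in line.replace(",", " ").split() if t]
                if len(tokens) % 2:
                    raise FormatError(f"{path}:{lineno}: odd token count in XY data")
                try:
                    vals = [float(t) for t in tokens]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric XY data: {exc}") from exc
                xs.extend(vals[0::2])
                ys.extend(vals[1::2])
    if len(xs) < 2:
        raise FormatError(f"{path}: fewer than 2 data points in JCAMP XY data")
    x = np.array(xs) * xfactor
    y = np.array(ys) * yfactor
    return Spectrum.from_unsorted(sample_id or title or path.stem, x, y)


# ---------------------------------------------------------------------------
# manifests and cohort assembly


def read_manifest(manifest_path) -> list[dict]:
    """Read a cohort manifest CSV with columns sample_id, path, label."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise AssemblyError(f"manifest not found: {manifest_path}")
    rows = []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "path", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AssemblyError(
                f"{manifest_path}: manifest must have columns {sorted(required)}"
            )
        for row in reader:
            rows.append({k: (row[k] or "").strip() for k in required})
    if not rows:
        raise AssemblyError(f"{manifest_path}: empty manifest")
    return rows


def write_manifest(rows: list[dict], manifest_path) -> None:
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sample_id", "path", "label"])
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def common_grid(spectra: list[Spectrum], step: float = 1.0) -> np.ndarray:
    """Uniform grid over the intersection of all spectra's axis ranges."""
    lo = max(s.shift[0] for s in spectra)
    hi = min(s.shift[-1] for s in spectra)
    if hi <= lo:
        raise AssemblyError(f"empty intersection range: [{lo}, {hi}]")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if n < 2:
        raise AssemblyError(f"intersection range [{lo}, {hi}] shorter than one step")
    return lo + step * np.arange(n)


def assemble_cohort(manifest_path, step: float = 1.0) -> LabeledCohort:
    """Read every spectrum in a manifest and resample onto a common grid.

    Paths are resolved relative to the manifest's directory.  All spectra
    are linearly resampled onto a uniform grid (default 1 cm^-1 step) over
    the intersection of their axis ranges.
    """
    manifest_path = Path(manifest_path)
    rows = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra, labels = [], {}
    for row in rows:
        sid, rel, label = row["sample_id"], row["path"], row["label"]
        if label not in VALID_LABELS:
            raise AssemblyError(f"sample {sid!r}: unknown label {label!r}")
        spath = (base / rel) if not Path(rel).is_absolute() else Path(rel)
        if not spath.exists():
            raise AssemblyError(f"sample {sid!r}: spectrum file missing: {spath}")
        try:
            spectra.append(read_spectrum(spath, sample_id=sid))
        except FormatError as exc:
            raise AssemblyError(f"sample {sid!r}: {exc}") from exc
        labels[sid] = label
    axis = common_grid(spectra, step=step)
    resampled = [s.resample(axis, log_entry=f"resample:step={step}") for s in spectra]
    return LabeledCohort(resampled, labels, axis)
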