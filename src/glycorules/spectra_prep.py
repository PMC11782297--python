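"""Spectrum I/O, base-peak normalization, 0.5-Da binning, and feature building.

Preprocessing pipeline for MS2 peak lists: intensities are expressed as
fractions of the base peak (so a 1% relative-intensity threshold is 0.01),
peaks are summed into half-open m/z windows of 0.5 Da anchored at zero, and
the per-bin intensity-weighted mean m/z is retained so that bins used in
mined rules can later be mapped back to exact m/z values.  Features offered
to the tree learner are the normalized bins themselves plus pairwise ratios
between all bins whose mean normalized value on the training spectra is at
least ``ratio_min_mean`` (default 0.01); ratios of base-peak-relative
intensities are invariant to any uniform rescaling of a spectrum's raw
intensities, which is what makes them robust to systematic inter-run
intensity shifts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "AnnotatedSpectrum",
    "BinnedSpectrum",
    "FeatureSpec",
    "Peak",
    "Spectrum",
    "SpectrumReadError",
    "apply_feature_specs",
    "bin_spectrum",
    "build_feature_matrix",
    "evaluate_feature",
    "normalize",
    "read_spectra",
    "write_spectra_tsv",
]

DEFAULT_BIN_WIDTH = 0.5
RATIO_EPSILON = 1e-4  # denominator floor keeping ratio features finite


class SpectrumReadError(ValueError):
    """Raised for malformed spectrum files/records."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with provenance keys."""

    peaks: tuple[Peak, ...]
    precursor_mz: float
    dataset_id: str = ""
    filename: str = ""
    scan_id: str = ""

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("spectrum must contain at least one peak")
        if any(p.mz <= 0 for p in self.peaks):
            raise ValueError("peak m/z must be positive")
        if any(p.intensity < 0 for p in self.peaks):
            raise ValueError("peak intensities must be non-negative")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    @property
    def provenance_key(self) -> tuple[str, str]:
        return (self.dataset_id, self.filename)


@dataclass(frozen=True)
class AnnotatedSpectrum:
    spectrum: Spectrum
    label: str  # structure or composition string


@dataclass(frozen=True)
class BinnedSpectrum:
    """Sparse binned spectrum: value and mean exact m/z per nonzero bin."""

    bin_values: tuple[tuple[int, float], ...]
    bin_offsets: tuple[tuple[int, float], ...]
    width: float = DEFAULT_BIN_WIDTH

    def values(self) -> dict[int, float]:
        return dict(self.bin_values)

    def offsets(self) -> dict[int, float]:
        return dict(self.bin_offsets)


@dataclass(frozen=True)
class FeatureSpec:
    """One model feature: a bin intensity or a ratio of two bin intensities."""

    kind: str  # {"bin", "ratio"}
    numerator_bin: int
    denominator_bin: int | None = None
    display_mz: float | None = None
    display_denominator_mz: float | None = None

    def __post_init__(self):
        if self.kind not in ("bin", "ratio"):
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if self.kind == "ratio" and (
            self.denominator_bin is None
            or self.denominator_bin == self.numerator_bin
        ):
            raise ValueError("ratio features need two distinct bins")

    def describe(self) -> str:
        if self.kind == "bin":
            return f"intensity(m/z {self.display_mz:.1f})"
        return (
            f"ratio(m/z {self.display_mz:.1f} / m/z "
            f"{self.display_denominator_mz:.1f})"
        )


# ---------------------------------------------------------------------------
# Normalization and binning
# ---------------------------------------------------------------------------


def normalize(s: Spectrum) -> Spectrum:
    """Express intensities as fractions of the base peak (max becomes 1.0)."""
    top = max(p.intensity for p in s.peaks)
    if top <= 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return replace(
        s, peaks=tuple(Peak(p.mz, p.intensity / top) for p in s.peaks)
    )


def bin_spectrum(s: Spectrum, width: float = DEFAULT_BIN_WIDTH) -> BinnedSpectrum:
    """Sum intensities in half-open windows [k*width, (k+1)*width).

    Offsets are the intensity-weighted mean m/z of each bin's member peaks
    (falling back to the unweighted mean if all members have zero intensity),
    enabling reconstruction of exact fragment m/z from bin indices.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    sums: dict[int, float] = {}
    wmz: dict[int, float] = {}
    umz: dict[int, list[float]] = {}
    for p in sorted(s.peaks, key=lambda p: p.mz):
        k = int(math.floor(p.mz / width))
        sums[k] = sums.get(k, 0.0) + p.intensity
        wmz[k] = wmz.get(k, 0.0) + p.mz * p.intensity
        umz.setdefault(k, []).append(p.mz)
    offsets = {
        k: (wmz[k] / sums[k]) if sums[k] > 0 else sum(umz[k]) / len(umz[k])
        for k in sums
    }
    keys = sorted(sums)
    return BinnedSpectrum(
        bin_values=tuple((k, sums[k]) for k in keys),
        bin_offsets=tuple((k, offsets[k]) for k in keys),
        width=width,
    )


def preprocess(s: Spectrum, width: float = DEFAULT_BIN_WIDTH) -> BinnedSpectrum:
    """normalize + bin, the canonical per-spectrum preprocessing."""
    return bin_spectrum(normalize(s), width)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


def _display_mz(
    spectra: Sequence[BinnedSpectrum], bin_index: int, width: float
) -> tuple[float, bool]:
    """Training-set intensity-weighted mean m/z of a bin.

    Returns (display_mz, populated).  Unpopulated bins fall back to the bin
    center and are flagged.
    """
    num = den = 0.0
    for bs in spectra:
        vals = bs.values()
        if bin_index in vals and vals[bin_index] > 0:
            num += bs.offsets()[bin_index] * vals[bin_index]
            den += vals[bin_index]
    if den > 0:
        return num / den, True
    return (bin_index + 0.5) * width, False


def build_feature_matrix(
    spectra: Sequence[BinnedSpectrum],
    ratio_min_mean: float = 0.01,
    epsilon: float = RATIO_EPSILON,
) -> tuple[np.ndarray, list[FeatureSpec]]:
    """Build the (spectra x features) matrix and its feature specifications.

    Bin features cover every bin nonzero in at least one input spectrum.
    Ratio features cover every ordered pair (i, j), i != j, of bins whose
    mean value across the input spectra is >= ``ratio_min_mean``; the ratio
    value is value_i / max(value_j, epsilon).  The inputs should be the
    *training* spectra: eligibility and display m/z are both computed here
    and then applied unchanged to validation/test data via
    :func:`apply_feature_specs`.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    width = spectra[0].width
    totals: dict[int, float] = {}
    for bs in spectra:
        for k, v in bs.bin_values:
            totals[k] = totals.get(k, 0.0) + v
    bins = sorted(totals)
    n = len(spectra)
    means = {k: totals[k] / n for k in bins}
    eligible = [k for k in bins if means[k] >= ratio_min_mean]

    specs: list[FeatureSpec] = []
    display = {k: _display_mz(spectra, k, width)[0] for k in bins}
    for k in bins:
        specs.append(FeatureSpec("bin", k, display_mz=display[k]))
    for i in eligible:
        for j in eligible:
            if i != j:
                specs.append(
                    FeatureSpec(
                        "ratio",
                        i,
                        j,
                        display_mz=display[i],
                        display_denominator_mz=display[j],
                    )
                )
    return apply_feature_specs(spectra, specs, epsilon), specs


def apply_feature_specs(
    spectra: Sequence[BinnedSpectrum],
    specs: Sequence[FeatureSpec],
    epsilon: float = RATIO_EPSILON,
) -> np.ndarray:
    """Evaluate fixed feature specs on (possibly unseen) binned spectra."""
    X = np.zeros((len(spectra), len(specs)))
    for row, bs in enumerate(spectra):
        vals = bs.values()
        for col, spec in enumerate(specs):
            X[row, col] = _evaluate(spec, vals, epsilon)
    return X


def _evaluate(spec: FeatureSpec, vals: dict[int, float], epsilon: float) -> float:
    if spec.kind == "bin":
        return vals.get(spec.numerator_bin, 0.0)
    num = vals.get(spec.numerator_bin, 0.0)
    den = vals.get(spec.denominator_bin, 0.0)
    return num / max(den, epsilon)


def evaluate_feature(
    spec: FeatureSpec, binned: BinnedSpectrum, epsilon: float = RATIO_EPSILON
) -> float:
    """Value of one feature on one binned spectrum (used by rule matching)."""
    return _evaluate(spec, binned.values(), epsilon)


# ---------------------------------------------------------------------------
# Spectrum file I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["scan_id", "dataset_id", "filename", "precursor_mz", "peaks"]


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read centroided spectra from MGF, mzML, or the package TSV dialect.

    The format is inferred from the file suffix when not given.  Provenance
    fields default to the file name where the format's headers carry none.
    """
    path = Path(path)
    if format is None:
        format = {".mgf": "mgf", ".mzml": "mzml", ".tsv": "tsv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise SpectrumReadError(f"cannot infer format of {path.name!r}")
    if format == "mgf":
        return _read_mgf(path)
    if format == "mzml":
        return _read_mzml(path)
    if format == "tsv":
        return _read_tsv(path)
    raise SpectrumReadError(f"unknown format: {format!r}")


def _read_mgf(path: Path) -> list[Spectrum]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(str(path)) as reader:
        for idx, rec in enumerate(reader):
            params = rec.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                raise SpectrumReadError(
                    f"record {idx} in {path.name}: missing PEPMASS"
                )
            title = str(params.get("title", f"scan={idx}"))
            peaks = tuple(
                Peak(float(mz), float(it))
                for mz, it in zip(rec["m/z array"], rec["intensity array"])
            )
            if not peaks:
                raise SpectrumReadError(f"record {idx} in {path.name}: no peaks")
            out.append(
                Spectrum(
                    peaks=peaks,
                    precursor_mz=float(pepmass[0]),
                    dataset_id=str(params.get("dataset_id", path.stem)),
                    filename=path.name,
                    scan_id=title,
                )
            )
    return out


def _read_mzml(path: Path) -> list[Spectrum]:
    from pyteomics import mzml

    out = []
    with mzml.MzML(str(path)) as reader:
        for idx, rec in enumerate(reader):
            if rec.get("ms level") != 2:
                continue
            if "profile spectrum" in rec:
                raise SpectrumReadError(
                    f"record {idx} in {path.name} is profile mode; "
                    "centroid the data before import"
                )
            try:
                precursor = rec["precursorList"]["precursor"][0][
                    "selectedIonList"
                ]["selectedIon"][0]["selected ion m/z"]
            except (KeyError, IndexError) as exc:
                raise SpectrumReadError(
                    f"record {idx} in {path.name}: missing precursor"
                ) from exc
            peaks = tuple(
                Peak(float(mz), float(it))
                for mz, it in zip(rec["m/z array"], rec["intensity array"])
            )
            if not peaks:
                raise SpectrumReadError(f"record {idx} in {path.name}: no peaks")
            out.append(
                Spectrum(
                    peaks=peaks,
                    precursor_mz=float(precursor),
                    dataset_id=path.stem,
                    filename=path.name,
                    scan_id=str(rec.get("id", f"scan={idx}")),
                )
            )
    return out


def _read_tsv(path: Path) -> list[Spectrum]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SpectrumReadError(
                f"{path.name}: missing TSV columns {sorted(missing)}"
            )
        for idx, row in enumerate(reader):
            try:
                peaks = tuple(
                    Peak(float(pair.split(":")[0]), float(pair.split(":")[1]))
                    for pair in row["peaks"].split(";")
                    if pair
                )
                spectrum = Spectrum(
                    peaks=peaks,
                    precursor_mz=float(row["precursor_mz"]),
                    dataset_id=row["dataset_id"],
                    filename=row["filename"],
                    scan_id=row["scan_id"],
                )
            except (ValueError, IndexError) as exc:
                raise SpectrumReadError(
                    f"{path.name}: malformed record {idx}: {exc}"
                ) from exc
            out.append(spectrum)
    return out


def write_spectra_tsv(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the TSV dialect read back by :func:`read_spectra`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TSV_COLUMNS)
        for s in spectra:
            writer.writerow(
                [
                    s.scan_id,
                    s.dataset_id,
                    s.filename,
                    repr(float(s.precursor_mz)),
                    ";".join(
                        f"{float(p.mz)!r}:{float(p.intensity)!r}"
                        for p in s.peaks
                    ),
                ]
            )
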