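"""Synthetic MS2 corpora with planted diagnostic structure.

The generator emulates the statistical structure that the tree learner
exploits in real glycomics spectra: per-isomer characteristic fragments
with Bernoulli presence probabilities and log-normal intensities, backbone
fragments shared across a mass group, Poisson noise peaks at uniform m/z,
Gaussian m/z jitter, and a multi-experiment provenance structure in which
every provenance key (dataset, file) carries its own systematic intensity
scale factor — the inter-lab shift that base-peak normalization and ratio
features are designed to cancel.  It does not attempt to simulate CID
physics, isotope envelopes, or chemically consistent fragment ladders; it
is the controlled test bed for rule recovery, not a spectrum simulator.

Everything is a pure function of (config, seed): the same config yields a
byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .glycan_core import label_to_composition, precursor_mz
from .spectra_prep import AnnotatedSpectrum, Peak, Spectrum, write_spectra_tsv

__all__ = [
    "CorpusConfig",
    "IsomerProfile",
    "PlantedRatio",
    "fig1c_like_fixture",
    "generate_corpus",
    "three_topology_fixture",
    "write_corpus",
]


@dataclass(frozen=True)
class PlantedRatio:
    """A planted intensity ratio between two m/z positions.

    The denominator peak is drawn log-normally; the numerator intensity is
    denominator * ratio, with the ratio drawn log-normally around
    ``ratio_log_mean`` — except with probability ``contamination`` it is
    drawn around ``contamination_log_mean`` instead (spectra that look like
    the other class; annotation noise).  The numerator peak is present with
    probability ``presence``.
    """

    mz_num: float
    mz_den: float
    presence: float = 1.0
    ratio_log_mean: float = 0.0
    ratio_log_sd: float = 0.35
    contamination: float = 0.0
    contamination_log_mean: float = 0.0
    den_log_mean: float = np.log(0.2)
    den_log_sd: float = 0.4


@dataclass(frozen=True)
class IsomerProfile:
    """One isomer class of a mass group."""

    label: str  # structure string; parseable by glycan_core
    characteristic_peaks: tuple[tuple[float, float, float, float], ...] = ()
    # (mz, presence probability, intensity log-mean, log-sd)
    shared_peaks: tuple[tuple[float, float, float], ...] = ()
    # (mz, intensity log-mean, log-sd); always present
    planted_ratio: PlantedRatio | None = None

    def __post_init__(self):
        for _mz, p, *_rest in self.characteristic_peaks:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence probability {p} outside [0, 1]")
        if self.planted_ratio is not None:
            pr = self.planted_ratio
            if not (0 <= pr.presence <= 1 and 0 <= pr.contamination <= 1):
                raise ValueError("planted ratio probabilities outside [0, 1]")


@dataclass(frozen=True)
class CorpusConfig:
    profiles: tuple[IsomerProfile, ...]
    n_spectra: int = 500  # per profile
    n_provenance_keys: int = 10  # shared across profiles, round-robin
    noise_peak_rate: float = 5.0  # Poisson mean per spectrum
    noise_log_mean: float = np.log(0.02)
    noise_log_sd: float = 0.7
    noise_mz_range: tuple[float, float] = (100.0, 420.0)
    mz_jitter_sd: float = 0.05  # Da; keeps peaks inside their 0.5-Da bin
    key_scale_log_sd: float = 0.6  # per-key systematic intensity shift
    seed: int = 0

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("config needs at least one isomer profile")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.n_provenance_keys < 3:
            raise ValueError(
                "need >= 3 provenance keys per profile (split precondition)"
            )


def _provenance_keys(n: int) -> list[tuple[str, str]]:
    # a handful of synthetic GlycoPOST-style datasets, several files each
    return [
        (f"GPST{900000 + k // 3:06d}", f"run_{k:02d}.mzML") for k in range(n)
    ]


def generate_corpus(
    cfg: CorpusConfig, seed: int | None = None
) -> list[AnnotatedSpectrum]:
    """Generate the labeled corpus described by *cfg* (deterministic).

    ``seed`` overrides ``cfg.seed`` when given.  Provenance keys are
    assigned round-robin within each profile, so every key sees every
    class; each key applies a fixed log-normal intensity scale factor to
    all of its raw spectra.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    keys = _provenance_keys(cfg.n_provenance_keys)
    key_scale = np.exp(rng.normal(0.0, cfg.key_scale_log_sd, len(keys)))
    lo, hi = cfg.noise_mz_range
    out: list[AnnotatedSpectrum] = []
    for prof in cfg.profiles:
        prec = precursor_mz(label_to_composition(prof.label))
        for i in range(cfg.n_spectra):
            ki = i % len(keys)
            dataset_id, filename = keys[ki]
            peaks: list[Peak] = []
            for mz, log_mean, log_sd in prof.shared_peaks:
                peaks.append(Peak(mz, float(np.exp(rng.normal(log_mean, log_sd)))))
            for mz, p, log_mean, log_sd in prof.characteristic_peaks:
                if rng.random() < p:
                    peaks.append(
                        Peak(mz, float(np.exp(rng.normal(log_mean, log_sd))))
                    )
            if prof.planted_ratio is not None:
                pr = prof.planted_ratio
                den = float(np.exp(rng.normal(pr.den_log_mean, pr.den_log_sd)))
                contaminated = rng.random() < pr.contamination
                mu = pr.contamination_log_mean if contaminated else pr.ratio_log_mean
                ratio = float(np.exp(rng.normal(mu, pr.ratio_log_sd)))
                peaks.append(Peak(pr.mz_den, den))
                if rng.random() < pr.presence:
                    peaks.append(Peak(pr.mz_num, den * ratio))
            n_noise = int(rng.poisson(cfg.noise_peak_rate))
            for _ in range(n_noise):
                peaks.append(
                    Peak(
                        float(rng.uniform(lo, min(hi, prec + 1.0))),
                        float(np.exp(rng.normal(cfg.noise_log_mean, cfg.noise_log_sd))),
                    )
                )
            jitter = rng.normal(0.0, cfg.mz_jitter_sd, len(peaks))
            scale = key_scale[ki]
            peaks = [
                Peak(max(p.mz + dz, 1e-6), p.intensity * scale)
                for p, dz in zip(peaks, jitter)
            ]
            spectrum = Spectrum(
                peaks=tuple(peaks),
                precursor_mz=prec,
                dataset_id=dataset_id,
                filename=filename,
                scan_id=f"{prof.label}|{i}",
            )
            out.append(AnnotatedSpectrum(spectrum=spectrum, label=prof.label))
    return out


# ---------------------------------------------------------------------------
# Fixtures with known ground truth
# ---------------------------------------------------------------------------

#: Planted diagnostic-ratio geometry of the two-isomer HexNAc2 fixture:
#: numerator/denominator m/z, the presence probability of the numerator
#: peak in the high-ratio class, and the contamination rate of the
#: low-ratio class.  Exposed so tests can derive expected coverage and
#: confidence instead of hard-coding them.
FIG1C_MZ_NUM = 365.13
FIG1C_MZ_DEN = 317.10
FIG1C_PRESENCE = 0.9
FIG1C_CONTAMINATION = 0.05


def fig1c_like_fixture(
    n_spectra: int = 500, n_provenance_keys: int = 10, seed: int = 0
) -> CorpusConfig:
    """Two HexNAc2 isomers separable by one planted intensity ratio.

    Core 3 (GlcNAc-GalNAc) and core 5 (GalNAc-GalNAc) alditols at the same
    precursor (m/z 425.18), sharing backbone peaks; both carry peaks near
    m/z 365.1 and 317.1, with the 365/317 intensity ratio centered around
    0.4 for core 3 and 3.0 for core 5, well separated across a threshold of
    1.5.  The numerator peak is present with probability 0.9 in the core 5
    class; 5% of core 3 spectra are contaminated with core-5-like ratios
    (annotation noise), so a recovered ratio rule for core 5 has an
    expected coverage of ~0.9 and a confidence governed by the 0.9 * 0.05
    contamination flow from core 3.
    """
    shared = (
        (204.09, np.log(0.35), 0.8),
        (222.10, np.log(0.55), 0.8),
        (407.17, np.log(0.25), 0.8),
    )
    core3 = IsomerProfile(
        label="GlcNAc(b1-3)GalNAc",
        shared_peaks=shared,
        planted_ratio=PlantedRatio(
            mz_num=FIG1C_MZ_NUM,
            mz_den=FIG1C_MZ_DEN,
            presence=FIG1C_PRESENCE,
            ratio_log_mean=np.log(0.4),
            contamination=FIG1C_CONTAMINATION,
            contamination_log_mean=np.log(3.0),
        ),
    )
    core5 = IsomerProfile(
        label="GalNAc(a1-3)GalNAc",
        shared_peaks=shared,
        planted_ratio=PlantedRatio(
            mz_num=FIG1C_MZ_NUM,
            mz_den=FIG1C_MZ_DEN,
            presence=FIG1C_PRESENCE,
            ratio_log_mean=np.log(3.0),
            contamination=0.0,
        ),
    )
    return CorpusConfig(
        profiles=(core3, core5),
        n_spectra=n_spectra,
        n_provenance_keys=n_provenance_keys,
        seed=seed,
    )


def three_topology_fixture(
    n_spectra: int = 250, n_provenance_keys: int = 10, seed: int = 0
) -> CorpusConfig:
    """A Hex1HexNAc2dHex1-like group: 3 topologies x 2 linkage isomers.

    Each topology carries its own marker peak (present at p=0.97 in its
    spectra, absent elsewhere), and its own pair of low-abundance fragment
    peaks whose intensity ratio separates the topology's two linkage
    isomers.  Those pair peaks occur only within their topology, so their
    mean normalized intensity pooled over the whole mass group falls below
    the 1% ratio-eligibility floor, while within the topology it clears
    the floor: a model trained per topology sees the clean diagnostic
    ratio, whereas a single flat model must fall back on the noisier raw
    bins — the regime in which classifying topology first and isomers
    second genuinely helps.
    """
    shared = ((204.09, np.log(0.4), 0.8), (384.15, np.log(0.2), 0.8))
    markers = {  # topology -> marker m/z
        "lewis": 359.12,
        "core1": 425.17,
        "core2": 510.19,
    }
    # per-topology isomer-diagnostic ratio pair (numerator m/z, denominator
    # m/z); the denominator abundance is tuned so its group-wide mean is
    # ~1/3 of the within-topology mean (each topology is 1/3 of the group)
    pair_mz = {
        "lewis": (290.09, 247.10),
        "core1": (472.15, 318.13),
        "core2": (433.14, 262.11),
    }
    centers = (0.5, 2.0)  # ratio centers for the (low, high) isomer
    structures = {
        ("lewis", 0): "Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-3)GalNAc",
        ("lewis", 1): "Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-3)GalNAc",
        ("core1", 0): "Fuc(a1-2)[GlcNAc(b1-3)]Gal(b1-3)GalNAc",
        ("core1", 1): "Fuc(a1-2)[GlcNAc(b1-6)]Gal(b1-3)GalNAc",
        ("core2", 0): "Fuc(a1-2)Gal(b1-3)[GlcNAc(b1-6)]GalNAc",
        ("core2", 1): "Fuc(a1-2)Gal(b1-4)[GlcNAc(b1-6)]GalNAc",
    }
    profiles = []
    for topo, marker_mz in markers.items():
        num_mz, den_mz = pair_mz[topo]
        for iso in (0, 1):
            profiles.append(
                IsomerProfile(
                    label=structures[(topo, iso)],
                    shared_peaks=shared,
                    characteristic_peaks=((marker_mz, 0.97, np.log(0.3), 0.5),),
                    planted_ratio=PlantedRatio(
                        mz_num=num_mz,
                        mz_den=den_mz,
                        presence=1.0,
                        ratio_log_mean=np.log(centers[1] if iso else centers[0]),
                        ratio_log_sd=0.3,
                        den_log_mean=np.log(0.009),
                        den_log_sd=0.3,
                    ),
                )
            )
    return CorpusConfig(
        profiles=tuple(profiles),
        n_spectra=n_spectra,
        n_provenance_keys=n_provenance_keys,
        noise_peak_rate=3.0,
        noise_mz_range=(100.0, 730.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Corpus files
# ---------------------------------------------------------------------------


def write_corpus(
    corpus: Sequence[AnnotatedSpectrum], out_dir: str | Path, cfg: CorpusConfig | None = None
) -> dict[str, Path]:
    """Write spectra TSV + annotation TSV (+ ground-truth config JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra_path = out_dir / "spectra.tsv"
    annot_path = out_dir / "annotations.tsv"
    write_spectra_tsv([a.spectrum for a in corpus], spectra_path)
    with open(annot_path, "w") as fh:
        fh.write("scan_id\tlabel\n")
        for a in corpus:
            fh.write(f"{a.spectrum.scan_id}\t{a.label}\n")
    paths = {"spectra": spectra_path, "annotations": annot_path}
    if cfg is not None:
        config_path = out_dir / "ground_truth.json"
        with open(config_path, "w") as fh:
            json.dump(asdict(cfg), fh, indent=1, default=float)
        paths["config"] = config_path
    return paths
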