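"""Synthetic multi-class MALDI-like serum cohorts with planted signal.

The generator emulates the structure of a serum LMI screening study: one
target class and several non-target classes, each sample measured several
times (default six), roughly 10^3-10^4 detectable ions on m/z 50-2500, a
small number of *planted* class-discriminative ions, multiplicative
replicate noise and per-measurement mass-axis jitter.  Ground truth (which
ions carry signal and in which direction) is returned alongside the data so
every downstream stage can be tested for recovery and for the absence of
leakage.

Intensity model: each ion has a baseline log-intensity; each sample adds
ion-level biological variation; each replicate measurement multiplies by
log-normal noise with the configured coefficient of variation.  Planted
ions shift the target class's log-intensity by ``effect_size`` (signed per
ion).  Mass jitter perturbs every observed m/z by a centered Gaussian
relative error with the configured ppm standard deviation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_io import RawSpectrum, write_manifest, write_peaklist

__all__ = ["CohortConfig", "SyntheticTruth", "generate_cohort", "write_cohort"]

#: Nominal m/z range of detectable low-mass ions (Thomson).
MZ_RANGE = (50.0, 2500.0)

#: Minimum relative spacing between nominal ions; chosen at twice the
#: standard 300 ppm matching tolerance so alignment is unambiguous.
MIN_SPACING_PPM = 600.0


class CohortConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    ``effect_size`` is the mean log-intensity shift (natural log) of planted
    ions in the target class; ``noise_cv`` the coefficient of variation of
    multiplicative replicate noise (the cohort's only noise source by
    default); ``mass_jitter_ppm`` the SD of the per-measurement relative
    m/z error.  ``sample_log_sd`` (default 0) adds ion-level biological
    variation between samples on the log scale, for stress-testing the
    pipeline under within-class heterogeneity beyond measurement noise.
    """

    n_per_class: int = 30
    class_labels: tuple[str, ...] = ("OVC", "Control", "OtherCancer", "Benign")
    target_label: str = "OVC"
    n_ions: int = 2000
    n_planted: int = 3
    effect_size: float = 3.0
    noise_cv: float = 0.2
    sample_log_sd: float = 0.0
    mass_jitter_ppm: float = 50.0
    n_replicates: int = 6
    rng_seed: int = 0
    enforce_min_spacing: bool = True
    base_log_intensity: float = math.log(1000.0)
    base_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise CohortConfigError("n_per_class must be >= 1")
        if len(self.class_labels) < 2:
            raise CohortConfigError("class_labels must list >= 2 classes")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise CohortConfigError("class_labels must be unique")
        if self.target_label not in self.class_labels:
            raise CohortConfigError(
                f"target_label {self.target_label!r} not among class_labels"
            )
        if not 0 <= self.n_planted < self.n_ions:
            raise CohortConfigError("n_planted must satisfy 0 <= n_planted < n_ions")
        if self.effect_size < 0:
            raise CohortConfigError("effect_size must be >= 0")
        if self.noise_cv < 0:
            raise CohortConfigError("noise_cv must be >= 0")
        if self.mass_jitter_ppm < 0:
            raise CohortConfigError("mass_jitter_ppm must be >= 0")
        if self.n_replicates < 2:
            raise CohortConfigError("n_replicates must be >= 2")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: which nominal m/z carry class signal, and the sign."""

    planted_mz: tuple[float, ...]
    planted_direction: tuple[int, ...]
    planted_indices: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.planted_mz) != len(self.planted_direction):
            raise ValueError("planted_mz and planted_direction lengths differ")


def _draw_axis(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Nominal ion m/z: uniform on the mass range, optionally spaced apart."""
    lo, hi = MZ_RANGE
    if not config.enforce_min_spacing:
        return np.sort(rng.uniform(lo, hi, config.n_ions))
    accepted: list[float] = []
    # Rejection by greedy spacing on sorted draws; repeat until enough ions.
    while len(accepted) < config.n_ions:
        draws = np.sort(rng.uniform(lo, hi, max(4 * config.n_ions, 1000)))
        accepted = []
        last = -math.inf
        for mz in draws:
            if (mz - last) / mz * 1e6 > MIN_SPACING_PPM:
                accepted.append(float(mz))
                last = mz
    idx = np.sort(rng.choice(len(accepted), size=config.n_ions, replace=False))
    return np.asarray(accepted)[idx]


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[RawSpectrum], pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: spectra, manifest and planted-ion ground truth.

    Yields ``n_per_class x len(class_labels)`` samples, each with
    ``n_replicates`` measurements.  Identical configs (same seed) give
    byte-identical output: one root seed sequence is spawned once and every
    sample consumes its own deterministic child stream.
    """
    root = np.random.SeedSequence(config.rng_seed)
    axis_ss, plant_ss, samples_ss = root.spawn(3)
    rng = np.random.default_rng(axis_ss)
    axis = _draw_axis(rng, config)
    base_log = config.base_log_intensity + config.base_log_sd * rng.standard_normal(
        config.n_ions
    )
    prng = np.random.default_rng(plant_ss)
    planted_idx = np.sort(
        prng.choice(config.n_ions, size=config.n_planted, replace=False)
    )
    directions = np.where(prng.random(config.n_planted) < 0.5, -1, 1).astype(int)
    truth = SyntheticTruth(
        tuple(float(axis[i]) for i in planted_idx),
        tuple(int(d) for d in directions),
        tuple(int(i) for i in planted_idx),
    )

    shift = np.zeros(config.n_ions)
    shift[planted_idx] = directions * config.effect_size
    sigma_rep = math.sqrt(math.log1p(config.noise_cv**2))
    jitter_sd = config.mass_jitter_ppm * 1e-6

    n_samples = config.n_per_class * len(config.class_labels)
    child_seeds = samples_ss.spawn(n_samples)
    spectra: list[RawSpectrum] = []
    manifest_rows: list[dict] = []
    width = len(str(n_samples))
    k = 0
    for label in config.class_labels:
        is_target = label == config.target_label
        for i in range(config.n_per_class):
            sid = f"{label}_{i + 1:0{width}d}"
            srng = np.random.default_rng(child_seeds[k])
            k += 1
            log_level = base_log + config.sample_log_sd * srng.standard_normal(
                config.n_ions
            )
            if is_target:
                log_level = log_level + shift
            for rep in range(1, config.n_replicates + 1):
                noise = sigma_rep * srng.standard_normal(config.n_ions)
                intensity = np.exp(log_level + noise)
                mz = axis * (1.0 + jitter_sd * srng.standard_normal(config.n_ions))
                spectra.append(RawSpectrum.from_unsorted(sid, rep, mz, intensity))
                manifest_rows.append(
                    {
                        "sample_id": sid,
                        "label": label,
                        "replicate": rep,
                        "set": "none",
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    return spectra, manifest, truth


def write_cohort(
    spectra,
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    out_dir,
    dialect: str = "tsv",
) -> pd.DataFrame:
    """Write peak lists, manifest and ground truth to a directory.

    Returns the manifest augmented with each measurement's file path.
    """
    os.makedirs(out_dir, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "csv"
    manifest = manifest.copy()
    paths = []
    for s in spectra:
        fname = f"{s.sample_id}_r{s.replicate_index}.{ext}"
        write_peaklist(s, os.path.join(out_dir, fname), dialect)
        paths.append(fname)
    manifest["path"] = paths
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(
            {
                "planted_mz": list(truth.planted_mz),
                "planted_direction": list(truth.planted_direction),
                "planted_indices": list(truth.planted_indices),
            },
            fh,
            indent=1,
        )
    return manifest
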