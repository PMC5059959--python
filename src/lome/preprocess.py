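"""Spectrum preprocessing: ppm alignment, normalization, Pareto scaling.

The preprocessing chain mirrors how MALDI-TOF peak tables are prepared for
discriminant scoring:

1. align every measurement to the reference mass spectrum's m/z axis at a
   relative (ppm) mass tolerance;
2. realign an already-tabulated matrix to the reference axis (idempotent);
3. normalize each intensity column to a common total area;
4. Pareto-scale each ion row: ``(x - mean) / sqrt(sd)``;
5. multiply by per-ion weighting factors (the PCA-DA loading vector);
6. average the replicate measurements of each sample.

Scaling statistics (per-ion mean/sd and the normalization target area) are
fitted once on training columns and *frozen*; validation columns are
transformed with the frozen statistics so no information flows back from the
validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peak_io import PeakTable, RawSpectrum

__all__ = [
    "ScalingStats",
    "build_consensus_axis",
    "align_to_reference",
    "build_table",
    "realign",
    "normalize_total_area",
    "apply_normalization",
    "pareto_scale",
    "apply_pareto",
    "apply_weights",
    "average_replicates",
]

#: Default relative mass-matching window (ppm).
DEFAULT_TOLERANCE_PPM = 300.0


@dataclass(frozen=True)
class ScalingStats:
    """Frozen per-ion scaling statistics plus the normalization target area.

    ``mean``/``sd`` are per-ion statistics of the normalized training columns
    (sd is the sample, n-1, estimator); ``target_area`` is the mean training
    column sum used by total-area normalization.
    """

    mean: np.ndarray
    sd: np.ndarray
    target_area: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")
        if not self.target_area > 0:
            raise ValueError("target_area must be positive")


def _ppm_distance(peak_mz: np.ndarray, ref_mz: np.ndarray) -> np.ndarray:
    return np.abs(peak_mz - ref_mz) / ref_mz * 1e6


def build_consensus_axis(spectra, tolerance_ppm: float = DEFAULT_TOLERANCE_PPM) -> np.ndarray:
    """Build a reference m/z axis by pooling peaks from several measurements.

    All peaks are pooled and sorted; a new axis ion starts wherever the gap to
    the previous pooled peak exceeds the ppm tolerance, and each ion's m/z is
    the mean of its cluster members.  With well-separated ions (nominal
    spacing comfortably above the tolerance) this recovers one axis entry per
    true ion.
    """
    pooled = np.sort(np.concatenate([s.mz for s in spectra]))
    if pooled.size == 0:
        raise ValueError("cannot build an axis from empty spectra")
    gaps = np.diff(pooled) / pooled[:-1] * 1e6
    starts = np.concatenate(([0], np.flatnonzero(gaps > tolerance_ppm) + 1))
    ends = np.concatenate((starts[1:], [pooled.size]))
    return np.array([pooled[a:b].mean() for a, b in zip(starts, ends)])


def align_to_reference(
    spectrum: RawSpectrum,
    axis_mz: np.ndarray,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> np.ndarray:
    """Project one measurement onto the reference axis.

    Each sample peak is assigned to the nearest reference ion in ppm distance
    (``|mz_peak - mz_ref| / mz_ref``), provided that distance is within the
    tolerance (boundary inclusive); ties between two equidistant reference
    ions go to the lower m/z.  Peaks mapping to the same ion are summed;
    reference ions receiving no peak get intensity 0.
    """
    axis_mz = np.asarray(axis_mz, dtype=float)
    if axis_mz.size == 0:
        raise ValueError("reference axis is empty")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    out = np.zeros(axis_mz.size)
    if len(spectrum) == 0:
        return out
    right = np.searchsorted(axis_mz, spectrum.mz)
    left = np.clip(right - 1, 0, axis_mz.size - 1)
    right = np.clip(right, 0, axis_mz.size - 1)
    d_left = _ppm_distance(spectrum.mz, axis_mz[left])
    d_right = _ppm_distance(spectrum.mz, axis_mz[right])
    nearest = np.where(d_left <= d_right, left, right)  # tie -> lower m/z
    dist = np.minimum(d_left, d_right)
    ok = dist <= tolerance_ppm
    np.add.at(out, nearest[ok], spectrum.intensity[ok])
    return out


def build_table(
    spectra,
    axis_mz: np.ndarray,
    metadata: pd.DataFrame,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> PeakTable:
    """Align a list of measurements to a common axis, yielding a peak table.

    ``metadata`` must have one row per spectrum with the standard column
    fields (sample_id, label, set, replicate).
    """
    if len(metadata) != len(spectra):
        raise ValueError("metadata rows must match the number of spectra")
    matrix = np.column_stack(
        [align_to_reference(s, axis_mz, tolerance_ppm) for s in spectra]
    ) if spectra else np.empty((len(axis_mz), 0))
    return PeakTable(np.asarray(axis_mz, float), matrix, metadata.reset_index(drop=True))


def realign(
    table: PeakTable,
    axis_mz: np.ndarray,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> PeakTable:
    """Re-project a peak table onto the reference axis.

    Every row of the input is treated as a peak at the input axis m/z and
    assigned to the nearest reference ion within tolerance; rows colliding on
    one reference ion are summed, rows outside tolerance are dropped.  The
    result's axis equals ``axis_mz`` exactly, so the operation is idempotent.
    """
    if table.n_ions == 0:
        raise ValueError("cannot realign an empty table")
    axis_mz = np.asarray(axis_mz, dtype=float)
    carrier = RawSpectrum("axis", 1, table.axis_mz, np.zeros(table.n_ions))
    # Reuse the peak->ion assignment on the axis values, then scatter rows.
    right = np.searchsorted(axis_mz, carrier.mz)
    left = np.clip(right - 1, 0, axis_mz.size - 1)
    right = np.clip(right, 0, axis_mz.size - 1)
    d_left = _ppm_distance(carrier.mz, axis_mz[left])
    d_right = _ppm_distance(carrier.mz, axis_mz[right])
    nearest = np.where(d_left <= d_right, left, right)
    ok = np.minimum(d_left, d_right) <= tolerance_ppm
    matrix = np.zeros((axis_mz.size, table.n_columns))
    np.add.at(matrix, nearest[ok], table.intensities[ok])
    return PeakTable(axis_mz, matrix, table.columns.copy())


def normalize_total_area(table: PeakTable) -> tuple[PeakTable, float]:
    """Scale every column to the same total area (sum of intensities).

    The common target is the mean of the input column sums, so the average
    column is left unchanged.  Returns the normalized table and the target.
    """
    sums = table.intensities.sum(axis=0)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        sid = table.columns["sample_id"].iloc[bad[0]] if len(table.columns) else bad[0]
        raise ValueError(f"column {bad[0]} (sample {sid}) has non-positive total area")
    target = float(sums.mean())
    out = table.copy()
    out.intensities = table.intensities * (target / sums)
    return out, target


def apply_normalization(table: PeakTable, target_area: float) -> PeakTable:
    """Scale every column to a frozen target area."""
    sums = table.intensities.sum(axis=0)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        sid = table.columns["sample_id"].iloc[bad[0]] if len(table.columns) else bad[0]
        raise ValueError(f"column {bad[0]} (sample {sid}) has non-positive total area")
    out = table.copy()
    out.intensities = table.intensities * (target_area / sums)
    return out


def pareto_scale(table: PeakTable, target_area: float | None = None) -> tuple[PeakTable, ScalingStats]:
    """Fit Pareto scaling on a (normalized) table and transform it.

    Per ion ``i`` and column ``j``: ``out_ij = (x_ij - mean_i) / sqrt(sd_i)``
    with the sample (n-1) standard deviation.  Ions with zero sd map to 0 in
    every column.  ``target_area`` is stored in the returned frozen stats
    (defaults to the table's mean column sum) so the full transform can be
    replayed on held-out columns.
    """
    if table.n_columns < 2:
        raise ValueError("Pareto scaling requires at least 2 columns to fit")
    mean = table.intensities.mean(axis=1)
    sd = table.intensities.std(axis=1, ddof=1)
    if target_area is None:
        computed = float(table.intensities.sum(axis=0).mean())
        # fitting on not-yet-normalized (possibly signed) data: keep a
        # neutral replay target rather than a meaningless one
        target_area = computed if computed > 0 else 1.0
    stats = ScalingStats(mean, sd, target_area)
    return apply_pareto(table, stats), stats


def apply_pareto(table: PeakTable, stats: ScalingStats) -> PeakTable:
    """Transform a table with frozen Pareto statistics."""
    if stats.mean.size != table.n_ions:
        raise ValueError(
            f"stats cover {stats.mean.size} ions but table has {table.n_ions}"
        )
    denom = np.sqrt(stats.sd)
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (table.intensities - stats.mean[:, None]) / denom[:, None]
    scaled[stats.sd == 0] = 0.0
    out.intensities = scaled
    return out


def apply_weights(table: PeakTable, weights: np.ndarray) -> PeakTable:
    """Multiply each ion row by its weighting factor."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != table.n_ions:
        raise ValueError(
            f"{weights.size} weights for {table.n_ions} ions"
        )
    out = table.copy()
    out.intensities = table.intensities * weights[:, None]
    return out


def average_replicates(table: PeakTable) -> PeakTable:
    """Collapse replicate measurement columns to one column per sample.

    Each output cell is the arithmetic mean over that sample's replicate
    columns; metadata collapses to (sample_id, label, set) with replicate 0.
    Sample order follows first appearance in the input.
    """
    if table.n_columns == 0:
        raise ValueError("cannot average an empty table")
    sids = table.columns["sample_id"].tolist()
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, sid in enumerate(sids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(j)
    matrix = np.column_stack(
        [table.intensities[:, groups[sid]].mean(axis=1) for sid in order]
    )
    meta_rows = []
    for sid in order:
        first = table.columns.iloc[groups[sid][0]]
        meta_rows.append(
            {
                "sample_id": sid,
                "label": first["label"],
                "set": first["set"],
                "replicate": 0,
            }
        )
    return PeakTable(table.axis_mz.copy(), matrix, pd.DataFrame(meta_rows))
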