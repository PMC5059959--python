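"""LOME model assembly: two-stage training, scoring, and evaluation.

A LOME (low-mass-ion discriminant equation) is a signed linear score over a
small panel of discriminative ions:

    DS(sample) = sum over panel ions of (Pareto-scaled intensity x weight)

with screen-positive declared when DS exceeds the decision threshold
(default 0, the sign rule).  Training follows a two-stage scheme: samples
are trisected into Sets A1, A2 and B; the reference measurement and the
per-ion weighting factors come from Set A1 alone; the discriminative panel
is searched on Set A = A1 u A2; Set B is touched only at evaluation time.
All scaling statistics are fitted on Set A and frozen before they ever see
a Set B column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pcada, preprocess, search
from .metrics import ClassMetrics, evaluate
from .peak_io import PeakTable, RawSpectrum, apply_import_filters
from .preprocess import ScalingStats

__all__ = [
    "RunConfig",
    "LOMEModel",
    "trisect",
    "mean_ds",
    "classify",
    "train_threshold",
    "build_lome",
    "augment_model",
    "score_spectra",
    "save_model",
    "load_model",
    "model_hash",
]

SETS = ("A1", "A2", "B")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the defaults are the standard import/search values.

    ``tolerance_ppm``, ``min_response``, ``max_peaks`` control spectrum
    import and alignment; ``magnitude_threshold`` and ``column_fraction``
    are the preliminary-candidate criteria; ``variance_rule`` picks the
    number of PCA components; ``threshold_mode`` is ``sign`` (decision at
    DS 0) or ``trained`` (cut-point optimized on Set A).
    """

    target_label: str = "OVC"
    tolerance_ppm: float = 300.0
    min_response: float = 10.0
    max_peaks: int = 10000
    magnitude_threshold: float = 0.1
    column_fraction: float = 0.5
    variance_rule: float = 0.95
    max_components: int | None = None
    candidate_cap: int = search.DEFAULT_CANDIDATE_CAP
    threshold_mode: str = "sign"
    include_reference_replicate: bool = False
    refit_scaling_on_validation: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("sign", "trained"):
            raise ValueError("threshold_mode must be 'sign' or 'trained'")
        for name in ("tolerance_ppm", "min_response", "max_peaks", "column_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LOMEModel:
    """A trained low-mass-ion discriminant equation.

    Carries the reference m/z axis, the full loading vector (per-ion
    weighting factors), the discriminative panel (indices into the axis),
    frozen scaling statistics, and the decision threshold.
    """

    axis_mz: np.ndarray
    loading: np.ndarray
    panel_indices: tuple[int, ...]
    stats: ScalingStats
    threshold: float = 0.0
    target_label: str = "OVC"
    reference_replicate: int = 1
    tolerance_ppm: float = 300.0
    config_hash: str = ""
    excluded_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.axis_mz = np.asarray(self.axis_mz, float)
        self.loading = np.asarray(self.loading, float)
        if self.loading.size != self.axis_mz.size:
            raise ValueError("loading vector length must match the axis")
        if self.panel_indices and max(self.panel_indices) >= self.axis_mz.size:
            raise ValueError("panel index outside the reference axis")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def panel_mz(self) -> tuple[float, ...]:
        return tuple(float(self.axis_mz[i]) for i in self.panel_indices)

    @property
    def panel_weights(self) -> np.ndarray:
        return self.loading[list(self.panel_indices)]


# ---------------------------------------------------------------------------
# Set assignment


def trisect(
    manifest: pd.DataFrame,
    strata: tuple[str, ...] = ("label",),
    rng_seed: int = 0,
    validation_only: tuple[str, ...] = (),
) -> pd.Series:
    """Assign each sample to Set A1, A2 or B, stratified and almost even.

    Within every stratum (e.g. class x clinical stage) the three set sizes
    differ by at most one; which sets receive the remainder is decided by
    the seeded RNG.  Labels in ``validation_only`` (groups kept out of
    training entirely) go straight to Set B.  Returns a Series of set labels
    indexed by sample_id.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    per_sample = manifest.drop_duplicates("sample_id").set_index("sample_id")
    rng = np.random.default_rng(rng_seed)
    assignment: dict[str, str] = {}
    strata_cols = [c for c in strata if c in per_sample.columns]
    keyed = (
        per_sample[strata_cols].astype(str).agg("|".join, axis=1)
        if strata_cols
        else pd.Series("all", index=per_sample.index)
    )
    for stratum in sorted(keyed.unique()):
        ids = sorted(keyed.index[keyed == stratum])
        labels = per_sample.loc[ids, "label"] if "label" in per_sample else None
        if labels is not None and len(ids) and labels.iloc[0] in validation_only:
            for sid in ids:
                assignment[sid] = "B"
            continue
        ids = list(rng.permutation(ids))
        base, rem = divmod(len(ids), 3)
        set_order = list(rng.permutation(list(SETS)))
        sizes = {s: base for s in SETS}
        for s in set_order[:rem]:
            sizes[s] += 1
        pos = 0
        for s in SETS:
            for sid in ids[pos : pos + sizes[s]]:
                assignment[sid] = s
            pos += sizes[s]
    return pd.Series(assignment, name="set")


# ---------------------------------------------------------------------------
# Scoring primitives


def mean_ds(averaged_intensities: np.ndarray, model: LOMEModel) -> float:
    """Mean discriminant score of one sample from its averaged weighted column."""
    averaged_intensities = np.asarray(averaged_intensities, float)
    if averaged_intensities.size != model.axis_mz.size:
        raise ValueError(
            f"sample vector has {averaged_intensities.size} ions; model axis "
            f"has {model.axis_mz.size}"
        )
    return float(averaged_intensities[list(model.panel_indices)].sum())


def classify(ds: float, threshold: float = 0.0) -> bool:
    """Screen decision: positive iff DS strictly exceeds the threshold."""
    return bool(ds > threshold)


def train_threshold(ds_values, is_target) -> float:
    """Optimal DS cut-point on a training set.

    Candidate thresholds are the midpoints of consecutive sorted DS values;
    the one maximizing sensitivity + specificity wins, with ties resolved
    toward maximal specificity and then the smaller threshold.
    """
    ds_values = np.asarray(ds_values, float)
    is_target = np.asarray(is_target, bool)
    if is_target.all() or not is_target.any():
        raise ValueError("training a threshold requires both classes")
    order = np.argsort(ds_values, kind="stable")
    sorted_ds = ds_values[order]
    mids = (sorted_ds[:-1] + sorted_ds[1:]) / 2.0
    mids = np.unique(mids)
    best: tuple[float, float, float] | None = None  # (sum_ss, spec, -t)
    best_t = float(mids[0]) if mids.size else float(sorted_ds[0])
    n1, n0 = is_target.sum(), (~is_target).sum()
    for t in mids:
        pos = ds_values > t
        sens = np.sum(pos & is_target) / n1
        spec = np.sum(~pos & ~is_target) / n0
        key = (sens + spec, spec, -t)
        if best is None or key > best:
            best, best_t = key, float(t)
    return best_t


# ---------------------------------------------------------------------------
# The two-stage pipeline


def _spectra_frame(spectra, manifest: pd.DataFrame) -> pd.DataFrame:
    by_key = {(s.sample_id, s.replicate_index): s for s in spectra}
    rows = []
    for _, row in manifest.iterrows():
        key = (row["sample_id"], int(row["replicate"]))
        if key not in by_key:
            raise ValueError(f"no spectrum for sample {key[0]} replicate {key[1]}")
        rows.append(
            {
                "sample_id": row["sample_id"],
                "label": row["label"],
                "set": row.get("set", "none"),
                "replicate": int(row["replicate"]),
                "spectrum": by_key[key],
            }
        )
    return pd.DataFrame(rows)


def _reference_stage(frame: pd.DataFrame, config: RunConfig):
    """Per-replicate PCA-DA on Set A1; returns the chosen reference pieces."""
    a1 = frame[frame["set"] == "A1"]
    if a1.empty:
        raise ValueError("reference selection: no Set A1 samples in the manifest")
    sample_order = sorted(a1["sample_id"].unique())
    replicate_indices = sorted(a1["replicate"].unique())
    if len(replicate_indices) < 2:
        raise ValueError("reference selection: need >= 2 replicate measurements")
    tables: dict[int, PeakTable] = {}
    stats_by_rep: dict[int, ScalingStats] = {}
    is_target_by_rep: dict[int, np.ndarray] = {}
    for r in replicate_indices:
        sub = a1[a1["replicate"] == r].set_index("sample_id").loc[sample_order]
        spectra = list(sub["spectrum"])
        axis = preprocess.build_consensus_axis(spectra, config.tolerance_ppm)
        meta = pd.DataFrame(
            {
                "sample_id": sample_order,
                "label": sub["label"].tolist(),
                "set": "A1",
                "replicate": r,
            }
        )
        table = preprocess.build_table(spectra, axis, meta, config.tolerance_ppm)
        table, target_area = preprocess.normalize_total_area(table)
        table, stats = preprocess.pareto_scale(table, target_area)
        tables[r] = table
        stats_by_rep[r] = stats
        is_target_by_rep[r] = (meta["label"] == config.target_label).to_numpy()
    ref_rep, ref_score, all_scores = pcada.select_reference_measurement(
        tables, is_target_by_rep, config.variance_rule, config.max_components
    )
    return ref_rep, ref_score, all_scores, tables[ref_rep], is_target_by_rep[ref_rep]


def build_lome(spectra, manifest: pd.DataFrame, config: RunConfig = RunConfig()):
    """Train a LOME end to end; returns ``(model, report)``.

    ``spectra`` is a list of :class:`RawSpectrum` (all replicates of all
    samples); ``manifest`` must carry sample_id, label, replicate and a set
    assignment (A1/A2/B).  Stages: import filters -> reference-measurement
    selection and PCA-DA loading on Set A1 -> alignment of every measurement
    to the reference axis -> frozen normalization/Pareto fitted on Set A ->
    weighting -> replicate averaging -> preliminary candidates (search 1 on
    the weighted reference table) -> discriminative panel (search 2 on the
    averaged Set A table) -> decision threshold -> per-set evaluation.
    """
    required = {"sample_id", "label", "replicate", "set"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if not (manifest["set"].isin(SETS)).all():
        raise ValueError("every manifest row needs a set assignment A1/A2/B")
    filtered = [
        apply_import_filters(s, config.min_response, config.max_peaks) for s in spectra
    ]
    frame = _spectra_frame(filtered, manifest)

    trained_labels = set(frame.loc[frame["set"].isin(("A1", "A2")), "label"])
    excluded_groups = tuple(
        sorted(set(frame["label"]) - trained_labels)
    )

    # Stage 1: reference measurement + loading vector (Set A1 only).
    ref_rep, ref_score, all_scores, ref_table, ref_is_target = _reference_stage(
        frame, config
    )
    loading, _ = pcada.fit_pcada(
        ref_table, ref_is_target, config.variance_rule, config.max_components
    )
    axis = ref_table.axis_mz

    # Stage 2: preliminary candidates on the weighted reference table.
    weighted_ref = preprocess.apply_weights(ref_table, loading.weights)
    candidates = search.search1(
        weighted_ref, config.magnitude_threshold, config.column_fraction
    )
    if len(candidates) == 0:
        raise ValueError("search algorithm 1 selected no preliminary candidates")

    # Stage 3: align every downstream measurement to the reference axis.
    work = frame if config.include_reference_replicate else frame[
        frame["replicate"] != ref_rep
    ]
    meta = work[["sample_id", "label", "set", "replicate"]].reset_index(drop=True)
    table = preprocess.build_table(
        list(work["spectrum"]), axis, meta, config.tolerance_ppm
    )
    a_mask = meta["set"].isin(("A1", "A2")).to_numpy()
    a_sums = table.intensities[:, a_mask].sum(axis=0)
    if np.any(a_sums <= 0):
        raise ValueError("a training column has non-positive total area")
    target_area = float(a_sums.mean())
    table = preprocess.apply_normalization(table, target_area)
    if config.refit_scaling_on_validation:
        table, stats = preprocess.pareto_scale(table, target_area)
    else:
        a_table = table.select(a_mask)
        mean = a_table.intensities.mean(axis=1)
        sd = a_table.intensities.std(axis=1, ddof=1)
        stats = ScalingStats(mean, sd, target_area)
        table = preprocess.apply_pareto(table, stats)
    table = preprocess.apply_weights(table, loading.weights)
    averaged = preprocess.average_replicates(table)

    # Stage 4: discriminative panel on averaged Set A.
    avg_a = averaged.select(averaged.columns["set"].isin(("A1", "A2")).to_numpy())
    avg_a_target = (avg_a.columns["label"] == config.target_label).to_numpy()
    panel, trace = search.search2(
        candidates, avg_a, avg_a_target, 0.0, config.candidate_cap
    )

    # Stage 5: decision threshold.
    ds_a = panel_ds(avg_a, panel.indices)
    threshold = (
        train_threshold(ds_a, avg_a_target)
        if config.threshold_mode == "trained"
        else 0.0
    )

    model = LOMEModel(
        axis_mz=axis,
        loading=loading.weights,
        panel_indices=panel.indices,
        stats=stats,
        threshold=threshold,
        target_label=config.target_label,
        reference_replicate=ref_rep,
        tolerance_ppm=config.tolerance_ppm,
        config_hash=config.hash(),
        excluded_groups=excluded_groups,
    )
    report = _build_report(model, averaged, candidates, panel, trace, ref_rep, all_scores)
    return model, report


def panel_ds(averaged: PeakTable, panel_indices) -> np.ndarray:
    """Per-sample DS: sum of the panel rows of an averaged weighted table."""
    return averaged.intensities[list(panel_indices)].sum(axis=0)


def _build_report(model, averaged, candidates, panel, trace, ref_rep, rep_scores):
    report = {
        "reference_replicate": ref_rep,
        "replicate_scores": [dataclasses.asdict(s) for s in rep_scores],
        "n_candidates": len(candidates),
        "candidate_mz": list(candidates.mz),
        "panel_mz": list(panel.mz),
        "panel_size": len(panel),
        "threshold": model.threshold,
        "excluded_groups": list(model.excluded_groups),
        "search_trace": trace.records,
        "sets": {},
    }
    for set_name in SETS:
        mask = (averaged.columns["set"] == set_name).to_numpy()
        if not mask.any():
            continue
        sub = averaged.select(mask)
        report["sets"][set_name] = evaluate_set(model, sub)
    return report


def evaluate_set(model: LOMEModel, averaged: PeakTable) -> dict:
    """Per-set metrics; excluded groups contribute only per-group specificity."""
    ds = panel_ds(averaged, model.panel_indices)
    preds = ds > model.threshold
    labels = averaged.columns["label"].to_numpy()
    is_target = labels == model.target_label
    core = ~np.isin(labels, list(model.excluded_groups))
    cm, _ = evaluate(preds[core], is_target[core])
    _, per_group = evaluate(
        preds, is_target, labels, excluded_groups=model.excluded_groups
    )
    out = cm.reported()
    out["per_group_specificity"] = {
        g: (None if v is None else round(v, 2)) for g, v in per_group.items()
    }
    out["n_samples"] = int(len(labels))
    return out


def augment_model(
    model: LOMEModel,
    extra_mz,
    averaged_training: PeakTable,
    is_target,
) -> LOMEModel:
    """Add extra ions (by m/z) to the panel and re-train the threshold.

    Each extra m/z must match a reference-axis ion within the model's ppm
    tolerance (nearest ion wins); weights come from the stored loading
    vector.  The decision threshold is re-trained on the supplied averaged
    training table (Set A).
    """
    indices = set(model.panel_indices)
    for mz in extra_mz:
        j = int(np.argmin(np.abs(model.axis_mz - mz)))
        ppm = abs(model.axis_mz[j] - mz) / model.axis_mz[j] * 1e6
        if ppm > model.tolerance_ppm:
            raise ValueError(
                f"m/z {mz} is {ppm:.0f} ppm from the nearest axis ion; "
                f"outside the {model.tolerance_ppm:.0f} ppm tolerance"
            )
        indices.add(j)
    new_panel = tuple(sorted(indices))
    ds = panel_ds(averaged_training, new_panel)
    threshold = train_threshold(ds, np.asarray(is_target, bool))
    return dataclasses.replace(model, panel_indices=new_panel, threshold=threshold)


def score_spectra(model: LOMEModel, spectra, manifest: pd.DataFrame, config: RunConfig | None = None):
    """Score new samples with a frozen model.

    Applies the import filters, aligns to the model axis, replays the frozen
    normalization/Pareto statistics and loading weights, averages replicates
    and returns a DataFrame (sample_id, ds, decision).
    """
    cfg = config or RunConfig(target_label=model.target_label, tolerance_ppm=model.tolerance_ppm)
    filtered = [apply_import_filters(s, cfg.min_response, cfg.max_peaks) for s in spectra]
    frame = _spectra_frame(filtered, manifest)
    if frame.empty:
        return pd.DataFrame(columns=["sample_id", "ds", "decision"])
    work = frame if cfg.include_reference_replicate else frame[
        frame["replicate"] != model.reference_replicate
    ]
    if work.empty:
        return pd.DataFrame(columns=["sample_id", "ds", "decision"])
    meta = work[["sample_id", "label", "set", "replicate"]].reset_index(drop=True)
    table = preprocess.build_table(
        list(work["spectrum"]), model.axis_mz, meta, model.tolerance_ppm
    )
    table = preprocess.apply_normalization(table, model.stats.target_area)
    table = preprocess.apply_pareto(table, model.stats)
    table = preprocess.apply_weights(table, model.loading)
    averaged = preprocess.average_replicates(table)
    ds = panel_ds(averaged, model.panel_indices)
    return pd.DataFrame(
        {
            "sample_id": averaged.columns["sample_id"],
            "ds": ds,
            "decision": np.where(ds > model.threshold, "positive", "negative"),
        }
    )


# ---------------------------------------------------------------------------
# Bundle serialization


def save_model(model: LOMEModel, path, report: dict | None = None) -> None:
    """Write a model bundle directory (loading/panel CSVs + JSON sidecars)."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "loading.csv"), "w") as fh:
        fh.write("mz,weight\n")
        for m, w in zip(model.axis_mz, model.loading):
            fh.write(f"{float(m)!r},{float(w)!r}\n")
    with open(os.path.join(path, "panel.csv"), "w") as fh:
        fh.write("mz,weight\n")
        for i in model.panel_indices:
            fh.write(f"{float(model.axis_mz[i])!r},{float(model.loading[i])!r}\n")
    scaling = {
        "mean": [repr(float(v)) for v in model.stats.mean],
        "sd": [repr(float(v)) for v in model.stats.sd],
        "target_area": repr(float(model.stats.target_area)),
    }
    with open(os.path.join(path, "scaling.json"), "w") as fh:
        json.dump(scaling, fh)
    meta = {
        "panel_indices": list(model.panel_indices),
        "threshold": repr(float(model.threshold)),
        "target_label": model.target_label,
        "reference_replicate": int(model.reference_replicate),
        "tolerance_ppm": float(model.tolerance_ppm),
        "config_hash": model.config_hash,
        "excluded_groups": list(model.excluded_groups),
    }
    with open(os.path.join(path, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    if report is not None:
        with open(os.path.join(path, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_model(path) -> LOMEModel:
    """Read a bundle written by :func:`save_model`."""
    loading = pd.read_csv(
        os.path.join(path, "loading.csv"), float_precision="round_trip"
    )
    with open(os.path.join(path, "scaling.json")) as fh:
        scaling = json.load(fh)
    with open(os.path.join(path, "model.json")) as fh:
        meta = json.load(fh)
    stats = ScalingStats(
        [float(v) for v in scaling["mean"]],
        [float(v) for v in scaling["sd"]],
        float(scaling["target_area"]),
    )
    return LOMEModel(
        axis_mz=loading["mz"].to_numpy(),
        loading=loading["weight"].to_numpy(),
        panel_indices=tuple(int(i) for i in meta["panel_indices"]),
        stats=stats,
        threshold=float(meta["threshold"]),
        target_label=meta["target_label"],
        reference_replicate=int(meta["reference_replicate"]),
        tolerance_ppm=float(meta["tolerance_ppm"]),
        config_hash=meta.get("config_hash", ""),
        excluded_groups=tuple(meta.get("excluded_groups", ())),
    )


def model_hash(model: LOMEModel) -> str:
    """Content hash of a model (axis, loading, panel, stats, threshold)."""
    h = hashlib.sha256()
    for arr in (model.axis_mz, model.loading, model.stats.mean, model.stats.sd):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    h.update(repr(model.panel_indices).encode())
    h.update(repr(float(model.threshold)).encode())
    h.update(repr(float(model.stats.target_area)).encode())
    h.update(repr(int(model.reference_replicate)).encode())
    return h.hexdigest()
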