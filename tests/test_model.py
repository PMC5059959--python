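"""Trisection, thresholds, scoring, model bundles and the two-stage build."""

import numpy as np
import pandas as pd
import pytest

from lome.model import (
    LOMEModel,
    RunConfig,
    augment_model,
    build_lome,
    classify,
    load_model,
    mean_ds,
    model_hash,
    panel_ds,
    save_model,
    score_spectra,
    train_threshold,
    trisect,
)
from lome.preprocess import ScalingStats

from conftest import make_table


def _sample_manifest(counts: dict, stages: dict | None = None) -> pd.DataFrame:
    rows = []
    for label, n in counts.items():
        for i in range(n):
            stage = stages[label][i % len(stages[label])] if stages else "I"
            rows.append(
                {"sample_id": f"{label}{i}", "label": label, "replicate": 1,
                 "stage": stage}
            )
    return pd.DataFrame(rows)


class TestTrisect:
    def test_nine_split_evenly(self):
        manifest = _sample_manifest({"x": 9})
        sizes = trisect(manifest, ("label",), 0).value_counts()
        assert sorted(sizes) == [3, 3, 3]

    def test_seven_split_almost_evenly(self):
        manifest = _sample_manifest({"x": 7})
        sizes = trisect(manifest, ("label",), 0).value_counts()
        assert sorted(sizes) == [2, 2, 3]

    def test_control_cohort_of_276_trisects_to_92(self):
        manifest = _sample_manifest({"Control": 276})
        sizes = trisect(manifest, ("label",), 5).value_counts()
        assert sizes.tolist() == [92, 92, 92]

    def test_stratified_by_stage_within_class(self):
        manifest = _sample_manifest(
            {"OVC": 12}, stages={"OVC": ["I", "II", "III"]}
        )
        assignment = trisect(manifest, ("label", "stage"), 1)
        merged = manifest.assign(set=manifest["sample_id"].map(assignment))
        for _, grp in merged.groupby("stage"):
            sizes = grp["set"].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic_under_seed(self):
        manifest = _sample_manifest({"a": 10, "b": 7})
        a = trisect(manifest, ("label",), 42)
        b = trisect(manifest, ("label",), 42)
        assert a.equals(b)

    def test_validation_only_groups_go_to_b(self):
        manifest = _sample_manifest({"a": 6, "ucc": 5})
        assignment = trisect(manifest, ("label",), 0, validation_only=("ucc",))
        ucc = assignment[[s.startswith("ucc") for s in assignment.index]]
        assert (ucc == "B").all()

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            trisect(pd.DataFrame(columns=["sample_id", "label"]), ("label",), 0)


class TestThresholdAndClassify:
    def test_separable_groups_midpoint_zero(self):
        ds = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([False, False, True, True])
        assert train_threshold(ds, labels) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_cut_point_scan(self, seed):
        rng = np.random.default_rng(seed)
        ds = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        t = train_threshold(ds, labels)
        def sum_ss(th):
            pos = ds > th
            return pos[labels].mean() + (~pos[~labels]).mean()
        best = max(sum_ss(th) for th in np.unique(ds) - 1e-9)
        assert sum_ss(t) == pytest.approx(best)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(7)
        ds = rng.normal(0, 1, 20)
        labels = np.zeros(20, bool)
        labels[:8] = True
        ds[labels] += 3.0  # unique optimum
        t = train_threshold(ds, labels)
        t_flip = train_threshold(-ds, ~labels)
        assert t_flip == pytest.approx(-t)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_threshold([1.0, 2.0], [True, True])

    def test_classify_boundary(self):
        assert classify(0.01, 0.0) is True
        assert classify(-0.01, 0.0) is False
        assert classify(0.0, 0.0) is False  # exact zero screens negative


def _toy_model(n_ions=6, panel=(0, 1)):
    axis = 100.0 + 10.0 * np.arange(n_ions)
    loading = np.linspace(1.0, 2.0, n_ions)
    stats = ScalingStats(np.zeros(n_ions), np.ones(n_ions), 1.0)
    return LOMEModel(axis, loading, tuple(panel), stats)


class TestMeanDs:
    def test_zero_panel_intensities(self):
        model = _toy_model()
        assert mean_ds(np.zeros(6), model) == 0.0

    def test_two_ion_sum(self):
        model = _toy_model(panel=(0, 2))
        v = np.zeros(6)
        v[0], v[2] = 0.5, 1.0
        assert mean_ds(v, model) == 1.5

    def test_linearity_and_partition_additivity(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=6)
        model = _toy_model(panel=(0, 2, 4))
        assert mean_ds(3.0 * v, model) == pytest.approx(3.0 * mean_ds(v, model))
        parts = [_toy_model(panel=(0,)), _toy_model(panel=(2, 4))]
        assert mean_ds(v, model) == pytest.approx(
            sum(mean_ds(v, p) for p in parts)
        )

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_ds(np.zeros(5), _toy_model())


class TestAugment:
    def _training_tables(self, seed=0, n_ions=20, n_target=10, n_other=20, gap=2.0):
        rng = np.random.default_rng(seed)
        n = n_target + n_other
        train = rng.normal(0, 1, (n_ions, n))
        valid = rng.normal(0, 1, (n_ions, n))
        is_target = np.zeros(n, bool)
        is_target[:n_target] = True
        for m in (train, valid):
            m[0, is_target] += gap
            m[0, ~is_target] -= gap
            m[1, is_target] += gap * 0.8
            m[1, ~is_target] -= gap * 0.8
        labels = ["OVC" if t else "CTL" for t in is_target]
        return (
            make_table(train, labels=labels),
            make_table(valid, labels=labels, sets=["B"] * n),
            is_target,
        )

    def _model_for(self, table, panel):
        n = table.n_ions
        return LOMEModel(
            table.axis_mz,
            np.ones(n),
            panel,
            ScalingStats(np.zeros(n), np.ones(n), 1.0),
        )

    @staticmethod
    def _sum_ss(table, panel, is_target, threshold):
        ds = panel_ds(table, panel)
        pos = ds > threshold
        return pos[is_target].mean() + (~pos[~is_target]).mean()

    def test_empty_augment_keeps_decisions(self):
        train, _, is_target = self._training_tables(gap=4.0)
        model = self._model_for(train, (0,))
        out = augment_model(model, [], train, is_target)
        assert out.panel_indices == model.panel_indices
        ds = panel_ds(train, out.panel_indices)
        assert np.array_equal(ds > out.threshold, ds > model.threshold)

    def test_absent_mz_rejected(self):
        train, _, is_target = self._training_tables()
        model = self._model_for(train, (0,))
        with pytest.raises(ValueError, match="ppm"):
            augment_model(model, [5000.0], train, is_target)

    def test_noise_ions_do_not_help_validation(self):
        deltas = []
        for seed in range(9):
            train, valid, is_target = self._training_tables(seed=seed)
            model = self._model_for(train, (0, 1))
            base_t = train_threshold(panel_ds(train, model.panel_indices), is_target)
            base = self._sum_ss(valid, model.panel_indices, is_target, base_t)
            noisy = augment_model(
                model, [train.axis_mz[i] for i in (10, 11, 12)], train, is_target
            )
            aug = self._sum_ss(valid, noisy.panel_indices, is_target, noisy.threshold)
            deltas.append(aug - base)
        assert np.median(deltas) <= 1e-9

    def test_withheld_signal_ion_helps_validation(self):
        deltas = []
        for seed in range(9):
            train, valid, is_target = self._training_tables(seed=seed)
            model = self._model_for(train, (0,))
            base_t = train_threshold(panel_ds(train, model.panel_indices), is_target)
            base = self._sum_ss(valid, model.panel_indices, is_target, base_t)
            enriched = augment_model(model, [train.axis_mz[1]], train, is_target)
            aug = self._sum_ss(
                valid, enriched.panel_indices, is_target, enriched.threshold
            )
            deltas.append(aug - base)
        assert np.median(deltas) >= 0.0


class TestBuildLome:
    def test_small_cohort_validates_well(self, trained_small_cohort):
        report = trained_small_cohort["report"]
        b = report["sets"]["B"]
        assert b["sensitivity"] >= 90.0
        assert b["specificity"] >= 90.0

    def test_determinism_same_seed_same_bundle(self, trained_small_cohort):
        c = trained_small_cohort
        model2, _ = build_lome(c["spectra"], c["manifest"], c["run_config"])
        assert model_hash(model2) == model_hash(c["model"])

    def test_permuting_validation_labels_leaves_model_unchanged(
        self, trained_small_cohort
    ):
        c = trained_small_cohort
        manifest = c["manifest"].copy()
        b_rows = manifest["set"] == "B"
        rng = np.random.default_rng(0)
        manifest.loc[b_rows, "label"] = rng.permutation(
            manifest.loc[b_rows, "label"].to_numpy()
        )
        model2, _ = build_lome(c["spectra"], manifest, c["run_config"])
        assert model_hash(model2) == model_hash(c["model"])

    def test_excluded_groups_detected_and_scored_separately(self):
        from lome import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n_per_class=8, n_ions=200, n_planted=2, effect_size=3.0,
            class_labels=("OVC", "CTL", "UCC"), rng_seed=3,
        )
        spectra, manifest, _ = generate_cohort(cfg)
        manifest["set"] = manifest["sample_id"].map(
            trisect(manifest, ("label",), 3, validation_only=("UCC",))
        )
        model, report = build_lome(
            spectra, manifest, RunConfig(rng_seed=3)
        )
        assert model.excluded_groups == ("UCC",)
        assert "UCC" in report["sets"]["B"]["per_group_specificity"]
        # excluded group must not contribute to the headline confusion counts
        b = report["sets"]["B"]
        n_core = b["TP"] + b["FP"] + b["TN"] + b["FN"]
        assert n_core == b["n_samples"] - 8

    def test_missing_set_assignment_rejected(self, trained_small_cohort):
        c = trained_small_cohort
        manifest = c["manifest"].copy()
        manifest.loc[0, "set"] = "none"
        with pytest.raises(ValueError, match="set"):
            build_lome(c["spectra"], manifest, c["run_config"])


class TestBundleAndScoring:
    def test_save_load_roundtrip(self, trained_small_cohort, tmp_path):
        model = trained_small_cohort["model"]
        save_model(model, tmp_path / "bundle", trained_small_cohort["report"])
        back = load_model(tmp_path / "bundle")
        assert model_hash(back) == model_hash(model)

    def test_scoring_training_cohort_reproduces_training_decisions(
        self, trained_small_cohort
    ):
        c = trained_small_cohort
        scores = score_spectra(c["model"], c["spectra"], c["manifest"])
        merged = scores.merge(
            c["manifest"].drop_duplicates("sample_id")[["sample_id", "label", "set"]],
            on="sample_id",
        )
        b = merged[merged["set"] == "B"]
        is_target = b["label"] == c["run_config"].target_label
        positive = b["decision"] == "positive"
        rep = c["report"]["sets"]["B"]
        assert int((positive & is_target).sum()) == rep["TP"]
        assert int((positive & ~is_target).sum()) == rep["FP"]

    def test_score_empty_input(self, trained_small_cohort):
        out = score_spectra(
            trained_small_cohort["model"], [], pd.DataFrame(
                columns=["sample_id", "label", "replicate", "set"]
            )
        )
        assert list(out.columns) == ["sample_id", "ds", "decision"]
        assert out.empty
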