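"""PCA-based discriminant analysis (PCA-DA) and reference-run selection.

PCA-DA separates the target class from all other classes: the Pareto-scaled
intensity columns are decomposed by (uncentered) PCA, a two-class Fisher
discriminant is fitted on the retained component scores, and the discriminant
direction is projected back to ion space.  The back-projected direction is
the *loading vector* of per-ion weighting factors ``w``, chosen so that the
discriminant score of column ``j`` is exactly the linear form

    DS_j = sum_i w_i * x_ij

with no intercept.  The sign convention makes the target class score
positive; ``w`` is scaled so the training scores have unit pooled
within-class standard deviation (the usual canonical-variate convention),
which is what makes a fixed magnitude threshold on per-ion contributions
meaningful downstream.

The PCA step is intentionally uncentered: a Pareto-scaled training table has
zero row means by construction, and keeping the map strictly linear is what
lets the same loading vector score held-out columns that were transformed
with frozen statistics.

When each sample has been measured several times, the replicate measurement
whose own PCA-DA fit separates the classes best (largest sensitivity +
specificity at score threshold 0) is designated the *reference measurement*;
its axis and loading vector anchor the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peak_io import PeakTable

__all__ = [
    "LoadingVector",
    "SeparationScore",
    "fit_pcada",
    "separation_at_zero",
    "select_reference_measurement",
]

#: Fraction of variance the retained principal components must explain.
DEFAULT_VARIANCE_RULE = 0.95

#: Ridge added to the pooled covariance diagonal, as a fraction of trace/dim.
_COV_RIDGE = 1e-8


@dataclass(frozen=True)
class LoadingVector:
    """Per-ion weighting factors indexed by the reference axis."""

    axis_mz: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis_mz", np.asarray(self.axis_mz, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.axis_mz.size != self.weights.size:
            raise ValueError("loading vector length must match the axis")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("loading vector contains non-finite weights")
        if not np.any(self.weights):
            raise ValueError("loading vector is identically zero")


@dataclass(frozen=True)
class SeparationScore:
    """Training separation of one replicate's PCA-DA fit at threshold 0."""

    replicate_index: int
    sensitivity: float
    specificity: float
    fisher_ratio: float

    @property
    def sum_ss(self) -> float:
        return self.sensitivity + self.specificity


def _n_components(explained: np.ndarray, variance_rule: float, cap: int) -> int:
    cum = np.cumsum(explained) / explained.sum()
    k = int(np.searchsorted(cum, variance_rule) + 1)
    return max(1, min(k, cap))


def fit_pcada(
    table: PeakTable,
    is_target: np.ndarray,
    variance_rule: float = DEFAULT_VARIANCE_RULE,
    max_components: int | None = None,
) -> tuple[LoadingVector, np.ndarray]:
    """Fit PCA-DA on a Pareto-scaled table; return loading vector and scores.

    ``is_target`` is a boolean mask over columns (True = target class).
    Components are retained up to the smallest number explaining at least
    ``variance_rule`` of the variance, capped at ``n_columns - 2`` (or
    ``max_components``).  The Fisher direction is computed with the pooled
    within-class covariance, ridge-regularized on the diagonal.

    Returns ``(loading, ds)`` where ``ds[j] == loading.weights @ x[:, j]``.
    """
    is_target = np.asarray(is_target, dtype=bool)
    if is_target.size != table.n_columns:
        raise ValueError("label mask length must match the column count")
    n1, n0 = int(is_target.sum()), int((~is_target).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both classes need at least 2 columns to fit PCA-DA")
    X = table.intensities  # ions x columns
    n = table.n_columns
    # Uncentered PCA via SVD of the column observations.
    U, s, Vt = np.linalg.svd(X.T, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size else np.zeros(0, bool)
    s, U, Vt = s[nonzero], U[:, nonzero], Vt[nonzero]
    if s.size == 0:
        raise ValueError("table has rank 0; cannot fit PCA-DA")
    cap = max(1, n - 2)
    if max_components is not None:
        cap = min(cap, int(max_components))
    k = _n_components(s**2, variance_rule, cap)
    scores = U[:, :k] * s[:k]  # n x k PC scores
    mu1 = scores[is_target].mean(axis=0)
    mu0 = scores[~is_target].mean(axis=0)
    d1 = scores[is_target] - mu1
    d0 = scores[~is_target] - mu0
    pooled = (d1.T @ d1 + d0.T @ d0) / (n - 2)
    pooled = pooled + np.eye(k) * (_COV_RIDGE * np.trace(pooled) / k)
    w_pc = np.linalg.solve(pooled, mu1 - mu0)
    w = Vt[:k].T @ w_pc  # back-projection to ion space
    ds = X.T @ w
    if ds[is_target].mean() <= ds[~is_target].mean():
        w, ds = -w, -ds
    # Canonical-variate scaling: unit pooled within-class sd of the score.
    e1 = ds[is_target] - ds[is_target].mean()
    e0 = ds[~is_target] - ds[~is_target].mean()
    pooled_sd = np.sqrt((e1 @ e1 + e0 @ e0) / (n - 2))
    if pooled_sd <= 0:
        pooled_sd = np.linalg.norm(w)
    w, ds = w / pooled_sd, ds / pooled_sd
    return LoadingVector(table.axis_mz, w), ds


def separation_at_zero(ds: np.ndarray, is_target: np.ndarray) -> tuple[float, float, float]:
    """Sensitivity, specificity and Fisher ratio of a score at threshold 0."""
    is_target = np.asarray(is_target, dtype=bool)
    pos = ds > 0
    sens = float(pos[is_target].mean())
    spec = float((~pos[~is_target]).mean())
    d1, d0 = ds[is_target], ds[~is_target]
    num = (d1.mean() - d0.mean()) ** 2
    den = d1.var(ddof=1) + d0.var(ddof=1)
    if den == 0:
        fisher = float("inf") if num > 0 else 0.0
    else:
        fisher = float(num / den)
    return sens, spec, fisher


def select_reference_measurement(
    replicate_tables: dict[int, PeakTable],
    is_target_by_replicate: dict[int, np.ndarray],
    variance_rule: float = DEFAULT_VARIANCE_RULE,
    max_components: int | None = None,
) -> tuple[int, SeparationScore, list[SeparationScore]]:
    """Pick the replicate measurement with the best class separation.

    Each replicate's table (already preprocessed and Pareto-scaled) is fitted
    with PCA-DA independently; the replicate maximizing sensitivity +
    specificity at threshold 0 wins, with ties broken by the larger Fisher
    ratio and then the lower replicate index.
    """
    if len(replicate_tables) < 2:
        raise ValueError("need at least 2 replicate measurements to choose from")
    sample_sets = {
        r: tuple(sorted(t.columns["sample_id"])) for r, t in replicate_tables.items()
    }
    if len(set(sample_sets.values())) != 1:
        raise ValueError("replicate tables do not share the same sample set")
    scores: list[SeparationScore] = []
    for r in sorted(replicate_tables):
        _, ds = fit_pcada(
            replicate_tables[r],
            is_target_by_replicate[r],
            variance_rule,
            max_components,
        )
        sens, spec, fisher = separation_at_zero(ds, is_target_by_replicate[r])
        scores.append(SeparationScore(r, sens, spec, fisher))
    best = max(
        scores,
        key=lambda sc: (sc.sum_ss, sc.fisher_ratio, -sc.replicate_index),
    )
    return best.replicate_index, best, scores
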