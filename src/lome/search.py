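"""Combinatorial selection of the discriminative ion panel.

Two search stages operate on weighted (Pareto-scaled x loading-vector)
intensity tables:

*Search algorithm 1* screens the weighted reference table for preliminary
candidates: an ion qualifies when the magnitude of its weighted intensity
exceeds a threshold (default 0.1, strict) in strictly more than a fraction
(default half) of the intensity columns.

*Search algorithm 2* picks the discriminative panel from the candidates on
the replicate-averaged training table, judging every combination by the sum
of its sensitivity and specificity at discriminant-score threshold 0.  It
has two phases:

- **germination** — if no single candidate separates perfectly, all 2- and
  3-combinations are scored and the best is repeatedly set aside until at
  most one candidate remains; the set-aside units are then themselves
  grouped 2 or 3 at a time, hierarchically, until a single unit remains.
  The best-scoring unit formed anywhere in the hierarchy (singletons
  included) becomes the seed set.
- **growth** — 1-, 2- and 3-subsets of the remaining candidates are tried as
  additions to the seed; the best strictly-improving enlargement is
  accepted and the step repeats; otherwise the current seed is the panel.

Ties on the sum of sensitivity and specificity are broken by (1) fewest
ions, (2) largest Fisher's discriminant ratio, then lexicographic ion order
for full determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .peak_io import PeakTable

__all__ = [
    "CandidateSet",
    "ComboScore",
    "SearchTrace",
    "search1",
    "combo_score",
    "tie_break",
    "search2",
]

#: Two scores within this distance count as tied on sum_ss.
TIE_TOL = 1e-12

#: Candidate-count cap for the exact combinatorial search.
DEFAULT_CANDIDATE_CAP = 64


@dataclass(frozen=True)
class CandidateSet:
    """Preliminary candidate ions: unique sorted indices into the axis."""

    indices: tuple[int, ...]
    mz: tuple[float, ...]

    def __post_init__(self) -> None:
        if list(self.indices) != sorted(set(self.indices)):
            raise ValueError("candidate indices must be unique and sorted")
        if len(self.indices) != len(self.mz):
            raise ValueError("indices and m/z lists must have equal length")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ComboScore:
    """Classification score of one ion subset at DS threshold 0."""

    subset: tuple[int, ...]
    sensitivity: float
    specificity: float
    fisher_ratio: float

    @property
    def sum_ss(self) -> float:
        return self.sensitivity + self.specificity

    @property
    def size(self) -> int:
        return len(self.subset)


@dataclass
class SearchTrace:
    """Audit trail of every accepted combination during search algorithm 2."""

    records: list[dict] = field(default_factory=list)

    def log(self, phase: str, score: ComboScore) -> None:
        self.records.append(
            {
                "phase": phase,
                "subset": list(score.subset),
                "sensitivity": score.sensitivity,
                "specificity": score.specificity,
                "sum_ss": score.sum_ss,
                "fisher_ratio": score.fisher_ratio,
            }
        )


def search1(
    weighted_reference: PeakTable,
    magnitude_threshold: float = 0.1,
    column_fraction: float = 0.5,
) -> CandidateSet:
    """Select preliminary candidates from the weighted reference table.

    Ion ``i`` qualifies iff ``|weighted intensity_ij| > magnitude_threshold``
    (strict) in strictly more than ``column_fraction`` of the columns ``j``.
    """
    if weighted_reference.n_columns == 0 or weighted_reference.n_ions == 0:
        raise ValueError("weighted reference table is empty")
    hits = np.abs(weighted_reference.intensities) > magnitude_threshold
    count = hits.sum(axis=1)
    selected = np.flatnonzero(count > column_fraction * weighted_reference.n_columns)
    return CandidateSet(
        tuple(int(i) for i in selected),
        tuple(float(weighted_reference.axis_mz[i]) for i in selected),
    )


def _score_subset(
    subset: tuple[int, ...],
    weighted: np.ndarray,
    is_target: np.ndarray,
    threshold: float,
) -> ComboScore:
    ds = weighted[list(subset)].sum(axis=0)
    pos = ds > threshold
    sens = float(pos[is_target].mean())
    spec = float((~pos[~is_target]).mean())
    d1, d0 = ds[is_target], ds[~is_target]
    num = (d1.mean() - d0.mean()) ** 2
    den = (d1.var(ddof=1) if d1.size > 1 else 0.0) + (
        d0.var(ddof=1) if d0.size > 1 else 0.0
    )
    if den == 0:
        fisher = float("inf") if num > 0 else 0.0
    else:
        fisher = float(num / den)
    return ComboScore(tuple(sorted(subset)), sens, spec, fisher)


def combo_score(
    subset,
    averaged_table: PeakTable,
    is_target: np.ndarray,
    threshold: float = 0.0,
) -> ComboScore:
    """Score an ion subset on the weighted, replicate-averaged table.

    The per-sample discriminant score is the sum of the subset's weighted
    intensities; a sample is called positive iff DS > ``threshold``.  The
    Fisher ratio is ``(mean_pos - mean_neg)^2 / (var_pos + var_neg)`` with
    sample (n-1) variances.
    """
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    if max(subset) >= averaged_table.n_ions or min(subset) < 0:
        raise IndexError(f"subset index out of range for {averaged_table.n_ions} ions")
    is_target = np.asarray(is_target, dtype=bool)
    if is_target.size != averaged_table.n_columns:
        raise ValueError("label mask length must match the column count")
    return _score_subset(subset, averaged_table.intensities, is_target, threshold)


def tie_break(combos: list[ComboScore]) -> ComboScore:
    """Resolve combinations tied on sum of sensitivity and specificity.

    Priority 1: fewest ions.  Priority 2: largest Fisher's discriminant
    ratio.  Residual ties go to the lexicographically smallest ion-index
    tuple, making the choice fully deterministic.
    """
    if not combos:
        raise ValueError("tie_break needs at least one combination")
    best_ss = max(c.sum_ss for c in combos)
    tied = [c for c in combos if c.sum_ss >= best_ss - TIE_TOL]
    min_size = min(c.size for c in tied)
    tied = [c for c in tied if c.size == min_size]
    best_fisher = max(c.fisher_ratio for c in tied)
    tied = [
        c
        for c in tied
        if c.fisher_ratio == best_fisher
        or (
            np.isfinite(best_fisher)
            and abs(c.fisher_ratio - best_fisher) <= TIE_TOL * max(1.0, abs(best_fisher))
        )
    ]
    return min(tied, key=lambda c: c.subset)


def _best_grouping(
    units: list[tuple[int, ...]],
    scorer,
) -> tuple[ComboScore, tuple[int, ...], tuple[int, ...]] | None:
    """Best 2- or 3-unit grouping; returns (score, member unit ids)."""
    scored = []
    ids = range(len(units))
    for r in (2, 3):
        if len(units) < r:
            continue
        for member_ids in combinations(ids, r):
            ions: list[int] = []
            for m in member_ids:
                ions.extend(units[m])
            scored.append((scorer(tuple(sorted(ions))), member_ids))
    if not scored:
        return None
    best = tie_break([s for s, _ in scored])
    for s, member_ids in scored:
        if s is best:
            return best, member_ids, tuple(best.subset)
    raise AssertionError("unreachable")


def search2(
    candidates: CandidateSet,
    averaged_table: PeakTable,
    is_target: np.ndarray,
    threshold: float = 0.0,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
) -> tuple[CandidateSet, SearchTrace]:
    """Run search algorithm 2 (germination + growth) over the candidates.

    Returns the discriminative panel as a :class:`CandidateSet` plus a trace
    of every accepted combination.  ``candidate_cap`` bounds the exact
    search; if more candidates arrive, the cap keeps the ones with the
    largest median absolute weighted intensity (a warning is emitted).
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    is_target = np.asarray(is_target, dtype=bool)
    weighted = averaged_table.intensities
    pool = list(candidates.indices)
    if len(pool) > candidate_cap:
        warnings.warn(
            f"{len(pool)} candidates exceed the exact-search cap "
            f"({candidate_cap}); keeping the strongest by median |weighted "
            "intensity|",
            stacklevel=2,
        )
        strength = np.median(np.abs(weighted[pool]), axis=1)
        order = np.argsort(-strength, kind="stable")[:candidate_cap]
        pool = sorted(pool[i] for i in order)

    cache: dict[tuple[int, ...], ComboScore] = {}

    def scorer(subset: tuple[int, ...]) -> ComboScore:
        if subset not in cache:
            cache[subset] = _score_subset(subset, weighted, is_target, threshold)
        return cache[subset]

    trace = SearchTrace()

    # Germination step 1: a perfect single ion short-circuits the search.
    singles = [scorer((i,)) for i in pool]
    perfect = [s for s in singles if s.sensitivity == 1.0 and s.specificity == 1.0]
    if perfect:
        best = tie_break(perfect)
        trace.log("germination:perfect-single", best)
        return _to_candidate_set(best.subset, averaged_table), trace

    all_units: list[ComboScore] = list(singles)

    if len(pool) >= 2:
        # Steps 2-3: set aside the best 2-/3-combination until <=1 remains.
        work = list(pool)
        level_units: list[tuple[int, ...]] = []
        while len(work) >= 2:
            got = _best_grouping([(i,) for i in work], scorer)
            assert got is not None
            best, _, ions = got
            trace.log("germination:set-aside", best)
            all_units.append(best)
            level_units.append(ions)
            for i in ions:
                work.remove(i)
        # Steps 4-5: group the set-aside units hierarchically.
        current = level_units
        while len(current) >= 2:
            next_level: list[tuple[int, ...]] = []
            work_units = list(current)
            while len(work_units) >= 2:
                got = _best_grouping(work_units, scorer)
                assert got is not None
                best, member_ids, ions = got
                trace.log("germination:merge", best)
                all_units.append(best)
                next_level.append(ions)
                for m in sorted(member_ids, reverse=True):
                    work_units.pop(m)
            next_level.extend(work_units)  # unpaired unit passes through
            if len(next_level) >= len(current):
                break
            current = next_level

    # Step 6: the best unit formed anywhere becomes the seed set.
    seed = tie_break(all_units)
    trace.log("germination:seed", seed)

    # Growth steps 7-9: add the best strictly-improving 1-/2-/3-subset.
    seed_ions = set(seed.subset)
    remaining = [i for i in pool if i not in seed_ions]
    while remaining:
        enlargements = []
        for r in (1, 2, 3):
            if len(remaining) < r:
                continue
            for extra in combinations(remaining, r):
                enlargements.append(scorer(tuple(sorted(seed_ions | set(extra)))))
        best = tie_break(enlargements)
        if best.sum_ss > seed.sum_ss + TIE_TOL:
            seed = best
            trace.log("growth:accept", best)
            seed_ions = set(seed.subset)
            remaining = [i for i in remaining if i not in seed_ions]
        else:
            break

    return _to_candidate_set(seed.subset, averaged_table), trace


def _to_candidate_set(subset, table: PeakTable) -> CandidateSet:
    idx = tuple(sorted(int(i) for i in subset))
    return CandidateSet(idx, tuple(float(table.axis_mz[i]) for i in idx))
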