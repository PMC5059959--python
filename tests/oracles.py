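"""Independent brute-force oracles used to cross-check the search module.

Everything here is written from the algorithm's written description, on
purpose without reusing any code from :mod:`lome.search`: scores are
computed by explicit loops and the combinatorial phases are enumerated
recursively.  At every "pick the best combination" step the oracle applies
the written selection rules — maximum sensitivity+specificity, then fewest
ions (Priority 1), then largest Fisher ratio (Priority 2) — and branches
over every residually tied choice.  It therefore returns the set of all
final panels reachable by a trajectory consistent with the algorithm's
rules; a correct implementation must return one of them, and one whose
sum_ss equals the best over all of them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

TOL = 1e-12


def brute_score(subset, weighted, is_target, threshold=0.0):
    """(sum_ss, sensitivity, specificity, fisher) of an ion subset, by loops."""
    n = weighted.shape[1]
    ds = np.zeros(n)
    for i in subset:
        ds = ds + weighted[i]
    tp = fn = tn = fp = 0
    for j in range(n):
        positive = ds[j] > threshold
        if is_target[j]:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    d1 = ds[np.asarray(is_target, bool)]
    d0 = ds[~np.asarray(is_target, bool)]
    num = (d1.mean() - d0.mean()) ** 2
    den = d1.var(ddof=1) + d0.var(ddof=1)
    fisher = float("inf") if den == 0 and num > 0 else (0.0 if den == 0 else num / den)
    return sens + spec, sens, spec, fisher


class TrajectoryOracle:
    """Enumerate every germination/growth trajectory over a candidate pool."""

    def __init__(self, candidates, weighted, is_target, threshold=0.0, max_states=500_000):
        self.pool = tuple(sorted(candidates))
        self.weighted = weighted
        self.is_target = np.asarray(is_target, bool)
        self.threshold = threshold
        self.max_states = max_states
        self.states = 0
        self._cache: dict[frozenset, float] = {}

    def score(self, ions) -> float:
        return self.full_score(ions)[0]

    def full_score(self, ions):
        key = frozenset(ions)
        if key not in self._cache:
            self._cache[key] = brute_score(
                sorted(key), self.weighted, self.is_target, self.threshold
            )
        return self._cache[key]

    def select(self, options):
        """All residually tied best choices among candidate ion sets.

        Applies the written selection order: maximum sum of sensitivity and
        specificity, fewest ions, largest Fisher ratio; whatever remains is
        a genuine tie and every member is returned.
        """
        options = list(options)
        best_ss = max(self.score(o) for o in options)
        tied = [o for o in options if self.score(o) >= best_ss - TOL]
        min_size = min(len(o) for o in tied)
        tied = [o for o in tied if len(o) == min_size]
        best_f = max(self.full_score(o)[3] for o in tied)
        out = []
        for o in tied:
            f = self.full_score(o)[3]
            if f == best_f or (
                np.isfinite(best_f) and abs(f - best_f) <= TOL * max(1.0, abs(best_f))
            ):
                out.append(o)
        return out

    def _tick(self) -> None:
        self.states += 1
        if self.states > self.max_states:
            raise RuntimeError("trajectory oracle exceeded its state budget")

    def final_panels(self) -> set[frozenset]:
        """All final panels over every maximal-choice trajectory."""
        perfect = [
            i
            for i in self.pool
            if brute_score([i], self.weighted, self.is_target, self.threshold)[1:3]
            == (1.0, 1.0)
        ]
        if perfect:
            return {frozenset([i]) for i in perfect}
        panels: set[frozenset] = set()
        for units in self._level0(frozenset(self.pool)):
            for all_units in self._hierarchy(units):
                pool_units = all_units | {frozenset([i]) for i in self.pool}
                for seed in self.select(pool_units):
                    panels |= self._grow(seed)
        return panels

    def _level0(self, remaining: frozenset):
        """Set-aside sequences over single ions -> frozensets of units."""
        self._tick()
        if len(remaining) < 2:
            yield frozenset()
            return
        combos = [
            frozenset(c)
            for r in (2, 3)
            if len(remaining) >= r
            for c in combinations(sorted(remaining), r)
        ]
        seen = set()
        for c in self.select(combos):
            for rest in self._level0(remaining - c):
                out = rest | {c}
                if out not in seen:
                    seen.add(out)
                    yield out

    def _one_level(self, avail: frozenset, formed: frozenset):
        """One hierarchical pass: set aside unit-groups until < 2 remain."""
        self._tick()
        if len(avail) < 2:
            yield frozenset(avail), formed
            return
        units = sorted(avail, key=sorted)
        groups = [
            tuple(g)
            for r in (2, 3)
            if len(units) >= r
            for g in combinations(units, r)
        ]
        merged = {g: frozenset().union(*g) for g in groups}
        chosen = set(self.select(list(merged.values())))
        for g, m in merged.items():
            if m in chosen:
                rest = avail - set(g)
                for nxt, f in self._one_level(rest, formed | {m}):
                    yield nxt | {m}, f

    def _hierarchy(self, units: frozenset):
        """All_units sets over every hierarchical merge trajectory."""
        seen = set()
        stack = [(units, frozenset(units))]
        while stack:
            current, formed = stack.pop()
            if len(current) < 2:
                if formed not in seen:
                    seen.add(formed)
                    yield formed
                continue
            for nxt, f in self._one_level(current, formed):
                if len(nxt) >= len(current):
                    if f not in seen:
                        seen.add(f)
                        yield f
                else:
                    stack.append((nxt, f))

    def _grow(self, seed: frozenset) -> set[frozenset]:
        """Growth closure: branch over every maximal improving enlargement."""
        self._tick()
        remaining = [i for i in self.pool if i not in seed]
        enlargements = [
            seed | set(extra)
            for r in (1, 2, 3)
            if len(remaining) >= r
            for extra in combinations(remaining, r)
        ]
        if not enlargements:
            return {seed}
        chosen = self.select(enlargements)
        if self.score(chosen[0]) <= self.score(seed) + TOL:
            return {seed}
        out: set[frozenset] = set()
        for e in chosen:
            out |= self._grow(e)
        return out
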