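"""Candidate enumeration, ranking and permutation significance.

Candidates are sets of windows (or of single markers for the classic
cell-vote baseline) scored by cross-validated balanced accuracy.
Significance comes from phenotype-permutation tests with an add-one
p-value convention, optionally with adaptive early stopping, and
family-wise control either by the max-statistic permutation null or by
Bonferroni over the number of tested models.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Iterator, Sequence

import numpy as np

from .engine import CVPlan, KnnConfig, cv_neighbors, knn_cv_ba_batch, mdr_cv_ba_batch
from .windowing import (
    WindowDistanceSet,
    WindowPartition,
    combine_window_distances,
    compute_distance_set,
    make_windows,
)

logger = logging.getLogger("knnmdr")

__all__ = [
    "DEFAULT_ADAPTIVE_SCHEDULE",
    "SearchConfig",
    "ModelCandidate",
    "enumerate_window_sets",
    "count_window_sets",
    "candidate_ba_matrix",
    "build_neighbor_cache",
    "scan",
    "permutation_test",
    "adaptive_permutation",
    "bonferroni_threshold",
    "hierarchical_scan",
    "HierarchicalResult",
]

#: cumulative permutation counts and survival thresholds of the staged
#: permutation scheme used for deep p-values on large panels
DEFAULT_ADAPTIVE_SCHEDULE = (
    (100, 0.05),
    (1000, 0.005),
    (10_000, 5.0e-4),
    (100_000, 5.0e-5),
    (1_000_000, 5.0e-6),
    (2_000_000, 2.5e-6),
)

_PERM_CHUNK = 512


@dataclasses.dataclass(frozen=True)
class SearchConfig:
    """Knobs of an exhaustive window-set scan."""

    max_order: int = 2
    min_order: int = 1
    alpha: float = 0.05
    n_perm: int = 100
    n_folds: int = 10
    knn: KnnConfig = dataclasses.field(default_factory=KnnConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_order <= self.max_order):
            raise ValueError("need 1 <= min_order <= max_order")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclasses.dataclass
class ModelCandidate:
    """A window (or marker) set with its score and significance."""

    ids: tuple[int, ...]
    kind: str  # "windows" | "markers"
    cv_ba: float
    p_value: float | None = None
    n_perm: int | None = None
    significant: bool | None = None
    abandoned: bool = False


def enumerate_window_sets(
    n_windows: int, max_order: int, min_order: int = 1
) -> tuple[Iterator[tuple[int, ...]], int]:
    """All window subsets of sizes ``min_order..max_order``.

    Returns a deterministic lexicographic iterator together with the
    total count ``sum_k C(W, k)``.
    """
    if not (1 <= min_order <= max_order <= n_windows):
        raise ValueError("need 1 <= min_order <= max_order <= n_windows")
    count = count_window_sets(n_windows, max_order, min_order)
    iterator = itertools.chain.from_iterable(
        itertools.combinations(range(n_windows), k)
        for k in range(min_order, max_order + 1)
    )
    return iterator, count


def count_window_sets(n_windows: int, max_order: int, min_order: int = 1) -> int:
    return sum(math.comb(n_windows, k) for k in range(min_order, max_order + 1))


def build_neighbor_cache(
    dset: WindowDistanceSet,
    candidates: Sequence[tuple[int, ...]],
    plan: CVPlan,
    k: int,
) -> list[np.ndarray]:
    """Out-of-fold neighbor lists per candidate; label-free, so shareable
    between the observed scan and every permutation pass."""
    return [
        cv_neighbors(combine_window_distances(dset, ids), plan, k)
        for ids in candidates
    ]


def candidate_ba_matrix(
    dset: WindowDistanceSet,
    candidates: Sequence[tuple[int, ...]],
    plan: CVPlan,
    Y: np.ndarray,
    knn_cfg: KnnConfig,
    neighbor_cache: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """CV balanced accuracy of every candidate for every label row.

    Returns shape ``(R, n_candidates)``; row 0 is conventionally the
    observed phenotype and the remaining rows are permutations, so the
    max-statistic null falls out of one call.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=bool))
    out = np.empty((Y.shape[0], len(candidates)))
    for j, ids in enumerate(candidates):
        if neighbor_cache is not None:
            out[:, j] = knn_cv_ba_batch(None, plan, Y, knn_cfg, neighbors=neighbor_cache[j])
        else:
            d2 = combine_window_distances(dset, ids)
            out[:, j] = knn_cv_ba_batch(d2, plan, Y, knn_cfg)
    return out


def _perm_rows(rng: np.random.Generator, is_case: np.ndarray, m: int) -> np.ndarray:
    """Draw m label permutations row by row (stream is batch-invariant)."""
    return np.stack([rng.permutation(is_case) for _ in range(m)])


def scan(
    dset: WindowDistanceSet,
    is_case: np.ndarray,
    plan: CVPlan,
    cfg: SearchConfig,
    candidates: Sequence[tuple[int, ...]] | None = None,
) -> list[ModelCandidate]:
    """Score every candidate window set; rank by descending CV BA.

    Equal-BA ties keep the lexicographic candidate order so the ranking
    is fully deterministic.
    """
    if candidates is None:
        it, _ = enumerate_window_sets(dset.n_windows, cfg.max_order, cfg.min_order)
        candidates = list(it)
    is_case = np.asarray(is_case, dtype=bool)
    bas = candidate_ba_matrix(dset, candidates, plan, is_case[None, :], cfg.knn)[0]
    order = np.argsort(-bas, kind="stable")
    return [ModelCandidate(candidates[j], "windows", float(bas[j])) for j in order]


def permutation_test(
    dset: WindowDistanceSet,
    is_case: np.ndarray,
    candidates: Sequence[tuple[int, ...]],
    plan: CVPlan,
    knn_cfg: KnnConfig,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    mode: str = "max_over_models",
    observed: np.ndarray | None = None,
    neighbor_cache: Sequence[np.ndarray] | None = None,
) -> np.ndarray | float:
    """Phenotype-permutation p-values with the add-one convention.

    ``max_over_models`` recomputes the maximum BA over all candidates per
    permutation (one family-wise null number per permutation) and returns
    the scalar p of the best observed model; ``per_model`` returns one p
    per candidate, each against its own permutation distribution.  The
    smallest attainable p is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    is_case = np.asarray(is_case, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if neighbor_cache is None:
        neighbor_cache = build_neighbor_cache(dset, candidates, plan, knn_cfg.k)
    if observed is None:
        observed = candidate_ba_matrix(
            dset, candidates, plan, is_case[None, :], knn_cfg,
            neighbor_cache=neighbor_cache,
        )[0]
    exceed = np.zeros(len(candidates), dtype=np.int64)
    max_exceed = 0
    obs_max = observed.max()
    done = 0
    while done < n_perm:
        m = min(_PERM_CHUNK, n_perm - done)
        Y = _perm_rows(rng, is_case, m)
        perm_bas = np.empty((m, len(candidates)))
        for j, nb in enumerate(neighbor_cache):
            perm_bas[:, j] = knn_cv_ba_batch(None, plan, Y, knn_cfg, neighbors=nb)
        exceed += (perm_bas >= observed[None, :]).sum(axis=0)
        max_exceed += int((perm_bas.max(axis=1) >= obs_max).sum())
        done += m
    if mode == "max_over_models":
        return float((max_exceed + 1) / (n_perm + 1))
    if mode == "per_model":
        return (exceed + 1) / (n_perm + 1)
    raise ValueError(f"unknown mode {mode!r}")


def adaptive_permutation(
    dset: WindowDistanceSet,
    is_case: np.ndarray,
    candidates: Sequence[tuple[int, ...]],
    plan: CVPlan,
    knn_cfg: KnnConfig,
    schedule: Sequence[tuple[int, float]] = DEFAULT_ADAPTIVE_SCHEDULE,
    seed: int = 0,
    observed: np.ndarray | None = None,
) -> list[ModelCandidate]:
    """Staged per-model permutation testing with progressive abandonment.

    Rounds run in schedule order (strictly increasing cumulative counts,
    strictly decreasing thresholds).  A candidate whose running add-one p
    exceeds the round threshold is abandoned and keeps its last running
    p; survivors of the final round carry p-values at full cumulative
    resolution.  Each candidate owns an independent seed substream, so
    dropping other candidates never perturbs a survivor's p-value — a
    survivor's p is exactly what a single-shot test at the same
    cumulative count and substream would give.
    """
    _validate_schedule(schedule)
    if len(candidates) == 0:
        return []
    is_case = np.asarray(is_case, dtype=bool)
    if observed is None:
        observed = candidate_ba_matrix(dset, candidates, plan, is_case[None, :], knn_cfg)[0]
    children = np.random.SeedSequence(seed).spawn(len(candidates))
    results = []
    for j, ids in enumerate(candidates):
        d2 = combine_window_distances(dset, ids)
        nb = cv_neighbors(d2, plan, knn_cfg.k)
        rng = np.random.default_rng(children[j])
        exceed = 0
        done = 0
        abandoned = False
        for cum, threshold in schedule:
            while done < cum:
                m = min(_PERM_CHUNK, cum - done)
                Y = _perm_rows(rng, is_case, m)
                bas = knn_cv_ba_batch(None, plan, Y, knn_cfg, neighbors=nb)
                exceed += int((bas >= observed[j]).sum())
                done += m
            p = (exceed + 1) / (done + 1)
            if p > threshold:
                abandoned = True
                break
        results.append(
            ModelCandidate(
                tuple(ids), "windows", float(observed[j]),
                p_value=float(p), n_perm=done, abandoned=abandoned,
            )
        )
    return results


def _validate_schedule(schedule: Sequence[tuple[int, float]]) -> None:
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    counts = [c for c, _ in schedule]
    thresholds = [t for _, t in schedule]
    if any(b <= a for a, b in zip(counts[:-1], counts[1:])):
        raise ValueError("cumulative permutation counts must strictly increase")
    if any(b >= a for a, b in zip(thresholds[:-1], thresholds[1:])):
        raise ValueError("survival thresholds must strictly decrease")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _schedule_for(bonf: float, base: Sequence[tuple[int, float]] | None) -> tuple:
    """Clip a staged schedule so its final round can resolve p <= bonf."""
    if base is None:
        base = DEFAULT_ADAPTIVE_SCHEDULE
    need = int(math.ceil(2.0 / bonf))
    rounds = [(c, t) for c, t in base if t > bonf and c < need]
    rounds.append((need, bonf))
    return tuple(rounds)


@dataclasses.dataclass
class HierarchicalResult:
    """Final marker-level hits plus a per-round log of the funnel."""

    final: list[ModelCandidate]
    rounds: list[dict]


def hierarchical_scan(
    values: np.ndarray,
    is_case: np.ndarray,
    stride: int,
    round1_window: int,
    round2_window: int,
    knn_cfg: KnnConfig | None = None,
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
    metric: str = "normalized_euclidean",
    schedule: Sequence[tuple[int, float]] | None = None,
    dtype: type = np.float64,
) -> HierarchicalResult:
    """Three-stage scan for large marker panels.

    Round 1 keeps every ``stride``-th marker, splits them into coarse
    windows of ``round1_window`` and tests all window pairs; pairs passing
    Bonferroni (at *alpha* over the pair count, via staged adaptive
    permutations) have their hidden markers restored.  Round 2 rescans
    each recovered region with windows of ``round2_window``.  The final
    stage runs the classic cell-vote predictor on all marker pairs inside
    surviving regions and reports pairs passing Bonferroni.  Rounds with
    no survivor end the funnel with an empty result, not an error.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    knn_cfg = knn_cfg or KnnConfig()
    is_case = np.asarray(is_case, dtype=bool)
    n, M = values.shape
    plan_seed, perm_seed1, perm_seed2, perm_seed3 = (
        np.random.SeedSequence(seed).generate_state(4).tolist()
    )
    plan = _make_plan(is_case, n_folds, plan_seed)
    rounds_log: list[dict] = []

    # --- round 1: stride-subsampled coarse window pairs -------------------
    sel = np.arange(0, M, stride)
    part1 = make_windows(len(sel), round1_window)
    dset1 = compute_distance_set(values[:, sel], part1, metric=metric, dtype=dtype)
    pairs1 = list(itertools.combinations(range(part1.n_windows), 2))
    bonf1 = bonferroni_threshold(alpha, len(pairs1))
    res1 = adaptive_permutation(
        dset1, is_case, pairs1, plan, knn_cfg,
        schedule=_schedule_for(bonf1, schedule), seed=perm_seed1,
    )
    surv1 = [c for c in res1 if not c.abandoned and c.p_value <= bonf1]
    rounds_log.append(
        {"round": 1, "n_markers": len(sel), "n_windows": part1.n_windows,
         "n_tests": len(pairs1), "threshold": bonf1, "n_survivors": len(surv1)}
    )
    logger.info("hierarchical round 1: %s", rounds_log[-1])
    if not surv1:
        return HierarchicalResult([], rounds_log)

    # --- round 2: recover hidden markers, rescan finer --------------------
    final: list[ModelCandidate] = []
    seen_pairs: set[tuple[int, int]] = set()
    n_tests2 = 0
    n_surv2 = 0
    for pair_no, cand in enumerate(surv1):
        region = _recovered_region(sel, part1, cand.ids, stride, M)
        part2 = make_windows(len(region), min(round2_window, len(region)))
        dset2 = compute_distance_set(
            values[:, region], part2, metric=metric, dtype=dtype
        )
        pairs2 = list(itertools.combinations(range(part2.n_windows), 2))
        if not pairs2:
            continue
        bonf2 = bonferroni_threshold(alpha, len(pairs2))
        n_tests2 += len(pairs2)
        res2 = adaptive_permutation(
            dset2, is_case, pairs2, plan, knn_cfg,
            schedule=_schedule_for(bonf2, schedule), seed=perm_seed2 + pair_no,
        )
        surv2 = [c for c in res2 if not c.abandoned and c.p_value <= bonf2]
        n_surv2 += len(surv2)

        # --- final stage: classic cell vote on marker pairs inside -------
        for k, cand2 in enumerate(surv2):
            markers = region[part2.markers_of(cand2.ids)]
            final.extend(
                _final_mdr_pairs(
                    values, is_case, markers, plan, alpha,
                    seed=perm_seed3 + pair_no * 1000 + k,
                    schedule=schedule, seen=seen_pairs,
                )
            )
    rounds_log.append(
        {"round": 2, "n_tests": n_tests2, "n_survivors": n_surv2}
    )
    rounds_log.append({"round": 3, "n_hits": len(final)})
    logger.info("hierarchical rounds 2-3: %s", rounds_log[-2:])
    final.sort(key=lambda c: (c.p_value, -c.cv_ba, c.ids))
    return HierarchicalResult(final, rounds_log)


def _make_plan(is_case: np.ndarray, n_folds: int, seed: int) -> CVPlan:
    from .engine import make_cv_plan

    return make_cv_plan(is_case, n_folds=n_folds, seed=seed)


def _recovered_region(
    sel: np.ndarray,
    partition: WindowPartition,
    window_ids: Iterable[int],
    stride: int,
    n_markers: int,
) -> np.ndarray:
    """Original marker indices spanned by coarse windows, hidden ones restored."""
    pieces = []
    for w in sorted(window_ids):
        start, end = partition.intervals[w]
        lo = sel[start]
        hi = min(int(sel[end - 1]) + stride, n_markers)
        pieces.append(np.arange(lo, hi))
    return np.unique(np.concatenate(pieces))


def _final_mdr_pairs(
    values: np.ndarray,
    is_case: np.ndarray,
    markers: np.ndarray,
    plan: CVPlan,
    alpha: float,
    seed: int,
    schedule: Sequence[tuple[int, float]] | None,
    seen: set[tuple[int, int]],
) -> list[ModelCandidate]:
    pairs = [
        p for p in itertools.combinations(markers.tolist(), 2) if p not in seen
    ]
    seen.update(pairs)
    if not pairs:
        return []
    bonf = bonferroni_threshold(alpha, len(pairs))
    observed = np.array(
        [mdr_cv_ba_batch(values, p, plan, is_case[None, :])[0] for p in pairs]
    )
    sched = _schedule_for(bonf, schedule)
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    hits = []
    for j, pair in enumerate(pairs):
        rng = np.random.default_rng(children[j])
        exceed = 0
        done = 0
        abandoned = False
        for cum, threshold in sched:
            while done < cum:
                m = min(_PERM_CHUNK, cum - done)
                Y = _perm_rows(rng, is_case, m)
                bas = mdr_cv_ba_batch(values, pair, plan, Y)
                exceed += int((bas >= observed[j]).sum())
                done += m
            p = (exceed + 1) / (done + 1)
            if p > threshold:
                abandoned = True
                break
        if not abandoned and p <= bonf:
            hits.append(
                ModelCandidate(
                    pair, "markers", float(observed[j]),
                    p_value=float(p), n_perm=done, significant=True,
                )
            )
    return hits
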