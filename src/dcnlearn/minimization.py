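"""Minimizing classifier inputs while holding near-benchmark learnability.

The full input space is 35 candidates (5 signal features x 7 electrodes).
Exhausting all subsets of sizes 3-6 over 35 candidates would take over two
million learnability evaluations, so the search uses an *adapted* sequential
forward selection (SFS): candidates rejected in one round stay in the pool
and are re-tested in every later round (after a new best subset is
established), and the search stops as soon as the current subset's
learnability is statistically indistinguishable from the benchmark.

Two candidate orderings steer the search:

- ``input_rank``: candidates in descending order of their single-input
  learnability;
- ``electrode_rank``: electrodes ordered by the mean learnability of their
  five single-input candidates; candidates emitted electrode block by
  electrode block (all of the best electrode's features first), within a
  block by single-input rank.  This prioritizes few-electrode solutions.

On small spaces (e.g. the 10 candidates of the two best electrodes, where
sizes 3-6 give 792 subsets) exhaustive enumeration is feasible and serves
as the optimality reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .features import SF_NAMES
from .learnability import (
    ClassifierSpec,
    LearnabilityResult,
    PartitionScheme,
    near_benchmark,
    rank_results,
    run_learnability,
    CHANCE_LEVEL,
)

__all__ = [
    "ALL_CANDIDATES",
    "SelectionTrace",
    "single_feature_grid",
    "order_candidates",
    "adapted_sfs",
    "exhaustive_subsets",
    "count_subsets",
    "candidate_name",
]

#: The full 35-candidate space: (electrode index, SF name).
ALL_CANDIDATES: tuple[tuple[int, str], ...] = tuple(
    (e, sf) for e in range(1, 8) for sf in SF_NAMES
)


def candidate_name(candidate: tuple[int, str]) -> str:
    e, sf = candidate
    return f"e{e}_{sf}"


@dataclass
class SelectionTrace:
    """Ordered record of an adapted-SFS run.

    ``rounds`` holds one entry per round: the candidate sets tested (with
    their results) and which candidate was accepted.  The terminal set
    either reaches near-benchmark learnability (``reached_benchmark``) or
    the pool was exhausted.
    """

    strategy: str
    rounds: list[dict] = field(default_factory=list)
    terminal_set: list[tuple[int, str]] = field(default_factory=list)
    terminal_result: LearnabilityResult | None = None
    terminal_p: float | None = None
    reached_benchmark: bool = False
    degenerate_benchmark: bool = False

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "rounds": [
                {
                    "tested": [
                        {
                            "candidates": [list(c) for c in t["candidates"]],
                            "fl_mean": t["result"].fl_mean,
                            "fl_sem": t["result"].fl_sem,
                        }
                        for t in rnd["tested"]
                    ],
                    "accepted": list(rnd["accepted"]),
                }
                for rnd in self.rounds
            ],
            "terminal_set": [list(c) for c in self.terminal_set],
            "terminal_fl": (
                None
                if self.terminal_result is None
                else [self.terminal_result.fl_mean, self.terminal_result.fl_sem]
            ),
            "terminal_p": self.terminal_p,
            "reached_benchmark": self.reached_benchmark,
            "degenerate_benchmark": self.degenerate_benchmark,
        }


def single_feature_grid(
    table: pd.DataFrame,
    scheme: PartitionScheme | str = "WIA",
    spec: ClassifierSpec | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    candidates: tuple[tuple[int, str], ...] = ALL_CANDIDATES,
) -> dict[tuple[int, str], LearnabilityResult]:
    """Learnability of every single SF/electrode candidate on its own."""
    grid = {}
    for i, cand in enumerate(candidates):
        grid[cand] = run_learnability(
            table,
            [cand],
            scheme=scheme,
            spec=spec,
            n_repeats=n_repeats,
            seed=int(np.random.SeedSequence((int(seed), i, 0x6D)).generate_state(1)[0]),
            descriptor=candidate_name(cand),
        )
    return grid


def order_candidates(
    grid: dict[tuple[int, str], LearnabilityResult], strategy: str
) -> list[tuple[int, str]]:
    """Candidate ordering for the SFS.

    ``input_rank`` ranks the candidates globally by their single-input
    learnability (mean desc, SEM asc, name).  ``electrode_rank`` orders
    electrodes by the mean learnability of their candidates (ties broken by
    the electrode's best single-candidate learnability, then by electrode
    index) and emits each electrode's candidates as a block, within-block by
    single-input rank.
    """
    if strategy == "input_rank":
        ranked = rank_results(list(grid.values()))
        by_name = {candidate_name(c): c for c in grid}
        return [by_name[r.descriptor] for r in ranked]
    if strategy == "electrode_rank":
        electrodes = sorted({e for e, _ in grid})
        stats = []
        for e in electrodes:
            results = [grid[c] for c in grid if c[0] == e]
            mean_fl = float(np.mean([r.fl_mean for r in results]))
            best_fl = float(max(r.fl_mean for r in results))
            stats.append((-mean_fl, -best_fl, e))
        ordered_electrodes = [e for *_, e in sorted(stats)]
        out = []
        for e in ordered_electrodes:
            block = rank_results([grid[c] for c in grid if c[0] == e])
            by_name = {candidate_name(c): c for c in grid if c[0] == e}
            out.extend(by_name[r.descriptor] for r in block)
        return out
    raise ValueError(f"unknown strategy {strategy!r}")


def adapted_sfs(
    table: pd.DataFrame,
    strategy: str,
    benchmark: LearnabilityResult,
    scheme: PartitionScheme | str = "WIA",
    spec: ClassifierSpec | None = None,
    grid: dict[tuple[int, str], LearnabilityResult] | None = None,
    candidates: tuple[tuple[int, str], ...] = ALL_CANDIDATES,
    n_repeats: int = 10,
    grid_repeats: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> SelectionTrace:
    """Adapted sequential forward selection toward benchmark learnability.

    Each round evaluates ``current_set + {c}`` for every candidate still in
    the pool, in the strategy's ordering, and accepts the best extension
    (learnability rank order; ties go to the earlier-ordered candidate).
    Rejected candidates are never pruned — they are re-tested in every
    subsequent round once a new best subset is established.  The search
    terminates when the accepted set is near-benchmark (paired t-test
    p >= alpha against the benchmark's per-animal values) or the pool is
    exhausted.

    A benchmark whose learnability is itself at chance level cannot anchor
    the stopping rule; the trace is then flagged ``degenerate_benchmark``
    (the search still runs, terminating only on pool exhaustion or when the
    t-test cannot distinguish the candidate from the chance-level benchmark).
    """
    if benchmark.per_animal_fl is None:
        raise ValueError("benchmark must carry per-animal FL values")
    trace = SelectionTrace(strategy=strategy)
    if benchmark.fl_mean <= CHANCE_LEVEL + 3.0 * max(benchmark.fl_sem, 1e-9):
        trace.degenerate_benchmark = True
    if grid is None:
        grid = single_feature_grid(
            table, scheme, spec, grid_repeats or n_repeats, seed, candidates
        )
    ordering = order_candidates(grid, strategy)
    pool = list(ordering)
    current: list[tuple[int, str]] = []
    current_result: LearnabilityResult | None = None
    round_idx = 0
    while pool:
        tested = []
        for cand in pool:
            trial_set = current + [cand]
            res = run_learnability(
                table,
                trial_set,
                scheme=scheme,
                spec=spec,
                n_repeats=n_repeats,
                seed=int(
                    np.random.SeedSequence(
                        (int(seed), round_idx, ordering.index(cand), 0x5F5)
                    ).generate_state(1)[0]
                ),
                descriptor="+".join(candidate_name(c) for c in trial_set),
            )
            tested.append({"candidates": tuple(trial_set), "result": res})
        # best extension: FL rank order, ties to the earlier-ordered candidate
        best = min(
            tested,
            key=lambda t: (
                -t["result"].fl_mean,
                t["result"].fl_sem,
                ordering.index(t["candidates"][-1]),
            ),
        )
        accepted = best["candidates"][-1]
        current = list(best["candidates"])
        current_result = best["result"]
        pool.remove(accepted)
        trace.rounds.append({"tested": tested, "accepted": accepted})
        is_near, p = near_benchmark(current_result, benchmark, alpha)
        if is_near:
            trace.reached_benchmark = True
            trace.terminal_p = p
            break
        trace.terminal_p = p
        round_idx += 1
    trace.terminal_set = current
    trace.terminal_result = current_result
    return trace


def count_subsets(n_candidates: int, sizes) -> int:
    """Number of subsets of the given sizes from ``n_candidates`` items
    (closed-form binomial sums; sizes beyond n contribute 0)."""
    return sum(comb(n_candidates, k) for k in sizes if 0 <= k <= n_candidates)


def exhaustive_subsets(
    candidates: list[tuple[int, str]],
    sizes,
    table: pd.DataFrame | None = None,
    scheme: PartitionScheme | str = "WIA",
    spec: ClassifierSpec | None = None,
    n_repeats: int = 3,
    rescore_top: int = 10,
    rescore_repeats: int = 10,
    seed: int = 0,
) -> tuple[int, LearnabilityResult | None]:
    """Count — and optionally evaluate — all subsets of the given sizes.

    The count is always the exact binomial sum.  When a feature table is
    supplied, every subset is scored with ``n_repeats`` learnability repeats
    (reduced by default for tractability) and the ``rescore_top`` best are
    re-scored at ``rescore_repeats`` repeats; the overall best (by
    learnability rank order) is returned alongside the count.
    """
    sizes = sorted(set(int(k) for k in sizes))
    total = count_subsets(len(candidates), sizes)
    if table is None or total == 0:
        return total, None
    results = []
    i = 0
    for k in sizes:
        if k > len(candidates):
            continue
        for subset in combinations(candidates, k):
            res = run_learnability(
                table,
                list(subset),
                scheme=scheme,
                spec=spec,
                n_repeats=n_repeats,
                seed=int(
                    np.random.SeedSequence((int(seed), i, 0xE8)).generate_state(1)[0]
                ),
                descriptor="+".join(candidate_name(c) for c in subset),
            )
            results.append((subset, res))
            i += 1
    ranked = rank_results([r for _, r in results])
    by_desc = {r.descriptor: s for s, r in results}
    finalists = ranked[: max(1, rescore_top)]
    rescored = []
    for j, res in enumerate(finalists):
        subset = by_desc[res.descriptor]
        rescored.append(
            run_learnability(
                table,
                list(subset),
                scheme=scheme,
                spec=spec,
                n_repeats=rescore_repeats,
                seed=int(
                    np.random.SeedSequence((int(seed), j, 0xF9)).generate_state(1)[0]
                ),
                descriptor=res.descriptor,
            )
        )
    best = rank_results(rescored)[0]
    return total, best
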