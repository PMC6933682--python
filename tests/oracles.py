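"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming /
binary-search code paths: alignment scores come from exhaustive
enumeration of all global alignments, affinity percentiles from the
literal delta-sum definition.
"""

from __future__ import annotations

import numpy as np


def brute_force_align_score(q: str, r: str, params) -> float:
    """Optimal global alignment score by exhaustive enumeration.

    Scores every possible global alignment (exponentially many; keep
    len <= 8) with affine gap cost ``gap_open + L * gap_extend`` per
    gap run; with ``free_end_gaps`` a run touching the first or last
    alignment column is free.
    """
    match, mismatch = params.match, params.mismatch
    open_, ext = params.gap_open, params.gap_extend
    free = params.free_end_gaps
    amb = params.ambiguous_score
    m, n = len(q), len(r)
    best = [-np.inf]

    def pair(a: str, b: str) -> float:
        a = "T" if a == "U" else a
        b = "T" if b == "U" else b
        if a not in "ACGT" or b not in "ACGT":
            return amb
        return match if a == b else mismatch

    def commit(score, kind, run_cost, run_leading):
        if kind is None:
            return score
        return score if (free and run_leading) else score - run_cost

    def rec(i, j, score, kind, run_cost, run_leading):
        if i == m and j == n:
            # run in progress here is trailing
            total = score if (kind is None or free) else score - run_cost
            if total > best[0]:
                best[0] = total
            return
        if i < m and j < n:
            s2 = commit(score, kind, run_cost, run_leading) + pair(q[i], r[j])
            rec(i + 1, j + 1, s2, None, 0.0, False)
        if i < m:  # gap in reference, consumes q[i]
            if kind == "r":
                rec(i + 1, j, score, "r", run_cost + ext, run_leading)
            else:
                s2 = commit(score, kind, run_cost, run_leading)
                rec(i + 1, j, s2, "r", open_ + ext, i + j == 0)
        if j < n:  # gap in query, consumes r[j]
            if kind == "q":
                rec(i, j + 1, score, "q", run_cost + ext, run_leading)
            else:
                s2 = commit(score, kind, run_cost, run_leading)
                rec(i, j + 1, s2, "q", open_ + ext, i + j == 0)

    rec(0, 0, 0.0, None, 0.0, False)
    return float(best[0])


def brute_force_affinity(background_scores: np.ndarray, query_score: float) -> float:
    """Literal percentile definition: mean of delta(score >= r_i)."""
    bg = np.asarray(background_scores, dtype=float)
    return float(np.mean(query_score >= bg))


def brute_force_pwm_score(log_odds: np.ndarray, idx: np.ndarray) -> float:
    """Max-over-windows PWM score by explicit window loop."""
    m = log_odds.shape[0]
    L = len(idx)
    return max(
        sum(log_odds[k, idx[off + k]] for k in range(m)) for off in range(L - m + 1)
    )
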