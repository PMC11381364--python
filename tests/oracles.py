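"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where feasible, the libraries)
they check: the aligner oracle is a plain edit-distance dynamic program, the
Fisher oracle a hypergeometric tail built from ``math.comb``, and the BH
oracle a literal step-up procedure.
"""

from __future__ import annotations

from math import comb

import numpy as np


def u_indel_dp(read: str, template: str) -> tuple[int, list[int]] | None:
    """Minimum-cost alignment of ``read`` to ``template`` allowing only U indels.

    Non-U characters must match one-to-one; inserting a U from the read or
    deleting a U from the template each cost 1.  Returns ``(cost, gap_counts)``
    where ``gap_counts[j]`` is the number of read Us placed in the template
    gap after template non-U character ``j`` (j = 0: before the first), or
    ``None`` if no alignment exists (backbone mismatch).
    """
    n, m = len(read), len(template)
    INF = float("inf")
    cost = [[INF] * (m + 1) for _ in range(n + 1)]
    cost[0][0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            c = cost[i][j]
            if c == INF:
                continue
            if i < n and j < m and read[i] == template[j]:
                step = 1 if read[i] == "U" else 0  # matching a U costs nothing
                if c < cost[i + 1][j + 1]:
                    cost[i + 1][j + 1] = c
            if i < n and read[i] == "U" and c + 1 < cost[i + 1][j]:
                cost[i + 1][j] = c + 1  # insert read U
            if j < m and template[j] == "U" and c + 1 < cost[i][j + 1]:
                cost[i][j + 1] = c + 1  # delete template U
    if cost[n][m] == INF:
        return None
    # traceback: count read Us per backbone gap (preferring matches keeps the
    # per-gap totals unique because Us inside a gap are interchangeable)
    i, j = n, m
    ops: list[tuple[str, int, int]] = []
    while i > 0 or j > 0:
        c = cost[i][j]
        if (
            i > 0
            and j > 0
            and read[i - 1] == template[j - 1]
            and cost[i - 1][j - 1] == c
        ):
            ops.append(("match", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and read[i - 1] == "U" and cost[i - 1][j] == c - 1:
            ops.append(("ins", i - 1, j))
            i -= 1
        else:
            assert j > 0 and template[j - 1] == "U" and cost[i][j - 1] == c - 1
            ops.append(("del", i, j - 1))
            j -= 1
    ops.reverse()
    n_backbone = sum(1 for ch in template if ch != "U")
    gaps = [0] * (n_backbone + 1)
    seen_backbone = 0
    for op, ri, tj in ops:
        if op == "del":
            continue
        if read[ri] == "U":
            gaps[seen_backbone] += 1
        else:
            seen_backbone += 1
    return int(cost[n][m]), gaps


def hypergeom_tail(k_obs: int, K: int, n: int, N: int) -> float:
    """P(X >= k_obs) for X ~ Hypergeom(N, K, n), via exact binomials."""
    denom = comb(N, n)
    upper = min(K, n)
    return sum(comb(K, k) * comb(N - K, n - k) for k in range(k_obs, upper + 1)) / denom


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up recipe."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adj[idx] = running_min
    return adj
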