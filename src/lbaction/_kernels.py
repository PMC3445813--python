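"""Fused numba kernel for the simulation-based fitting objective.

One call evaluates one condition's n_sim races from pre-drawn noise and
accumulates the predicted RT-bin and selection counts in a single pass,
avoiding the large temporaries of the vectorised path.  The kernel is the
performance core of the fitter only; the public simulation API
(:mod:`lbaction.simulate`) keeps the plain numpy implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["condition_counts"]


@njit(cache=True)
def condition_counts(
    valid,  # (n, k) int64 action ids; column 0 is the modulated accumulator
    z,  # (n, k) standard normal draws
    u,  # (n, k) uniform draws
    mu4,  # (4,) mean rates by action id (specified-equal already applied)
    sd4,  # (4,) rate SDs by action id
    c04,  # (4,) start ranges by action id
    b,  # threshold
    t0,  # non-decision time
    rate_ratio,  # condition ratio for the mean rate (1.0 if unmodulated)
    b_ratio,  # condition ratio for the threshold
    t0_ratio,  # condition ratio for the non-decision time
    scope_all,  # ratios multiply all columns, not just column 0
    rep_cat,  # count column-0 (repetition) wins in their own category
    deadline,
    edges,  # (5,) observed RT quantiles
    bin_counts,  # (6,) output, zeroed by caller
    sel_counts,  # (5,) output, zeroed by caller: [repetition, finger 0..3]
):
    """Race the accumulators and histogram responded trials.

    Finishing time of an accumulator is (b_eff - u*c0)/rate for a positive
    rate, 0 when the start point is at/above threshold, and infinite for a
    non-positive rate.  Returns the number of responded trials.
    """
    n, k = valid.shape
    n_resp = 0
    for i in range(n):
        best_ft = np.inf
        best_j = -1
        for j in range(k):
            a = valid[i, j]
            mod = scope_all or j == 0
            rate = mu4[a] * (rate_ratio if mod else 1.0) + sd4[a] * z[i, j]
            gap = b * (b_ratio if mod else 1.0) - u[i, j] * c04[a]
            if gap <= 0.0:
                ft = 0.0
            elif rate > 0.0:
                ft = gap / rate
            else:
                ft = np.inf
            if ft < best_ft:
                best_ft = ft
                best_j = j
        if best_j < 0 or best_ft == np.inf:
            continue
        mod = scope_all or best_j == 0
        rt = best_ft + t0 * (t0_ratio if mod else 1.0)
        if rt > deadline:
            continue
        n_resp += 1
        if rep_cat and best_j == 0:
            sel_counts[0] += 1
        else:
            sel_counts[1 + valid[i, best_j]] += 1
        if rt < edges[0]:
            bin_counts[0] += 1
        elif rt < edges[1]:
            bin_counts[1] += 1
        elif rt < edges[2]:
            bin_counts[2] += 1
        elif rt < edges[3]:
            bin_counts[3] += 1
        elif rt < edges[4]:
            bin_counts[4] += 1
        else:
            bin_counts[5] += 1
    return n_resp
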