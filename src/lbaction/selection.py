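"""Group-level model selection and nonparametric comparisons.

Per-participant BIC values are summed across the group to score each
design; lower summed BIC wins.  Competing designs are compared with the
exact binomial sign test and the one-sample Wilcoxon signed-rank test
(zeros dropped, midranks for ties; exact p for n <= 25, else normal
approximation with continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignComparison", "rank_designs", "sign_test", "wilcoxon_signed_rank"]


@dataclass
class DesignComparison:
    """Ranking of designs by summed BIC across participants."""

    bic_matrix: pd.DataFrame  # participants x designs
    summed_bic: pd.Series
    ranking: list  # design labels, best (lowest summed BIC) first
    pairwise: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "design": self.summed_bic.index,
                "summed_bic": self.summed_bic.values,
                "delta_bic": self.summed_bic.values - self.summed_bic.min(),
            }
        )
        order = {d: i + 1 for i, d in enumerate(self.ranking)}
        df["rank"] = df["design"].map(order)
        return df.sort_values("rank").reset_index(drop=True)


def rank_designs(
    bic_matrix: pd.DataFrame,
    parameter_counts: dict | None = None,
    pairwise: bool = False,
) -> DesignComparison:
    """Rank designs by ascending summed BIC.

    ``bic_matrix`` is participants x designs with no missing entries.
    Ties are broken by fewer parameters (when ``parameter_counts`` maps
    design label -> count), then by design order.
    """
    if bic_matrix.isna().any().any():
        missing = [
            (p, d)
            for p in bic_matrix.index
            for d in bic_matrix.columns
            if pd.isna(bic_matrix.loc[p, d])
        ]
        raise ValueError(f"missing fits for participant/design pairs: {missing}")
    summed = bic_matrix.sum(axis=0)
    cols = list(bic_matrix.columns)

    def key(d):
        k = parameter_counts.get(d, 0) if parameter_counts else 0
        return (summed[d], k, cols.index(d))

    ranking = sorted(cols, key=key)
    pw = None
    if pairwise:
        rows = []
        best = ranking[0]
        for other in ranking[1:]:
            diff = (bic_matrix[other] - bic_matrix[best]).to_numpy(dtype=float)
            s_stat, s_p = sign_test(diff)
            rows.append(
                {
                    "design_a": best,
                    "design_b": other,
                    "test": "sign",
                    "statistic": s_stat,
                    "p_value": s_p,
                }
            )
        pw = pd.DataFrame(rows)
    return DesignComparison(
        bic_matrix=bic_matrix, summed_bic=summed, ranking=ranking, pairwise=pw
    )


def sign_test(paired_differences) -> tuple[int, float]:
    """Exact two-sided binomial sign test on paired differences.

    Zeros are dropped; the statistic is the count of positive differences
    among the nonzero ones, and the p-value is the exact two-sided
    binomial probability under p = 1/2 (capped at 1).
    """
    d = np.asarray(paired_differences, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("sign test requires at least one nonzero difference")
    n_pos = int((nz > 0).sum())
    p = stats.binomtest(n_pos, nz.size, 0.5, alternative="two-sided").pvalue
    return n_pos, float(min(p, 1.0))


def wilcoxon_signed_rank(
    values, null_location: float = 0.0, exact_max_n: int = 25
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test against a null location.

    Deviations of zero are dropped (Wilcoxon's rule) and ties receive
    midranks.  The statistic is W+ (the sum of ranks of positive
    deviations).  The p-value is exact for n <= ``exact_max_n`` when there
    are no tied absolute deviations, otherwise a normal approximation with
    continuity and tie correction is used.
    """
    d = np.asarray(values, dtype=float) - null_location
    d = d[d != 0]
    if d.size < 1:
        raise ValueError("all deviations are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    mode = "exact" if (d.size <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=(mode == "approx"),
        alternative="two-sided",
        method=mode,
    )
    # scipy reports min(W+, W-); convert to W+ for reporting
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(min(res.pvalue, 1.0))
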