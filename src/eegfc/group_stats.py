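"""Between-group comparisons with false-discovery-rate control.

Every scalar feature (an edge weight, a graph metric, a state entropy, a
cross-band global metric) is compared between the two groups with an
independent-sample t-test (pooled variance by default, Welch optional), and
p-values are corrected within each analysis family by the
Benjamini-Hochberg step-up procedure. Both raw and adjusted p-values are
always reported so alternative correction scopes can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "two_sample_t", "fdr_bh", "compare_cohorts", "significance_stars"]


@dataclass
class GroupComparison:
    """Per-family test results as a tidy table.

    ``table`` has one row per item with columns item, mean_a, mean_b, t, df,
    p, q, significant, direction (sign of mean_a - mean_b).
    """

    family_id: str
    group_a: str
    group_b: str
    q_star: float
    table: pd.DataFrame = field(repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_items(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "item"])


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, p, df).

    Degenerate zero-variance inputs are resolved rather than propagated as
    NaN: equal means give (0, 1), unequal means a signed infinite t with
    p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, 1.0, df
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, df
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def fdr_bh(p: np.ndarray, q_star: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, rejection mask)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_star, method="fdr_bh")
    return q, reject


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * for 0.01 < p < 0.05, ** for 0.001 < p < 0.01."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_cohorts(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    q_star: float = 0.05,
    variant: str = "pooled",
    family_col: str = "family",
) -> list[GroupComparison]:
    """Family-wise group comparison of a tidy feature table.

    ``features`` must have columns subject, group, ``family_col``, item,
    value, with every subject contributing each (family, item) exactly once.
    One :class:`GroupComparison` is returned per family, FDR-corrected
    within that family. Results are invariant to the order of subjects.
    """
    required = {"subject", "group", family_col, "item", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    out = []
    for family, fam in features.groupby(family_col, sort=True):
        rows = []
        for item, sub in fam.groupby("item", sort=True):
            va = sub.loc[sub["group"] == group_a, ["subject", "value"]]
            vb = sub.loc[sub["group"] == group_b, ["subject", "value"]]
            for g, v in ((group_a, va), (group_b, vb)):
                if v["subject"].duplicated().any():
                    dup = v.loc[v["subject"].duplicated(), "subject"].iloc[0]
                    raise ValueError(
                        f"subject {dup!r} contributes item {item!r} more than once"
                    )
            a = np.sort(va["value"].to_numpy())
            b = np.sort(vb["value"].to_numpy())
            t, p, df = two_sample_t(a, b, variant=variant)
            rows.append(
                {
                    "item": item,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t": t,
                    "df": df,
                    "p": p,
                    "direction": int(np.sign(a.mean() - b.mean())),
                }
            )
        table = pd.DataFrame(rows)
        q, reject = fdr_bh(table["p"].to_numpy(), q_star=q_star)
        table["q"] = q
        table["significant"] = reject
        table["stars"] = table["p"].map(significance_stars)
        out.append(
            GroupComparison(
                family_id=str(family),
                group_a=group_a,
                group_b=group_b,
                q_star=q_star,
                table=table,
            )
        )
    return out
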