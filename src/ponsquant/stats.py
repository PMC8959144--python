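"""Group statistics for count, width and AUC tables.

The comparison scheme used throughout: two-way ANOVA (genotype × region)
for panelled profiles, one-way ANOVA for per-animal summaries, and
Bonferroni correction for the family of pairwise contrasts.  Sums of
squares are Type II, appropriate for the unbalanced animal numbers typical
of mouse cohorts.  Significance tiers follow *P<0.05 and ***P<0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p) over a family of size m.

    ``m`` defaults to the number of p-values; an externally declared family
    must be at least that large.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    elif m < p.size:
        raise ValueError("declared family smaller than the number of p-values")
    return np.minimum(1.0, m * p)


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Marker tiering: *** for P<0.005, * for P<alpha, else ns."""
    if p < 0.005:
        return "***"
    if p < alpha:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    """F tests per factor plus Bonferroni-corrected pairwise contrasts.

    ``factors`` maps factor name → (F, df_num, df_den, p); ``comparisons``
    has one row per contrast with raw and adjusted p; ``family_size`` is
    the m used for the Bonferroni family.
    """

    factors: dict[str, tuple[float, int, int, float]]
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05
    family_size: int = 0

    def p_value(self, factor: str) -> float:
        return self.factors[factor][3]


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    """Treatment-coded dummy columns (drop first level)."""
    return (codes[:, None] == np.arange(1, k)).astype(float)


def _f_p(ss: float, df: int, ss_res: float, df_res: int) -> tuple[float, float]:
    """F statistic and p; a zero-variance (degenerate) effect reports p=1."""
    ss = max(ss, 0.0)
    if df_res <= 0 or ss_res <= 0:
        if ss <= 1e-12:  # no effect variance either: fully degenerate
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss / df) / (ss_res / df_res)
    return F, float(sps.f.sf(F, df, df_res))


def _pairwise_t(
    values: np.ndarray, codes: np.ndarray, labels: list, prefix: str = ""
) -> list[dict]:
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        a, b = values[codes == i], values[codes == j]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = sps.ttest_ind(a, b)
        if np.isnan(p):  # zero pooled variance
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        rows.append(
            {
                "contrast": f"{prefix}{labels[i]} vs {labels[j]}",
                "t": float(t) if not np.isnan(t) else 0.0,
                "raw_p": float(p),
            }
        )
    return rows


def _finish_comparisons(rows: list[dict], alpha: float) -> tuple[pd.DataFrame, int]:
    if not rows:
        return pd.DataFrame(columns=["contrast", "t", "raw_p", "adj_p", "stars"]), 0
    comp = pd.DataFrame(rows)
    m = len(comp)
    comp["adj_p"] = bonferroni(comp["raw_p"].to_numpy(), m)
    comp["stars"] = [significance_stars(p, alpha) for p in comp["adj_p"]]
    return comp, m


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "region",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Factor and interaction SS come from residual differences of nested
    least-squares fits (SS_A = RSS(B) − RSS(A+B), etc.), which equals the
    classical partition in balanced designs and Type II in unbalanced
    ones.  Pairwise factor-A contrasts within each level of factor B are
    Bonferroni-corrected as one family.  Requires ≥2 levels per factor and
    no empty cells.
    """
    y = table[value].to_numpy(dtype=float)
    a_labels, a_codes = np.unique(table[factor_a].to_numpy(), return_inverse=True)
    b_labels, b_codes = np.unique(table[factor_b].to_numpy(), return_inverse=True)
    ka, kb = len(a_labels), len(b_labels)
    if ka < 2 or kb < 2:
        raise ValueError("two-way ANOVA requires ≥2 levels per factor")
    cells = np.bincount(a_codes * kb + b_codes, minlength=ka * kb)
    if (cells == 0).any():
        raise ValueError("empty factor cell: interaction is not estimable")
    n = len(y)
    ones = np.ones((n, 1))
    Da = _dummies(a_codes, ka)
    Db = _dummies(b_codes, kb)
    Dab = (Da[:, :, None] * Db[:, None, :]).reshape(n, -1)
    rss_a = _rss(y, np.hstack([ones, Da]))
    rss_b = _rss(y, np.hstack([ones, Db]))
    rss_ab = _rss(y, np.hstack([ones, Da, Db]))
    rss_full = _rss(y, np.hstack([ones, Da, Db, Dab]))
    # snap round-off residue to exact zero so noise-free designs report the
    # degenerate limits (p = 0 for a real effect, p = 1 for an absent one)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-10 * max(ss_total, 1e-300)
    rss_a, rss_b, rss_ab, rss_full = (
        0.0 if v < tol else v for v in (rss_a, rss_b, rss_ab, rss_full)
    )
    df_res = n - ka * kb
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need >1 obs per cell)")
    effects = {
        factor_a: (rss_b - rss_ab, ka - 1),
        factor_b: (rss_a - rss_ab, kb - 1),
        "interaction": (rss_ab - rss_full, (ka - 1) * (kb - 1)),
    }
    factors = {}
    for name, (ss, df) in effects.items():
        F, p = _f_p(ss, df, rss_full, df_res)
        factors[name] = (F, df, df_res, p)
    rows: list[dict] = []
    for bi, blab in enumerate(b_labels):
        sel = b_codes == bi
        rows.extend(
            _pairwise_t(y[sel], a_codes[sel], list(a_labels), prefix=f"{blab}: ")
        )
    comp, m = _finish_comparisons(rows, alpha)
    return AnovaResult(factors=factors, comparisons=comp, alpha=alpha, family_size=m)


def one_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise t contrasts."""
    y = table[value].to_numpy(dtype=float)
    labels, codes = np.unique(table[group].to_numpy(), return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("one-way ANOVA requires ≥2 groups")
    counts = np.bincount(codes, minlength=k)
    if (counts < 2).any():
        raise ValueError("each group needs ≥2 observations")
    n = len(y)
    grand = y.mean()
    means = np.array([y[codes == i].mean() for i in range(k)])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(sum(np.sum((y[codes == i] - means[i]) ** 2) for i in range(k)))
    F, p = _f_p(ss_between, k - 1, ss_within, n - k)
    comp, m = _finish_comparisons(_pairwise_t(y, codes, list(labels)), alpha)
    return AnovaResult(
        factors={group: (F, k - 1, n - k, p)},
        comparisons=comp,
        alpha=alpha,
        family_size=m,
    )
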