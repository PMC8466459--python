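"""Sensory questionnaire scales and the statistics linking them to physiology.

Covers the acceptance/preference analyses of the protocol:

* NPS categorisation of the 0-10 recommendation scale (promoter 9-10,
  passively satisfied 7-8, detractor 0-6);
* selection of within-subject *opposed-score* product pairs (global
  acceptance difference of at least five points on the 9-point hedonic
  scale) and the sign-fraction statistic over the per-pair feature
  differences low-minus-high;
* a pairwise Wilcoxon matrix across products (signed-rank over subjects
  observed for both products, raw alpha = 0.01 as in the source
  analysis; optional Holm correction);
* Kendall tau-b repeatability of acceptance scores across sessions;
* preference rank sums with the Friedman statistic and the
  normal-approximation critical difference for pairwise rank-sum
  comparisons;
* per-product hedonic histograms and descriptive statistics.

Questionnaire tables are tidy DataFrames with columns
``subject, session, product, question, response``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "nps_categorize",
    "select_opposed_pairs",
    "attach_feature_diffs",
    "sign_fraction",
    "wilcoxon_matrix",
    "kendall_repeatability",
    "preference_rank_sums",
    "hedonic_summary",
    "RankSumResult",
]

GLOBAL_ACCEPTANCE = "global_acceptance"
OPPOSED_MIN_DIFF = 5
WILCOXON_ALPHA = 0.01
KENDALL_ALPHA = 0.05


def nps_categorize(score: int) -> str:
    """Place a 0-10 recommendation score in its NPS category."""
    if not float(score).is_integer() or not 0 <= score <= 10:
        raise ValueError(f"NPS score must be an integer in [0, 10], got {score}")
    s = int(score)
    if s >= 9:
        return "promoter"
    if s >= 7:
        return "passively_satisfied"
    return "detractor"


def select_opposed_pairs(
    table: pd.DataFrame,
    min_diff: int = OPPOSED_MIN_DIFF,
    question: str = GLOBAL_ACCEPTANCE,
) -> pd.DataFrame:
    """Within-subject-session product pairs with opposed acceptance scores.

    A pair qualifies when the two global-acceptance scores differ by at
    least ``min_diff`` points (difference of exactly 5 qualifies). Each
    pair is oriented high/low. Returns columns subject, session,
    product_high, product_low, score_high, score_low.
    """
    ga = table[table["question"] == question]
    if ga.empty:
        raise ValueError(f"no {question!r} responses in table")
    rows = []
    for (subject, session), grp in ga.groupby(["subject", "session"]):
        scores = dict(zip(grp["product"], grp["response"]))
        for a, b in combinations(sorted(scores), 2):
            if abs(scores[a] - scores[b]) >= min_diff:
                hi, lo = (a, b) if scores[a] > scores[b] else (b, a)
                rows.append(
                    {
                        "subject": subject,
                        "session": session,
                        "product_high": hi,
                        "product_low": lo,
                        "score_high": scores[hi],
                        "score_low": scores[lo],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "product_high", "product_low", "score_high", "score_low"],
    )


def attach_feature_diffs(
    pairs: pd.DataFrame,
    features: pd.DataFrame,
    feature_cols: tuple[str, ...] = ("lf_power", "hf_power", "lf_norm", "hf_norm"),
) -> pd.DataFrame:
    """Join per-window features onto opposed pairs as low-minus-high diffs.

    ``features`` must carry subject, session, product plus the feature
    columns. For each pair and each feature f the column ``f_diff`` is
    ``f(low product) - f(high product)``; pairs missing either window are
    dropped.
    """
    idx = features.set_index(["subject", "session", "product"])
    out = pairs.copy()
    keep = np.ones(len(out), dtype=bool)
    for col in feature_cols:
        diffs = []
        for i, r in out.iterrows():
            try:
                lo = idx.loc[(r["subject"], r["session"], r["product_low"]), col]
                hi = idx.loc[(r["subject"], r["session"], r["product_high"]), col]
                diffs.append(float(lo) - float(hi))
            except KeyError:
                diffs.append(np.nan)
        out[f"{col}_diff"] = diffs
        keep &= ~np.isnan(out[f"{col}_diff"])
    return out[keep].reset_index(drop=True)


def sign_fraction(pairs: pd.DataFrame, feature: str) -> float:
    """Fraction of opposed pairs with a strictly positive feature difference.

    Ties (zero difference) count as non-positive.
    """
    col = feature if feature in pairs.columns else f"{feature}_diff"
    if col not in pairs.columns:
        raise KeyError(f"feature column {feature!r} not found")
    vals = pairs[col].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("sign fraction undefined for an empty pair list")
    return float(np.mean(vals > 0))


def _pairwise_wilcoxon(a: np.ndarray, b: np.ndarray, paired: bool) -> float:
    if paired:
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def wilcoxon_matrix(
    values: pd.DataFrame,
    value_col: str,
    alpha: float = WILCOXON_ALPHA,
    paired: bool = True,
    min_n: int = 5,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Wilcoxon tests between products.

    ``values`` is tidy with subject, session, product and ``value_col``.
    For each unordered product pair a paired signed-rank test is run over
    the subject x session observations present for both products (or an
    unpaired rank-sum test with ``paired=False``). Cells with fewer than
    ``min_n`` observations are NaN. Returns the symmetric p-value matrix
    and the significance mask (p <= alpha; optionally Holm-corrected).
    """
    products = sorted(values["product"].unique())
    if len(products) < 2:
        raise ValueError("need at least 2 products")
    piv = values.pivot_table(
        index=["subject", "session"], columns="product", values=value_col, aggfunc="mean"
    )
    p = pd.DataFrame(np.nan, index=products, columns=products, dtype=float)
    raw = []
    cells = []
    for a, b in combinations(products, 2):
        if paired:
            sub = piv[[a, b]].dropna()
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            n = len(sub)
        else:
            xa = piv[a].dropna().to_numpy()
            xb = piv[b].dropna().to_numpy()
            n = min(len(xa), len(xb))
        if n < min_n:
            continue
        pv = _pairwise_wilcoxon(xa, xb, paired)
        p.loc[a, b] = p.loc[b, a] = pv
        raw.append(pv)
        cells.append((a, b))
    if holm and raw:
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[i]))
            adj[i] = running
        for (a, b), pv in zip(cells, adj):
            p.loc[a, b] = p.loc[b, a] = pv
    mask = p <= alpha
    return p, mask


def kendall_repeatability(scores_a, scores_b, alpha: float = KENDALL_ALPHA):
    """Kendall tau-b between paired per-subject scores of two sessions.

    Exact two-sided p for small tie-free samples, normal approximation
    otherwise (scipy's ``auto`` policy). Returns ``(tau, p, verdict)``
    with verdict ``correlated`` iff p <= alpha.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if len(a) < 4:
        raise ValueError(f"need at least 4 paired scores, got {len(a)}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("tau undefined for an all-constant score vector")
    res = stats.kendalltau(a, b, variant="b")
    tau, p = float(res.statistic), float(res.pvalue)
    return tau, p, ("correlated" if p <= alpha else "uncorrelated")


@dataclass
class RankSumResult:
    """Preference-ranking analysis: rank sums, Friedman test, pairwise calls."""

    rank_sums: pd.Series
    friedman_statistic: float
    friedman_p: float
    critical_difference: float
    significant_pairs: pd.DataFrame
    n_subjects: int
    n_dropped: int


def preference_rank_sums(rankings: pd.DataFrame, alpha: float = 0.05) -> RankSumResult:
    """Analyse complete preference rankings of k items.

    ``rankings``: one row per subject, one column per item, entries the
    rank (1 = most preferred .. k). Rows that are not a complete
    permutation of 1..k are dropped (count reported). Pairwise
    significance uses the normal-approximation critical difference for
    rank sums, ``z_{1-alpha/2} * sqrt(n k (k+1) / 6)``, alongside the
    Friedman test.
    """
    k = rankings.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    valid_rows = []
    n_dropped = 0
    expected = set(range(1, k + 1))
    for _, row in rankings.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.any(np.isnan(vals)) or set(vals.astype(int)) != expected:
            n_dropped += 1
        else:
            valid_rows.append(vals)
    if not valid_rows:
        raise ValueError("no complete ranking rows")
    R = np.asarray(valid_rows)
    n = len(R)
    sums = pd.Series(R.sum(axis=0), index=rankings.columns)
    if k >= 3:
        fstat, fp = stats.friedmanchisquare(*[R[:, j] for j in range(k)])
    else:
        # Friedman needs >= 3 treatments; two items reduce to a sign test.
        wins = np.sum(R[:, 0] < R[:, 1])
        fp = float(stats.binomtest(int(wins), n, 0.5).pvalue)
        fstat = float("nan")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    cd = float(z * np.sqrt(n * k * (k + 1) / 6.0))
    pairs = []
    for a, b in combinations(rankings.columns, 2):
        diff = abs(float(sums[a] - sums[b]))
        pairs.append({"item_a": a, "item_b": b, "rank_sum_diff": diff, "significant": diff > cd})
    return RankSumResult(
        rank_sums=sums,
        friedman_statistic=float(fstat),
        friedman_p=float(fp),
        critical_difference=cd,
        significant_pairs=pd.DataFrame(pairs),
        n_subjects=n,
        n_dropped=n_dropped,
    )


def hedonic_summary(
    table: pd.DataFrame,
    product: str,
    question: str = GLOBAL_ACCEPTANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-session 9-point histogram and descriptive stats for one product.

    Returns ``(histogram, stats)``: histogram has one row per scale point
    1..9 and one column per session; stats has per-session n, mean, sd.
    """
    sub = table[(table["question"] == question) & (table["product"] == product)]
    sessions = sorted(sub["session"].unique())
    hist = pd.DataFrame(0, index=range(1, 10), columns=sessions)
    for sess in sessions:
        counts = sub[sub["session"] == sess]["response"].value_counts()
        for point, c in counts.items():
            hist.loc[int(point), sess] = int(c)
    desc = (
        sub.groupby("session")["response"]
        .agg(n="count", mean="mean", sd=lambda x: float(np.std(x, ddof=0)))
        .reset_index()
    )
    return hist, desc
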