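"""Corroboration against researcher call labels and species-level tests.

Call names are classified as "musical" by case-insensitive keyword matching
(song, duet, trio, chorus, great, music, scale, coda, intro, interlude by
default); the index is then correlated with that binary label, compared
between labelled groups with a rank-sum test, and the species-level maxima
are compared across socioecological covariates (monogamy, wooded habitat,
arboreality, territoriality, group-size class) with Welch t-tests.  No
multiple-testing correction is applied by default, matching the exploratory
design; outputs carry an explicit flag plus an optional Holm column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_MUSICAL_KEYWORDS


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None
    effect: float | None = None
    n_a: int | None = None
    n_b: int | None = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect": self.effect,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "p_adjusted": "unadjusted",
        }
        row.update(self.extra)
        return row


def classify_call_names(
    metadata: pd.DataFrame, keywords: tuple[str, ...] = DEFAULT_MUSICAL_KEYWORDS
) -> pd.DataFrame:
    """Flag vocalizations whose researcher-given name contains a keyword.

    Case-insensitive substring match; the first keyword (in list order) found
    in the name is recorded.  Returns a table indexed by vocalization_id with
    ``musical_flag`` and ``matched_keyword``.
    """
    names = metadata.set_index("vocalization_id")["call_name"].fillna("")
    matched = []
    for name in names:
        low = str(name).lower()
        hit = next((kw for kw in keywords if kw.lower() in low), None)
        matched.append(hit)
    return pd.DataFrame(
        {
            "musical_flag": [m is not None for m in matched],
            "matched_keyword": [m if m is not None else "" for m in matched],
        },
        index=names.index,
    )


def index_label_correlation(
    index_values: pd.Series | np.ndarray,
    musical_flag: pd.Series | np.ndarray,
    method: str = "pearson_on_ranks",
) -> TestResult:
    """Correlation between an index and the binary musical label.

    ``pearson_on_ranks`` (default; Pearson of midrank-transformed values,
    identical to Spearman), ``pearson`` and ``spearman`` are available since
    the phrase "rank correlation with a binary label" admits several
    conventions.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(musical_flag, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 calls")
    if len(np.unique(y)) < 2:
        raise ValueError("both musical and non-musical calls are required")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method in ("pearson_on_ranks", "spearman"):
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        name=f"index_label_correlation[{method}]",
        statistic=float(r),
        p_value=float(p),
        effect=float(r),
        n_a=int(y.sum()),
        n_b=int(len(y) - y.sum()),
        extra={"n": len(x)},
    )


def _exact_ranksum_distribution(double_ranks: np.ndarray, n1: int) -> dict[int, int]:
    """Count, over all C(n, n1) group assignments, the rank-sum values.

    ``double_ranks`` are midranks times two (integers even under ties), so
    the dynamic program over (chosen count, running sum) enumerates the exact
    tie-aware permutation distribution of the first group's rank sum.
    """
    total = int(double_ranks.sum())
    # counts fit in int64: C(40, 20) ~ 1.4e11 is the largest possible total
    counts = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in double_ranks:
        r = int(r)
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return {s: int(c) for s, c in enumerate(counts[n1]) if c}


def ranksum_test(values_a, values_b) -> TestResult:
    """Two-sample Wilcoxon/Mann-Whitney rank-sum test with midrank ties.

    Reports U for the first group, plus W as the rank sum of the smaller
    group (first group on ties) — the convention is recorded in the output
    since W is software-dependent.  When n1*n2 <= 400 the p-values come from
    exact enumeration of the tie-aware permutation distribution; otherwise
    from the normal approximation with tie correction.  Two-sided p is
    2*min(tail) capped at 1; both one-sided tails are exposed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 <= n2:
        w = r1
        w_group = "a"
    else:
        w = ranks[n1:].sum()
        w_group = "b"

    if n1 * n2 <= 400:
        dist = _exact_ranksum_distribution(np.round(2 * ranks).astype(int), n1)
        total = sum(dist.values())
        s_obs = int(round(2 * r1))
        p_less = sum(c for s, c in dist.items() if s <= s_obs) / total
        p_greater = sum(c for s, c in dist.items() if s >= s_obs) / total
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        z = (u1 - mu) / sigma if sigma > 0 else 0.0
        p_less = float(stats.norm.cdf(z))
        p_greater = float(stats.norm.sf(z))
        method = "normal_approx"
    p_two = min(1.0, 2 * min(p_less, p_greater))
    return TestResult(
        name="ranksum",
        statistic=float(u1),
        p_value=p_two,
        effect=float(u1 - n1 * n2 / 2.0),
        n_a=n1,
        n_b=n2,
        extra={
            "U": float(u1),
            "U_prime": float(n1 * n2 - u1),
            "W": float(w),
            "w_convention": f"rank sum of smaller group ({w_group})",
            "p_less": p_less,
            "p_greater": p_greater,
            "method": method,
        },
    )


def welch_t_test(values_a, values_b) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided.

    The effect is mean(a) - mean(b).  Zero variance in both groups with
    equal means yields t = 0, p = 1; zero variance with unequal means is an
    error (the statistic is unbounded).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    effect = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if effect == 0:
            return TestResult("welch_t", 0.0, 1.0, df=float(len(a) + len(b) - 2),
                              effect=0.0, n_a=len(a), n_b=len(b))
        raise ValueError("zero variance in both groups with unequal means")
    se2a, se2b = va / len(a), vb / len(b)
    t = effect / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult("welch_t", float(t), float(p), df=float(df),
                      effect=float(effect), n_a=len(a), n_b=len(b))


def categorize_group_size(group_size, solitary: bool) -> str:
    """Class a species as solitary, small-group (2-6) or large-group (>6)."""
    if solitary:
        return "solitary"
    if group_size is None or (isinstance(group_size, float) and np.isnan(group_size)):
        return "unknown"
    if group_size < 2:
        return "solitary"
    if group_size <= 6:
        return "small"
    return "large"


def run_hypothesis_battery(species_summary: pd.DataFrame,
                           index_col: str = "max_ardi") -> list[TestResult]:
    """Welch t-tests of the species-level index across covariates.

    Binary covariates (monogamous, wooded, arboreal, territorial) compare
    True vs False species; group size compares small groups (2-6) against
    large and solitary species pooled.  Covariates with a single class are
    skipped with a notice in the result list.  P-values are deliberately
    unadjusted (flagged); Holm adjustment can be added downstream.
    """
    results: list[TestResult] = []
    df = species_summary.dropna(subset=[index_col])
    for cov in ("monogamous", "wooded", "arboreal", "territorial"):
        if cov not in df.columns:
            continue
        sub = df.dropna(subset=[cov])
        yes = sub.loc[sub[cov].astype(bool), index_col].to_numpy()
        no = sub.loc[~sub[cov].astype(bool), index_col].to_numpy()
        if len(yes) < 2 or len(no) < 2:
            results.append(
                TestResult(f"{cov}_skipped", float("nan"), float("nan"),
                           extra={"notice": "single class; test skipped"})
            )
            continue
        res = welch_t_test(yes, no)
        res.name = f"{index_col}~{cov}"
        results.append(res)
    if "group_size" in df.columns and "solitary" in df.columns:
        cats = [
            categorize_group_size(gs, bool(sol) if pd.notna(sol) else False)
            for gs, sol in zip(df["group_size"], df["solitary"])
        ]
        cats = pd.Series(cats, index=df.index)
        small = df.loc[cats == "small", index_col].to_numpy()
        other = df.loc[cats.isin(["large", "solitary"]), index_col].to_numpy()
        if len(small) >= 2 and len(other) >= 2:
            res = welch_t_test(small, other)
            res.name = f"{index_col}~small_group_vs_rest"
            results.append(res)
        else:
            results.append(
                TestResult("group_size_skipped", float("nan"), float("nan"),
                           extra={"notice": "single class; test skipped"})
            )
    return results


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional output column)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def tests_table(results: list[TestResult]) -> pd.DataFrame:
    table = pd.DataFrame([r.as_row() for r in results])
    valid = table["p_value"].notna()
    if valid.any():
        table.loc[valid, "p_holm"] = holm_adjust(table.loc[valid, "p_value"].to_numpy())
    return table


def ranking_table(
    index_table: pd.DataFrame,
    metadata: pd.DataFrame,
    name_contains: tuple[str, ...] | None = None,
    metrics: tuple[str, ...] = ("ardi", "syllables", "pc1_score", "log_sci"),
) -> pd.DataFrame:
    """Rank calls by each index (descending, minimum rank for ties).

    ``name_contains`` keeps only calls whose name contains any of the given
    substrings (case-insensitive), e.g. ("song", "duet").  The pc1_score is
    ranked on its canonicalized sign; its orientation relative to musicality
    should be read off the reported ARDI-PC1 correlation.
    """
    meta = metadata.set_index("vocalization_id")
    df = index_table.join(meta[["species", "genus", "call_name"]], how="left")
    if name_contains is not None:
        low = df["call_name"].fillna("").str.lower()
        mask = np.zeros(len(df), dtype=bool)
        for token in name_contains:
            mask |= low.str.contains(token.lower(), regex=False)
        df = df[mask]
        if df.empty:
            return df
    out = df[["genus", "species", "call_name"] + [m for m in metrics if m in df.columns]].copy()
    for m in metrics:
        if m in out.columns:
            out[f"rank_{m}"] = out[m].rank(ascending=False, method="min")
    return out.sort_values("rank_ardi") if "rank_ardi" in out.columns else out


DEFAULT_CONTEXT_MAP: dict[str, str] = {
    # keyword (substring of the free-text context) -> higher-order category
    "song": "display", "duet": "display", "display": "display", "chorus": "display",
    "territor": "territorial", "defense": "territorial", "loud": "territorial",
    "alarm": "alarm", "predator": "alarm", "warning": "alarm",
    "forag": "foraging", "food": "foraging", "feed": "foraging",
    "contact": "contact", "location": "contact", "isolat": "contact",
    "social": "social", "greet": "social", "groom": "social", "play": "social",
    "mating": "sociosexual", "copulat": "sociosexual", "sexual": "sociosexual",
    "infant": "infant care", "mother": "infant care",
    "aggress": "agonistic", "distress": "agonistic", "submiss": "agonistic",
    "threat": "agonistic",
}


def assign_context_categories(
    metadata: pd.DataFrame, context_map: dict[str, str] | None = None
) -> pd.Series:
    """Map free-text contexts into higher-order categories via keywords."""
    if context_map is None:
        context_map = DEFAULT_CONTEXT_MAP
    contexts = metadata.set_index("vocalization_id")["context"].fillna("")
    out = []
    for ctx in contexts:
        low = str(ctx).strip().lower()
        if not low:
            out.append("unlabeled")
            continue
        hit = next((cat for kw, cat in context_map.items() if kw in low), "other")
        out.append(hit)
    return pd.Series(out, index=contexts.index, name="context_category")


def context_summaries(
    index_table: pd.DataFrame,
    context_category: pd.Series,
    metrics: tuple[str, ...] = ("ardi", "sci", "syllables"),
) -> pd.DataFrame:
    """Per-category distribution summaries (n, mean, median, quartiles).

    The underlying numbers of a violin-style display; categories with fewer
    than 3 calls are flagged as too small to summarise meaningfully.
    """
    df = index_table.join(context_category, how="left")
    df["context_category"] = df["context_category"].fillna("unlabeled")
    rows = []
    for (cat, metric) in itertools.product(
        sorted(df["context_category"].unique()), metrics
    ):
        if metric not in df.columns:
            continue
        vals = df.loc[df["context_category"] == cat, metric].dropna()
        rows.append(
            {
                "context_category": cat,
                "metric": metric,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else float("nan"),
                "median": vals.median() if len(vals) else float("nan"),
                "q1": vals.quantile(0.25) if len(vals) else float("nan"),
                "q3": vals.quantile(0.75) if len(vals) else float("nan"),
                "small_sample": len(vals) < 3,
            }
        )
    return pd.DataFrame(rows)
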