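"""Rater aggregation, probability rescaling, standardization and reliability.

The score panel is averaged across raters per vocalization, the five 1-10
features are rescaled to [0, 1] "probabilities" by dividing by 10 (the
syllable count keeps its native scale), and the six columns are standardized
to zero mean / unit variance before PCA.  Reliability of the raw panel is
summarised by mean pairwise Spearman correlation between raters, Cronbach's
alpha with raters as items, and mean absolute differences between
disjoint-rater-subset means (the aggregation-stability curve).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FEATURES, PROB_FEATURES


def average_raters(panel: pd.DataFrame) -> pd.DataFrame:
    """Average the available rater scores per vocalization x feature.

    Returns a wide table indexed by ``vocalization_id`` with one column per
    feature (arithmetic mean of the raters that scored the cell, on the
    original 1-10 / count scale) and a ``sigma_<feature>`` column holding the
    sample standard deviation across raters (0 when only one rater scored).
    """
    if panel is None or len(panel) == 0:
        raise ValueError("empty score panel")
    grouped = panel.groupby(["vocalization_id", "feature"])["score"]
    means = grouped.mean().unstack("feature")
    sds = grouped.std(ddof=1).unstack("feature").fillna(0.0)
    sds.columns = [f"sigma_{c}" for c in sds.columns]
    table = pd.concat([means, sds], axis=1)
    table.index.name = "vocalization_id"
    # keep canonical feature order for the columns that are present
    ordered = [f for f in FEATURES if f in means.columns]
    return table[ordered + [f"sigma_{f}" for f in ordered]]


def rescale_probabilities(table: pd.DataFrame) -> pd.DataFrame:
    """Divide the five 1-10 feature means by 10; leave the syllable count.

    Rater dispersion (``sigma_``) columns stay on the original 10-point scale
    so they remain comparable with the "average sigma below 2 of 10"
    reliability yardstick.
    """
    out = table.copy()
    for feat in PROB_FEATURES:
        if feat in out.columns:
            out[feat] = out[feat] / 10.0
    return out


def standardize(table: pd.DataFrame, features: tuple[str, ...] = FEATURES) -> pd.DataFrame:
    """Z-score the feature columns (sample variance) for PCA input.

    Raises ``ValueError`` naming the feature if a column has zero variance.
    Idempotent within floating tolerance.
    """
    cols = [f for f in features if f in table.columns]
    if len(table) < 2:
        raise ValueError("standardize needs at least 2 vocalizations")
    X = table[cols].astype(float)
    sd = X.std(ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance feature column: {dead[0]!r}")
    return (X - X.mean()) / sd


def _rater_matrix(panel: pd.DataFrame, feature: str) -> pd.DataFrame:
    sub = panel[panel["feature"] == feature]
    if sub.empty:
        raise ValueError(f"no scores for feature {feature!r}")
    return sub.pivot(index="vocalization_id", columns="rater_id", values="score")


def pairwise_intercoder_correlation(
    panel: pd.DataFrame, feature: str, min_shared: int = 3
) -> tuple[float, pd.DataFrame]:
    """Mean Spearman correlation over all rater pairs for one feature.

    Each pair is correlated on its pairwise-complete vocalizations (midrank
    ties).  Pairs sharing fewer than ``min_shared`` vocalizations are skipped
    with a warning; if every pair is skipped a ``ValueError`` is raised.

    Returns the mean rho and a per-pair table (rater_a, rater_b, rho,
    n_shared) so alternative poolings can be reported.
    """
    mat = _rater_matrix(panel, feature)
    if mat.shape[1] < 2:
        raise ValueError(f"need >= 2 raters for feature {feature!r}")
    rows = []
    for a, b in itertools.combinations(mat.columns, 2):
        pair = mat[[a, b]].dropna()
        if len(pair) < min_shared:
            warnings.warn(
                f"skipping rater pair ({a}, {b}) for {feature}: "
                f"only {len(pair)} shared vocalizations"
            )
            continue
        rho = stats.spearmanr(pair[a], pair[b]).statistic
        rows.append({"rater_a": a, "rater_b": b, "rho": rho, "n_shared": len(pair)})
    if not rows:
        raise ValueError(f"all rater pairs skipped for feature {feature!r}")
    per_pair = pd.DataFrame(rows)
    return float(per_pair["rho"].mean()), per_pair


def cronbach_alpha(panel: pd.DataFrame, feature: str) -> float:
    """Cronbach's alpha with raters as items and vocalizations as cases.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), with sample variances
    over complete cases only.  Returns NaN when the rater-sum variance is
    zero (alpha undefined).
    """
    mat = _rater_matrix(panel, feature).dropna()
    k = mat.shape[1]
    if k < 2:
        raise ValueError(f"need >= 2 raters for feature {feature!r}")
    if len(mat) < 3:
        raise ValueError(f"need >= 3 complete vocalizations for {feature!r}")
    item_vars = mat.var(ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class SubsetDifferenceResult:
    """|mean(subset A) - mean(subset B)| per vocalization and rater split."""

    per_split: pd.DataFrame  # vocalization_id, split, abs_diff
    grand_means: pd.Series  # mean abs_diff per split
    overall_mean: float


def subset_mean_differences(
    panel: pd.DataFrame, feature: str, subset_size_a: int, subset_size_b: int
) -> SubsetDifferenceResult:
    """Distribution of |mean_A - mean_B| over disjoint rater subsets.

    All unordered disjoint pairs of rater subsets of the two sizes are
    enumerated (for sizes (2, 3) of five raters: the 10 pair/triad splits).
    Larger subsets average away rater noise, so these differences shrink as
    the subset sizes grow — the aggregation-stability argument for using
    rater means.
    """
    mat = _rater_matrix(panel, feature)
    raters = list(mat.columns)
    if subset_size_a + subset_size_b > len(raters):
        raise ValueError(
            f"subset sizes {subset_size_a}+{subset_size_b} exceed "
            f"{len(raters)} raters"
        )
    rows = []
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for a_sub in itertools.combinations(raters, subset_size_a):
        rest = [r for r in raters if r not in a_sub]
        for b_sub in itertools.combinations(rest, subset_size_b):
            key = (a_sub, b_sub)
            if subset_size_a == subset_size_b:
                key = tuple(sorted([a_sub, b_sub]))  # type: ignore[assignment]
                if key in seen:
                    continue
            if key in seen:
                continue
            seen.add(key)
            diff = (mat[list(a_sub)].mean(axis=1) - mat[list(b_sub)].mean(axis=1)).abs()
            label = "+".join(a_sub) + "|" + "+".join(b_sub)
            for voc, d in diff.dropna().items():
                rows.append({"vocalization_id": voc, "split": label, "abs_diff": d})
    per_split = pd.DataFrame(rows)
    grand = per_split.groupby("split")["abs_diff"].mean()
    return SubsetDifferenceResult(per_split, grand, float(per_split["abs_diff"].mean()))


def reliability_report(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-feature reliability table: mean pairwise rho, alpha, pair count."""
    rows = []
    for feat in FEATURES:
        if feat not in set(panel["feature"]):
            continue
        rho, per_pair = pairwise_intercoder_correlation(panel, feat)
        alpha = cronbach_alpha(panel, feat)
        rows.append(
            {"feature": feat, "mean_rho": rho, "alpha": alpha, "n_pairs": len(per_pair)}
        )
    return pd.DataFrame(rows)
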