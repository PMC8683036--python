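"""Correlation-matrix PCA, backward variable elimination, and stopping rules.

The PCA is an eigendecomposition of the sample correlation matrix; loadings
are variable-component correlations (eigenvector entries scaled by
sqrt(eigenvalue)).  Component signs are canonicalized so the largest-|loading|
variable of each component loads positively.

Variable reduction follows the non-clustering backward scheme (Jolliffe's
method B2): walking from the smallest-eigenvalue component upward, each
component with an eigenvalue below the cutoff eliminates the not-yet-removed
variable loading most heavily on it.  A battery of component-retention
stopping rules (Kaiser-Guttman, Jolliffe's lowered Kaiser, cumulative
variance, Horn's parallel analysis, broken stick, Velicer's MAP, Bartlett's
eigenvalue-homogeneity test, scree / log-eigenvalue elbows) is provided for
the companion question of how many components to keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # variable x component, correlation scale
    components: pd.DataFrame  # eigenvectors, variable x component
    scores: pd.DataFrame  # observation x component
    n: int
    p: int
    correlation: pd.DataFrame


@dataclass
class ReductionTrace:
    eliminations: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    mode: str = "single_pca"

    @property
    def eliminated(self) -> list[str]:
        return [e["variable"] for e in self.eliminations]


def run_pca(X: pd.DataFrame) -> PCAResult:
    """PCA of the sample correlation matrix of ``X`` (observations x variables).

    Components are sorted by descending eigenvalue; rank-deficient input
    yields zero eigenvalues rather than an error.  Scores are the z-scored
    data projected on the eigenvectors.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if p < 2 or n <= p:
        raise ValueError(f"need n > p >= 2, got n={n}, p={p}")
    variables = list(X.columns)
    R = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # sign convention: the max-|loading| variable of each component positive
    for k in range(p):
        j = np.argmax(np.abs(vec[:, k]))
        if vec[j, k] < 0:
            vec[:, k] = -vec[:, k]
    loadings = vec * np.sqrt(lam)
    Z = (X - X.mean()) / X.std(ddof=1)
    comp_names = [f"PC{k + 1}" for k in range(p)]
    return PCAResult(
        eigenvalues=lam,
        variance_fractions=lam / lam.sum(),
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        components=pd.DataFrame(vec, index=variables, columns=comp_names),
        scores=pd.DataFrame(Z.to_numpy() @ vec, index=X.index, columns=comp_names),
        n=n,
        p=p,
        correlation=pd.DataFrame(R, index=variables, columns=variables),
    )


def jolliffe_b2_eliminate(
    X: pd.DataFrame, cutoff: float = 0.7, mode: str = "single_pca"
) -> ReductionTrace:
    """Backward variable elimination from low-eigenvalue components.

    ``single_pca`` (default): one decomposition; components are visited from
    the smallest eigenvalue upward and each with eigenvalue below ``cutoff``
    discards the remaining variable with the largest |loading| on it; the
    walk stops at the first component at or above the cutoff.  ``iterative``
    recomputes the PCA after every elimination (sensitivity variant).
    """
    if not (0 < cutoff < 1.5):
        raise ValueError(f"cutoff must lie in (0, 1.5), got {cutoff}")
    X = pd.DataFrame(X)
    trace = ReductionTrace(mode=mode)
    if mode == "single_pca":
        res = run_pca(X)
        remaining = list(X.columns)
        for k in range(res.p - 1, -1, -1):
            if res.eigenvalues[k] >= cutoff:
                break
            col = res.loadings.iloc[:, k].abs()
            victim = col.loc[remaining].idxmax()
            trace.eliminations.append(
                {
                    "component": k + 1,
                    "eigenvalue": float(res.eigenvalues[k]),
                    "variable": victim,
                    "abs_loading": float(col[victim]),
                }
            )
            remaining.remove(victim)
            if not remaining:
                raise ValueError("cutoff eliminated every variable")
        trace.retained = remaining
    elif mode == "iterative":
        remaining = list(X.columns)
        while True:
            if len(remaining) < 2:
                raise ValueError("cutoff eliminated every variable")
            res = run_pca(X[remaining])
            k = len(remaining) - 1
            if res.eigenvalues[k] >= cutoff:
                break
            col = res.loadings.iloc[:, k].abs()
            victim = col.idxmax()
            trace.eliminations.append(
                {
                    "component": k + 1,
                    "eigenvalue": float(res.eigenvalues[k]),
                    "variable": victim,
                    "abs_loading": float(col[victim]),
                }
            )
            remaining.remove(victim)
        trace.retained = remaining
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return trace


def threshold_rules(
    eigenvalues: np.ndarray,
    kaiser_threshold: float = 1.0,
    jolliffe_cutoff: float = 0.7,
    cumvar_threshold: float = 0.90,
) -> dict[str, int]:
    """Kaiser-Guttman, Jolliffe's lowered Kaiser, and cumulative-variance counts."""
    lam = np.asarray(eigenvalues, dtype=float)
    frac = np.cumsum(lam) / lam.sum()
    return {
        "kaiser_guttman": int(np.sum(lam >= kaiser_threshold)),
        "jolliffe_kg": int(np.sum(lam >= jolliffe_cutoff)),
        "cumulative_variance": int(np.searchsorted(frac, cumvar_threshold) + 1),
    }


def parallel_analysis(
    eigenvalues: np.ndarray,
    n_obs: int,
    replicates: int = 1000,
    criterion: str = "mean",
    rng: np.random.Generator | int | None = None,
) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis against iid-normal null eigenvalue spectra.

    Simulates ``replicates`` matrices of standard normals with the observed
    dimensions, takes correlation-matrix eigenvalues per replicate, and
    aggregates per rank by the mean (default) or 95th percentile.  Retains
    the leading components whose observed eigenvalue exceeds its rank's
    threshold, stopping at the first failure.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p == 1:
        return 1, np.ones(1)
    rng = np.random.default_rng(rng)
    sims = np.empty((replicates, p))
    for r in range(replicates):
        Z = rng.standard_normal((n_obs, p))
        ev = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))
        sims[r] = ev[::-1]
    if criterion == "mean":
        thresholds = sims.mean(axis=0)
    elif criterion == "percentile95":
        thresholds = np.percentile(sims, 95, axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    retained = 0
    for k in range(p):
        if lam[k] > thresholds[k]:
            retained += 1
        else:
            break
    return retained, thresholds


def broken_stick(eigenvalues: np.ndarray) -> tuple[int, np.ndarray]:
    """Broken-stick rule: keep components beating the expected stick fractions.

    b_k = (1/p) * sum_{i=k}^{p} 1/i; the count stops at the first component
    whose variance fraction fails to exceed its b_k.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p < 2:
        raise ValueError("broken stick needs p >= 2")
    inv = 1.0 / np.arange(1, p + 1)
    expected = np.cumsum(inv[::-1])[::-1] / p
    frac = lam / lam.sum()
    retained = 0
    for k in range(p):
        if frac[k] > expected[k]:
            retained += 1
        else:
            break
    return retained, expected


def velicer_map(
    correlation: np.ndarray, max_components: int | None = None
) -> tuple[int, np.ndarray]:
    """Velicer's minimum-average-partial test for component retention.

    For m = 0..max, the first m principal components are partialled out of
    the correlation matrix and the mean squared off-diagonal partial
    correlation recorded; the retained count is the argmin.  A degenerate
    partial covariance (non-positive diagonal) stops the loop.
    """
    R = np.asarray(correlation, dtype=float)
    p = R.shape[0]
    if max_components is None:
        max_components = p - 1
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0, None), vec[:, order]
    off = ~np.eye(p, dtype=bool)
    stats_out = []
    for m in range(max_components + 1):
        if m == 0:
            partial = R
        else:
            L = vec[:, :m] * np.sqrt(lam[:m])
            C = R - L @ L.T
            d = np.diag(C)
            if np.any(d <= 1e-12):
                break
            partial = C / np.sqrt(np.outer(d, d))
        stats_out.append(np.mean(partial[off] ** 2))
    avg_sq = np.array(stats_out)
    return int(np.argmin(avg_sq)), avg_sq


def bartlett_retention(
    eigenvalues: np.ndarray, n_obs: int, alpha_level: float = 0.05
) -> int:
    """Bartlett's sequential test of homogeneity of the trailing eigenvalues.

    Retains the smallest k for which the likelihood-ratio chi-square test of
    equality of the last p-k eigenvalues is non-significant; p-1 if every
    remainder is heterogeneous.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    for k in range(p - 1):
        rest = lam[k:]
        q = len(rest)
        if np.any(rest <= 1e-12):
            continue  # a zero eigenvalue is maximal heterogeneity
        lam_bar = rest.mean()
        stat = (n_obs - k - (2 * q + 1 + 2.0 / q) / 6.0) * (
            q * np.log(lam_bar) - np.sum(np.log(rest))
        )
        df = (q + 2) * (q - 1) / 2.0
        if stats.chi2.sf(max(stat, 0.0), df) > alpha_level:
            return k
    return p - 1


def scree_elbows(eigenvalues: np.ndarray) -> tuple[int, int]:
    """Elbow indices of the scree and log-eigenvalue (LEV) plots.

    The elbow is the interior index maximizing the second difference of the
    eigenvalues (scree) or of their logs (LEV); ties break to the smallest
    index.  This is a stated mechanical stand-in for a visual judgment.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p < 3:
        raise ValueError("elbow detection needs p >= 3")

    def elbow(values: np.ndarray) -> int:
        second = values[:-2] - 2 * values[1:-1] + values[2:]
        return int(np.argmax(second)) + 2  # 1-based interior index

    scree = elbow(lam)
    positive = lam[lam > 1e-12]
    lev = elbow(np.log(positive)) if len(positive) >= 3 else scree
    return scree, lev


def stopping_rule_report(
    result: PCAResult,
    kaiser_threshold: float = 1.0,
    jolliffe_cutoff: float = 0.7,
    cumvar_threshold: float = 0.90,
    pa_replicates: int = 1000,
    pa_criterion: str = "mean",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Run the whole retention battery on one PCA result."""
    lam = result.eigenvalues
    thr = threshold_rules(lam, kaiser_threshold, jolliffe_cutoff, cumvar_threshold)
    pa, _ = parallel_analysis(lam, result.n, pa_replicates, pa_criterion, rng)
    bs, _ = broken_stick(lam)
    vm, _ = velicer_map(result.correlation.to_numpy())
    bart = bartlett_retention(lam, result.n)
    scree, lev = scree_elbows(lam)
    rows = [
        ("kaiser_guttman", kaiser_threshold, thr["kaiser_guttman"]),
        ("jolliffe_kg", jolliffe_cutoff, thr["jolliffe_kg"]),
        ("cumulative_variance", cumvar_threshold, thr["cumulative_variance"]),
        ("parallel_analysis", float("nan"), pa),
        ("broken_stick", float("nan"), bs),
        ("velicer_map", float("nan"), vm),
        ("bartlett", 0.05, bart),
        ("scree_elbow", float("nan"), scree),
        ("lev_elbow", float("nan"), lev),
    ]
    return pd.DataFrame(rows, columns=["rule", "threshold", "retained"])


def attach_pc1_scores(result: PCAResult, index_table: pd.DataFrame) -> pd.DataFrame:
    """Fill the index table's pc1_score column from the PCA scores.

    Scores keep the canonicalized sign; the correlation between ARDI and PC1
    (and hence the component's orientation relative to "more musical") is for
    the caller to report, not imposed here.
    """
    if len(result.scores) != len(index_table):
        raise ValueError(
            f"score rows ({len(result.scores)}) do not match index table "
            f"rows ({len(index_table)})"
        )
    out = index_table.copy()
    out["pc1_score"] = result.scores["PC1"].to_numpy()
    return out
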