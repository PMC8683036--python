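"""The acoustic reappearance diversity index (ARDI) and related complexity.

ARDI estimates the expected number of distinct syllables that reappear —
by repetition (same frequency, later in time) or transposition (different
frequency) — within a call:

    P(reappearance) = P(repetition) + P(transposition)          (joint term 0)
    ARDI            = syllable_count * P(reappearance)

Repetition and transposition of a given unit are treated as mutually
exclusive, so the addition rule's joint term is dropped.  The sum can exceed
one; by default it is left unclamped (the worked examples use e.g.
2.6 x (0.54 + 0.56)), with an optional clamp to 1.

The song complexity index (SCI) is the Euclidean-style measure
sqrt(n * l^2 - sum_i (m_i - 1)^2) over n syllables, l units and per-syllable
repetition counts m_i; when per-syllable counts are unknown it is
approximated with the uniform estimate E(m) = l / n.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import normalize_species


def _check_unit_interval(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def reappearance_probability(p_rep, p_trans, clamp: bool = False):
    """P(reappearance) = P(repetition) + P(transposition), optionally clamped.

    Accepts scalars or arrays on the probability (tenth) scale.  With
    ``clamp=False`` (default) the sum may exceed 1, reproducing the index's
    worked examples; ``clamp=True`` re-bounds it at 1.
    """
    _check_unit_interval("p_repetition", p_rep)
    _check_unit_interval("p_transposition", p_trans)
    p = np.asarray(p_rep, dtype=float) + np.asarray(p_trans, dtype=float)
    if clamp:
        p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def compute_ardi(syllables, p_rep, p_trans, clamp: bool = False):
    """ARDI = syllable count x P(reappearance); exact product, no rounding.

    Zero syllables or zero reappearance probability guarantee an index of
    zero; the index is nondecreasing in each argument.
    """
    n = np.asarray(syllables, dtype=float)
    if np.any(n < 0):
        raise ValueError(f"syllable count must be >= 0, got {syllables}")
    out = n * reappearance_probability(p_rep, p_trans, clamp=clamp)
    return float(out) if np.ndim(out) == 0 else out


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round to a number of significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sigfigs - 1 - exponent)


def approximate_sci(n: float, l: float) -> float:
    """Approximate song complexity from syllable count n and unit count l.

    Uses the uniform per-syllable repetition estimate E(m) = l/n:
    sci = sqrt(n*l^2 - n*(l/n - 1)^2).  Defined as 0 when n = 0; raises
    ``ValueError`` (inputs echoed) on a negative radicand.
    """
    if n == 0:
        return 0.0
    if n < 1 or l < 1:
        raise ValueError(f"need n >= 1 and l >= 1, got n={n}, l={l}")
    radicand = n * l**2 - n * (l / n - 1.0) ** 2
    if radicand < 0:
        raise ValueError(f"negative radicand for sci with n={n}, l={l}")
    return math.sqrt(radicand)


def exact_sci(n: int, l: float, m_i: Sequence[float]) -> float:
    """Exact song complexity sqrt(n*l^2 - sum_i (m_i - 1)^2).

    ``m_i`` holds the repetition count of each of the n syllables (all >= 1).
    Equals :func:`approximate_sci` when all m_i are the uniform l/n.
    """
    if len(m_i) != n:
        raise ValueError(f"m_i must have n={n} entries, got {len(m_i)}")
    if any(m < 1 for m in m_i):
        raise ValueError(f"per-syllable repetition counts must be >= 1: {m_i}")
    radicand = n * l**2 - sum((m - 1.0) ** 2 for m in m_i)
    if radicand < 0:
        raise ValueError(f"negative radicand for sci with n={n}, l={l}, m_i={m_i}")
    return math.sqrt(radicand)


def build_index_table(
    feature_table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    clamp: bool = False,
) -> pd.DataFrame:
    """Per-vocalization index table from the rescaled feature table.

    Columns: syllables, p_repetition, p_transposition, reappearance, ardi,
    sci, log_sci (natural log), pc1_score (NaN until attached).  SCI needs
    the unit count from the metadata; rows without one get NaN there.
    """
    out = pd.DataFrame(index=feature_table.index)
    out["syllables"] = feature_table["syllables"].astype(float)
    out["p_repetition"] = feature_table["repetition"].astype(float)
    out["p_transposition"] = feature_table["transposition"].astype(float)
    out["reappearance"] = reappearance_probability(
        out["p_repetition"].to_numpy(), out["p_transposition"].to_numpy(), clamp=clamp
    )
    out["ardi"] = out["syllables"] * out["reappearance"]

    sci = np.full(len(out), np.nan)
    if metadata is not None and "unit_count" in metadata.columns:
        units = metadata.set_index("vocalization_id")["unit_count"]
        units = units.reindex(out.index)
        for i, (n, l) in enumerate(zip(out["syllables"], units)):
            if pd.notna(l) and n >= 1 and l >= 1:
                sci[i] = approximate_sci(float(n), float(l))
    out["sci"] = sci
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_sci"] = np.where(out["sci"] > 0, np.log(out["sci"]), np.nan)
    out["pc1_score"] = np.nan
    return out


def species_max_index(
    index_table: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per species: maxima of the per-call indices plus covariates.

    The species-level score is the maximum over that species' scored call
    types (interest lies in the most elaborate display a species can
    produce).  Species missing from the covariate table are kept and flagged.
    """
    meta = metadata.set_index("vocalization_id")
    df = index_table.join(meta[["species", "sex"]], how="left")
    if df["species"].isna().any():
        missing = df.index[df["species"].isna()][0]
        raise ValueError(f"vocalization {missing!r} has no species in metadata")
    rows = []
    for species, grp in df.groupby("species"):
        top = grp["ardi"].idxmax()
        rows.append(
            {
                "species": species,
                "max_ardi": grp["ardi"].max(),
                "max_sci": grp["sci"].max(),
                "max_syllables": grp["syllables"].max(),
                "repertoire_size": len(grp),
                "top_call_sex": grp.loc[top, "sex"] if pd.notna(top) else None,
            }
        )
    summary = pd.DataFrame(rows)
    if covariates is not None:
        cov = covariates.copy()
        cov["_key"] = cov["species"].map(normalize_species)
        summary["_key"] = summary["species"].map(normalize_species)
        summary = summary.merge(
            cov.drop(columns=["species"]), on="_key", how="left"
        ).drop(columns=["_key"])
        summary["covariates_missing"] = summary["monogamous"].isna()
    return summary


def summarize_putative_musical(
    feature_table: pd.DataFrame, index_table: pd.DataFrame, threshold: float = 2.0
) -> dict[str, float]:
    """Mean tone and reappearance probabilities above an ARDI cutoff.

    Returns subset means (NaN when no call clears the threshold) alongside
    the overall means, plus the subset size.  Used to check that high-index
    calls are both tonal and redundant.
    """
    tone = feature_table["tone"].astype(float)
    reap = index_table["reappearance"].astype(float)
    mask = index_table["ardi"] > threshold
    return {
        "threshold": float(threshold),
        "n_above": int(mask.sum()),
        "mean_tone_above": float(tone[mask].mean()) if mask.any() else float("nan"),
        "mean_reappearance_above": float(reap[mask].mean()) if mask.any() else float("nan"),
        "mean_tone_overall": float(tone.mean()),
        "mean_reappearance_overall": float(reap.mean()),
    }
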