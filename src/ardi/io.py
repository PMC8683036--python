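"""Reading, validation and writing of the tabular inputs and outputs.

The canonical on-disk score format is a long (tidy) CSV with one row per
(vocalization, feature, rater) cell::

    vocalization_id,feature,rater_id,score

Five features (tone, interval, rhythm, repetition, transposition) are ordinal
scores on a 1-10 scale; ``syllables`` is an unbounded count of distinct
syllable shapes.  Vocalization metadata and species covariates are plain wide
CSVs (see :data:`METADATA_COLUMNS` and :data:`SPECIES_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

#: Features scored on the ordinal 1-10 scale (probability scale after /10).
PROB_FEATURES: tuple[str, ...] = (
    "tone",
    "interval",
    "rhythm",
    "repetition",
    "transposition",
)

#: The unbounded count feature (number of distinct syllable shapes).
COUNT_FEATURE = "syllables"

FEATURES: tuple[str, ...] = PROB_FEATURES + (COUNT_FEATURE,)

# The count feature is called "variation" in some scoring protocols.
FEATURE_ALIASES = {"variation": COUNT_FEATURE, "syllable": COUNT_FEATURE}

PANEL_COLUMNS = ("vocalization_id", "feature", "rater_id", "score")
METADATA_COLUMNS = (
    "vocalization_id",
    "species",
    "genus",
    "call_name",
    "context",
    "sex",
    "unit_count",
)
SPECIES_COLUMNS = (
    "species",
    "monogamous",
    "group_size",
    "arboreal",
    "wooded",
    "territorial",
    "solitary",
)

#: Call-name keywords treated as "musical" designations by researchers.
DEFAULT_MUSICAL_KEYWORDS: tuple[str, ...] = (
    "song",
    "duet",
    "trio",
    "chorus",
    "great",
    "music",
    "scale",
    "coda",
    "intro",
    "interlude",
)


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline with their replication defaults.

    ``clamp_reappearance`` keeps P(reappearance) unbounded by default because
    the index's worked examples use sums above one directly.  The PCA-related
    thresholds follow the component-retention battery defaults.
    """

    clamp_reappearance: bool = False
    jolliffe_cutoff: float = 0.7
    kaiser_threshold: float = 1.0
    cumvar_threshold: float = 0.90
    pa_replicates: int = 1000
    pa_criterion: str = "mean"  # or "percentile95"
    rng_seed: int = 0
    musical_keywords: tuple[str, ...] = DEFAULT_MUSICAL_KEYWORDS
    final_feature_set: tuple[str, ...] = ("syllables", "repetition", "transposition")

    def __post_init__(self) -> None:
        if not (0 < self.jolliffe_cutoff < self.kaiser_threshold <= 2):
            raise ValueError(
                "require 0 < jolliffe_cutoff < kaiser_threshold <= 2, got "
                f"{self.jolliffe_cutoff} and {self.kaiser_threshold}"
            )
        if self.pa_replicates < 100:
            raise ValueError("pa_replicates must be >= 100")
        if self.pa_criterion not in ("mean", "percentile95"):
            raise ValueError(f"unknown pa_criterion {self.pa_criterion!r}")


class Violation(NamedTuple):
    """One data-validation failure; violations are data, not exceptions."""

    vocalization_id: str
    feature: str
    rater_id: str
    rule: str


def normalize_feature(name: str) -> str:
    key = str(name).strip().lower()
    key = FEATURE_ALIASES.get(key, key)
    return key


def normalize_species(name: str) -> str:
    """Species names are matched case-insensitively after trimming."""
    return " ".join(str(name).split()).lower()


def read_score_panel(path: str | Path) -> pd.DataFrame:
    """Read a long-format rater score CSV into a score panel.

    Returns a DataFrame with columns ``vocalization_id, feature, rater_id,
    score``; feature names are normalized to the canonical lowercase set.

    Raises
    ------
    SchemaError
        If required columns are missing, a feature name is unknown (the
        offending row index is named), or a score fails to parse as a number.
    """
    df = pd.read_csv(path, dtype={"vocalization_id": str, "rater_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"score file {path} is missing columns {missing}")
    df = df.loc[:, list(PANEL_COLUMNS)].copy()
    df["feature"] = df["feature"].map(normalize_feature)
    bad = df.index[~df["feature"].isin(FEATURES)]
    if len(bad):
        row = int(bad[0])
        raise SchemaError(
            f"unknown feature {df.at[row, 'feature']!r} at row {row} of {path}"
        )
    try:
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric score in {path}: {exc}") from exc
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"vocalization_id": str})
    missing = [c for c in ("vocalization_id", "species", "call_name") if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file {path} is missing columns {missing}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    if df["vocalization_id"].duplicated().any():
        dup = df.loc[df["vocalization_id"].duplicated(), "vocalization_id"].iloc[0]
        raise SchemaError(f"duplicate vocalization_id {dup!r} in {path}")
    return df.loc[:, list(METADATA_COLUMNS)]


def read_species_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"species file {path} is missing columns {missing}")
    if df["species"].map(normalize_species).duplicated().any():
        raise SchemaError(f"duplicate species in {path}")
    return df.loc[:, list(SPECIES_COLUMNS)]


def validate_panel(panel: pd.DataFrame) -> list[Violation]:
    """Check score-range and completeness invariants of a score panel.

    The five 1-10 features must lie in [1, 10]; the syllable count must be
    nonnegative (it has no upper bound).  Every vocalization that scores a
    feature at all must have at least one rater for it — a feature entirely
    absent for a vocalization that other vocalizations score is reported as a
    completeness violation.
    """
    violations: list[Violation] = []
    for row in panel.itertuples(index=False):
        if row.feature == COUNT_FEATURE:
            if row.score < 0:
                violations.append(
                    Violation(row.vocalization_id, row.feature, row.rater_id,
                              "syllable count must be >= 0")
                )
        elif not (1 <= row.score <= 10):
            violations.append(
                Violation(row.vocalization_id, row.feature, row.rater_id,
                          "score outside [1, 10]")
            )
    scored_features = sorted(panel["feature"].unique())
    have = panel.groupby("vocalization_id")["feature"].agg(set)
    for voc, feats in have.items():
        for feat in scored_features:
            if feat not in feats:
                violations.append(
                    Violation(str(voc), feat, "", "no rater scores for this feature")
                )
    return violations


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV; round-trip stable via :func:`read_table`."""
    if table is None or len(table) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
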