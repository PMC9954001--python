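"""Treatment × sample score matrices and panel-wide treatment ranking.

Assembles the per-curve 0–100 scores into a matrix with explicit
tested/untested masking (untested cells never enter any aggregate), ranks
treatments by their mean score across tested samples, and emits a
heatmap-ready long table. The headline ranking is conventionally taken at
the 10% Cmax dose tier, favouring combinations that act at the lowest
concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScoreMatrix", "build_score_matrix", "rank_treatments", "to_heatmap_table"]

logger = logging.getLogger(__name__)

#: Treatments tested on fewer samples than this are listed but unranked.
MIN_SAMPLES = 3


@dataclass
class ScoreMatrix:
    """Treatments × samples score matrix; NaN marks untested cells."""

    scores: pd.DataFrame
    dose_tier: str = "cmax"

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean tested-flag matrix (True = tested)."""
        return self.scores.notna()

    @property
    def treatments(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


def build_score_matrix(scored: pd.DataFrame, dose_tier: str = "cmax") -> ScoreMatrix:
    """Pivot per-curve scores into a treatments × samples matrix for one tier.

    ``scored`` is the long table from :func:`combiscreen.dose_response.score_plate`
    (columns sample_id, treatment, dose_tier, score). Duplicate
    (sample, treatment) entries within the tier are a hard error; absent
    pairs are masked.
    """
    sub = scored.loc[scored["dose_tier"] == dose_tier]
    if sub.empty:
        raise ValueError(f"no scores at dose tier {dose_tier!r}")
    dup = sub.duplicated(["sample_id", "treatment"], keep=False)
    if dup.any():
        offending = sub.loc[dup, ["sample_id", "treatment"]].drop_duplicates()
        raise ValueError(
            f"duplicate (sample, treatment) entries at tier {dose_tier!r}: "
            f"{offending.to_records(index=False).tolist()}"
        )
    matrix = sub.pivot(index="treatment", columns="sample_id", values="score")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "treatment"
    matrix.columns.name = "sample_id"
    return ScoreMatrix(scores=matrix, dose_tier=dose_tier)


def rank_treatments(
    matrix: ScoreMatrix,
    min_samples: int = MIN_SAMPLES,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Rank treatments by aggregate score over tested samples (1 = best).

    Aggregate is the unweighted mean across tested samples (``"median"``
    available). Treatments tested on fewer than ``min_samples`` samples are
    listed with rank NaN. Ties share the minimal rank and are ordered
    lexicographically.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if matrix.scores.empty:
        raise ValueError("empty score matrix")
    agg_fn = matrix.scores.mean(axis=1) if aggregate == "mean" else matrix.scores.median(axis=1)
    n_tested = matrix.mask.sum(axis=1)
    df = pd.DataFrame(
        {"aggregate_score": agg_fn, "n_samples_tested": n_tested}
    ).reset_index()
    rankable = df["n_samples_tested"] >= min_samples
    excluded = df.loc[~rankable, "treatment"].tolist()
    if excluded:
        logger.info("unranked (tested on < %d samples): %s", min_samples, excluded)
    # competition ranking on the rankable subset: ties share the min rank
    ranks = df.loc[rankable, "aggregate_score"].rank(method="min", ascending=False)
    df["rank"] = np.nan
    df.loc[rankable, "rank"] = ranks
    df = df.sort_values(
        ["rank", "treatment"], na_position="last", kind="mergesort", ignore_index=True
    )
    return df[["treatment", "aggregate_score", "n_samples_tested", "rank"]]


def to_heatmap_table(matrix: ScoreMatrix, ranking: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long table: rows in rank order, untested cells sentinel-flagged."""
    order = ranking["treatment"].tolist()
    rows = []
    for treatment in order:
        for sample in matrix.samples:
            value = matrix.scores.at[treatment, sample] if treatment in matrix.scores.index else np.nan
            tested = bool(pd.notna(value))
            rows.append(
                {
                    "treatment": treatment,
                    "sample_id": sample,
                    "score": float(value) if tested else np.nan,
                    "status": "tested" if tested else "not_tested",
                    "dose_tier": matrix.dose_tier,
                }
            )
    return pd.DataFrame(rows)


def heatmap_table_to_matrix(table: pd.DataFrame) -> ScoreMatrix:
    """Inverse of :func:`to_heatmap_table` (row order follows the table)."""
    tier = str(table["dose_tier"].iloc[0]) if "dose_tier" in table and len(table) else "cmax"
    pivot = table.pivot(index="treatment", columns="sample_id", values="score")
    order = table["treatment"].drop_duplicates().tolist()
    samples = table["sample_id"].drop_duplicates().tolist()
    return ScoreMatrix(scores=pivot.loc[order, samples], dose_tier=tier)
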