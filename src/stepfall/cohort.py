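"""Collapse bout-level parameters to participants, join outcomes, standardize.

Each participant contributes the median of every bout-level parameter over
their kept walking bouts (medians over bouts where the parameter is
defined), plus the three gait-quantity totals. Participants with zero kept
bouts are excluded and tallied — this mirrors how a long-bout criterion
removes the least ambulatory fraction of a cohort. A Spearman correlation
screen with weak/moderate/strong banding supports choosing uncorrelated
model candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (
    BOUT_PARAMETER_NAMES,
    PARAMETER_NAMES,
    BoutParameterRecord,
    QuantityRecord,
    compute_bout_parameters,
    quantity_params,
)
from .streams import Bouts, OutcomeRecord, StepEventSeries, segment_bouts

__all__ = [
    "ParticipantRecord",
    "CorrelationMatrix",
    "Standardizer",
    "aggregate_participant",
    "build_cohort",
    "cohort_frame",
    "spearman_matrix",
    "correlation_band",
]


class CohortError(ValueError):
    """Inconsistent cohort inputs (missing outcomes, degenerate columns)."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's 12-parameter vector joined with their fall outcome."""

    participant_id: str
    group: int
    fall_count: int
    params: dict[str, float]
    n_bouts_used: int

    @property
    def faller(self) -> bool:
        return self.fall_count >= 1


def aggregate_participant(
    bout_records: list[BoutParameterRecord],
    quantity: QuantityRecord,
    outcome: OutcomeRecord,
) -> ParticipantRecord:
    """Median of bout-level parameters over defined bouts + quantity totals."""
    if not bout_records:
        raise CohortError(
            f"{outcome.participant_id}: no kept bouts; participant must be excluded"
        )
    params: dict[str, float] = dict(quantity.as_dict())
    for name in BOUT_PARAMETER_NAMES:
        vals = np.array([getattr(r, name) for r in bout_records], dtype=float)
        vals = vals[~np.isnan(vals)]
        params[name] = float(np.median(vals)) if vals.size else math.nan
    return ParticipantRecord(
        participant_id=outcome.participant_id,
        group=outcome.group,
        fall_count=outcome.fall_count,
        params=params,
        n_bouts_used=len(bout_records),
    )


def build_cohort(
    series_list: list[StepEventSeries],
    outcomes: list[OutcomeRecord],
    gap_s: float = 2.0,
    min_steps: int = 200,
    trim: int = 5,
    dfa_min_box: int = 4,
    dfa_n_boxes: int = 10,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
) -> tuple[list[ParticipantRecord], list[str]]:
    """Run segmentation + parameters + aggregation for a whole cohort.

    Returns the included participant records and the ids excluded for
    having zero kept bouts. A participant with gait data but no outcome
    row is an error (the join must be resolvable).
    """
    outcome_by_id = {o.participant_id: o for o in outcomes}
    missing = [s.participant_id for s in series_list if s.participant_id not in outcome_by_id]
    if missing:
        raise CohortError(f"no outcome rows for participants: {', '.join(missing)}")
    records, excluded = [], []
    for series in series_list:
        bouts = segment_bouts(series, gap_s=gap_s, min_steps=min_steps, trim=trim)
        if len(bouts) == 0:
            excluded.append(series.participant_id)
            continue
        bout_recs = [
            compute_bout_parameters(
                b,
                bout_id=i,
                dfa_min_box=dfa_min_box,
                dfa_n_boxes=dfa_n_boxes,
                sampen_m=sampen_m,
                sampen_r=sampen_r,
            )
            for i, b in enumerate(bouts)
        ]
        records.append(
            aggregate_participant(bout_recs, quantity_params(bouts), outcome_by_id[series.participant_id])
        )
    return records, excluded


def cohort_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Tabular cohort: id, group, fall_count, faller, the 12 parameters."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "group": r.group,
            "fall_count": r.fall_count,
            "faller": int(r.faller),
            "n_bouts_used": r.n_bouts_used,
        }
        row.update({name: r.params.get(name, math.nan) for name in PARAMETER_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_band(rho: float) -> str:
    """Qualitative band of |rho|: weak < 0.4 <= moderate < 0.7 <= strong."""
    if math.isnan(rho):
        return "undefined"
    a = abs(rho)
    if a >= 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


@dataclass
class CorrelationMatrix:
    """Spearman rank-correlation matrix of the 12 parameters with bands."""

    rho: pd.DataFrame
    band: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.band = self.rho.map(correlation_band)

    def long_format(self) -> pd.DataFrame:
        out = self.rho.stack().rename("rho").reset_index()
        out.columns = ["param_a", "param_b", "rho"]
        out["band"] = out["rho"].map(correlation_band)
        return out

    def correlated_pairs(self, threshold: float = 0.7) -> list[tuple[str, str]]:
        """Unordered pairs with |rho| >= threshold (excluding the diagonal)."""
        names = list(self.rho.columns)
        pairs = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                r = self.rho.loc[a, b]
                if not math.isnan(r) and abs(r) >= threshold:
                    pairs.append((a, b))
        return pairs

    def heatmap(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(self.rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.rho.columns)), self.rho.columns, rotation=90)
        ax.set_yticks(range(len(self.rho.index)), self.rho.index)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def spearman_matrix(
    cohort: pd.DataFrame, columns: tuple[str, ...] = PARAMETER_NAMES
) -> CorrelationMatrix:
    """Pairwise Spearman rho (average ranks for ties) over parameter columns.

    Constant columns yield NaN against every other column (rank correlation
    undefined); at least 3 complete parameter vectors are required.
    """
    data = cohort[list(columns)].dropna()
    if len(data) < 3:
        raise CohortError(f"need >= 3 complete parameter vectors, got {len(data)}")
    x = data.to_numpy(dtype=float)
    k = x.shape[1]
    rho = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                r = math.nan
            else:
                r = stats.spearmanr(x[:, i], x[:, j]).statistic
            rho[i, j] = rho[j, i] = r
    return CorrelationMatrix(pd.DataFrame(rho, index=list(columns), columns=list(columns)))


class Standardizer:
    """Center/scale parameter columns to mean 0, SD 1 (sample SD, n-1).

    The fitted means and SDs are reusable on held-out data so that
    cross-validation standardizes test splits with training statistics
    only (no leakage).
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, cohort: pd.DataFrame, columns) -> "Standardizer":
        data = cohort[list(columns)]
        sd = data.std(ddof=1)
        zero = sd.index[(sd == 0) | sd.isna()].tolist()
        if zero:
            raise CohortError(f"zero-variance parameter column(s): {', '.join(zero)}")
        self.mean_ = data.mean()
        self.sd_ = sd
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        out = cohort.copy()
        cols = self.mean_.index
        out[cols] = (cohort[cols] - self.mean_) / self.sd_
        return out

    def fit_transform(self, cohort: pd.DataFrame, columns) -> pd.DataFrame:
        return self.fit(cohort, columns).transform(cohort)
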