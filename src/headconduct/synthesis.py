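"""Weighted and unweighted descriptive synthesis per tissue.

Produces the per-tissue summary surface of the meta-analysis — minimum,
maximum, arithmetic mean, quality-weighted mean, sample SD and counts of
values / studies / participants — plus boxplot statistics for display.

The weighted mean is Σwᵢxᵢ/Σwᵢ with the quality weights of
:mod:`headconduct.quality`.  The weighted SD uses the frequency-weight
estimator

    √[ Σwᵢ(xᵢ − x̄_w)² / (Σwᵢ · (n_eff − 1)/n_eff) ],   n_eff = (Σw)²/Σw²,

chosen because it reduces exactly to the ordinary n−1 sample SD under
equal weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, TissueLabel
from .quality import QualityScore

__all__ = [
    "SynthesisError",
    "TissueSummary",
    "BoxplotStats",
    "weighted_mean",
    "weighted_sd",
    "summarise_tissue",
    "summarise_all",
    "summary_table",
    "boxplot_stats",
]

#: Column order of the exported per-tissue summary table.
SUMMARY_COLUMNS = [
    "tissue",
    "minimum",
    "maximum",
    "mean",
    "weighted_mean",
    "standard_deviation",
    "n_values",
    "n_studies",
    "n_participants",
]


class SynthesisError(ValueError):
    """Raised for undefined weighted statistics (e.g. all-zero weights)."""


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Σ(wᵢ·xᵢ)/Σwᵢ.  Rejects length mismatches, negative or all-zero weights."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise SynthesisError(f"values and weights must be 1-D and equal length, got {x.shape} vs {w.shape}")
    if x.size == 0:
        raise SynthesisError("weighted mean of empty input is undefined")
    if np.any(w < 0):
        raise SynthesisError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise SynthesisError("weighted mean undefined: all weights are zero")
    return float((w * x).sum() / total)


def weighted_sd(values: Sequence[float], weights: Sequence[float]) -> float | None:
    """Frequency-weight SD; ``None`` when fewer than 2 values carry weight.

    Equal weights reduce this exactly to the ordinary sample SD (n−1).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise SynthesisError(f"values and weights must be 1-D and equal length, got {x.shape} vs {w.shape}")
    if np.any(w < 0):
        raise SynthesisError("weights must be non-negative")
    effective = int((w > 0).sum())
    if effective < 2:
        return None
    total = w.sum()
    n_eff = total**2 / (w**2).sum()
    xbar = (w * x).sum() / total
    denom = total * (n_eff - 1.0) / n_eff
    if denom <= 0:
        return None
    return float(math.sqrt((w * (x - xbar) ** 2).sum() / denom))


@dataclass(frozen=True)
class TissueSummary:
    """Summary-table row for one tissue (conductivities in S/m; the
    brain-to-skull ratio is dimensionless)."""

    tissue: TissueLabel
    minimum: float
    maximum: float
    mean: float
    weighted_mean: float
    sd: float | None
    n_values: int
    n_studies: int
    n_participants: int

    def as_row(self) -> dict:
        return {
            "tissue": str(self.tissue),
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean": self.mean,
            "weighted_mean": self.weighted_mean,
            "standard_deviation": self.sd,
            "n_values": self.n_values,
            "n_studies": self.n_studies,
            "n_participants": self.n_participants,
        }


def summarise_tissue(
    corpus: Corpus,
    scores: Sequence[QualityScore],
    tissue: TissueLabel | str,
) -> TissueSummary:
    """Descriptive statistics over all records of one tissue.

    min/max/mean/SD are unweighted; the weighted mean uses the per-record
    quality weights.  When every record weight is zero (all clamped) the
    weighted mean falls back to the unweighted mean rather than being
    undefined, and the situation is visible through the weights table.
    Participants are counted once per contributing study and summed;
    studies with unknown participant counts contribute zero.
    """
    if isinstance(tissue, str):
        tissue = TissueLabel.from_name(tissue)
    if len(scores) != len(corpus.records):
        raise SynthesisError(
            f"scores ({len(scores)}) are not aligned with records ({len(corpus.records)})"
        )
    idx = [i for i, r in enumerate(corpus.records) if r.tissue == tissue]
    if not idx:
        raise SynthesisError(f"no records for tissue {tissue}")
    values = np.array([corpus.records[i].sigma for i in idx])
    weights = np.array([scores[i].weight for i in idx])
    studies = []
    for i in idx:
        sid = corpus.records[i].study_id
        if sid not in studies:
            studies.append(sid)
    n_participants = 0
    for sid in studies:
        info = corpus.studies.get(sid)
        if info is not None and info.n_participants is not None:
            n_participants += info.n_participants
    wmean = (
        weighted_mean(values, weights)
        if weights.sum() > 0
        else float(values.mean())
    )
    # guard the min ≤ weighted_mean ≤ max invariant against last-ulp rounding
    wmean = min(max(wmean, float(values.min())), float(values.max()))
    return TissueSummary(
        tissue=tissue,
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        weighted_mean=wmean,
        sd=float(values.std(ddof=1)) if values.size > 1 else None,
        n_values=int(values.size),
        n_studies=len(studies),
        n_participants=n_participants,
    )


def summarise_all(corpus: Corpus, scores: Sequence[QualityScore]) -> list[TissueSummary]:
    """One :class:`TissueSummary` per tissue present, in corpus order."""
    return [summarise_tissue(corpus, scores, t) for t in corpus.tissues()]


def summary_table(summaries: Sequence[TissueSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame in the exported column order."""
    return pd.DataFrame([s.as_row() for s in summaries], columns=SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# Boxplot statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxplotStats:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        return {
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
        }


def _median(sorted_x: np.ndarray) -> float:
    n = sorted_x.size
    mid = n // 2
    if n % 2:
        return float(sorted_x[mid])
    return float((sorted_x[mid - 1] + sorted_x[mid]) / 2.0)


def boxplot_stats(values: Sequence[float], whiskers: str = "minmax") -> BoxplotStats:
    """Five-number boxplot summary with inclusive-median (Tukey hinge)
    quartiles.

    ``whiskers="minmax"`` places the whiskers at the data extremes (no
    outliers flagged); ``whiskers="tukey"`` uses the 1.5·IQR rule and
    reports points beyond the fences as outliers.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise SynthesisError("boxplot of empty input is undefined")
    med = _median(x)
    n = x.size
    if n == 1:
        v = float(x[0])
        return BoxplotStats(v, v, v, v, v)
    half = (n + 1) // 2  # inclusive of the median point when n is odd
    q1 = _median(x[:half])
    q3 = _median(x[n - half :])
    if whiskers == "minmax":
        return BoxplotStats(q1, med, q3, float(x[0]), float(x[-1]))
    if whiskers == "tukey":
        iqr = q3 - q1
        lo_fence = q1 - 1.5 * iqr
        hi_fence = q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
        return BoxplotStats(
            q1, med, q3, float(inside[0]), float(inside[-1]), outliers
        )
    raise SynthesisError(f"unknown whisker mode {whiskers!r} (use 'minmax' or 'tukey')")
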