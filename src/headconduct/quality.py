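"""Quality Assessment Score, per-record confidence and study weights.

The synthesis down-weights unreliable measurements with a bespoke scheme:

* **QAS** — per-study Quality Assessment Score: the mean score over the
  *relevant* items of a risk-of-bias checklist (each item scored in
  [0, 1]; irrelevant items are ignored).  The checklist itself is data,
  not code: a generic default is shipped and users may load their own.
* **confidence** — per-record: one minus the record's relative error,
  where the relative error is the reported SD percentage as a decimal
  or, failing that, the methodological error.  Relative errors above
  100% clamp the confidence to zero (the record is flagged, not deleted,
  so audit trails survive).
* **weight** = QAS × confidence, in [0, 1]; the record's contribution
  factor to every weighted statistic downstream.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .corpus import Corpus

__all__ = [
    "ChecklistItem",
    "QualityError",
    "QualityScore",
    "ConfidenceSource",
    "Confidence",
    "compute_qas",
    "compute_confidence",
    "compute_weight",
    "merge_scorers",
    "weight_records",
    "study_weight_summary",
    "default_checklist",
    "load_checklist",
    "load_study_checklists",
    "save_study_checklists",
]


class QualityError(ValueError):
    """Raised for undefined or out-of-range quality inputs."""


@dataclass
class ChecklistItem:
    item_id: str
    description: str = ""
    relevant: bool = True
    score: float | None = None  # in [0, 1]; ignored when irrelevant

    def __post_init__(self) -> None:
        if self.relevant:
            if self.score is None:
                raise QualityError(f"relevant item {self.item_id!r} has no score")
            if not (0.0 <= self.score <= 1.0):
                raise QualityError(
                    f"item {self.item_id!r} score {self.score} outside [0, 1]"
                )


class ConfidenceSource(str, enum.Enum):
    SD_PERCENT = "sd_percent"
    METHOD_ERROR = "method_error"
    NONE = "none"


class Confidence(NamedTuple):
    value: float
    source: ConfidenceSource
    clamped: bool  # relative error exceeded 100%


@dataclass(frozen=True)
class QualityScore:
    """Per-record quality triple: study QAS, record confidence, weight."""

    study_id: str
    qas: float
    confidence: float
    weight: float
    confidence_source: ConfidenceSource
    clamped: bool = False

    def __post_init__(self) -> None:
        for name in ("qas", "confidence", "weight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise QualityError(f"{name} {v} outside [0, 1]")
        if abs(self.weight - self.qas * self.confidence) > 1e-12:
            raise QualityError("weight must equal qas × confidence")


def compute_qas(items: Sequence[ChecklistItem]) -> float:
    """Sum of relevant-item scores divided by the number of relevant items."""
    relevant = [it for it in items if it.relevant]
    if not relevant:
        raise QualityError("QAS undefined: checklist has no relevant items")
    return sum(it.score for it in relevant) / len(relevant)


def compute_confidence(
    sd_percent: float | None = None, method_error: float | None = None
) -> Confidence:
    """Confidence = 1 − relative error, floored at zero.

    The relative error is ``sd_percent / 100`` when a standard-deviation
    percentage is reported; only in its absence does the methodological
    error (already a decimal fraction) stand in.  A relative error above
    one clamps the confidence to zero and flags the record — this is how
    unstable estimates (reported SDs of several thousand percent) are
    removed from the weighting without deleting them from the corpus.
    """
    if sd_percent is None and method_error is None:
        raise QualityError(
            "confidence undefined: neither sd_percent nor method_error present; "
            "supply a default-confidence policy for such records"
        )
    if sd_percent is not None:
        if sd_percent < 0 or not math.isfinite(sd_percent):
            raise QualityError(f"sd_percent must be a finite non-negative %, got {sd_percent}")
        rel, source = sd_percent / 100.0, ConfidenceSource.SD_PERCENT
    else:
        if method_error < 0 or not math.isfinite(method_error):
            raise QualityError(f"method_error must be a finite non-negative fraction, got {method_error}")
        rel, source = float(method_error), ConfidenceSource.METHOD_ERROR
    return Confidence(max(0.0, 1.0 - rel), source, clamped=rel > 1.0)


def compute_weight(qas: float, confidence: float) -> float:
    """Product of QAS and confidence; both (and hence the weight) in [0, 1]."""
    if not (0.0 <= qas <= 1.0):
        raise QualityError(f"qas {qas} outside [0, 1]")
    if not (0.0 <= confidence <= 1.0):
        raise QualityError(f"confidence {confidence} outside [0, 1]")
    return qas * confidence


def merge_scorers(
    a: Sequence[ChecklistItem], b: Sequence[ChecklistItem]
) -> list[ChecklistItem]:
    """Mean-of-scores reconciliation when two raters disagree.

    Items are matched by id; an item is relevant if either rater deemed it
    so, and its score is the mean of the scores the raters assigned.
    """
    by_id = {it.item_id: it for it in a}
    merged: list[ChecklistItem] = []
    seen: set[str] = set()
    for it_b in b:
        it_a = by_id.get(it_b.item_id)
        if it_a is None:
            merged.append(it_b)
            seen.add(it_b.item_id)
            continue
        seen.add(it_b.item_id)
        relevant = it_a.relevant or it_b.relevant
        scores = [it.score for it in (it_a, it_b) if it.relevant and it.score is not None]
        score = sum(scores) / len(scores) if scores else None
        merged.append(
            ChecklistItem(
                item_id=it_b.item_id,
                description=it_b.description or it_a.description,
                relevant=relevant,
                score=score,
            )
        )
    merged.extend(it for it in a if it.item_id not in seen)
    return merged


def weight_records(
    corpus: Corpus,
    qas_by_study: dict[str, float],
    missing_confidence: str | float = "unit",
) -> list[QualityScore]:
    """Per-record quality scores, index-aligned with ``corpus.records``.

    ``missing_confidence`` is the policy for records reporting neither a
    standard deviation nor a methodological error: ``"unit"`` assigns
    confidence 1 (no penalty beyond the study QAS), ``"zero"`` excludes
    them from the weighting, a float assigns that confidence, and
    ``"reject"`` raises.
    """
    scores: list[QualityScore] = []
    for i, rec in enumerate(corpus.records):
        if rec.study_id not in qas_by_study:
            raise QualityError(f"record {i}: no QAS for study {rec.study_id!r}")
        qas = qas_by_study[rec.study_id]
        if rec.sd_percent is None and rec.method_error is None:
            if missing_confidence == "reject":
                raise QualityError(
                    f"record {i} (study {rec.study_id!r}): no dispersion reported "
                    "and policy is 'reject'"
                )
            if missing_confidence == "unit":
                conf = Confidence(1.0, ConfidenceSource.NONE, False)
            elif missing_confidence == "zero":
                conf = Confidence(0.0, ConfidenceSource.NONE, False)
            else:
                conf = Confidence(float(missing_confidence), ConfidenceSource.NONE, False)
        else:
            conf = compute_confidence(rec.sd_percent, rec.method_error)
        scores.append(
            QualityScore(
                study_id=rec.study_id,
                qas=qas,
                confidence=conf.value,
                weight=compute_weight(qas, conf.value),
                confidence_source=conf.source,
                clamped=conf.clamped,
            )
        )
    return scores


def study_weight_summary(scores: Iterable[QualityScore]) -> pd.DataFrame:
    """Per-study mean ± sample SD (n−1) of record weights.

    Mirrors the mean ± SD convention of per-study weight reporting; the SD
    is absent (NaN) for single-record studies.
    """
    rows: dict[str, list[float]] = {}
    for s in scores:
        rows.setdefault(s.study_id, []).append(s.weight)
    out = []
    for sid, ws in rows.items():
        n = len(ws)
        mean = sum(ws) / n
        sd = math.sqrt(sum((w - mean) ** 2 for w in ws) / (n - 1)) if n > 1 else float("nan")
        out.append({"study_id": sid, "weight_mean": mean, "weight_sd": sd, "n_records": n})
    return pd.DataFrame(out, columns=["study_id", "weight_mean", "weight_sd", "n_records"])


# ---------------------------------------------------------------------------
# Checklist I/O
# ---------------------------------------------------------------------------


def _items_from_payload(payload: list[dict]) -> list[ChecklistItem]:
    return [
        ChecklistItem(
            item_id=entry["item_id"],
            description=entry.get("description", ""),
            relevant=entry.get("relevant", True),
            score=entry.get("score"),
        )
        for entry in payload
    ]


def default_checklist() -> list[ChecklistItem]:
    """The shipped generic risk-of-bias checklist (all items unscored
    templates: ``relevant`` true, ``score`` None → fill in per study)."""
    text = resources.files("headconduct.data").joinpath("default_checklist.json").read_text(
        encoding="utf-8"
    )
    payload = json.loads(text)
    return [
        ChecklistItem(
            item_id=entry["item_id"],
            description=entry.get("description", ""),
            relevant=False,  # templates carry no score until applied to a study
            score=None,
        )
        for entry in payload["items"]
    ]


def load_checklist(path: str | Path) -> list[ChecklistItem]:
    """Load one scored checklist from JSON or YAML (a list of items)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return _items_from_payload(payload)


def load_study_checklists(path: str | Path) -> dict[str, list[ChecklistItem]]:
    """Load per-study scored checklists: ``{study_id: [items...]}``."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return {sid: _items_from_payload(items) for sid, items in payload.items()}


def save_study_checklists(
    checklists: dict[str, list[ChecklistItem]], path: str | Path
) -> None:
    payload = {
        sid: [
            {
                "item_id": it.item_id,
                "description": it.description,
                "relevant": it.relevant,
                "score": it.score,
            }
            for it in items
        ]
        for sid, items in sorted(checklists.items())
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def qas_by_study(checklists: dict[str, list[ChecklistItem]]) -> dict[str, float]:
    """Convenience: QAS per study from scored checklists."""
    return {sid: compute_qas(items) for sid, items in checklists.items()}
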