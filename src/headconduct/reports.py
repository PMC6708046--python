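"""Pipeline orchestration and report emission.

``run_pipeline`` ties the stages together — load/validate the corpus,
apply the frequency filter, score quality weights, summarise every tissue
(summary table + boxplot statistics) and run the inferential battery
(weighted meta-regression, ANOVA/t per categorical covariate, Pearson per
continuous covariate) wherever the analysability rule is met — and writes
a deterministic report bundle: identical inputs, config and seed yield
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .corpus import (
    Corpus,
    DEFAULT_FREQUENCY_CUTOFF_HZ,
    apply_frequency_filter,
    read_corpus,
    read_study_info,
    validate_corpus,
)
from .inference import (
    DEFAULT_PREDICTORS,
    InferenceError,
    InsufficientDataError,
    build_design,
    one_way_anova,
    pearson_correlation,
    t_test_two_tailed,
    weighted_regression,
)
from .quality import (
    load_study_checklists,
    qas_by_study,
    study_weight_summary,
    weight_records,
)
from .reference import build_head_profile
from .synthesis import boxplot_stats, summarise_all, summary_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report_reference"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all stages)."""

    corpus_path: str | Path
    checklists_path: str | Path
    out_dir: str | Path
    studies_path: str | Path | None = None
    frequency_cutoff_hz: float = DEFAULT_FREQUENCY_CUTOFF_HZ
    missing_confidence: str | float = "unit"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    weighted_tests: bool = False
    log_response: bool = False
    boxplot_whiskers: str = "minmax"
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "corpus_path": str(self.corpus_path),
            "checklists_path": str(self.checklists_path),
            "studies_path": str(self.studies_path) if self.studies_path else None,
            "out_dir": str(self.out_dir),
            "frequency_cutoff_hz": self.frequency_cutoff_hz,
            "missing_confidence": self.missing_confidence,
            "predictors": list(self.predictors),
            "weighted_tests": self.weighted_tests,
            "log_response": self.log_response,
            "boxplot_whiskers": self.boxplot_whiskers,
            "seed": self.seed,
        }


def _write_json(path: Path, payload) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_CONTINUOUS_PREDICTORS = ("frequency_hz", "age")


def _covariate_value(rec, predictor: str):
    from .inference import _record_covariate

    return _record_covariate(rec, predictor)


def _tissue_inference(corpus: Corpus, scores, tissue, config: PipelineConfig) -> dict:
    """Regression plus per-covariate group tests for one tissue."""
    out: dict = {}
    try:
        design = build_design(
            corpus,
            scores,
            tissue,
            predictors=config.predictors,
            log_response=config.log_response,
        )
        out["regression"] = weighted_regression(design).as_dict()
    except InsufficientDataError as exc:
        out["regression"] = {"skipped": "insufficient data", "detail": str(exc)}
        logger.info("regression skipped for %s: %s", tissue, exc)
    except InferenceError as exc:
        out["regression"] = {"skipped": "inference error", "detail": str(exc)}
        logger.warning("regression failed for %s: %s", tissue, exc)

    records = [
        (rec, scores[i].weight)
        for i, rec in enumerate(corpus.records)
        if rec.tissue == tissue
    ]
    group_tests: dict = {}
    for predictor in config.predictors:
        if predictor in _CONTINUOUS_PREDICTORS:
            pairs = [
                (_covariate_value(rec, predictor), rec.sigma)
                for rec, _ in records
                if _covariate_value(rec, predictor) is not None
            ]
            if len(pairs) < 3:
                group_tests[predictor] = {"skipped": "insufficient data"}
                continue
            x = [p[0] for p in pairs]
            y = [p[1] for p in pairs]
            try:
                group_tests[predictor] = pearson_correlation(x, y).as_dict()
            except InferenceError as exc:
                group_tests[predictor] = {"skipped": str(exc)}
        else:
            groups: dict[str, list[float]] = {}
            gweights: dict[str, list[float]] = {}
            for rec, w in records:
                level = _covariate_value(rec, predictor)
                if level is None:
                    continue
                groups.setdefault(level, []).append(rec.sigma)
                gweights.setdefault(level, []).append(w)
            usable = {lv: v for lv, v in groups.items() if len(v) >= 2}
            if len(usable) < 2:
                group_tests[predictor] = {"skipped": "insufficient data"}
                continue
            labels = sorted(usable)
            values = [usable[lv] for lv in labels]
            wvals = [gweights[lv] for lv in labels] if config.weighted_tests else None
            try:
                if len(labels) == 2:
                    res = t_test_two_tailed(
                        values[0],
                        values[1],
                        labels=(labels[0], labels[1]),
                        weights=(wvals[0], wvals[1]) if wvals else None,
                    )
                else:
                    res = one_way_anova(values, labels=labels, weights=wvals)
                group_tests[predictor] = res.as_dict()
            except InferenceError as exc:
                group_tests[predictor] = {"skipped": str(exc)}
    out["group_tests"] = group_tests
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Emitted files: ``validation.json``, ``weights.tsv`` (per-study mean ±
    SD of record weights), ``summary.tsv`` (per-tissue descriptive table),
    ``boxplots.json``, ``inference.json``, ``accounting.json`` (every
    record attributed to exactly one of analysed / filtered) and
    ``manifest.json`` (inputs, hashes, config, version).  Returns the
    in-memory bundle.  Raises :class:`PipelineError` on unreadable input.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        corpus = read_corpus(config.corpus_path)
        checklists = load_study_checklists(config.checklists_path)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"unreadable input: {exc}") from exc
    if config.studies_path:
        try:
            corpus.studies.update(read_study_info(config.studies_path))
        except (OSError, ValueError) as exc:
            raise PipelineError(f"unreadable study metadata: {exc}") from exc

    report = validate_corpus(corpus)
    (out_dir / "validation.json").write_text(report.to_json() + "\n", encoding="utf-8")
    if not report.ok:
        raise PipelineError(
            f"corpus failed validation with {len(report.errors)} error(s); "
            f"see {out_dir / 'validation.json'}"
        )

    n_input = len(corpus)
    filtered = apply_frequency_filter(corpus, config.frequency_cutoff_hz)
    n_filtered = n_input - len(filtered)

    qas = qas_by_study(checklists)
    scores = weight_records(filtered, qas, missing_confidence=config.missing_confidence)

    weights_df = study_weight_summary(scores)
    weights_df.to_csv(out_dir / "weights.tsv", sep="\t", index=False, float_format="%.6g")

    summaries = summarise_all(filtered, scores)
    table = summary_table(summaries)
    table.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.6g")

    boxplots = {
        str(t): boxplot_stats(
            [r.sigma for r in filtered.for_tissue(t)], whiskers=config.boxplot_whiskers
        ).as_dict()
        for t in filtered.tissues()
    }
    _write_json(out_dir / "boxplots.json", boxplots)

    inference = {
        str(t): _tissue_inference(filtered, scores, t, config) for t in filtered.tissues()
    }
    _write_json(out_dir / "inference.json", inference)

    n_zero_weight = sum(1 for s in scores if s.weight == 0.0)
    accounting = {
        "n_input_records": n_input,
        "n_filtered_frequency": n_filtered,
        "n_analysed": len(filtered),
        "n_zero_weight": n_zero_weight,
        "frequency_cutoff_hz": config.frequency_cutoff_hz,
    }
    _write_json(out_dir / "accounting.json", accounting)

    manifest = {
        "tool": "headconduct",
        "version": __version__,
        "config": config.as_dict(),
        "inputs": {
            "corpus_sha256": _sha256(Path(config.corpus_path)),
            "checklists_sha256": _sha256(Path(config.checklists_path)),
            "studies_sha256": (
                _sha256(Path(config.studies_path)) if config.studies_path else None
            ),
        },
    }
    _write_json(out_dir / "manifest.json", manifest)

    return {
        "validation": report,
        "weights": weights_df,
        "summaries": summaries,
        "boxplots": boxplots,
        "inference": inference,
        "accounting": accounting,
        "manifest": manifest,
    }


def report_reference(
    skull_mode: str = "whole",
    brain_mode: str = "gm_wm",
    wm_mode: str = "isotropic",
    out_path: str | Path | None = None,
) -> dict:
    """Write (or return) a head-profile conductivity map built from the
    packaged reference values."""
    profile = build_head_profile(skull_mode, brain_mode, wm_mode)
    payload = {
        "skull_mode": profile.skull_mode.value,
        "brain_mode": profile.brain_mode.value,
        "wm_mode": profile.wm_mode.value,
        "layers": profile.as_dict(),
    }
    if out_path is not None:
        _write_json(Path(out_path), payload)
    return payload
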