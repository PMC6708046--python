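"""Extraction-record data model for head-tissue conductivity measurements.

One :class:`ConductivityRecord` holds a single reported conductivity value
(converted to S/m) together with the covariates that the meta-analysis
regresses against: measurement method, condition (in vivo / ex vivo /
in vitro), applied-current frequency, sample temperature, participant age
and pathology.  A :class:`Corpus` is an ordered collection of records plus
per-study metadata (participant counts, provenance).

All internal values are SI: conductivity in S/m (dimensionless for the
brain-to-skull conductivity ratio), frequency in Hz, temperature in °C,
age in years.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CORPUS_FORMAT_VERSION = 1

#: Exact column order of the tabular exchange format (tab-separated,
#: UTF-8, empty string = absent).
CORPUS_COLUMNS = [
    "study_id",
    "tissue",
    "value",
    "unit",
    "sd_percent",
    "method_error",
    "method",
    "condition",
    "frequency_hz",
    "temperature_c",
    "age_mean",
    "age_sd",
    "age_class",
    "pathology",
]


class CorpusError(ValueError):
    """Raised when a record or corpus file cannot be interpreted."""


# ---------------------------------------------------------------------------
# Tissue taxonomy
# ---------------------------------------------------------------------------


class Compartment(str, enum.Enum):
    SCALP = "scalp"
    SKULL = "skull"
    CSF = "csf"
    BRAIN = "brain"
    BSCR = "bscr"


class Subtissue(str, enum.Enum):
    WHOLE_SCALP = "whole_scalp"
    SKIN = "skin"
    FAT = "fat"
    MUSCLE = "muscle"
    WHOLE_SKULL = "whole_skull"
    SPONGIFORM = "spongiform"
    WHOLE_COMPACT = "whole_compact"
    INNER_COMPACT = "inner_compact"
    OUTER_COMPACT = "outer_compact"
    SUTURES = "sutures"
    CSF = "csf"
    WHOLE_BRAIN = "whole_brain"
    GM = "gm"
    WM = "wm"
    WM_PAR = "wm_par"
    WM_PERP = "wm_perp"
    DURA = "dura"
    BLOOD = "blood"
    CEREBELLUM = "cerebellum"
    LESION = "lesion"
    EZ = "ez"
    BSCR = "bscr"


_COMPARTMENT_OF: dict[Subtissue, Compartment] = {
    Subtissue.WHOLE_SCALP: Compartment.SCALP,
    Subtissue.SKIN: Compartment.SCALP,
    Subtissue.FAT: Compartment.SCALP,
    Subtissue.MUSCLE: Compartment.SCALP,
    Subtissue.WHOLE_SKULL: Compartment.SKULL,
    Subtissue.SPONGIFORM: Compartment.SKULL,
    Subtissue.WHOLE_COMPACT: Compartment.SKULL,
    Subtissue.INNER_COMPACT: Compartment.SKULL,
    Subtissue.OUTER_COMPACT: Compartment.SKULL,
    Subtissue.SUTURES: Compartment.SKULL,
    Subtissue.CSF: Compartment.CSF,
    Subtissue.WHOLE_BRAIN: Compartment.BRAIN,
    Subtissue.GM: Compartment.BRAIN,
    Subtissue.WM: Compartment.BRAIN,
    Subtissue.WM_PAR: Compartment.BRAIN,
    Subtissue.WM_PERP: Compartment.BRAIN,
    Subtissue.DURA: Compartment.BRAIN,
    Subtissue.BLOOD: Compartment.BRAIN,
    Subtissue.CEREBELLUM: Compartment.BRAIN,
    Subtissue.LESION: Compartment.BRAIN,
    Subtissue.EZ: Compartment.BRAIN,
    Subtissue.BSCR: Compartment.BSCR,
}


@dataclass(frozen=True)
class TissueLabel:
    """A tissue identified by sub-tissue; the compartment is derived.

    ``bscr`` (brain-to-skull conductivity ratio) is a dimensionless
    pseudo-tissue: its "conductivity" is a unitless ratio.
    """

    subtissue: Subtissue

    def __post_init__(self) -> None:
        if not isinstance(self.subtissue, Subtissue):
            object.__setattr__(self, "subtissue", Subtissue(self.subtissue))

    @property
    def compartment(self) -> Compartment:
        return _COMPARTMENT_OF[self.subtissue]

    @property
    def is_ratio(self) -> bool:
        return self.subtissue is Subtissue.BSCR

    @classmethod
    def from_name(cls, name: str) -> "TissueLabel":
        try:
            return cls(Subtissue(name.strip().lower()))
        except ValueError:
            valid = ", ".join(s.value for s in Subtissue)
            raise CorpusError(f"unknown tissue {name!r}; expected one of: {valid}")

    def __str__(self) -> str:
        return self.subtissue.value


# ---------------------------------------------------------------------------
# Covariate enums
# ---------------------------------------------------------------------------


class Method(str, enum.Enum):
    DAC = "DAC"       # directly applied current (invasive)
    EIT = "EIT"       # electrical impedance tomography
    EMEG = "EMEG"     # conductivity estimated from E/MEG recordings
    MREIT = "MREIT"   # magnetic-resonance EIT
    DTI = "DTI"       # diffusion-tensor-derived conductivity


class Condition(str, enum.Enum):
    IN_VIVO = "in_vivo"
    EX_VIVO = "ex_vivo"
    IN_VITRO = "in_vitro"


class TemperatureClass(str, enum.Enum):
    BODY = "body"
    ROOM = "room"
    UNKNOWN = "unknown"


class AgeClass(str, enum.Enum):
    ADULT = "adult"
    PAEDIATRIC = "paediatric"
    BOTH = "both"
    UNKNOWN = "unknown"


class Pathology(str, enum.Enum):
    HEALTHY = "healthy"
    EPILEPSY = "epilepsy"
    TUMOUR = "tumour"
    NEURO = "neuro"
    PARKINSONS = "parkinsons"
    ALZHEIMERS = "alzheimers"
    STROKE = "stroke"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Unit normalisation
# ---------------------------------------------------------------------------


class Unit(str, enum.Enum):
    S_PER_M = "S/m"
    MS_PER_CM = "mS/cm"
    S_PER_CM = "S/cm"
    OHM_M = "ohm.m"      # resistivity
    OHM_CM = "ohm.cm"    # resistivity
    KOHM_CM = "kohm.cm"  # resistivity
    RATIO = "ratio"      # dimensionless (BSCR)


_RESISTIVITY_TO_OHM_M = {Unit.OHM_M: 1.0, Unit.OHM_CM: 0.01, Unit.KOHM_CM: 10.0}
_CONDUCTIVITY_TO_S_PER_M = {Unit.S_PER_M: 1.0, Unit.MS_PER_CM: 0.1, Unit.S_PER_CM: 100.0}


def to_conductivity(value: float, unit: Unit | str) -> float:
    """Convert a reported value to conductivity in S/m.

    Conductivity units are rescaled to S/m; resistivity units are rescaled
    to Ω·m and inverted (σ = 1/ρ); a dimensionless ratio passes through
    unchanged.  Impedance values that would require electrode geometry to
    convert are not accepted.
    """
    if isinstance(unit, str):
        try:
            unit = Unit(unit)
        except ValueError:
            valid = ", ".join(u.value for u in Unit)
            raise CorpusError(f"unknown unit {unit!r}; expected one of: {valid}")
    if not math.isfinite(value) or value <= 0:
        raise CorpusError(f"non-positive reported value {value!r} ({unit.value})")
    if unit in _CONDUCTIVITY_TO_S_PER_M:
        return value * _CONDUCTIVITY_TO_S_PER_M[unit]
    if unit in _RESISTIVITY_TO_OHM_M:
        return 1.0 / (value * _RESISTIVITY_TO_OHM_M[unit])
    return value  # ratio


# ---------------------------------------------------------------------------
# Covariate classification
# ---------------------------------------------------------------------------

# Body temperature is taken as the 35-38 °C neighbourhood of 37 °C; room as
# the stated 18-25 °C band.  Temperatures between the bands (or above body)
# are deliberately left unknown rather than snapped to the nearer band.
BODY_TEMPERATURE_BAND_C = (35.0, 38.0)
ROOM_TEMPERATURE_BAND_C = (18.0, 25.0)

ADULT_AGE_YEARS = 18.0


def classify_temperature(temperature_c: float | None) -> TemperatureClass:
    """Classify a sample temperature as body, room or unknown (total function)."""
    if temperature_c is None or not math.isfinite(temperature_c):
        return TemperatureClass.UNKNOWN
    lo, hi = BODY_TEMPERATURE_BAND_C
    if lo <= temperature_c <= hi:
        return TemperatureClass.BODY
    lo, hi = ROOM_TEMPERATURE_BAND_C
    if lo <= temperature_c <= hi:
        return TemperatureClass.ROOM
    return TemperatureClass.UNKNOWN


def classify_age(
    ages_years: Sequence[float] | None = None,
    label: AgeClass | str | None = None,
) -> AgeClass:
    """Classify participant ages: all ≥18 → adult, all <18 → paediatric,
    mixed → both, no information → unknown.

    A pre-assigned label wins when no numeric ages are given.  Negative
    ages are rejected.
    """
    if ages_years:
        ages = list(ages_years)
        if any(a < 0 for a in ages):
            raise CorpusError(f"negative age in {ages}")
        adult = [a >= ADULT_AGE_YEARS for a in ages]
        if all(adult):
            return AgeClass.ADULT
        if not any(adult):
            return AgeClass.PAEDIATRIC
        return AgeClass.BOTH
    if label is not None:
        return AgeClass(label)
    return AgeClass.UNKNOWN


# ---------------------------------------------------------------------------
# Records and corpus
# ---------------------------------------------------------------------------


@dataclass
class ConductivityRecord:
    """One extracted conductivity measurement with its covariates.

    ``sigma`` is the value in S/m (a unitless ratio for BSCR).  At most
    one of ``sd_percent`` (relative SD of the reported value, in percent)
    and ``method_error`` (methodology error as a decimal fraction) is used
    downstream; when both are present the standard deviation takes
    precedence.  Optional covariates are ``None`` when unreported — never
    silently defaulted to a number.
    """

    study_id: str
    tissue: TissueLabel
    sigma: float
    reported_value: float | None = None
    reported_unit: Unit | None = None
    sd_percent: float | None = None
    method_error: float | None = None
    method: Method | None = None
    condition: Condition | None = None
    frequency_hz: float | None = None
    frequency_is_midpoint: bool = False
    temperature_c: float | None = None
    temperature_class: TemperatureClass = TemperatureClass.UNKNOWN
    age_mean_years: float | None = None
    age_sd_years: float | None = None
    age_class: AgeClass = AgeClass.UNKNOWN
    pathology: Pathology = Pathology.UNKNOWN

    @classmethod
    def from_reported(
        cls,
        study_id: str,
        tissue: TissueLabel | str,
        value: float,
        unit: Unit | str,
        **kwargs,
    ) -> "ConductivityRecord":
        """Build a record from an as-printed value, converting to S/m and
        deriving temperature/age classes when not supplied."""
        if isinstance(tissue, str):
            tissue = TissueLabel.from_name(tissue)
        if isinstance(unit, str):
            try:
                unit = Unit(unit)
            except ValueError:
                valid = ", ".join(u.value for u in Unit)
                raise CorpusError(
                    f"unknown unit {unit!r} in study {study_id!r}; "
                    f"expected one of: {valid}"
                )
        for key, enum_cls in (
            ("method", Method),
            ("condition", Condition),
            ("temperature_class", TemperatureClass),
            ("age_class", AgeClass),
            ("pathology", Pathology),
        ):
            if isinstance(kwargs.get(key), str):
                kwargs[key] = enum_cls(kwargs[key])
        if tissue.is_ratio and unit is not Unit.RATIO:
            raise CorpusError(
                f"study {study_id!r}: BSCR is dimensionless and may not carry "
                f"unit {unit.value!r}"
            )
        try:
            sigma = to_conductivity(value, unit)
        except CorpusError as exc:
            raise CorpusError(f"study {study_id!r}, tissue {tissue}: {exc}") from None
        rec = cls(
            study_id=study_id,
            tissue=tissue,
            sigma=sigma,
            reported_value=value,
            reported_unit=unit,
            **kwargs,
        )
        if rec.temperature_class is TemperatureClass.UNKNOWN and rec.temperature_c is not None:
            rec.temperature_class = classify_temperature(rec.temperature_c)
        if rec.age_class is AgeClass.UNKNOWN and rec.age_mean_years is not None:
            rec.age_class = (
                AgeClass.ADULT
                if rec.age_mean_years >= ADULT_AGE_YEARS
                else AgeClass.PAEDIATRIC
            )
        return rec


@dataclass
class StudyInfo:
    """Per-study metadata that is not part of the per-record schema."""

    n_participants: int | None = None
    provenance: str = ""


@dataclass
class Corpus:
    records: list[ConductivityRecord] = field(default_factory=list)
    studies: dict[str, StudyInfo] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ConductivityRecord]:
        return iter(self.records)

    def study_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.study_id)
        return list(seen)

    def for_tissue(self, tissue: TissueLabel | str) -> list[ConductivityRecord]:
        if isinstance(tissue, str):
            tissue = TissueLabel.from_name(tissue)
        return [r for r in self.records if r.tissue == tissue]

    def tissues(self) -> list[TissueLabel]:
        seen: dict[TissueLabel, None] = {}
        for rec in self.records:
            seen.setdefault(rec.tissue)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-record view (one row per record, enums as strings)."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "study_id": rec.study_id,
                    "tissue": str(rec.tissue),
                    "compartment": rec.tissue.compartment.value,
                    "sigma": rec.sigma,
                    "sd_percent": rec.sd_percent,
                    "method_error": rec.method_error,
                    "method": rec.method.value if rec.method else None,
                    "condition": rec.condition.value if rec.condition else None,
                    "frequency_hz": rec.frequency_hz,
                    "temperature_c": rec.temperature_c,
                    "temperature_class": rec.temperature_class.value,
                    "age_mean_years": rec.age_mean_years,
                    "age_sd_years": rec.age_sd_years,
                    "age_class": rec.age_class.value,
                    "pathology": rec.pathology.value,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

DEFAULT_FREQUENCY_CUTOFF_HZ = 1000.0


def apply_frequency_filter(
    corpus: Corpus, cutoff_hz: float = DEFAULT_FREQUENCY_CUTOFF_HZ
) -> Corpus:
    """Remove records whose applied-current frequency exceeds ``cutoff_hz``.

    The comparison is strict (a record exactly at the cutoff is retained)
    and records with unreported frequency are kept.  Frequencies above
    ~1 kHz lie outside the bandwidth of the neuronal signals that E/MEG
    records, which is why the synthesis drops them; the cutoff stays
    configurable because a handful of studies report points a few hertz
    above it.  Idempotent; never increases the record count.
    """
    if cutoff_hz <= 0:
        raise CorpusError(f"cutoff_hz must be positive, got {cutoff_hz}")
    kept = [
        r
        for r in corpus.records
        if r.frequency_hz is None or r.frequency_hz <= cutoff_hz
    ]
    removed = len(corpus.records) - len(kept)
    if removed:
        logger.info(
            "frequency filter (> %g Hz): removed %d of %d records",
            cutoff_hz,
            removed,
            len(corpus.records),
        )
    return Corpus(records=kept, studies=dict(corpus.studies))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

# Sanity bands: tissues in (0, 10] S/m, BSCR in (0, 1000].
SIGMA_SANITY_MAX_S_PER_M = 10.0
BSCR_SANITY_MAX = 1000.0


@dataclass(frozen=True)
class ValidationIssue:
    index: int
    study_id: str
    field: str
    message: str

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "study_id": self.study_id,
            "field": self.field,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self, **kwargs) -> str:
        payload = {
            "analysable": self.ok,
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "errors": [e.as_dict() for e in self.errors],
            "warnings": [w.as_dict() for w in self.warnings],
        }
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(payload, **kwargs)


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Check every record invariant; a corpus with zero errors is analysable.

    Violations are reported (with record index and field), never raised.
    """
    report = ValidationReport()

    def err(i: int, rec: ConductivityRecord, fieldname: str, msg: str) -> None:
        report.errors.append(ValidationIssue(i, rec.study_id, fieldname, msg))

    def warn(i: int, rec: ConductivityRecord, fieldname: str, msg: str) -> None:
        report.warnings.append(ValidationIssue(i, rec.study_id, fieldname, msg))

    for i, rec in enumerate(corpus.records):
        if not rec.study_id:
            err(i, rec, "study_id", "empty study identifier")
        if not isinstance(rec.tissue, TissueLabel):
            err(i, rec, "tissue", f"not a defined tissue label: {rec.tissue!r}")
            continue
        if not math.isfinite(rec.sigma) or rec.sigma <= 0:
            err(i, rec, "sigma", f"non-positive conductivity ({rec.sigma!r})")
        elif rec.tissue.is_ratio:
            if rec.sigma > BSCR_SANITY_MAX:
                err(i, rec, "sigma", f"BSCR {rec.sigma} outside (0, {BSCR_SANITY_MAX}]")
        elif rec.sigma > SIGMA_SANITY_MAX_S_PER_M:
            err(
                i, rec, "sigma",
                f"conductivity {rec.sigma} S/m outside (0, {SIGMA_SANITY_MAX_S_PER_M}]",
            )
        if rec.tissue.is_ratio and rec.reported_unit not in (None, Unit.RATIO):
            err(i, rec, "reported_unit", "BSCR may not carry a unit of S/m")
        if rec.sd_percent is not None and rec.sd_percent < 0:
            err(i, rec, "sd_percent", f"negative sd_percent ({rec.sd_percent})")
        if rec.method_error is not None and rec.method_error < 0:
            err(i, rec, "method_error", f"negative method_error ({rec.method_error})")
        if rec.sd_percent is not None and rec.method_error is not None:
            warn(
                i, rec, "sd_percent",
                "both sd_percent and method_error present; sd_percent takes precedence",
            )
        if rec.frequency_hz is not None and rec.frequency_hz < 0:
            err(i, rec, "frequency_hz", f"negative frequency ({rec.frequency_hz})")
        if rec.age_mean_years is not None and rec.age_mean_years < 0:
            err(i, rec, "age_mean", f"negative age ({rec.age_mean_years})")
        for fieldname, value in (
            ("sd_percent/method_error", rec.sd_percent if rec.sd_percent is not None else rec.method_error),
            ("method", rec.method),
            ("condition", rec.condition),
            ("frequency_hz", rec.frequency_hz),
        ):
            if value is None:
                warn(i, rec, fieldname, "absent optional covariate")
        if rec.temperature_class is TemperatureClass.UNKNOWN and rec.temperature_c is None:
            warn(i, rec, "temperature_c", "absent optional covariate")
        if rec.age_class is AgeClass.UNKNOWN and rec.age_mean_years is None:
            warn(i, rec, "age_mean", "absent optional covariate")
    return report


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus in the versioned tab-separated exchange format."""
    path = Path(path)
    lines = [f"#headconduct-corpus\tv{CORPUS_FORMAT_VERSION}", "\t".join(CORPUS_COLUMNS)]
    for rec in corpus.records:
        value = rec.reported_value if rec.reported_value is not None else rec.sigma
        unit = rec.reported_unit
        if unit is None:
            unit = Unit.RATIO if rec.tissue.is_ratio else Unit.S_PER_M
        lines.append(
            "\t".join(
                [
                    rec.study_id,
                    str(rec.tissue),
                    _fmt(value),
                    _fmt(unit),
                    _fmt(rec.sd_percent),
                    _fmt(rec.method_error),
                    _fmt(rec.method),
                    _fmt(rec.condition),
                    _fmt(rec.frequency_hz),
                    _fmt(rec.temperature_c),
                    _fmt(rec.age_mean_years),
                    _fmt(rec.age_sd_years),
                    rec.age_class.value if rec.age_class is not AgeClass.UNKNOWN else "",
                    rec.pathology.value if rec.pathology is not Pathology.UNKNOWN else "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _opt_float(token: str, where: str) -> float | None:
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise CorpusError(f"{where}: not a number: {token!r}")


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus from the versioned tab-separated exchange format."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CorpusError(f"{path}: empty file")
    start = 0
    if lines[0].startswith("#headconduct-corpus"):
        version = lines[0].split("\t")[-1].lstrip("v")
        if version != str(CORPUS_FORMAT_VERSION):
            raise CorpusError(f"{path}: unsupported corpus format version {version!r}")
        start = 1
    header = lines[start].split("\t")
    if header != CORPUS_COLUMNS:
        raise CorpusError(
            f"{path}: header mismatch; expected columns {CORPUS_COLUMNS}, got {header}"
        )
    records: list[ConductivityRecord] = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(CORPUS_COLUMNS):
            raise CorpusError(
                f"{path}:{lineno}: expected {len(CORPUS_COLUMNS)} fields, got {len(cells)}"
            )
        row = dict(zip(CORPUS_COLUMNS, cells))
        where = f"{path}:{lineno}"
        value = _opt_float(row["value"], where)
        if value is None:
            raise CorpusError(f"{where}: missing value")
        try:
            rec = ConductivityRecord.from_reported(
                study_id=row["study_id"],
                tissue=row["tissue"],
                value=value,
                unit=row["unit"],
                sd_percent=_opt_float(row["sd_percent"], where),
                method_error=_opt_float(row["method_error"], where),
                method=Method(row["method"]) if row["method"] else None,
                condition=Condition(row["condition"]) if row["condition"] else None,
                frequency_hz=_opt_float(row["frequency_hz"], where),
                temperature_c=_opt_float(row["temperature_c"], where),
                age_mean_years=_opt_float(row["age_mean"], where),
                age_sd_years=_opt_float(row["age_sd"], where),
                age_class=AgeClass(row["age_class"]) if row["age_class"] else AgeClass.UNKNOWN,
                pathology=Pathology(row["pathology"]) if row["pathology"] else Pathology.UNKNOWN,
            )
        except ValueError as exc:
            raise CorpusError(f"{where}: {exc}") from None
        records.append(rec)
    return Corpus(records=records)


def write_study_info(studies: dict[str, StudyInfo], path: str | Path) -> None:
    payload = {
        sid: {"n_participants": info.n_participants, "provenance": info.provenance}
        for sid, info in sorted(studies.items())
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_study_info(path: str | Path) -> dict[str, StudyInfo]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        sid: StudyInfo(
            n_participants=entry.get("n_participants"),
            provenance=entry.get("provenance", ""),
        )
        for sid, entry in payload.items()
    }
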