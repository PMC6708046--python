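"""Inferential stages of the meta-analysis.

Weighted multiple regression of conductivity on study-level covariates
(meta-regression), one-way ANOVA, pooled two-tailed t test and Pearson
correlation.  The estimators are implemented directly with numpy linear
algebra so each is verifiable against a brute-force oracle; only the
reference distributions (F, t) come from scipy.

Weights enter the regression as weighted least squares minimising
Σwᵢ(yᵢ − xᵢᵀβ)².  The group-comparison tests are unweighted by default —
the quality weights attach to the regression stage — with frequency-
weighted variants behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .corpus import AgeClass, Corpus, TemperatureClass, TissueLabel
from .quality import QualityScore

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceError",
    "InsufficientDataError",
    "DesignMatrix",
    "RegressionResult",
    "TestResult",
    "DEFAULT_PREDICTORS",
    "build_design",
    "weighted_regression",
    "one_way_anova",
    "t_test_two_tailed",
    "pearson_correlation",
    "benjamini_hochberg",
]


class InferenceError(ValueError):
    pass


class InsufficientDataError(InferenceError):
    """A tissue below the analysability threshold (too few records or too
    little covariate contrast) — reported, not silently skipped."""


#: Covariates the meta-regression considers, in reporting order.
DEFAULT_PREDICTORS = (
    "condition",
    "method",
    "frequency_hz",
    "temperature_class",
    "age",
    "pathology",
)

_CATEGORICAL = {"condition", "method", "temperature_class", "pathology", "age_class"}
_CONTINUOUS = {"frequency_hz", "age"}


@dataclass
class DesignMatrix:
    """Response, coded predictor columns and weights for one tissue.

    Categorical predictors are reference-coded against their most frequent
    level (ties broken lexicographically); records missing any required
    covariate are masked out and counted in ``n_masked``.
    """

    tissue: TissueLabel
    y: np.ndarray
    X: np.ndarray                      # includes leading intercept column
    columns: list[str]                 # names matching X's columns
    weights: np.ndarray
    n_total: int
    n_masked: int
    coding: dict[str, dict] = field(default_factory=dict)
    dropped_predictors: list[str] = field(default_factory=list)
    substitutions: dict[str, str] = field(default_factory=dict)
    log_response: bool = False

    @property
    def n(self) -> int:
        return int(self.y.size)


def _record_covariate(rec, predictor: str):
    """Covariate value for design construction; None = missing/uninformative."""
    if predictor == "method":
        return rec.method.value if rec.method is not None else None
    if predictor == "condition":
        return rec.condition.value if rec.condition is not None else None
    if predictor == "temperature_class":
        if rec.temperature_class is TemperatureClass.UNKNOWN:
            return None
        return rec.temperature_class.value
    if predictor == "pathology":
        from .corpus import Pathology

        return rec.pathology.value if rec.pathology is not Pathology.UNKNOWN else None
    if predictor == "frequency_hz":
        return rec.frequency_hz
    if predictor == "age":
        return rec.age_mean_years
    if predictor == "age_class":
        return rec.age_class.value if rec.age_class is not AgeClass.UNKNOWN else None
    raise InferenceError(f"unknown predictor {predictor!r}")


def build_design(
    corpus: Corpus,
    scores: Sequence[QualityScore],
    tissue: TissueLabel | str,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    min_records: int = 4,
    min_predictors: int = 2,
    log_response: bool = False,
) -> DesignMatrix:
    """Assemble the weighted design matrix for one tissue.

    Mirrors the analysability rule used in the synthesis — more than three
    results with contrast in at least two covariates — and raises
    :class:`InsufficientDataError` labelled "insufficient data" otherwise.
    Predictors with a single observed level carry no contrast and are
    dropped with a warning.  ``age`` enters as mean age in years; use
    ``age_class`` instead for class indicators (never both in one design).
    """
    if isinstance(tissue, str):
        tissue = TissueLabel.from_name(tissue)
    if "age" in predictors and "age_class" in predictors:
        raise InferenceError("use either 'age' (years) or 'age_class', not both")
    if len(scores) != len(corpus.records):
        raise InferenceError("scores are not aligned with corpus records")

    rows = [
        (rec, scores[i].weight)
        for i, rec in enumerate(corpus.records)
        if rec.tissue == tissue
    ]
    n_total = len(rows)

    # Age enters as mean age in years when most records report it
    # numerically; otherwise as age-class indicators (never both).
    substitutions: dict[str, str] = {}
    predictors = list(predictors)
    if "age" in predictors and n_total > 0:
        n_numeric = sum(1 for rec, _ in rows if rec.age_mean_years is not None)
        if n_numeric < 0.5 * n_total:
            predictors[predictors.index("age")] = "age_class"
            substitutions["age"] = "age_class"
            logger.info(
                "age reported numerically for only %d/%d %s records; "
                "using age_class indicators instead",
                n_numeric, n_total, tissue,
            )

    # Mask records missing any covariate that any requested predictor needs.
    usable: list[tuple[object, float, dict]] = []
    for rec, w in rows:
        covs = {p: _record_covariate(rec, p) for p in predictors}
        if any(v is None for v in covs.values()):
            continue
        usable.append((rec, w, covs))
    n_masked = n_total - len(usable)

    if len(usable) <= min_records - 1 or len(usable) < 2:
        raise InsufficientDataError(
            f"insufficient data for {tissue}: {len(usable)} usable records "
            f"(of {n_total}; {n_masked} masked for missing covariates); "
            f"need more than {min_records - 1}"
        )

    coding: dict[str, dict] = {}
    dropped: list[str] = []
    columns: list[str] = ["const"]
    col_data: list[np.ndarray] = [np.ones(len(usable))]

    for p in predictors:
        vals = [covs[p] for _, _, covs in usable]
        if p in _CONTINUOUS:
            arr = np.asarray(vals, dtype=float)
            if np.allclose(arr, arr[0]):
                dropped.append(p)
                logger.warning("predictor %s has a single value for %s; dropped", p, tissue)
                continue
            columns.append(p)
            col_data.append(arr)
            coding[p] = {"type": "continuous"}
        else:
            levels = sorted(set(vals))
            if len(levels) < 2:
                dropped.append(p)
                logger.warning("predictor %s has a single level for %s; dropped", p, tissue)
                continue
            counts = {lv: vals.count(lv) for lv in levels}
            # reference = most frequent level; ties broken lexicographically
            best = max(counts.values())
            reference = sorted(lv for lv in levels if counts[lv] == best)[0]
            coding[p] = {"type": "categorical", "reference": reference, "levels": levels}
            for lv in levels:
                if lv == reference:
                    continue
                columns.append(f"{p}[{lv}]")
                col_data.append(np.asarray([1.0 if v == lv else 0.0 for v in vals]))

    n_usable_predictors = len(coding)
    if n_usable_predictors < min_predictors:
        raise InsufficientDataError(
            f"insufficient data for {tissue}: only {n_usable_predictors} "
            f"predictor(s) with contrast (need {min_predictors})"
        )

    y = np.asarray([rec.sigma for rec, _, _ in usable], dtype=float)
    if log_response:
        y = np.log(y)
    w = np.asarray([wt for _, wt, _ in usable], dtype=float)
    X = np.column_stack(col_data)
    return DesignMatrix(
        tissue=tissue,
        y=y,
        X=X,
        columns=columns,
        weights=w,
        n_total=n_total,
        n_masked=n_masked,
        coding=coding,
        dropped_predictors=dropped,
        substitutions=substitutions,
        log_response=log_response,
    )


@dataclass(frozen=True)
class RegressionResult:
    """Weighted least squares fit with its omnibus F test."""

    tissue: TissueLabel | None
    columns: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    n: int
    n_masked: int = 0
    dropped_columns: tuple[str, ...] = ()

    def coefficient(self, name: str) -> tuple[float, float]:
        i = self.columns.index(name)
        return self.coefficients[i], self.standard_errors[i]

    def confint(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for one coefficient."""
        est, se = self.coefficient(name)
        tcrit = float(stats.t.ppf(0.5 + level / 2.0, self.df_resid))
        return est - tcrit * se, est + tcrit * se

    def as_dict(self) -> dict:
        return {
            "tissue": str(self.tissue) if self.tissue else None,
            "n": self.n,
            "n_masked": self.n_masked,
            "coefficients": {
                c: {"estimate": b, "se": s}
                for c, b, s in zip(self.columns, self.coefficients, self.standard_errors)
            },
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "p_value": self.p_value,
            "dropped_columns": list(self.dropped_columns),
        }


def weighted_regression(design: DesignMatrix) -> RegressionResult:
    """Weighted least squares minimising Σwᵢ(yᵢ − xᵢᵀβ)².

    Solved through the √w-scaled design; exactly collinear columns are
    dropped (with a warning) until the design is full rank.  R² is the
    weighted coefficient of determination, F the omnibus test of all
    non-intercept terms, and coefficient standard errors come from
    s²(XᵀWX)⁻¹ with s² = Σwe²/df_resid.
    """
    y, X, w = design.y, design.X, design.weights
    if np.any(w < 0):
        raise InferenceError("negative weights")
    if w.sum() <= 0:
        raise InferenceError("all-zero weights")

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw

    # Rank repair: greedily drop later columns that add no rank.
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(Xw.shape[1]):
        candidate = Xw[:, keep + [j]]
        r = np.linalg.matrix_rank(candidate)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(design.columns[j])
    if dropped:
        logger.warning("dropped collinear columns: %s", ", ".join(dropped))
    cols = [design.columns[j] for j in keep]
    Xw = Xw[:, keep]

    n, p_full = Xw.shape
    df_model = p_full - 1  # non-intercept terms
    df_resid = n - p_full
    if df_resid < 1:
        raise InsufficientDataError(
            f"insufficient data: zero residual degrees of freedom (n={n}, p={p_full})"
        )

    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    ss_res = float(resid_w @ resid_w)
    ybar_w = float((w * y).sum() / w.sum())
    ss_tot = float((w * (y - ybar_w) ** 2).sum())
    if ss_tot <= 0:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)

    if df_model == 0:
        f = 0.0
        p = 1.0
    elif ss_res <= 1e-30 * max(ss_tot, 1.0):
        f = math.inf
        p = 0.0
    else:
        f = (r2 / df_model) / ((1.0 - r2) / df_resid) if r2 < 1.0 else math.inf
        p = float(stats.f.sf(f, df_model, df_resid)) if math.isfinite(f) else 0.0

    s2 = ss_res / df_resid
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    se = np.sqrt(np.clip(s2 * np.diag(xtx_inv), 0.0, None))

    return RegressionResult(
        tissue=design.tissue,
        columns=tuple(cols),
        coefficients=tuple(float(b) for b in beta),
        standard_errors=tuple(float(s) for s in se),
        r_squared=r2,
        f_stat=float(f),
        df_model=df_model,
        df_resid=df_resid,
        p_value=float(p),
        n=n,
        n_masked=design.n_masked,
        dropped_columns=tuple(dropped),
    )


@dataclass(frozen=True)
class TestResult:
    """A t, F or r statistic with its degrees of freedom and two-tailed /
    upper-tail p-value, plus the group labels and means it compares."""

    kind: str                      # "t" | "anova" | "pearson"
    statistic: float
    df: tuple[int, ...]
    p_value: float
    group_labels: tuple[str, ...] = ()
    group_means: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "group_labels": list(self.group_labels),
            "group_means": list(self.group_means),
        }


def _group_stats(g: np.ndarray, w: np.ndarray | None):
    if w is None:
        return g.size, float(g.mean()), float(((g - g.mean()) ** 2).sum())
    total = w.sum()
    n_eff = total**2 / (w**2).sum()
    mean = float((w * g).sum() / total)
    ss = float((w * (g - mean) ** 2).sum())
    return n_eff, mean, ss


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    weights: Sequence[Sequence[float]] | None = None,
) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within with
    (k−1, n−k) degrees of freedom and an upper-tail p.

    Identical group means with zero within-group variance give F = 0,
    p = 1.  ``weights`` switches to a frequency-weighted variant (weighted
    group means and sums of squares, effective n); unweighted by default
    because the quality weights attach to the regression stage.
    """
    if len(groups) < 2:
        raise InferenceError("ANOVA needs at least 2 groups")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in gs):
        raise InferenceError("empty group")
    ws = None
    if weights is not None:
        ws = [np.asarray(w, dtype=float) for w in weights]
        if any(w.shape != g.shape for w, g in zip(ws, gs)):
            raise InferenceError("weights are not aligned with groups")

    stats_per_group = [
        _group_stats(g, ws[i] if ws is not None else None) for i, g in enumerate(gs)
    ]
    ns = [s[0] for s in stats_per_group]
    means = [s[1] for s in stats_per_group]
    ss_within = sum(s[2] for s in stats_per_group)
    n = sum(ns)
    k = len(gs)
    if n <= k:
        raise InferenceError(f"total n ({n}) must exceed the number of groups ({k})")
    grand = sum(ni * mi for ni, mi in zip(ns, means)) / n
    ss_between = sum(ni * (mi - grand) ** 2 for ni, mi in zip(ns, means))
    df_b, df_w = k - 1, int(round(n)) - k

    if ss_within <= 1e-30 * max(ss_between, 1.0):
        if ss_between <= 1e-30:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    return TestResult(
        kind="anova",
        statistic=float(f),
        df=(df_b, df_w),
        p_value=float(p),
        group_labels=tuple(labels),
        group_means=tuple(means),
    )


def t_test_two_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    weights: tuple[Sequence[float], Sequence[float]] | None = None,
) -> TestResult:
    """Pooled-variance two-sample t test, df = n₁ + n₂ − 2, two-tailed p.

    Zero pooled variance with equal means gives t = 0, p = 1.  The pooled
    (classical) form is the default; a frequency-weighted variant is
    available through ``weights``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InferenceError("each group needs n ≥ 2")
    wa = wb = None
    if weights is not None:
        wa = np.asarray(weights[0], dtype=float)
        wb = np.asarray(weights[1], dtype=float)
    na, ma, ssa = _group_stats(a, wa)
    nb, mb, ssb = _group_stats(b, wb)
    df = int(round(na + nb)) - 2
    pooled_var = (ssa + ssb) / (na + nb - 2)
    denom = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb)) if pooled_var > 0 else 0.0
    diff = ma - mb
    if denom == 0.0:
        if abs(diff) <= 1e-30:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, diff), 0.0
    else:
        t = diff / denom
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(
        kind="t",
        statistic=float(t),
        df=(df,),
        p_value=float(p),
        group_labels=tuple(labels),
        group_means=(ma, mb),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with df = n − 2 and two-tailed p via t = r√df/√(1 − r²)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InferenceError("x and y must be 1-D and equal length")
    n = xa.size
    if n < 3:
        raise InferenceError("correlation needs n ≥ 3")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float((xc**2).sum())
    sy = float((yc**2).sum())
    if sx <= 0 or sy <= 0:
        raise InferenceError("correlation undefined for a constant input")
    r = float((xc * yc).sum() / math.sqrt(sx * sy))
    r = min(max(r, -1.0), 1.0)
    df = n - 2
    if abs(r) >= 1.0:
        t, p = math.copysign(math.inf, r), 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(kind="pearson", statistic=r, df=(df,), p_value=p)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (off by default in the
    pipeline: the synthesis reports raw p-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return [float(v) for v in adjusted]
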