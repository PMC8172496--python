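"""Mass-univariate group statistics on pointwise callosal thickness.

At every one of the ``n_points`` midline positions an ordinary least squares
model is fitted independently:

    cdv ~ 1 + diagnosis (reference-coded, HC reference) + covariates

The omnibus diagnosis effect is the extra-sum-of-squares F test of the joint
nullity of the group contrasts (df1 = k - 1); pairwise post-hoc contrasts
refit the same model on two groups (df1 = 1, reported F = t^2). Each
comparison's n_points raw p-values form one multiple-testing family and are
corrected with the Benjamini-Hochberg step-up procedure at level ``q``.

Clinical covariates (illness duration, chlorpromazine-equivalent dose) are
handled with the study's centering scheme: healthy controls sit at 0, each
patient's value is expressed as the distance from their own diagnostic
group's mean. This removes between-group differences in the clinical
covariates (their per-group means are all 0) while retaining within-group
variability, so the group contrasts are not absorbed by covariates that are
structurally zero in controls. For patient-vs-patient contrasts the raw
values are used instead. Missing patient values are imputed at their own
group mean, i.e. centered 0.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contour_io import CONTROL_LABEL, SubjectRecord, records_to_frame

#: Covariates that receive the centering treatment.
CLINICAL_COVARIATES = ("illness_duration", "cpz")

#: Mapping from covariate names to columns of the covariate table.
_COV_COLUMNS = {
    "age": "age_years",
    "education": "education_years",
    "tiv": "tiv_ml",
    "illness_duration": "illness_duration_years",
    "cpz": "cpz_mg_day",
}

DEFAULT_COVARIATES = ("age", "education", "tiv", "illness_duration", "cpz")

RESULT_COLUMNS = [
    "comparison", "position", "statistic", "df1", "df2",
    "p_raw", "p_fdr", "significant",
]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the pointwise analysis.

    ``center_clinical=None`` applies the study rule automatically: centering
    on whenever the control group is in the model (omnibus and
    patient-vs-control contrasts), off for patient-vs-patient contrasts.
    """

    n_points: int = 100
    q: float = 0.05
    covariates: Sequence[str] = DEFAULT_COVARIATES
    center_clinical: Optional[bool] = None
    alpha: float = 0.05
    fdr_method: str = "bh"
    control_label: str = CONTROL_LABEL

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        unknown = set(self.covariates) - set(_COV_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariate(s): {sorted(unknown)}")


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """A full-column-rank design with named columns and retained group labels."""

    X: np.ndarray                 # (n_subjects, n_columns)
    columns: tuple[str, ...]
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]       # diagnosis label per row
    group_columns: tuple[str, ...]  # names of the diagnosis contrast columns
    reference: str

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k_groups(self) -> int:
        return len(self.group_columns) + 1


class DesignError(ValueError):
    """Rank-deficient or under-determined design."""


def center_within_group(
    values: Sequence[float],
    groups: Sequence[str],
    control_label: str = CONTROL_LABEL,
) -> np.ndarray:
    """Center a clinical covariate to each patient group's mean; controls at 0.

    ``values`` may contain NaN for absent measurements: absent patient values
    are imputed at their own group mean, which is 0 after centering. A
    non-control group whose values are all absent is degenerate and raises.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    out = np.zeros_like(values)
    for g in np.unique(groups):
        mask = groups == g
        if g == control_label:
            out[mask] = 0.0
            continue
        present = mask & np.isfinite(values)
        if not present.any():
            raise ValueError(
                f"group {g!r}: all values absent, cannot center within group"
            )
        out[present] = values[present] - values[present].mean()
    return out


def build_design(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    contrast_groups: Optional[tuple[str, str]] = None,
) -> DesignMatrix:
    """Build the ANCOVA design matrix.

    Diagnosis is reference-coded with the control group as reference when
    present (else the alphabetically first group). Sex is never included:
    the study design is sex-matched and sex is collinear with head size.
    When ``contrast_groups`` is given the records are restricted to those
    two groups and the clinical-covariate centering rule is applied for that
    contrast (on iff the control group takes part, unless the config forces
    a choice).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.reset_index(drop=True)
    if contrast_groups is not None:
        a, b = contrast_groups
        if a == b:
            raise ValueError("contrast groups must differ")
        present = set(df["diagnosis"])
        for g in (a, b):
            if g not in present:
                raise ValueError(f"group {g!r} not present in records")
        df = df[df["diagnosis"].isin([a, b])].reset_index(drop=True)

    groups = df["diagnosis"].to_numpy(dtype=object)
    levels = sorted(set(groups))
    reference = config.control_label if config.control_label in levels else levels[0]
    contrast_levels = [g for g in levels if g != reference]

    center = config.center_clinical
    if center is None:
        center = config.control_label in levels

    columns: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(len(df))]
    for g in contrast_levels:
        columns.append(f"diagnosis[{g}]")
        cols.append((groups == g).astype(float))

    for cov in config.covariates:
        raw = df[_COV_COLUMNS[cov]].to_numpy(dtype=float)
        if cov in CLINICAL_COVARIATES:
            if center:
                col = center_within_group(raw, groups, config.control_label)
            else:
                # raw values; absent patient values imputed at own group mean
                col = raw.copy()
                for g in np.unique(groups):
                    mask = (groups == g) & ~np.isfinite(col)
                    if mask.any():
                        src = (groups == g) & np.isfinite(raw)
                        if not src.any():
                            raise ValueError(
                                f"group {g!r}: all {cov} values absent"
                            )
                        col[mask] = raw[src].mean()
        else:
            if not np.all(np.isfinite(raw)):
                raise ValueError(f"covariate {cov!r} has missing values")
            col = raw
        columns.append(cov)
        cols.append(col)

    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1] + 1:
        raise DesignError(
            f"under-determined design: {X.shape[0]} subjects for "
            f"{X.shape[1]} columns"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(
            "rank-deficient design; collinear columns: "
            + ", ".join(_collinear_columns(X, columns))
        )
    return DesignMatrix(
        X=X,
        columns=tuple(columns),
        subject_ids=tuple(str(s) for s in df["subject_id"]),
        groups=tuple(groups),
        group_columns=tuple(f"diagnosis[{g}]" for g in contrast_levels),
        reference=reference,
    )


def _collinear_columns(X: np.ndarray, columns: Sequence[str]) -> list[str]:
    """Greedily identify columns that do not increase the rank."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(columns):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    return bad


def bh_fdr(
    p_values: Sequence[float],
    q: float = 0.05,
    method: str = "bh",
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(p_adjusted, reject)`` in the input order. Adjusted p-values
    are ``min_{j >= i} m * p_(j) / j`` (with the Benjamini-Yekutieli
    harmonic-sum inflation when ``method='by'``), clipped at 1; rejection is
    ``p_adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    scale = 1.0
    if method == "by":
        scale = np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * scale / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    return p_adj, p_adj <= q


def _ols_rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x m) on X (n x p), per column."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _pointwise_f(
    Y: np.ndarray, design: DesignMatrix
) -> tuple[np.ndarray, int, int]:
    """Extra-sum-of-squares F for the joint diagnosis effect at each position."""
    keep = [i for i, c in enumerate(design.columns) if c not in design.group_columns]
    X_full, X_red = design.X, design.X[:, keep]
    df1 = len(design.group_columns)
    df2 = design.n - X_full.shape[1]
    if df2 < 1:
        raise DesignError("no residual degrees of freedom")
    rss_full = _ols_rss(X_full, Y)
    rss_red = _ols_rss(X_red, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F = np.where(np.isfinite(F), np.maximum(F, 0.0), np.inf)
    return F, df1, df2


def _results_frame(
    F: np.ndarray, df1: int, df2: int, comparison: str, config: AnalysisConfig
) -> pd.DataFrame:
    p_raw = sps.f.sf(F, df1, df2)
    p_fdr, reject = bh_fdr(p_raw, config.q, config.fdr_method)
    return pd.DataFrame(
        {
            "comparison": comparison,
            "position": np.arange(1, len(F) + 1),
            "statistic": F,
            "df1": df1,
            "df2": df2,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "significant": reject,
        }
    )


def _align(cdv: pd.DataFrame, design: DesignMatrix) -> np.ndarray:
    missing = set(design.subject_ids) - set(cdv.index)
    if missing:
        raise ValueError(f"profiles missing for subjects: {sorted(missing)[:5]}")
    return cdv.loc[list(design.subject_ids)].to_numpy(dtype=float)


def fit_pointwise_omnibus(
    cdv: pd.DataFrame,
    design: DesignMatrix,
    config: AnalysisConfig = AnalysisConfig(),
    comparison: str = "omnibus",
) -> pd.DataFrame:
    """Omnibus diagnosis ANCOVA at every position.

    ``cdv`` is the subjects x positions table from
    :func:`ccmorph.geometry.profiles_to_cdv`. Returns one row per position
    with the F statistic, degrees of freedom, raw and FDR-adjusted p-values
    (one family spanning this comparison's positions) and the significance
    flag at level ``config.q``.
    """
    Y = _align(cdv, design)
    F, df1, df2 = _pointwise_f(Y, design)
    return _results_frame(F, df1, df2, comparison, config)


def fit_pointwise_posthoc(
    cdv: pd.DataFrame,
    records: Iterable[SubjectRecord] | pd.DataFrame,
    group_a: str,
    group_b: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Pairwise contrast of two diagnostic groups at every position.

    The model is refitted on the two groups with the same covariate set;
    clinical covariates are centered iff the control group takes part
    (config override respected). FDR correction is applied within this
    contrast's own family of positions. F has df1 = 1 (the square of the
    corresponding t statistic).
    """
    design = build_design(records, config, contrast_groups=(group_a, group_b))
    Y = _align(cdv, design)
    F, df1, df2 = _pointwise_f(Y, design)
    return _results_frame(F, df1, df2, f"{group_a}_vs_{group_b}", config)


def adjusted_group_means(
    cdv: pd.DataFrame,
    design: DesignMatrix,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Least-squares (covariate-adjusted) group mean CDV per position.

    Predictions are evaluated at the sample mean of every covariate column;
    centered clinical covariates have mean 0 by construction, matching the
    convention that controls sit at 0. Returns a tidy frame with columns
    ``group, position, adjusted_mean_cdv_mm``.
    """
    Y = _align(cdv, design)
    beta, *_ = np.linalg.lstsq(design.X, Y, rcond=None)
    col_means = design.X.mean(axis=0)
    levels = [design.reference] + [
        c[len("diagnosis["):-1] for c in design.group_columns
    ]
    rows = []
    for g in sorted(levels):
        x = col_means.copy()
        x[0] = 1.0
        for j, c in enumerate(design.columns):
            if c in design.group_columns:
                x[j] = 1.0 if c == f"diagnosis[{g}]" else 0.0
        pred = x @ beta
        for pos, val in zip(cdv.columns, pred):
            rows.append((g, int(pos), float(val)))
    return pd.DataFrame(rows, columns=["group", "position", "adjusted_mean_cdv_mm"])


def anova_from_summary(
    means: Sequence[float],
    sds: Sequence[float],
    ns: Sequence[int],
) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group summary statistics.

    Returns ``(F, df1, df2, p)``. The between-group mean square is computed
    from the group means about the sample-size-weighted grand mean; the
    within-group mean square pools the group SDs. Suitable for checking
    published demographic tables.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = len(means)
    if k < 2 or len(sds) != k or len(ns) != k:
        raise ValueError("need >= 2 groups with matching means/sds/ns")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be >= 0")
    N = int(ns.sum())
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1, df2 = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all SDs zero and means equal: F undefined")
        return float("inf"), df1, df2, 0.0
    F = (ssb / df1) / (ssw / df2)
    return F, df1, df2, float(sps.f.sf(F, df1, df2))


def anova_power(
    n_groups: int,
    total_n: int,
    effect_size_f: float,
    alpha: float = 0.05,
    n_covariates: int = 0,
) -> float:
    """Power of the fixed-effects ANOVA/ANCOVA omnibus F test.

    Uses the noncentral F distribution with ``df1 = n_groups - 1``,
    ``df2 = total_n - n_groups - n_covariates`` and noncentrality
    ``lambda = effect_size_f**2 * total_n`` (Cohen's f convention, as in
    standard a-priori power software).
    """
    if effect_size_f < 0:
        raise ValueError("effect_size_f must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df1 = n_groups - 1
    df2 = total_n - n_groups - n_covariates
    if df1 < 1 or df2 < 1:
        raise ValueError(
            f"invalid degrees of freedom: df1={df1}, df2={df2}"
        )
    f_crit = sps.f.isf(alpha, df1, df2)
    if effect_size_f == 0.0:
        return float(alpha)
    lam = effect_size_f**2 * total_n
    return float(sps.ncf.sf(f_crit, df1, df2, lam))
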