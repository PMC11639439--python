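"""Pointwise linear age/BMI regression atlas.

At every retained cloud point, and for each sex separately, the sampled
density is modelled as

    BMD(r, phi, z) = age * q(r, phi, z) + BMI * s(r, phi, z) + b(r, phi, z)

by ordinary least squares across cases, giving an age slope q (mg/cm^3
per year), a BMI slope s (mg/cm^3 per BMI point) and an intercept b.
Two-sided t-tests on the slopes give per-covariate p-values; a slope is
called significant when p < 0.05, with no multiplicity correction —
each point is reported on its own. The fitted coefficient fields form a
generative atlas: evaluating the model at any (age, BMI) produces the
full spatial BMD distribution for that covariate combination.

Both femurs of a donor enter as independent cases; an optional
donor-cluster-robust covariance is available for sensitivity checks but
is off by default, mirroring common practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SubjectRecord

__all__ = [
    "PointRegression",
    "Atlas",
    "ROIDefinition",
    "DEFAULT_ROIS",
    "SIGNIFICANCE_ALPHA",
    "MIN_CASES_PER_FIT",
    "fit_point",
    "fit_atlas",
    "predict_bmd",
    "roi_regression",
    "significance_mask",
]

SIGNIFICANCE_ALPHA = 0.05
MIN_CASES_PER_FIT = 10


@dataclass(frozen=True)
class PointRegression:
    q: float          # mg/cm^3 per year
    s: float          # mg/cm^3 per BMI point
    b: float          # mg/cm^3
    p_age: float
    p_bmi: float
    n_cases: int
    se_q: float = float("nan")
    se_s: float = float("nan")

    def predict(self, age: float, bmi: float) -> float:
        return self.q * age + self.s * bmi + self.b


def _ols(X: np.ndarray, y: np.ndarray,
         cluster: np.ndarray | None = None) -> PointRegression:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        ptp = np.ptp(X, axis=0)
        name = "age" if ptp[0] == 0 else "BMI" if ptp[1] == 0 else "design"
        raise ValueError(f"rank-deficient design: {name} has no variation")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    if cluster is None:
        sigma2 = resid @ resid / dof if dof > 0 else np.nan
        se = np.sqrt(np.diag(xtx_inv) * sigma2)
    else:
        # cluster-robust sandwich (CR1 small-sample scaling, t with G-1 dof)
        groups = np.unique(cluster)
        G = len(groups)
        meat = np.zeros((p, p))
        for g in groups:
            sel = cluster == g
            u = X[sel].T @ resid[sel]
            meat += np.outer(u, u)
        scale = G / (G - 1) * (n - 1) / dof
        cov = scale * xtx_inv @ meat @ xtx_inv
        se = np.sqrt(np.diag(cov))
        dof = G - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return PointRegression(
        q=float(beta[0]), s=float(beta[1]), b=float(beta[2]),
        p_age=float(pvals[0]), p_bmi=float(pvals[1]), n_cases=int(n),
        se_q=float(se[0]), se_s=float(se[1]))


def fit_point(
    bmd: Sequence[float],
    ages: Sequence[float],
    bmis: Sequence[float],
    min_cases: int = MIN_CASES_PER_FIT,
    cluster: Sequence | None = None,
) -> PointRegression:
    """OLS fit of the linear age/BMI model at one cloud point.

    Rows with non-finite BMD (dismissed spheres) are dropped before
    fitting; fewer than ``min_cases`` usable rows is an error, as is a
    covariate with no variation across the usable cases. Passing donor
    ids as ``cluster`` switches the standard errors to a donor-cluster
    robust sandwich (both femurs of a donor are not independent); the
    default keeps conventional OLS errors.
    """
    y = np.asarray(bmd, dtype=float)
    a = np.asarray(ages, dtype=float)
    m = np.asarray(bmis, dtype=float)
    ok = np.isfinite(y) & np.isfinite(a) & np.isfinite(m)
    y, a, m = y[ok], a[ok], m[ok]
    cl = np.asarray(cluster)[ok] if cluster is not None else None
    if len(y) < min_cases:
        raise ValueError(
            f"only {len(y)} usable cases, minimum {min_cases}")
    X = np.column_stack([a, m, np.ones_like(a)])
    return _ols(X, y, cluster=cl)


@dataclass
class Atlas:
    """Per-point fitted coefficients for one sex."""

    sex: str
    point_ids: list[tuple[int, int, int]]
    table: pd.DataFrame   # q, s, b, p_age, p_bmi, n_cases, se_q, se_s
    n_cases: int = 0
    failed_points: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def predict(self, age: float, bmi: float) -> np.ndarray:
        return (self.table["q"].to_numpy() * age
                + self.table["s"].to_numpy() * bmi
                + self.table["b"].to_numpy())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "z_index", [p[0] for p in self.point_ids])
        out.insert(1, "phi_index", [p[1] for p in self.point_ids])
        out.insert(2, "radial_ordinal", [p[2] for p in self.point_ids])
        out.to_csv(path, index=False)


def fit_atlas(
    matrix: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    sex: str,
    retained: Sequence[tuple[int, int, int]] | None = None,
    min_cases: int = MIN_CASES_PER_FIT,
) -> Atlas:
    """Fit the pointwise model over all retained points for one sex.

    ``matrix`` is the long-format sample table (one row per case and
    point). Only that sex's cases and each point's non-dismissed samples
    enter its fit. Points that fail to fit (too few cases, degenerate
    design) are recorded in ``failed_points``, not silently dropped.
    """
    subj = {r.id: r for r in subjects if r.sex == sex}
    sub = matrix[matrix["case_id"].isin(subj)]
    if sub.empty:
        raise ValueError(f"no cases of sex {sex!r} in the sample matrix")
    ages = sub["case_id"].map(lambda c: subj[c].age).to_numpy()
    bmis = sub["case_id"].map(lambda c: subj[c].bmi).to_numpy()
    sub = sub.assign(_age=ages, _bmi=bmis)
    if retained is not None:
        keep = set(map(tuple, retained))
    rows, ids, failed = [], [], []
    for pid, g in sub.groupby(["z_index", "phi_index", "radial_ordinal"],
                              sort=True):
        pid = tuple(int(v) for v in pid)
        if retained is not None and pid not in keep:
            continue
        use = g[~g["dismissed"]]
        try:
            pr = fit_point(use["mean_bmd"], use["_age"], use["_bmi"],
                           min_cases=min_cases)
        except ValueError as e:
            failed.append((pid, str(e)))
            continue
        ids.append(pid)
        rows.append((pr.q, pr.s, pr.b, pr.p_age, pr.p_bmi, pr.n_cases,
                     pr.se_q, pr.se_s))
    table = pd.DataFrame(rows, columns=[
        "q", "s", "b", "p_age", "p_bmi", "n_cases", "se_q", "se_s"])
    return Atlas(sex=sex, point_ids=ids, table=table,
                 n_cases=len(set(sub["case_id"])), failed_points=failed)


def predict_bmd(atlas: Atlas, age: float, bmi: float,
                training_age_range: tuple[float, float] | None = None
                ) -> tuple[np.ndarray, bool]:
    """Per-point BMD field for arbitrary covariates (linear evaluation).

    No significance masking is applied. Returns the field and a flag
    marking extrapolation outside the training age range when known.
    """
    extrapolated = (training_age_range is not None
                    and not (training_age_range[0] <= age
                             <= training_age_range[1]))
    return atlas.predict(age, bmi), bool(extrapolated)


@dataclass(frozen=True)
class ROIDefinition:
    """Named subregion of the cloud via a (z, phi, r-ordinal) predicate."""

    name: str
    member: Callable[[int, int, int], bool]

    def select(self, ids: Sequence[tuple[int, int, int]]) -> np.ndarray:
        return np.array([self.member(*pid) for pid in ids], dtype=bool)


def _zrange(name, lo, hi):
    return ROIDefinition(name, lambda z, p, r, lo=lo, hi=hi: lo <= z <= hi)


# Fabricated z-index extents for the classical subregions; the head is
# the articular block, the neck the stations up to the cutting plane,
# and the shaft side is split at the lesser trochanter.
DEFAULT_ROIS: dict[str, ROIDefinition] = {
    "total": _zrange("total", 0, 38),
    "head": _zrange("head", 0, 7),
    "neck": _zrange("neck", 8, 12),
    "greater_trochanter": _zrange("greater_trochanter", 13, 19),
    "intertrochanteric": _zrange("intertrochanteric", 20, 28),
    "shaft": _zrange("shaft", 29, 38),
}


def roi_regression(
    matrix: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    roi: ROIDefinition,
    sex: str,
    min_cases: int = MIN_CASES_PER_FIT,
    baseline: tuple[float, float] = (20.0, 25.0),
) -> dict:
    """Average-BMD regression over one region of interest.

    Per case, BMD is averaged over the ROI's non-dismissed points; the
    same linear model is then fitted to those averages. Relative
    differences are the slopes as a percentage of the model prediction
    at the baseline covariates (age 20, BMI 25).
    """
    subj = {r.id: r for r in subjects if r.sex == sex}
    sub = matrix[matrix["case_id"].isin(subj)]
    ids = sub[["z_index", "phi_index", "radial_ordinal"]].to_numpy()
    inroi = np.array([roi.member(*row) for row in ids], dtype=bool)
    sub = sub[inroi & ~sub["dismissed"].to_numpy()]
    if sub.empty:
        raise ValueError(f"ROI {roi.name!r} empty for sex {sex!r}")
    means = sub.groupby("case_id")["mean_bmd"].mean()
    ages = np.array([subj[c].age for c in means.index])
    bmis = np.array([subj[c].bmi for c in means.index])
    pr = fit_point(means.to_numpy(), ages, bmis, min_cases=min_cases)
    base = pr.predict(*baseline)
    return {
        "roi": roi.name,
        "sex": sex,
        "slope_age": pr.q,
        "slope_bmi": pr.s,
        "intercept": pr.b,
        "p_age": pr.p_age,
        "p_bmi": pr.p_bmi,
        "baseline_bmd": base,
        "rel_diff_age_pct": 100.0 * pr.q / base,
        "rel_diff_bmi_pct": 100.0 * pr.s / base,
        "n_cases": pr.n_cases,
    }


def significance_mask(atlas: Atlas, alpha: float = SIGNIFICANCE_ALPHA
                      ) -> pd.DataFrame:
    """Per-point, per-covariate significance flags (strict p < alpha)."""
    return pd.DataFrame({
        "age_significant": atlas.table["p_age"].to_numpy() < alpha,
        "bmi_significant": atlas.table["p_bmi"].to_numpy() < alpha,
    })
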