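"""Survival association of gene set activity scores.

Univariate and covariate-adjusted Cox proportional hazards models (Efron
tie handling via lifelines), Kaplan-Meier / log-rank comparison of samples
dichotomized about GSAS = 0, Benjamini-Hochberg multiple-testing control,
cross-cohort intersection of significant sets, and hierarchical clustering
of samples by their activity profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import chi2

from .engine import GsasMatrix
from .io import ClinicalTable

logger = logging.getLogger(__name__)

COVARIATE_CHOICES = ("age", "tumor_size", "grade_binary", "er_status", "ln_status")


def binarize_grade(grade: pd.Series) -> pd.Series:
    """Grade 1 -> 0; grades 2 and 3 -> 1; missing stays missing."""
    out = pd.Series(np.nan, index=grade.index, dtype=float)
    out[grade == 1] = 0.0
    out[grade.isin([2.0, 3.0])] = 1.0
    return out


@dataclass
class CovariateEffect:
    coefficient: float
    hazard_ratio: float
    se: float
    wald_p: float


@dataclass
class CoxResult:
    """Fitted Cox model summary keyed by covariate name."""

    effects: dict[str, CovariateEffect]
    n: int
    n_events: int
    n_dropped: int
    converged: bool
    ties: str = "efron"
    note: str = ""

    def effect(self, name: str = "score") -> CovariateEffect:
        return self.effects[name]

    @property
    def coefficient(self) -> float:
        return self.effects["score"].coefficient

    @property
    def hazard_ratio(self) -> float:
        return self.effects["score"].hazard_ratio

    @property
    def wald_p(self) -> float:
        return self.effects["score"].wald_p


def _assemble_model_frame(
    scores: pd.Series, clinical: ClinicalTable, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, int]:
    unknown = set(covariates) - set(COVARIATE_CHOICES)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}; choose from {COVARIATE_CHOICES}")
    common = [s for s in scores.index if s in set(clinical.data.index)]
    df = pd.DataFrame(
        {
            "score": scores.loc[common].astype(float),
            "time": clinical.data.loc[common, "time"],
            "event": clinical.data.loc[common, "event"],
        }
    )
    for cov in covariates:
        if cov == "grade_binary":
            df[cov] = binarize_grade(clinical.data.loc[common, "grade"])
        else:
            df[cov] = clinical.data.loc[common, cov]
    n_before = len(df)
    df = df.dropna()
    return df, n_before - len(df)


def fit_cox(
    scores: pd.Series,
    clinical: ClinicalTable,
    covariates: tuple[str, ...] = (),
) -> CoxResult:
    """Cox proportional hazards fit of survival on a score (+ covariates).

    Partial likelihood with Efron tie handling and Wald per-covariate
    tests.  Samples missing any used covariate are dropped (count
    reported).  A constant score yields the degenerate exact result
    (coefficient 0, hazard ratio 1, p 1); non-convergence is returned as a
    flagged result, never raised silently.
    """
    df, n_dropped = _assemble_model_frame(scores, clinical, covariates)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no observed events among usable samples")
    if n_events < 2:
        raise ValueError("need >= 2 events to fit a Cox model")

    terms = ["score", *covariates]
    constant = [t for t in terms if df[t].nunique() <= 1]
    if constant:
        effects = {}
        for t in terms:
            if t in constant:
                effects[t] = CovariateEffect(0.0, 1.0, np.nan, 1.0)
            else:
                effects[t] = CovariateEffect(np.nan, np.nan, np.nan, np.nan)
        if set(constant) != set(terms):
            # refit without the constant terms so the rest are still informative
            sub = fit_cox(scores, clinical, tuple(c for c in covariates if c not in constant))
            for t in terms:
                if t not in constant:
                    effects[t] = sub.effects[t]
        return CoxResult(
            effects, len(df), n_events, n_dropped, converged=True,
            note=f"constant covariates: {constant}",
        )

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        logger.warning("Cox model failed to converge: %s", exc)
        effects = {t: CovariateEffect(np.nan, np.nan, np.nan, np.nan) for t in terms}
        return CoxResult(effects, len(df), n_events, n_dropped, converged=False, note=str(exc))

    summary = fitter.summary
    effects = {
        t: CovariateEffect(
            coefficient=float(summary.loc[t, "coef"]),
            hazard_ratio=float(np.exp(summary.loc[t, "coef"])),
            se=float(summary.loc[t, "se(coef)"]),
            wald_p=max(float(summary.loc[t, "p"]), np.finfo(float).tiny),
        )
        for t in terms
    }
    return CoxResult(effects, len(df), n_events, n_dropped, converged=True)


def cox_score_test(scores: pd.Series, clinical: ClinicalTable) -> tuple[float, float]:
    """Cox partial-likelihood score test of H0: beta = 0 for one covariate.

    Returns (chi-square, p).  For a binary covariate without tied event
    times this equals the two-group log-rank statistic exactly.
    """
    df, _ = _assemble_model_frame(scores, clinical, ())
    x = df["score"].to_numpy()
    time = df["time"].to_numpy()
    event = df["event"].to_numpy().astype(bool)
    if not event.any():
        raise ValueError("no observed events")
    u = 0.0
    v = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n_r = int(at_risk.sum())
        deaths = event & (time == t)
        d = int(deaths.sum())
        xbar = x[at_risk].mean()
        u += x[deaths].sum() - d * xbar
        s2 = ((x[at_risk] - xbar) ** 2).mean()
        if n_r > 1:
            v += d * (n_r - d) / (n_r - 1) * s2
    if v <= 0:
        return 0.0, 1.0
    stat = u * u / v
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


@dataclass
class KmComparison:
    groups: pd.Series  # sample -> "high" (score > 0) / "low" (score <= 0)
    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, survival
    chi_square: float
    p_value: float


def km_logrank(scores: pd.Series, clinical: ClinicalTable) -> KmComparison:
    """Kaplan-Meier curves and log-rank test for samples dichotomized at 0.

    Scores > 0 form the high-activity group, scores <= 0 the low-activity
    group.  Both groups must be non-empty.
    """
    df, _ = _assemble_model_frame(scores, clinical, ())
    groups = pd.Series(np.where(df["score"] > 0, "high", "low"), index=df.index)
    if groups.nunique() < 2:
        raise ValueError(
            "dichotomization at 0 left one group empty; use the continuous Cox model instead"
        )
    curves = {}
    for label in ("low", "high"):
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=label)
        table = kmf.event_table
        curves[label] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
                "survival": kmf.survival_function_[label].to_numpy(),
            }
        )
    high = groups == "high"
    res = logrank_test(
        df.loc[high, "time"], df.loc[~high, "time"],
        event_observed_A=df.loc[high, "event"], event_observed_B=df.loc[~high, "event"],
    )
    return KmComparison(groups, curves, float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Multiple testing and cross-cohort screening
# ---------------------------------------------------------------------------


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class SurvivalScreenResult:
    """Per-set Cox screen of one dataset (one row per scored gene set)."""

    dataset: str
    table: pd.DataFrame  # index: set name; columns: coef, hr, p, q, n, events, converged
    covariates: tuple[str, ...] = ()

    @property
    def set_names(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float, column: str = "p") -> list[str]:
        return list(self.table.index[self.table[column] < alpha])


def screen_collection(
    gsas: GsasMatrix,
    clinical: ClinicalTable,
    covariates: tuple[str, ...] = (),
    dataset: str = "",
) -> SurvivalScreenResult:
    """Cox screen of every scored gene set against survival.

    The screened covariate is the continuous GSAS; ``covariates`` adds
    clinical adjustment terms (the reported row is still the GSAS effect).
    BH q-values are computed across the screened collection.
    """
    rows = []
    for name in gsas.set_names:
        res = fit_cox(gsas.scores(name), clinical, covariates)
        eff = res.effect("score")
        rows.append(
            {
                "set": name,
                "coef": eff.coefficient,
                "hr": eff.hazard_ratio,
                "p": eff.wald_p,
                "n": res.n,
                "events": res.n_events,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("set")
    usable = table["p"].notna()
    q = np.full(len(table), np.nan)
    if usable.any():
        q[usable.to_numpy()] = bh_fdr(table.loc[usable, "p"].to_numpy())
    table["q"] = q
    logger.info("screened %d sets in dataset %r (%d converged)", len(table), dataset,
                int(table["converged"].sum()))
    return SurvivalScreenResult(dataset=dataset, table=table, covariates=covariates)


def robust_intersection(
    screens: list[SurvivalScreenResult], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Sets with univariate Cox p < alpha in every screen.

    Returns the robust set names plus a report with per-screen p and
    hazard ratio.  Screens must share at least one scored set.
    """
    if len(screens) < 2:
        raise ValueError("need >= 2 screens to intersect")
    common = set(screens[0].set_names)
    for s in screens[1:]:
        common &= set(s.set_names)
    if not common:
        raise ValueError("screens share no gene sets")
    robust = sorted(
        name
        for name in common
        if all(s.table.loc[name, "p"] < alpha for s in screens)
    )
    report = pd.DataFrame(index=robust)
    for s in screens:
        label = s.dataset or f"screen{screens.index(s)}"
        report[f"p_{label}"] = s.table.loc[robust, "p"]
        report[f"hr_{label}"] = s.table.loc[robust, "hr"]
    logger.info("robust intersection: %d of %d shared sets at alpha=%g",
                len(robust), len(common), alpha)
    return robust, report


# ---------------------------------------------------------------------------
# Sample clustering on activity profiles
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: pd.Series  # sample -> 1 or 2
    ordered_matrix: pd.DataFrame  # samples x sets, capped to [-3, 3], leaf order
    linkage_matrix: np.ndarray = field(repr=False, default=None)


def cluster_gsas(gsas: GsasMatrix, set_subset: list[str], cap: float = 3.0) -> ClusterResult:
    """Hierarchically cluster samples by their activity profiles.

    Agglomerative clustering (Euclidean, average linkage) on the uncapped
    scores, cut into two groups; the returned display matrix is capped to
    [-cap, cap].
    """
    if not set_subset:
        raise ValueError("set_subset must be non-empty")
    missing = [s for s in set_subset if s not in gsas.data.index]
    if missing:
        raise KeyError(f"sets not in matrix: {missing}")
    profile = gsas.data.loc[set_subset].T  # samples x sets
    if profile.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    z = linkage(profile.to_numpy(), method="average", metric="euclidean")
    labels = pd.Series(fcluster(z, t=2, criterion="maxclust"), index=profile.index)
    order = leaves_list(z)
    capped = profile.clip(lower=-cap, upper=cap).iloc[order]
    return ClusterResult(labels=labels, ordered_matrix=capped, linkage_matrix=z)
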