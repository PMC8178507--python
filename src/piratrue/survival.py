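"""Survival endpoints, eligibility, treatment subsets, expression quartiles,
and Cox proportional-hazards fits (univariate and forward-stepwise
multivariate) with Kaplan-Meier export.

Endpoints follow the standard clinical definitions: relapse-free survival
(RFS) runs from diagnosis to recurrence, breast-cancer-specific survival
(BCSS) to death from the disease (other-cause deaths censored), overall
survival (OS) to death from any cause. Only invasive, local disease enters
the analyses. For a given RNA, samples are split into expression quartiles
(Q1 = lowest) and every model compares Q2/Q3/Q4 against Q1; ties in the Cox
partial likelihood use the Breslow approximation (lifelines default). The
multivariate procedure forces the quartile block into the model and adds
clinical/treatment covariates forward-greedily by AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats as sps

from .expression import bh_adjust

logger = logging.getLogger(__name__)

ENDPOINTS = ("RFS", "BCSS", "OS")
CLINICAL_COVARIATES = ("grade", "histology", "tumor_size", "er", "pr", "her2", "age_at_dx")

SUBSET_NAMES = (
    "all_invasive_local",
    "rt_treated",
    "tamoxifen_treated",
    "rt_only",
    "adj_ct_treated",
    "surgery_only",
)


# ---------------------------------------------------------------------------
# Endpoints and eligibility


def make_endpoints(clinical: pd.DataFrame, censor_date) -> pd.DataFrame:
    """Build RFS/BCSS/OS records (long format: sample_id, endpoint, time, event).

    Times are in days from ``dx_date``. RFS: event at recurrence, else censored
    at the earliest of death, per-subject last follow-up (when recorded) and
    ``censor_date``. BCSS: event only for breast-cancer deaths; other-cause
    deaths censor at the death date. OS: event at any death.
    """
    censor_date = pd.Timestamp(censor_date)

    def _date(value):
        if value is None or (isinstance(value, str) and not value.strip()):
            return None
        ts = pd.Timestamp(value)
        return None if pd.isna(ts) else ts

    rows = []
    for _, r in clinical.iterrows():
        dx = _date(r["dx_date"])
        if dx is None:
            raise ValueError(f"{r['sample_id']}: missing diagnosis date")
        death = _date(r.get("death_date"))
        rec = _date(r.get("recurrence_date"))
        for d, label in ((death, "death"), (rec, "recurrence")):
            if d is not None and d < dx:
                raise ValueError(f"{r['sample_id']}: {label} date precedes diagnosis")
        last_fu = _date(r.get("last_followup_date")) or censor_date
        admin = min(last_fu, censor_date)
        cause = r.get("death_cause", "alive")

        # RFS
        if rec is not None:
            rows.append((r["sample_id"], "RFS", (rec - dx).days, 1))
        else:
            end = min(death, admin) if death is not None else admin
            rows.append((r["sample_id"], "RFS", (end - dx).days, 0))
        # BCSS
        if death is not None and cause == "breast_cancer":
            rows.append((r["sample_id"], "BCSS", (death - dx).days, 1))
        elif death is not None:
            rows.append((r["sample_id"], "BCSS", (death - dx).days, 0))
        else:
            rows.append((r["sample_id"], "BCSS", (admin - dx).days, 0))
        # OS
        if death is not None:
            rows.append((r["sample_id"], "OS", (death - dx).days, 1))
        else:
            rows.append((r["sample_id"], "OS", (admin - dx).days, 0))

    out = pd.DataFrame(rows, columns=["sample_id", "endpoint", "time", "event"])
    if (out["time"] <= 0).any():
        bad = out.loc[out["time"] <= 0, "sample_id"].unique()
        raise ValueError(f"non-positive survival time for: {list(bad)}")
    return out


def eligible_cases(clinical: pd.DataFrame) -> pd.DataFrame:
    """Invasive, local disease only: drop in-situ and metastatic-at-diagnosis."""
    mask = (
        clinical["invasive"].astype(bool)
        & ~clinical["in_situ"].astype(bool)
        & ~clinical["metastasis_at_dx"].astype(bool)
    )
    return clinical[mask]


def treatment_subset(
    clinical: pd.DataFrame, name: str, er_restrict: str | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict eligible cases to a treatment-defined subset.

    Returns the subset and its covariate plan: the base clinical covariates,
    ER dropped under an ER restriction, plus the treatment flags the subset
    definition leaves free (RT for tamoxifen- and CT-treated subsets; CT and
    ET for the RT-treated subset).
    """
    df = clinical
    yes = lambda col: df[col] == "yes"  # noqa: E731
    no = lambda col: df[col] == "no"  # noqa: E731
    extra: list[str] = []
    if name == "all_invasive_local":
        mask = pd.Series(True, index=df.index)
        extra = ["rt", "ct", "et"]
    elif name == "rt_treated":
        mask = yes("rt")
        extra = ["ct", "et"]
    elif name == "tamoxifen_treated":
        mask = (df["er"] == "pos") & yes("tamoxifen") & no("ct")
        er_restrict = "pos"
        extra = ["rt"]
    elif name == "rt_only":
        mask = yes("rt") & no("ct") & no("et")
    elif name == "adj_ct_treated":
        mask = yes("ct") & no("et")
        extra = ["rt"]
    elif name == "surgery_only":
        mask = no("rt") & no("ct") & no("et")
    else:
        raise ValueError(f"unknown treatment subset: {name!r}")
    if er_restrict is not None:
        mask = mask & (df["er"] == er_restrict)
    plan = [c for c in CLINICAL_COVARIATES if not (c == "er" and er_restrict)]
    return df[mask], plan + extra


# ---------------------------------------------------------------------------
# Quartiles


def assign_quartiles(values: pd.Series) -> pd.Series:
    """Rank-based split into Q1..Q4 (Q1 lowest), sizes ceil(n/4) first.

    Ties in value are broken by sample id ascending so the assignment is
    deterministic even when all values are equal.
    """
    n = len(values)
    if n < 8:
        raise ValueError(f"quartile assignment needs >=8 samples, got {n}")
    order = sorted(values.index, key=lambda s: (values[s], str(s)))
    sizes = [(n + 3 - i) // 4 for i in range(4)]  # ceil first, e.g. n=10 -> 3,3,2,2
    labels = {}
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for s in order[pos : pos + size]:
            labels[s] = f"Q{q}"
        pos += size
    return pd.Series(labels, name="quartile").loc[values.index]


# ---------------------------------------------------------------------------
# Cox fits


@dataclass
class CoxFit:
    """One Cox proportional-hazards fit (quartile block vs Q1)."""

    terms: pd.DataFrame  # index term; columns coef, hr, ci_low, ci_high, p
    overall_p: float
    aic: float
    n: int
    n_events: int
    log_likelihood: float
    selected_covariates: list[str] = field(default_factory=list)
    overall_p_adj: float | None = None
    converged: bool = True
    message: str = ""
    accession: str = ""
    endpoint: str = ""
    subset: str = ""


def _null_partial_loglik(times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood at beta = 0 (each event: -log risk-set size)."""
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    n = len(times)
    ll = 0.0
    for i in range(n):
        if events[i]:
            at_risk = np.sum(times >= times[i])
            ll -= np.log(at_risk)
    return float(ll)


def _quartile_design(quart: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    cols = []
    X = pd.DataFrame(index=quart.index)
    for q in ("Q2", "Q3", "Q4"):
        if (quart == q).any():
            X[q] = (quart == q).astype(float)
            cols.append(q)
    return X, cols


def _fit(df: pd.DataFrame, cols: list[str], penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny subsets routinely trip lifelines hints
        cph.fit(df[["time", "event"] + cols], duration_col="time", event_col="event")
    return cph


def _terms_frame(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return out


def cox_univariate(surv: pd.DataFrame, quart: pd.Series) -> CoxFit:
    """Cox PH on quartile indicators only (Breslow ties).

    ``surv`` needs columns sample_id, time, event for a single endpoint;
    ``quart`` maps sample_id -> Q1..Q4. The overall p is the likelihood-ratio
    test of the whole quartile block.
    """
    df = surv.set_index("sample_id")[["time", "event"]].join(quart.rename("quartile"))
    df = df.dropna(subset=["quartile"])
    if df["event"].sum() < 1:
        raise ValueError("no events")
    if not (df["quartile"] == "Q1").any():
        raise ValueError("empty reference quartile Q1")
    if df["quartile"].nunique() < 2:
        raise ValueError("need >=2 nonempty quartiles")
    Xq, qcols = _quartile_design(df["quartile"])
    data = pd.concat([df[["time", "event"]], Xq], axis=1)
    cph = _fit(data, qcols)
    ll = float(cph.log_likelihood_)
    ll0 = _null_partial_loglik(
        df["time"].to_numpy(float), df["event"].to_numpy(float)
    )
    overall_p = float(sps.chi2.sf(2 * (ll - ll0), df=len(qcols)))
    return CoxFit(
        terms=_terms_frame(cph),
        overall_p=overall_p,
        aic=-2 * ll + 2 * len(qcols),
        n=len(df),
        n_events=int(df["event"].sum()),
        log_likelihood=ll,
    )


def _encode_covariates(
    clinical: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Categoricals -> reference-dropped indicators; age stays continuous."""
    blocks: dict[str, list[str]] = {}
    X = pd.DataFrame(index=clinical.index)
    for cov in covariates:
        col = clinical[cov]
        if cov == "age_at_dx" or pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
            blocks[cov] = [cov]
        else:
            levels = sorted(col.dropna().astype(str).unique())
            cols = []
            for level in levels[1:]:
                name = f"{cov}[{level}]"
                X[name] = (col.astype(str) == level).astype(float)
                cols.append(name)
            if cols:
                blocks[cov] = cols
            # single-level covariates carry no information; skipped
            X.loc[col.isna(), [f"{cov}[{l}]" for l in levels[1:]]] = np.nan
    return X, blocks


def cox_multivariate_stepwise(
    surv: pd.DataFrame,
    quart: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str],
) -> CoxFit:
    """Forward-stepwise Cox: quartile block forced in, covariates added by AIC.

    Covariates enter greedily (whole indicator blocks) while each addition
    lowers AIC = -2*log partial likelihood + 2*k; complete cases on the
    candidate covariates. The overall p is the LRT of the quartile block
    against the same model without it. Non-convergence yields a flagged fit.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    df = surv.set_index("sample_id")[["time", "event"]].join(quart.rename("quartile"))
    Xc, blocks = _encode_covariates(clin, covariates)
    df = df.join(Xc).dropna()
    if df.empty or df["event"].sum() < 1:
        raise ValueError("no events among complete cases")
    if not (df["quartile"] == "Q1").any():
        raise ValueError("empty reference quartile Q1")
    Xq, qcols = _quartile_design(df["quartile"])
    data = pd.concat([df.drop(columns="quartile"), Xq], axis=1)
    # drop constant indicator columns within the analysis subset
    blocks = {
        cov: [c for c in cols if data[c].nunique() > 1]
        for cov, cols in blocks.items()
    }
    blocks = {cov: cols for cov, cols in blocks.items() if cols}

    def try_fit(cols: list[str]) -> CoxPHFitter | None:
        try:
            return _fit(data, cols)
        except (ConvergenceError, Exception) as exc:  # separation etc.
            logger.debug("cox fit failed for %s: %s", cols, exc)
            return None

    base = try_fit(qcols)
    if base is None:
        return CoxFit(
            terms=pd.DataFrame(columns=["coef", "hr", "ci_low", "ci_high", "p"]),
            overall_p=np.nan,
            aic=np.nan,
            n=len(data),
            n_events=int(data["event"].sum()),
            log_likelihood=np.nan,
            converged=False,
            message="base quartile model failed to converge",
        )
    selected: list[str] = []
    current_cols = list(qcols)
    best_aic = float(base.AIC_partial_)
    best_fit = base
    remaining = list(blocks)
    while remaining:
        candidates = []
        for cov in remaining:
            fit = try_fit(current_cols + blocks[cov])
            if fit is not None:
                candidates.append((float(fit.AIC_partial_), cov, fit))
        if not candidates:
            break
        candidates.sort(key=lambda t: (t[0], t[1]))
        aic, cov, fit = candidates[0]
        if aic < best_aic:
            best_aic, best_fit = aic, fit
            selected.append(cov)
            current_cols = current_cols + blocks[cov]
            remaining.remove(cov)
        else:
            break

    ll = float(best_fit.log_likelihood_)
    cov_cols = [c for c in current_cols if c not in qcols]
    if cov_cols:
        reduced = try_fit(cov_cols)
        ll_reduced = float(reduced.log_likelihood_) if reduced is not None else np.nan
    else:
        ll_reduced = _null_partial_loglik(
            data["time"].to_numpy(float), data["event"].to_numpy(float)
        )
    overall_p = (
        float(sps.chi2.sf(2 * (ll - ll_reduced), df=len(qcols)))
        if np.isfinite(ll_reduced)
        else np.nan
    )
    terms = _terms_frame(best_fit)
    unstable = bool((terms["coef"].abs() > 10).any())
    return CoxFit(
        terms=terms,
        overall_p=overall_p,
        aic=best_aic,
        n=len(data),
        n_events=int(data["event"].sum()),
        log_likelihood=ll,
        selected_covariates=selected,
        converged=not unstable,
        message="extreme coefficients (possible separation)" if unstable else "",
    )


def overall_fdr(fits: list[CoxFit]) -> list[CoxFit]:
    """BH-adjust overall p-values within each (endpoint, subset) family."""
    groups: dict[tuple[str, str], list[CoxFit]] = {}
    for f in fits:
        groups.setdefault((f.endpoint, f.subset), []).append(f)
    for fam in groups.values():
        adj = bh_adjust([f.overall_p for f in fam])
        for f, a in zip(fam, adj):
            f.overall_p_adj = float(a) if np.isfinite(a) else None
    return fits


# ---------------------------------------------------------------------------
# Kaplan-Meier


def kaplan_meier(
    surv: pd.DataFrame, groups: pd.Series, ref_group: str | None = None
) -> tuple[dict[str, pd.DataFrame], float, dict[str, float]]:
    """Product-limit curves per group, overall log-rank p, pairwise-vs-ref p.

    Returns (curves, overall_p, pairwise) where each curve is a DataFrame with
    columns ``time, survival``.
    """
    df = surv.set_index("sample_id")[["time", "event"]].join(groups.rename("group"))
    df = df.dropna(subset=["group"])
    labels = sorted(df["group"].unique())
    if ref_group is None:
        ref_group = labels[0]
    curves: dict[str, pd.DataFrame] = {}
    for g in labels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    if df["event"].sum() == 0 or len(labels) < 2:
        return curves, float("nan"), {}
    overall = multivariate_logrank_test(df["time"], df["group"], df["event"])
    pairwise: dict[str, float] = {}
    ref = df[df["group"] == ref_group]
    for g in labels:
        if g == ref_group:
            continue
        other = df[df["group"] == g]
        if ref["event"].sum() + other["event"].sum() == 0:
            pairwise[g] = float("nan")
            continue
        res = logrank_test(ref["time"], other["time"], ref["event"], other["event"])
        pairwise[g] = float(res.p_value)
    return curves, float(overall.p_value), pairwise
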