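"""Count normalization, negative-binomial Wald differential expression, FDR,
fold-change shrinkage and the ddCq/Pearson qPCR concordance check.

Normalization is median-of-ratios size factors followed by
``log2(count / factor + pseudocount)`` — a deliberately simple, monotone
stand-in for a variance-stabilizing transform; downstream quartile assignment
only needs the per-sample ordering it preserves.

Per-entry differential expression fits a negative-binomial log-linear model
(offset = log size factor, terms intercept + group, optionally an adjustment
covariate), with method-of-moments dispersion (floor 1e-8) and a Wald test on
the group coefficient. FDR control is Benjamini-Hochberg over the tested
entries; shrinkage is a normal-prior posterior mean pulling noisy log2
fold-changes toward zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to product 1.

    Reference = per-entry geometric mean over samples, computed on entries
    with all-positive counts. Errors if a sample has only zero counts.
    """
    zero_samples = counts.columns[(counts == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no entry with nonzero counts in every sample")
    geo = np.exp(np.log(positive).mean(axis=1))
    factors = positive.div(geo, axis=0).median(axis=0)
    factors = factors / np.exp(np.log(factors).mean())  # geometric-mean center
    factors.name = "size_factor"
    return factors


def normalize(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount); strictly increasing in count."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(counts.div(factors, axis=1) + pseudocount)


# ---------------------------------------------------------------------------
# Differential expression


@dataclass
class Contrast:
    """One two-group comparison, optionally adjusted by a categorical covariate."""

    name: str
    case: Sequence[str]
    ref: Sequence[str]
    adjust: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        case, ref = set(self.case), set(self.ref)
        if not case or not ref:
            raise ValueError(f"{self.name}: empty contrast group")
        if case & ref:
            raise ValueError(f"{self.name}: case and reference groups overlap")

    @property
    def samples(self) -> list[str]:
        return list(self.case) + list(self.ref)


def _mom_dispersion(q: np.ndarray, cells: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion over design cells.

    For each cell with >=2 samples: alpha_c = (var - mean) / mean^2, clipped at
    zero; pooled with weights (n_c - 1). Floor DISPERSION_FLOOR.
    """
    num, den = 0.0, 0.0
    for cell in np.unique(cells):
        y = q[cells == cell]
        if len(y) < 2:
            continue
        m = y.mean()
        if m <= 0:
            continue
        v = y.var(ddof=1)
        num += max(0.0, (v - m) / m**2) * (len(y) - 1)
        den += len(y) - 1
    alpha = num / den if den > 0 else 0.0
    return max(alpha, DISPERSION_FLOOR)


def nb_wald_de(
    counts: pd.DataFrame,
    contrast: Contrast,
    factors: pd.Series | None = None,
    prior_sd: float | None = None,
) -> pd.DataFrame:
    """Per-entry NB Wald test for one contrast.

    Returns a DataFrame indexed by accession with columns ``base_mean,
    log2fc, shrunk_log2fc, se, stat, p, padj``. Entries that are all-zero in
    the contrast samples get missing statistics and are excluded from the
    FDR family.
    """
    samples = contrast.samples
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"samples absent from count matrix: {missing}")
    if len(contrast.case) < 2 or len(contrast.ref) < 2:
        raise ValueError(f"{contrast.name}: both groups need >=2 samples")
    sub = counts[samples]
    if factors is None:
        factors = size_factors(sub)
    sf = factors.loc[samples].to_numpy(dtype=float)

    group = np.array([1.0 if s in set(contrast.case) else 0.0 for s in samples])
    X = [np.ones(len(samples)), group]
    colnames = ["intercept", "group"]
    if contrast.adjust is not None:
        adj = pd.Series([contrast.adjust[s] for s in samples], index=samples)
        for level in sorted(adj.unique())[1:]:
            X.append((adj == level).to_numpy(dtype=float))
            colnames.append(f"adjust[{level}]")
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"{contrast.name}: singular design (adjustment confounded with group)"
        )
    # design cells for dispersion estimation
    cells = np.array(["|".join(map(str, row[1:])) for row in X])

    rows = []
    offset = np.log(sf)
    for acc, y in sub.iterrows():
        y = y.to_numpy(dtype=float)
        base_mean = float((y / sf).mean())
        if not y.any():
            rows.append((acc, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        alpha = _mom_dispersion(y / sf, cells)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y,
                    X,
                    family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                )
                res = model.fit(maxiter=200, tol=1e-9)
            beta, se_nat = float(res.params[1]), float(res.bse[1])
        except Exception as exc:  # non-convergence on degenerate entries
            logger.warning("%s: NB fit failed (%s)", acc, exc)
            rows.append((acc, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        log2fc = beta / LN2
        se = se_nat / LN2
        z = log2fc / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((acc, base_mean, log2fc, se, z, p))

    out = pd.DataFrame(
        rows, columns=["accession", "base_mean", "log2fc", "se", "stat", "p"]
    ).set_index("accession")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["shrunk_log2fc"] = shrink_series(out["log2fc"], out["se"], prior_sd)
    return out[["base_mean", "log2fc", "shrunk_log2fc", "se", "stat", "p", "padj"]]


def shrink_series(
    log2fc: pd.Series, se: pd.Series, prior_sd: float | None = None
) -> pd.Series:
    """Normal-prior posterior-mean shrinkage: lfc * tau^2 / (tau^2 + se^2)."""
    if prior_sd is None:
        finite = log2fc[np.isfinite(log2fc)]
        prior_sd = float(finite.std(ddof=1)) if len(finite) > 1 else 1.0
        if not np.isfinite(prior_sd) or prior_sd == 0:
            prior_sd = 1.0
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    return log2fc * prior_sd**2 / (prior_sd**2 + se**2)


def shrink_lfc(results: pd.DataFrame, prior_sd: float | None = None) -> pd.DataFrame:
    """Recompute the ``shrunk_log2fc`` column of a DE result table."""
    out = results.copy()
    out["shrunk_log2fc"] = shrink_series(out["log2fc"], out["se"], prior_sd)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaN propagated."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# qPCR concordance


def ddcq_concordance(
    cq: pd.DataFrame,
    reference_sample: str,
    normalized_values: pd.Series,
) -> tuple[pd.Series, float, float]:
    """ddCq relative expression and its Pearson concordance with sequencing.

    ``cq`` needs columns ``sample, cq_target, cq_control`` (triplicate means).
    dCq = Cq_target - Cq_control; ddCq = dCq - dCq(reference sample);
    relative expression = 2**(-ddCq). Pearson r is computed between
    log2(relative expression) and ``normalized_values`` over shared samples
    (>=3 required).
    """
    cq = cq.set_index("sample") if "sample" in cq.columns else cq
    if cq[["cq_target", "cq_control"]].isna().any().any():
        raise ValueError("missing Cq values")
    if reference_sample not in cq.index:
        raise ValueError(f"reference sample {reference_sample!r} absent from Cq table")
    dcq = cq["cq_target"] - cq["cq_control"]
    ddcq = dcq - dcq.loc[reference_sample]
    rel = np.power(2.0, -ddcq)
    rel.name = "relative_expression"
    shared = rel.index.intersection(normalized_values.index)
    if len(shared) < 3:
        raise ValueError("need >=3 shared samples for correlation")
    r, p = sps.pearsonr(np.log2(rel.loc[shared]), normalized_values.loc[shared])
    return rel, float(r), float(p)
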