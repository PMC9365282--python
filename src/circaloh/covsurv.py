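"""Clock-Wnt covariance patient stratification and survival analysis.

Reproduces, on any expression cohort with TCGA-style barcodes, the
chain: filter expressed genes, split tumor vs surrounding-normal
samples by barcode sample code, per-gene Welch t tests, robust
biweight-midcorrelation networks between core clock and Wnt-pathway
genes, PCA of the significantly co-varying gene union on tumor samples,
per-patient principal-component contribution scores, a high/low
covariance median split, and Kaplan-Meier / log-rank comparison of
overall survival between the two groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

__all__ = [
    "CohortBundle",
    "CorrelationMatrix",
    "TestResult",
    "NoSignificantPairs",
    "filter_expressed_genes",
    "split_by_sample_code",
    "differential_means_test",
    "bicor",
    "correlation_matrix",
    "select_significant_pairs",
    "covariance_scores",
    "assign_groups",
    "kaplan_meier",
    "logrank_test",
    "covsurv_pipeline",
    "CovSurvResult",
]


class NoSignificantPairs(RuntimeError):
    """No clock-Wnt pair passed the correlation significance cutoff;
    there are no genes to score, so the stratification halts."""


@dataclass
class CohortBundle:
    """Expression matrix (genes x samples, log2-like), clinical table
    (sample_id, patient_id, type, time_days, event) and named gene sets
    (at least 'clock' and 'wnt')."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: dict | None = None  # simulation ground truth, if any

    def __post_init__(self) -> None:
        extra = set(self.clinical["sample_id"]) - set(self.expression.columns)
        if extra:
            raise ValueError(f"clinical samples missing from expression: {sorted(extra)[:5]}")
        if (self.clinical["time_days"] < 0).any():
            raise ValueError("negative survival times")


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int


def filter_expressed_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with value > 0 in strictly more than 50% of samples."""
    frac = (expression > 0).mean(axis=1)
    kept = expression.loc[frac > 0.5]
    if kept.empty:
        warnings.warn("no gene passed the >0 in >50% filter")
    return kept


def split_by_sample_code(clinical: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split sample ids by the trailing two-digit TCGA sample code:
    01-09 tumor, 10-19 normal; anything else is excluded with a log line."""
    tumor, normal = [], []
    for sid in clinical["sample_id"]:
        code = str(sid).rsplit("-", 1)[-1]
        if len(code) == 2 and code.isdigit():
            c = int(code)
            if 1 <= c <= 9:
                tumor.append(sid)
                continue
            if 10 <= c <= 19:
                normal.append(sid)
                continue
        logger.warning("sample %r has no recognised sample code; excluded", sid)
    return tumor, normal


def differential_means_test(
    expression: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    genes: list[str] | None = None,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Two-sided Welch t test per gene, tumor vs normal.

    Genes constant in both groups get p = 1 by convention. The
    significance flag uses the strict p < alpha rule.
    """
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need at least 2 samples per side")
    sub = expression.loc[genes] if genes is not None else expression
    x = sub[tumor_ids].to_numpy()
    y = sub[normal_ids].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({
        "mean_tumor": x.mean(axis=1),
        "mean_normal": y.mean(axis=1),
        "t": t,
        "p": p,
        "significant": p < alpha,
    }, index=sub.index)


# ---------------------------------------------------------------------------
# biweight midcorrelation

def _biweight_terms(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight-weighted deviations a_i (x_i - median)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None  # caller falls back to Pearson
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return w * (x - med)


def bicor(x, y) -> float:
    """Biweight midcorrelation: a robust correlation built from
    Tukey-biweight-weighted deviations around medians and MADs (unscaled
    MAD, 9*MAD tuning). Falls back to Pearson when a MAD is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    gx = _biweight_terms(x)
    gy = _biweight_terms(y)
    if gx is None or gy is None:
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt((gx ** 2).sum() * (gy ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((gx * gy).sum() / denom, -1.0, 1.0))


def _corr_pvalue(r: float, n: int) -> float:
    """Two-sided p from the t approximation t = r sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(max(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny))


def correlation_matrix(
    expression: pd.DataFrame,
    row_genes: list[str],
    col_genes: list[str],
    sample_ids: list[str] | None = None,
) -> CorrelationMatrix:
    """Pairwise bicor between two gene lists over the given samples,
    with t-approximation p-values on n-2 df."""
    sub = expression[sample_ids] if sample_ids is not None else expression
    n = sub.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples for correlations")
    missing = (set(row_genes) | set(col_genes)) - set(sub.index)
    if missing:
        raise KeyError(f"genes absent from expression: {sorted(missing)[:5]}")
    r = pd.DataFrame(index=row_genes, columns=col_genes, dtype=float)
    p = pd.DataFrame(index=row_genes, columns=col_genes, dtype=float)
    vecs = {g: sub.loc[g].to_numpy() for g in set(row_genes) | set(col_genes)}
    for gi in row_genes:
        for gj in col_genes:
            if gi == gj:
                r.loc[gi, gj], p.loc[gi, gj] = 1.0, np.finfo(float).tiny
                continue
            rij = bicor(vecs[gi], vecs[gj])
            r.loc[gi, gj] = rij
            p.loc[gi, gj] = _corr_pvalue(rij, n)
    return CorrelationMatrix(r, p, n)


def select_significant_pairs(
    cm: CorrelationMatrix, alpha: float = 0.001
) -> tuple[list[tuple[str, str, float, float]], list[str]]:
    """Cross-set gene pairs with p < alpha and the union of their genes."""
    pairs = []
    for gi in cm.r.index:
        for gj in cm.r.columns:
            if gi == gj:
                continue
            if cm.p.loc[gi, gj] < alpha:
                pairs.append((gi, gj, float(cm.r.loc[gi, gj]), float(cm.p.loc[gi, gj])))
    if not pairs:
        raise NoSignificantPairs(
            f"no gene pair significant at p < {alpha}; nothing to score")
    union = sorted({g for gi, gj, *_ in pairs for g in (gi, gj)})
    return pairs, union


def covariance_scores(
    expression: pd.DataFrame,
    tumor_ids: list[str],
    genes: list[str],
    component: int = 1,
) -> pd.DataFrame:
    """Per-individual contribution (%) to one principal component.

    Genes are standardised across tumor samples; PCA is the SVD of the
    standardised sample x gene matrix; the contribution of individual i
    to component k is 100 * score_ik^2 / sum_j score_jk^2 (sums to 100).
    Deciles (1..10) are assigned by contribution rank.
    """
    if len(tumor_ids) < 3:
        raise ValueError("need at least 3 tumor samples")
    sub = expression.loc[genes, tumor_ids].T  # samples x genes
    sd = sub.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant gene(s): {constant}")
        sub = sub.drop(columns=constant)
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant genes")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    if not 1 <= component <= len(s):
        raise ValueError(f"component {component} out of range 1..{len(s)}")
    score = u[:, component - 1] * s[component - 1]
    contrib = 100.0 * score ** 2 / (score ** 2).sum()
    order = pd.Series(contrib, index=sub.index).rank(method="first")
    decile = np.ceil(order / len(contrib) * 10).astype(int).clip(1, 10)
    return pd.DataFrame({
        "sample_id": sub.index,
        "score": score,
        "pc_contribution": contrib,
        "decile": decile.to_numpy(),
    }).set_index("sample_id")


def assign_groups(scores: pd.DataFrame) -> pd.Series:
    """Median split on |pc_contribution|: the upper half of the ranking
    is 'high' covariance, the lower half 'low'; ties break by stable
    sample-id order and an odd individual goes to 'low'."""
    abs_c = scores["pc_contribution"].abs()
    order = sorted(scores.index, key=lambda s: (abs_c[s], str(s)))
    n = len(order)
    n_high = n // 2
    labels = pd.Series("low", index=scores.index, name="group")
    labels.loc[order[n - n_high:]] = "high"
    return labels


def kaplan_meier(clinical: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns, per group, a table of event times with at-risk counts,
    observed events, censored counts and S(t).
    """
    if (clinical["time_days"] < 0).any():
        raise ValueError("negative survival times")
    merged = clinical.set_index("sample_id").join(groups.rename("group"), how="inner")
    if merged["event"].sum() < 1:
        warnings.warn("no events in cohort; curves are flat")
    out = {}
    for g, sub in merged.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"])
        tab = kmf.event_table.copy()
        surv = kmf.survival_function_.iloc[:, 0]
        out[str(g)] = pd.DataFrame({
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(),
            "events": tab["observed"].to_numpy(),
            "censored": tab["censored"].to_numpy(),
            "survival": surv.reindex(tab.index).to_numpy(),
        }).reset_index(drop=True)
    return out


def logrank_test(clinical: pd.DataFrame, groups: pd.Series) -> TestResult:
    """Two-group log-rank test (chi-square on 1 df) of survival."""
    merged = clinical.set_index("sample_id").join(groups.rename("group"), how="inner")
    labels = merged["group"].unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {list(labels)}")
    if merged["event"].sum() < 1:
        raise ValueError("no events; log-rank undefined")
    a = merged[merged["group"] == labels[0]]
    b = merged[merged["group"] == labels[1]]
    res = _ll_logrank(a["time_days"], b["time_days"], a["event"], b["event"])
    return TestResult(float(res.test_statistic), float(res.p_value), len(merged))


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class CovSurvResult:
    differential: pd.DataFrame
    corr_normal: CorrelationMatrix | None
    corr_tumor: CorrelationMatrix
    clock_wnt: CorrelationMatrix
    pairs: list[tuple[str, str, float, float]]
    gene_union: list[str]
    scores: pd.DataFrame
    groups: pd.Series
    curves: dict[str, pd.DataFrame]
    logrank: TestResult
    warnings: list[str] = field(default_factory=list)


def covsurv_pipeline(
    bundle: CohortBundle,
    alpha: float = 0.001,
    diff_alpha: float = 0.001,
    component: int = 1,
    corr_samples: str = "tumor",
) -> CovSurvResult:
    """Run the full stratification on a cohort bundle.

    ``corr_samples`` chooses which samples the clock-Wnt correlation
    screen uses ('tumor' or 'normal'); the PCA and survival comparison
    always use tumor samples. Samples lacking survival records are
    excluded before scoring.
    """
    notes: list[str] = []
    expr = filter_expressed_genes(bundle.expression)
    clin = bundle.clinical
    tumor_ids, normal_ids = split_by_sample_code(clin)
    clock = [g for g in bundle.gene_sets["clock"] if g in expr.index]
    wnt = [g for g in bundle.gene_sets["wnt"] if g in expr.index]
    if not clock or not wnt:
        raise ValueError("clock or Wnt gene set empty after expression filtering")

    diff = differential_means_test(expr, tumor_ids, normal_ids, genes=clock,
                                   alpha=diff_alpha)
    corr_tumor = correlation_matrix(expr, clock, clock, tumor_ids)
    corr_normal = (correlation_matrix(expr, clock, clock, normal_ids)
                   if len(normal_ids) >= 5 else None)
    screen_ids = tumor_ids if corr_samples == "tumor" else normal_ids
    clock_wnt = correlation_matrix(expr, clock, wnt, screen_ids)
    pairs, union = select_significant_pairs(clock_wnt, alpha=alpha)

    has_surv = set(clin.loc[clin["time_days"].notna(), "sample_id"])
    usable = [s for s in tumor_ids if s in has_surv]
    dropped = len(tumor_ids) - len(usable)
    if dropped:
        notes.append(f"{dropped} tumor sample(s) without survival excluded before scoring")
        logger.warning(notes[-1])
    scores = covariance_scores(expr, usable, union, component=component)
    groups = assign_groups(scores)
    tumor_clin = clin[clin["sample_id"].isin(usable)]
    curves = kaplan_meier(tumor_clin, groups)
    lr = logrank_test(tumor_clin, groups)
    return CovSurvResult(diff, corr_normal, corr_tumor, clock_wnt, pairs, union,
                         scores, groups, curves, lr, notes)
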