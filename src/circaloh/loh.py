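"""Loss-of-heterozygosity detection from exome-style interval read depth.

Input is a matrix of read counts over tiled genomic intervals (BED
semantics: 0-based, half-open) for replicate samples in two groups
(e.g. early vs late passage). Counts are assumed to come from reads
already filtered upstream (MAPQ >= 20, proper pairs <= 1000 bp apart);
this module normalises library sizes to the largest sample, converts to
length-corrected log2 densities, tests each interval with an
empirical-Bayes moderated t statistic, and calls contiguous runs of
significantly depleted intervals as LOH segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DepthTrackSet",
    "IntervalMatrix",
    "ModerationPrior",
    "ModeratedStats",
    "LohSegment",
    "normalize_depth",
    "quantify_intervals",
    "estimate_prior",
    "moderated_t_test",
    "detect_loh_segment",
    "loh_pipeline",
]


@dataclass
class DepthTrackSet:
    """Per-sample read counts over shared BED intervals.

    intervals: DataFrame with chrom/start/end; counts: DataFrame indexed
    like intervals, one column per sample; groups: sample -> label.
    """

    intervals: pd.DataFrame
    counts: pd.DataFrame
    groups: dict[str, str]
    planted_loh: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.counts):
            raise ValueError("intervals and counts row counts differ")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")


@dataclass
class IntervalMatrix:
    """Length-corrected, normalised, log2-transformed interval values."""

    log2_values: pd.DataFrame
    offsets: dict[str, float]  # per-sample scale factor applied before log


@dataclass
class ModerationPrior:
    """Empirical-Bayes prior on interval variances: d0 prior df, s0_sq
    prior variance (log2 units squared). d0 = inf means full shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq < 0:
            raise ValueError("prior parameters must be nonnegative")


@dataclass
class ModeratedStats:
    table: pd.DataFrame  # log2fc, t, p, s2, df_total per interval
    prior: ModerationPrior


@dataclass(frozen=True)
class LohSegment:
    start_index: int
    end_index: int  # half-open
    mean_log2fc: float
    n_significant: int


def normalize_depth(tracks: DepthTrackSet) -> DepthTrackSet:
    """Scale every sample to the total of the largest sample (library-size
    normalisation "to the largest data store")."""
    totals = tracks.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total depth: {list(zero.index)}")
    scale = totals.max() / totals
    scaled = tracks.counts * scale
    return DepthTrackSet(tracks.intervals, scaled, dict(tracks.groups), tracks.planted_loh)


def quantify_intervals(tracks: DepthTrackSet, pseudocount: float = 1.0) -> IntervalMatrix:
    """log2((count + pseudocount) / interval length in kb)."""
    lengths_kb = (tracks.intervals["end"] - tracks.intervals["start"]).to_numpy() / 1000.0
    if (lengths_kb <= 0).any():
        bad = int(np.argmax(lengths_kb <= 0))
        raise ValueError(f"zero-length interval at index {bad}")
    vals = np.log2((tracks.counts.to_numpy(dtype=float) + pseudocount) / lengths_kb[:, None])
    totals = tracks.counts.sum(axis=0)
    scale = (totals.max() / totals).to_dict()
    return IntervalMatrix(pd.DataFrame(vals, index=tracks.counts.index,
                                       columns=tracks.counts.columns), scale)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, as in the
    classic empirical-Bayes variance-moderation fit)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> ModerationPrior:
    """Fit (d0, s0_sq) by matching the first two moments of log s^2.

    Under the hierarchical model, Var(log s^2) = trigamma(df/2) +
    trigamma(d0/2); the excess of the observed variance of log s^2 over
    trigamma(df/2) identifies d0 via trigamma inversion, and the mean
    identifies s0_sq. Non-positive excess means no evidence of variance
    heterogeneity: d0 = inf (full shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 intervals with positive variance")
    z = np.log(s2[ok])
    e_mean, e_var = z.mean(), z.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_mean - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    else:
        half_d0 = _trigamma_inverse(float(excess))
        d0 = 2.0 * half_d0
        log_s0 = (e_mean - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
                  + special.polygamma(0, half_d0) - np.log(half_d0))
    return ModerationPrior(d0=float(d0), s0_sq=float(np.exp(log_s0)))


def moderated_t_test(
    matrix: IntervalMatrix,
    groups: dict[str, str],
    prior: ModerationPrior | str = "estimate",
    group_order: tuple[str, str] = ("early", "late"),
) -> ModeratedStats:
    """Per-interval moderated t test of late - early log2 values.

    The interval variance is shrunk toward the prior:
    s_tilde^2 = (d0 s0^2 + d s^2)/(d0 + d); t = diff / (s_tilde *
    sqrt(1/n1 + 1/n2)) referred to a t distribution on d0 + d df.
    d0 = 0 recovers the ordinary pooled-variance t; d0 = inf gives a
    fixed-variance z-like statistic.
    """
    g1, g2 = group_order
    cols1 = [s for s in matrix.log2_values.columns if groups.get(s) == g1]
    cols2 = [s for s in matrix.log2_values.columns if groups.get(s) == g2]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {g1}:{n1} {g2}:{n2}")
    x1 = matrix.log2_values[cols1].to_numpy()
    x2 = matrix.log2_values[cols2].to_numpy()
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    d = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / d

    if isinstance(prior, str):
        if prior != "estimate":
            raise ValueError("prior must be a ModerationPrior or 'estimate'")
        prior = estimate_prior(s2, d)

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    if np.isinf(prior.d0):
        s_tilde2 = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
        t = diff / np.sqrt(s_tilde2) / se_factor
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s_tilde2 = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(s_tilde2) / se_factor
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({
        "log2fc": diff, "t": t, "p": p, "s2": s2,
        "df_total": df_total,
    }, index=matrix.log2_values.index)
    return ModeratedStats(table, prior)


def detect_loh_segment(
    stats_table: pd.DataFrame,
    log2fc_threshold: float = -1.0,
    p_threshold: float = 0.01,
    min_run: int = 3,
    max_gap: int = 1,
) -> list[LohSegment]:
    """Runs of >= min_run intervals that are both significantly depleted
    (p < p_threshold) and below log2fc_threshold.

    Runs may bridge up to ``max_gap`` consecutive non-qualifying
    intervals (a single noisy tile inside a real deletion should not
    split the call); a segment never starts or ends on a bridged
    interval, and n_significant counts qualifying intervals only.
    """
    hit = ((stats_table["log2fc"].to_numpy() <= log2fc_threshold)
           & (stats_table["p"].to_numpy() < p_threshold))
    fc = stats_table["log2fc"].to_numpy()
    segments: list[LohSegment] = []
    n = len(hit)
    i = 0
    while i < n:
        if not hit[i]:
            i += 1
            continue
        # extend from i, allowing gaps of <= max_gap misses between hits
        j = i
        last_hit = i
        while j < n:
            if hit[j]:
                last_hit = j
            elif j - last_hit > max_gap:
                break
            j += 1
        end = last_hit + 1
        n_sig = int(hit[i:end].sum())
        if n_sig >= min_run:
            segments.append(LohSegment(i, end, float(fc[i:end].mean()), n_sig))
        i = end
    return segments


def loh_pipeline(
    tracks: DepthTrackSet,
    pseudocount: float = 1.0,
    prior: ModerationPrior | str = "estimate",
    log2fc_threshold: float = -1.0,
    p_threshold: float = 0.01,
    min_run: int = 3,
) -> tuple[ModeratedStats, list[LohSegment]]:
    """Normalise, quantify, test and segment in one call."""
    norm = normalize_depth(tracks)
    mat = quantify_intervals(norm, pseudocount=pseudocount)
    mod = moderated_t_test(mat, norm.groups, prior=prior)
    segs = detect_loh_segment(mod.table, log2fc_threshold, p_threshold, min_run)
    return mod, segs
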