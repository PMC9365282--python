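"""Seeded synthetic data generators for every analysis stage.

Each generator is a pure function of its config (seed included): the
same config yields byte-identical output. The generators plant known
ground truth — damping/amplitude of luminescence rhythms, true copy
number on dPCR plates, a latent clock-Wnt covariance level coupled to
survival hazard, and a deleted depth segment — so every downstream
module can be validated against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .covsurv import CohortBundle
from .dpcr import PartitionPlate
from .loh import DepthTrackSet
from .rhythm import Trace

__all__ = [
    "TraceConfig",
    "DpcrConfig",
    "CohortConfig",
    "DepthConfig",
    "TraceSet",
    "generate_traces",
    "generate_dpcr_plate",
    "generate_cohort",
    "generate_depth_tracks",
    "CLOCK_GENES",
]

# canonical core-clock symbols used as default labels for the 12 clock genes
CLOCK_GENES = ["ARNTL", "CLOCK", "PER1", "PER2", "PER3", "CRY1",
               "CRY2", "NR1D1", "NR1D2", "RORA", "RORC", "DBP"]

_WNT_SEED_GENES = ["CTNNB1", "AXIN2", "APC", "LEF1", "TCF7", "WNT3A",
                   "WNT5A", "FZD1", "LRP6", "DVL1", "GSK3B", "MYC"]


# ---------------------------------------------------------------------------
# luminescence traces

@dataclass(frozen=True)
class TraceConfig:
    """Damped-cosine luminescence model: y(t) = baseline + trend*t +
    A exp(-d t) cos(2 pi (t - phi)/T) + N(0, noise_sd)."""

    n_samples: int = 7
    duration_h: float = 72.0
    dt_h: float = 1.0
    period_h: float = 24.0
    amplitude: float = 3.0
    damping_per_h: float = 0.01
    phase_h: float = 0.0
    baseline: float = 100.0
    trend_per_h: float = -0.2
    noise_sd: float = 0.5
    condition: str = "normal"  # normal | tumor | arrhythmic | abnormal_period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_h <= 0 or self.duration_h <= 0:
            raise ValueError("dt_h and duration_h must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.condition not in {"normal", "tumor", "arrhythmic", "abnormal_period"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition in {"normal", "tumor"} and self.duration_h < 2 * self.period_h:
            raise ValueError("duration must cover at least two periods")


@dataclass
class TraceSet:
    traces: list[Trace]

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def to_frame(self) -> pd.DataFrame:
        """Long format: sample_id, patient_id, condition, time_h, signal."""
        parts = [pd.DataFrame({
            "sample_id": tr.sample_id, "patient_id": tr.patient_id,
            "condition": tr.condition, "time_h": tr.times, "signal": tr.values,
        }) for tr in self.traces]
        return pd.concat(parts, ignore_index=True)


# tumor recordings show strongly blunted rhythms: amplitude scaled down
_TUMOR_AMP_FACTOR = 0.2


def generate_traces(config: TraceConfig) -> TraceSet:
    """Simulate n_samples luminescence traces under one condition.

    'arrhythmic' forces amplitude 0; 'abnormal_period' draws each
    trace's period uniformly from [16, 20] or [32, 36] h (outside the
    circadian gate); 'tumor' blunts amplitude by a fixed factor.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration_h, config.dt_h)
    traces = []
    for i in range(config.n_samples):
        amp = config.amplitude
        period = config.period_h
        if config.condition == "arrhythmic":
            amp = 0.0
        elif config.condition == "tumor":
            amp = amp * _TUMOR_AMP_FACTOR
        elif config.condition == "abnormal_period":
            lo, hi = (16.0, 20.0) if rng.random() < 0.5 else (32.0, 36.0)
            period = rng.uniform(lo, hi)
        signal = (config.baseline + config.trend_per_h * times
                  + amp * np.exp(-config.damping_per_h * times)
                  * np.cos(2 * np.pi * (times - config.phase_h) / period))
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=len(times))
        traces.append(Trace(
            sample_id=f"S{i:02d}-{config.condition}",
            patient_id=f"P{i:02d}",
            condition=config.condition,
            times=times,
            values=signal,
        ))
    return TraceSet(traces)


# ---------------------------------------------------------------------------
# dPCR plates

@dataclass(frozen=True)
class DpcrConfig:
    """Poisson partition occupancy for a two-channel dPCR well."""

    n_partitions: int = 20000
    ref_lambda: float = 0.5  # reference copies / partition
    true_cnv: float = 2.0
    ref_copies: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        if not 0 < self.ref_lambda < 5:
            raise ValueError("ref_lambda must be in (0, 5)")
        if self.true_cnv < 0:
            raise ValueError("true_cnv must be nonnegative")


def generate_dpcr_plate(config: DpcrConfig, sample_id: str = "") -> PartitionPlate:
    """Each partition is positive in a channel with probability
    1 - exp(-lambda_channel); the target channel's lambda scales with
    the simulated copy number: lambda_t = ref_lambda * cnv / ref_copies."""
    rng = np.random.default_rng(config.seed)
    lam_t = config.ref_lambda * config.true_cnv / config.ref_copies
    p_t = -math.expm1(-lam_t)
    p_r = -math.expm1(-config.ref_lambda)
    target = int(rng.binomial(config.n_partitions, p_t)) if p_t > 0 else 0
    reference = int(rng.binomial(config.n_partitions, p_r))
    return PartitionPlate(config.n_partitions, target, reference,
                          sample_id=sample_id, true_cnv=config.true_cnv)


# ---------------------------------------------------------------------------
# expression + survival cohort

@dataclass(frozen=True)
class CohortConfig:
    """Tumor/normal expression cohort with a latent clock-Wnt factor.

    In normal samples clock and Wnt genes load on a shared Gaussian
    factor with strength ``covariance_strength``. In tumors each
    patient carries a binary latent covariance level; only
    high-covariance patients keep the shared factor, and survival is
    exponential with hazard multiplied by ``hazard_ratio`` for
    low-covariance patients. Defaults mirror a COAD-scale cohort
    (470 tumors, 57 matched normals, 12 core clock genes).
    """

    n_patients: int = 470
    n_normal: int = 57
    n_clock_genes: int = 12
    n_wnt_genes: int = 20
    n_background_genes: int = 200
    covariance_strength: float = 0.8
    hazard_ratio: float = 2.5
    censor_rate: float = 0.3
    baseline_hazard: float = 1e-3  # events / day
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_normal", "n_clock_genes",
                     "n_wnt_genes", "n_background_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normal > self.n_patients:
            raise ValueError("n_normal cannot exceed n_patients")
        if not 0 <= self.covariance_strength <= 1:
            raise ValueError("covariance_strength must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


def _gene_labels(config: CohortConfig) -> tuple[list[str], list[str], list[str]]:
    clock = [CLOCK_GENES[i] if i < len(CLOCK_GENES) else f"CLOCKG{i + 1}"
             for i in range(config.n_clock_genes)]
    wnt = [_WNT_SEED_GENES[i] if i < len(_WNT_SEED_GENES) else f"WNTG{i + 1}"
           for i in range(config.n_wnt_genes)]
    bg = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    return clock, wnt, bg


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate expression (log2-like), clinical survival and gene sets.

    Sample barcodes follow the TCGA suffix convention: tumor samples
    end in "-01", matched normals (same patient id) in "-11". A tenth
    of the background genes are made mostly-zero so the expressed-gene
    filter has something to remove.
    """
    rng = np.random.default_rng(config.seed)
    clock, wnt, bg = _gene_labels(config)
    genes = clock + wnt + bg
    n_cw = len(clock) + len(wnt)
    s = config.covariance_strength

    mu = rng.uniform(3.0, 8.0, size=len(genes))
    loadings = rng.uniform(0.7, 1.3, size=n_cw)

    tumor_ids = [f"SYN-{i + 1:04d}-01" for i in range(config.n_patients)]
    normal_ids = [f"SYN-{i + 1:04d}-11" for i in range(config.n_normal)]
    patients = [f"SYN-{i + 1:04d}" for i in range(config.n_patients)]

    # tumor latent covariance level: 1 = clock-Wnt factor intact ("high")
    z = rng.integers(0, 2, size=config.n_patients)
    f_tumor = rng.normal(size=config.n_patients)
    f_normal = rng.normal(size=config.n_normal)

    expr = np.empty((len(genes), config.n_patients + config.n_normal))
    noise = rng.normal(0.0, config.noise_sd, size=expr.shape)
    factor_t = s * z * f_tumor  # per-tumor factor exposure
    factor_n = s * f_normal
    for gi in range(len(genes)):
        load = loadings[gi] if gi < n_cw else 0.0
        expr[gi, :config.n_patients] = mu[gi] + load * factor_t + noise[gi, :config.n_patients]
        expr[gi, config.n_patients:] = mu[gi] + load * factor_n + noise[gi, config.n_patients:]

    # sparse background genes: mostly zero, should fail the >50% filter
    n_sparse = max(1, config.n_background_genes // 10)
    sparse_rows = np.arange(len(genes) - n_sparse, len(genes))
    zero_mask = rng.random((n_sparse, expr.shape[1])) < 0.6
    expr[sparse_rows, :] = np.where(zero_mask, 0.0, expr[sparse_rows, :])

    expression = pd.DataFrame(expr, index=genes, columns=tumor_ids + normal_ids)

    hazard = config.baseline_hazard * config.hazard_ratio ** (1 - z)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(config.n_patients) < config.censor_rate
    time = np.where(censored, rng.random(config.n_patients) * t_event, t_event)
    event = (~censored).astype(int)

    rows = []
    for i, sid in enumerate(tumor_ids):
        rows.append((sid, patients[i], "tumor", float(time[i]), int(event[i])))
    for i, sid in enumerate(normal_ids):
        rows.append((sid, patients[i], "normal", float(time[i]), int(event[i])))
    clinical = pd.DataFrame(rows, columns=["sample_id", "patient_id", "type",
                                           "time_days", "event"])

    truth = {
        "covariance_level": pd.Series(z, index=tumor_ids, name="high_covariance"),
        "loadings": pd.Series(loadings, index=clock + wnt),
        "config": config,
    }
    return CohortBundle(expression, clinical, {"clock": clock, "wnt": wnt}, truth)


# ---------------------------------------------------------------------------
# read-depth tracks

@dataclass(frozen=True)
class DepthConfig:
    """Negative-binomial depth over tiled intervals with a planted
    deletion: variance = mu + mu^2/dispersion; dispersion=None means
    Poisson. ``loh_fold`` multiplies the late-group mean inside
    ``loh_interval`` (0 = complete loss)."""

    n_intervals: int = 200
    interval_len_bp: int = 200
    mean_depth: float = 100.0
    dispersion: float | None = 40.0
    groups: tuple[tuple[str, int], ...] = (("early", 4), ("late", 4))
    loh_interval: tuple[int, int] = (40, 80)
    loh_fold: float = 0.5
    chrom: str = "chr18"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.loh_fold < 0:
            raise ValueError("loh_fold must be nonnegative")
        lo, hi = self.loh_interval
        if not (0 <= lo < hi <= self.n_intervals):
            raise ValueError("loh_interval outside [0, n_intervals)")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float | None) -> np.ndarray:
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion is None:
        out[pos] = rng.poisson(mean[pos])
    else:
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_depth_tracks(config: DepthConfig) -> DepthTrackSet:
    """Simulate replicate depth tracks with a planted LOH segment in
    the late group; intervals use 0-based half-open BED coordinates."""
    rng = np.random.default_rng(config.seed)
    starts = np.arange(config.n_intervals) * config.interval_len_bp
    intervals = pd.DataFrame({
        "chrom": config.chrom,
        "start": starts,
        "end": starts + config.interval_len_bp,
    })
    lo, hi = config.loh_interval
    cols, groups = {}, {}
    for label, n_rep in config.groups:
        for r in range(n_rep):
            mean = np.full(config.n_intervals, config.mean_depth, dtype=float)
            if label == "late":
                mean[lo:hi] *= config.loh_fold
            name = f"{label}_{r + 1}"
            cols[name] = _nb_draw(rng, mean, config.dispersion)
            groups[name] = label
    counts = pd.DataFrame(cols)
    return DepthTrackSet(intervals, counts, groups, planted_loh=(lo, hi))
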