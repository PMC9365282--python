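"""Digital-PCR copy-number estimation by Poisson partition correction.

A dPCR plate splits the template across ~20,000 partitions; molecules
land in partitions approximately Poisson, so the fraction of positive
partitions p relates to the mean template load per partition as
p = 1 - exp(-lambda), inverted as lambda = -ln(1 - p). Copy number of a
target locus is the ratio of target to reference concentration scaled
by the reference copy number (autosomal references: 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PartitionPlate",
    "ConcentrationEstimate",
    "CopyNumberResult",
    "SaturationError",
    "estimate_concentration",
    "estimate_copy_number",
    "call_plate",
]


class SaturationError(ValueError):
    """All partitions positive: lambda is unbounded."""


@dataclass(frozen=True)
class PartitionPlate:
    """Positive-partition counts for one two-channel dPCR well."""

    n_partitions: int
    target_positive: int
    reference_positive: int
    sample_id: str = ""
    true_cnv: float | None = None  # simulation ground truth only

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        for name in ("target_positive", "reference_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_partitions:
                raise ValueError(f"{name}={v} outside [0, n_partitions]")


@dataclass(frozen=True)
class ConcentrationEstimate:
    lam: float  # copies / partition
    ci_lo: float
    ci_hi: float
    positive_fraction: float


@dataclass(frozen=True)
class CopyNumberResult:
    cnv: float
    ci_lo: float
    ci_hi: float
    state: str  # diploid | het_loss | homozygous_loss | gain | indeterminate


def estimate_concentration(positive: int, total: int) -> ConcentrationEstimate:
    """Poisson-corrected concentration lambda = -ln(1 - positive/total).

    The 95% CI is the Wilson interval on the positive fraction pushed
    through the same transform (monotone, so endpoints map directly).
    """
    if total <= 0:
        raise ValueError("total partitions must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count outside [0, total]")
    if positive == total:
        raise SaturationError("all partitions positive; concentration not estimable")
    frac = positive / total
    lam = -np.log1p(-frac)
    lo, hi = proportion_confint(positive, total, alpha=0.05, method="wilson")
    return ConcentrationEstimate(
        lam=float(lam),
        ci_lo=float(-np.log1p(-min(lo, 1.0 - 1e-15))),
        ci_hi=float(-np.log1p(-min(hi, 1.0 - 1e-15))),
        positive_fraction=float(frac),
    )


def _state(cnv: float, ci_width: float, thresholds: tuple[float, float, float],
           indeterminate_width: float) -> str:
    t_homo, t_het, t_gain = thresholds
    if ci_width > indeterminate_width:
        return "indeterminate"
    if cnv < t_homo:
        return "homozygous_loss"
    if cnv < t_het:
        return "het_loss"
    if cnv <= t_gain:
        return "diploid"
    return "gain"


def estimate_copy_number(
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    ref_copies: float = 2.0,
    thresholds: tuple[float, float, float] = (0.3, 1.5, 2.5),
    indeterminate_width: float = 1.0,
) -> CopyNumberResult:
    """CNV = ref_copies * lambda_target / lambda_reference with a
    first-order delta-method CI combining both channel CIs.

    States: cnv < 0.3 homozygous_loss, < 1.5 het_loss, <= 2.5 diploid,
    else gain; a CI wider than ``indeterminate_width`` is reported
    indeterminate. Thresholds are conventions, overridable.
    """
    if reference.lam <= 0:
        raise ValueError("reference channel concentration is zero; reference failed")
    cnv = ref_copies * target.lam / reference.lam
    z = 1.959963984540054
    sd_t = (target.ci_hi - target.ci_lo) / (2 * z)
    sd_r = (reference.ci_hi - reference.ci_lo) / (2 * z)
    var = ((ref_copies / reference.lam) ** 2 * sd_t ** 2
           + (ref_copies * target.lam / reference.lam ** 2) ** 2 * sd_r ** 2)
    half = z * np.sqrt(var)
    lo, hi = max(0.0, cnv - half), cnv + half
    return CopyNumberResult(float(cnv), float(lo), float(hi),
                            _state(cnv, hi - lo, thresholds, indeterminate_width))


def call_plate(plate: PartitionPlate, ref_copies: float = 2.0, **kwargs) -> CopyNumberResult:
    """Convenience: concentration estimates for both channels, then CNV."""
    tgt = estimate_concentration(plate.target_positive, plate.n_partitions)
    ref = estimate_concentration(plate.reference_positive, plate.n_partitions)
    return estimate_copy_number(tgt, ref, ref_copies=ref_copies, **kwargs)
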