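"""Small bench-side quantitative procedures.

The statistics that accompany the array analysis at the bench: percent exon
inclusion (PSI) from gel band intensities with a t-test decision against
wild type, the myotube fusion index, comparative-CT (delta-delta-Ct) qPCR
quantification, mRNA half-life from a transcription-blocked decay course,
and RNA-immunoprecipitation fold enrichment over an IgG control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BandQuant",
    "DecaySeries",
    "percent_inclusion",
    "judge_different_from_wt",
    "fusion_index",
    "ddct_fold_change",
    "half_life",
    "rip_fold_enrichment",
]


@dataclass(frozen=True)
class BandQuant:
    """Inclusion and skip band intensities of one RT-PCR lane."""

    sample_id: str
    inclusion_intensity: float
    skip_intensity: float

    def __post_init__(self):
        if self.inclusion_intensity < 0 or self.skip_intensity < 0:
            raise ValueError("band intensities must be nonnegative")
        if self.inclusion_intensity == 0 and self.skip_intensity == 0:
            raise ValueError("at least one band intensity must be positive")


@dataclass(frozen=True)
class DecaySeries:
    """Relative mRNA abundance (fraction of t=0) over a time course in hours."""

    times_h: tuple[float, ...]
    abundance: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.abundance, dtype=float)
        if t.size != a.size or t.size < 2:
            raise ValueError("need >= 2 matched time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("abundance must be positive")


def percent_inclusion(inclusion_intensity: float, skip_intensity: float) -> float:
    """PSI (%) = 100 x inclusion / (inclusion + skip); skipping rate = 100 - PSI."""
    if inclusion_intensity < 0 or skip_intensity < 0:
        raise ValueError("band intensities must be nonnegative")
    total = inclusion_intensity + skip_intensity
    if total == 0:
        raise ValueError("PSI undefined: both band intensities are zero")
    # float rounding can push the ratio a ulp past the closed bounds
    return min(100.0, max(0.0, 100.0 * inclusion_intensity / total))


def judge_different_from_wt(
    test: Sequence[float],
    wt: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[bool, float]:
    """Two-sample t-test of replicate PSIs against the wild-type set.

    Student's equal-variance test by default (n is typically 3 per group);
    set ``welch=True`` for the unequal-variance variant.  Returns
    ``(different, p)`` with ``different = p < alpha``.  Two constant,
    identical groups give p = 1 and False.
    """
    t = np.asarray(test, dtype=float)
    w = np.asarray(wt, dtype=float)
    if t.size < 2 or w.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if t.var(ddof=1) == 0 and w.var(ddof=1) == 0:
        p = 1.0 if t.mean() == w.mean() else 0.0
        return p < alpha, p
    res = stats.ttest_ind(t, w, equal_var=not welch)
    p = float(res.pvalue)
    return p < alpha, p


def fusion_index(nuclei_in_mhc_multinucleated: int, total_nuclei: int) -> float:
    """Myogenic fusion index (%).

    100 x (nuclei inside MHC-positive myotubes with >= 3 nuclei) / (all
    nuclei counted).  Counts below 1500 total nuclei are accepted but
    logged, since a robust index needs at least that many.
    """
    if total_nuclei < 1:
        raise ValueError("total_nuclei must be >= 1")
    if not (0 <= nuclei_in_mhc_multinucleated <= total_nuclei):
        raise ValueError("numerator must lie in [0, total_nuclei]")
    if total_nuclei < 1500:
        logger.warning(
            "fusion index from only %d nuclei; >= 1500 recommended", total_nuclei
        )
    return 100.0 * nuclei_in_mhc_multinucleated / total_nuclei


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative-CT relative quantification: fold = 2**(-ddCt).

    ddCt = (Ct_target - Ct_reference) in the test sample minus the same
    difference in the control sample.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def half_life(series: DecaySeries) -> float:
    """mRNA half-life (hours) from a log-linear fit of the decay course.

    ln(abundance) is regressed on time; t1/2 = ln 2 / |slope|.  A
    non-negative slope (no decay within the course) returns ``math.inf``.
    """
    t = np.asarray(series.times_h, dtype=float)
    a = np.asarray(series.abundance, dtype=float)
    slope = stats.linregress(t, np.log(a)).slope
    if slope >= 0:
        return math.inf
    return math.log(2.0) / abs(slope)


def rip_fold_enrichment(
    ip_signal: float,
    igg_signal: float,
    input_signal: float,
    input_signal_igg: float | None = None,
) -> float:
    """RIP/ChIP fold enrichment: (IP/input) / (IgG/input).

    With a single shared input this reduces to IP/IgG; separate inputs for
    the IP and IgG aliquots are supported via ``input_signal_igg``.
    """
    if input_signal_igg is None:
        input_signal_igg = input_signal
    for name, v in (
        ("ip_signal", ip_signal),
        ("input_signal", input_signal),
        ("input_signal_igg", input_signal_igg),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if igg_signal <= 0:
        raise ValueError(
            "igg_signal must be positive; add a pseudocount to the IgG "
            "quantification if the control yielded no signal"
        )
    return (ip_signal / input_signal) / (igg_signal / input_signal_igg)
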