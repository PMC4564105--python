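"""Background-error threshold estimation from mutation-free reference samples.

Allele fractions of reference samples are approximately normal on the
log-odds scale.  After dropping the most extreme values at each end, the
detection threshold is set k standard deviations above the trimmed mean
and back-transformed to a fraction.  With k = 6 the implied two-sided
significance level is about 1.97e-9.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import (
    CohortMismatchError,
    InsufficientDataError,
    UndefinedFractionError,
)
from .tables import Cohort, CohortTable

__all__ = [
    "BackgroundModel",
    "allele_fraction",
    "to_log_odds",
    "inverse_log_odds",
    "trimmed_location_scale",
    "estimate_background",
    "sigma_to_alpha",
]


def allele_fraction(total_reads: int, alt_reads: int) -> float:
    """Mutant-allele fraction alt/total.

    Raises :class:`UndefinedFractionError` when ``total_reads`` is zero.
    """
    if total_reads == 0:
        raise UndefinedFractionError("allele fraction undefined for total_reads = 0")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError(f"need 0 <= alt_reads <= total_reads, got {alt_reads}/{total_reads}")
    return alt_reads / total_reads


def to_log_odds(
    value: float | tuple[int, int],
    pseudocount: float = 0.5,
) -> float:
    """Natural-log odds of a fraction or of a ``(total_reads, alt_reads)`` pair.

    For a count pair the pseudocount is added to both the mutant and the
    reference read count (Haldane continuity correction), keeping the
    result finite even with zero mutant reads:
    ``ln((alt + pc) / (total - alt + pc))``.

    A bare fraction of exactly 0 or 1 has no finite log-odds; pass the
    counts instead so the pseudocount can apply.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if isinstance(value, tuple):
        total, alt = value
        if not 0 <= alt <= total or total <= 0:
            raise ValueError(f"invalid count pair {value}")
        if pseudocount == 0 and (alt == 0 or alt == total):
            raise ValueError("zero pseudocount with boundary counts gives infinite log-odds")
        return math.log((alt + pseudocount) / (total - alt + pseudocount))
    f = float(value)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    if f in (0.0, 1.0):
        raise ValueError(
            "log-odds of a bare fraction 0 or 1 is infinite; "
            "supply the (total_reads, alt_reads) pair so the pseudocount applies"
        )
    return math.log(f / (1.0 - f))


def inverse_log_odds(x: float) -> float:
    """Back-transform a log-odds value to a fraction in (0, 1)."""
    return float(expit(x))


def trimmed_location_scale(
    values: Sequence[float], n_trim_each_end: int = 2
) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) after symmetric count trimming.

    The ``n_trim_each_end`` smallest and largest values are removed
    (stable sort: ties broken by input order) before the moments are
    computed.
    """
    if n_trim_each_end < 0:
        raise ValueError("n_trim_each_end must be non-negative")
    vals = np.asarray(values, dtype=float)
    n_min = 2 * n_trim_each_end + 2
    if vals.size < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} values to trim {n_trim_each_end} from each end, "
            f"got {vals.size}"
        )
    order = np.argsort(vals, kind="stable")
    kept = vals[order][n_trim_each_end : vals.size - n_trim_each_end or None]
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1))
    return mean, sd


def sigma_to_alpha(k_sigma: float) -> float:
    """Two-sided standard-normal tail probability at ``k_sigma``.

    ``sigma_to_alpha(0) == 1``; at 6 the value is about 1.97e-9.
    """
    if k_sigma < 0:
        raise ValueError(f"k_sigma must be non-negative, got {k_sigma}")
    return float(2.0 * norm.sf(k_sigma))


@dataclass(frozen=True)
class BackgroundModel:
    """Trimmed log-odds location/scale of the background error and the
    derived k-sigma detection threshold."""

    mu_logodds: float
    sd_logodds: float
    k_sigma: float
    n_trim_each_end: int
    n_reference_used: int
    threshold_fraction: float
    implied_alpha: float
    pseudocount: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_threshold(cls, threshold_fraction: float, k_sigma: float = 6.0) -> "BackgroundModel":
        """A degenerate model pinning the threshold directly (sd = 0),
        useful for applying a published threshold value."""
        if not 0.0 < threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        return cls(
            mu_logodds=math.log(threshold_fraction / (1 - threshold_fraction)),
            sd_logodds=0.0,
            k_sigma=k_sigma,
            n_trim_each_end=0,
            n_reference_used=0,
            threshold_fraction=threshold_fraction,
            implied_alpha=sigma_to_alpha(k_sigma),
            pseudocount=0.5,
        )


def estimate_background(
    reference: CohortTable,
    k_sigma: float = 6.0,
    n_trim_each_end: int = 2,
    pseudocount: float = 0.5,
) -> BackgroundModel:
    """Estimate the detection threshold from reference-only samples.

    Each sample's counts are transformed to log-odds, the trimmed mean and
    SD are computed, and the threshold is ``inverse_logit(mu + k * sd)``.

    Raises :class:`CohortMismatchError` if any sample is not from the
    REFERENCE cohort.
    """
    bad = [s.sample_id for s in reference if s.cohort is not Cohort.REFERENCE]
    if bad:
        raise CohortMismatchError(
            f"estimate_background expects REFERENCE samples only; offending: {bad[:5]}"
        )
    logodds = [to_log_odds((s.total_reads, s.alt_reads), pseudocount) for s in reference]
    mu, sd = trimmed_location_scale(logodds, n_trim_each_end)
    return BackgroundModel(
        mu_logodds=mu,
        sd_logodds=sd,
        k_sigma=float(k_sigma),
        n_trim_each_end=int(n_trim_each_end),
        n_reference_used=len(logodds) - 2 * n_trim_each_end,
        threshold_fraction=inverse_log_odds(mu + k_sigma * sd),
        implied_alpha=sigma_to_alpha(k_sigma),
        pseudocount=float(pseudocount),
    )
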