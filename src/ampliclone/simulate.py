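"""Synthetic count-table generation mirroring the study's data structure.

Three ingredients:

* reference samples whose allele fractions arise from sequencing error
  alone, logit-normal across samples;
* patient samples whose true mutant fraction at passage ``p`` follows a
  logit-linear law ``logit(f_p) = logit(af0) + fitness * min(p, plateau)``,
  observed binomially at a negative-binomially drawn depth;
* a two-group cohort layout (plus references) for end-to-end pipeline
  tests.

Randomness is fully determined by the seed.  Depth, error and clone
draws use distinct child streams so that, e.g., adding patients does not
perturb the reference draws.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .enrichment import PassageSeries
from .tables import AmpliconSample, Cohort, CohortTable, Component, Disease

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_patient_series",
    "simulate_cohort_study",
]

# sub-stream identifiers, combined with the seed to derive independent RNGs
_STREAM_DEPTH = 1
_STREAM_ERROR = 2
_STREAM_CLONE = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; see the module docstring."""

    n_reference: int = 55
    reference_logodds_mean: float = float(logit(0.001))
    reference_logodds_sd: float = 0.26
    depth_mean: float = 15000.0
    depth_dispersion: float = 10.0
    af0: float = 0.005
    fitness_logodds_per_passage: float = 0.35
    plateau_passage: int | None = None
    passages: tuple[int, ...] = (0, 4, 9)
    n_patients_per_group: tuple[int, int] = (37, 113)
    prevalence_per_group: tuple[float, float] = (0.405, 0.035)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.af0 < 1.0:
            raise ValueError("af0 must lie in (0, 1)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.reference_logodds_sd < 0:
            raise ValueError("reference_logodds_sd must be non-negative")
        for p in self.prevalence_per_group:
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        if any(n < 0 for n in self.n_patients_per_group) or self.n_reference < 0:
            raise ValueError("sample sizes must be non-negative")
        if any(p < 0 for p in self.passages):
            raise ValueError("passages must be non-negative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream) + extra))


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    depths = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(depths, 1)


def true_fraction(config: SimulationConfig, passage: int) -> float:
    """Expected mutant fraction at a passage under the logit-linear law."""
    eff = passage if config.plateau_passage is None else min(passage, config.plateau_passage)
    return float(expit(logit(config.af0) + config.fitness_logodds_per_passage * eff))


def simulate_reference(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Error-only reference samples (cohort REFERENCE, passage 9)."""
    seed = config.seed if seed is None else seed
    n = config.n_reference
    depth_rng = _rng(seed, _STREAM_DEPTH, 0)
    error_rng = _rng(seed, _STREAM_ERROR, 0)
    depths = _draw_depths(depth_rng, n, config.depth_mean, config.depth_dispersion)
    err_frac = expit(
        error_rng.normal(config.reference_logodds_mean, config.reference_logodds_sd, size=n)
    )
    alts = error_rng.binomial(depths, err_frac)
    samples = tuple(
        AmpliconSample(
            sample_id=f"REF{i + 1:03d}_p9",
            individual_id=f"REF{i + 1:03d}",
            family_id="",
            cohort=Cohort.REFERENCE,
            disease=Disease.OTHER,
            component=Component.NONE,
            passage=9,
            total_reads=int(depths[i]),
            alt_reads=int(alts[i]),
        )
        for i in range(n)
    )
    return CohortTable(samples, provenance=f"simulated reference (seed={seed})")


def simulate_patient_series(
    config: SimulationConfig,
    individual_id: str = "SIM001",
    seed: int | None = None,
    af0: float | None = None,
) -> PassageSeries:
    """One mutant-bearing individual's counts across ``config.passages``.

    Sequencing-error reads are pooled with true-mutant reads into a single
    binomial draw at the combined fraction ``f + (1 - f) * e``.
    """
    seed = config.seed if seed is None else seed
    cfg = config if af0 is None else config.replace(af0=af0)
    tag = zlib.crc32(individual_id.encode("utf-8"))  # stable across processes
    depth_rng = _rng(seed, _STREAM_DEPTH, 1, tag)
    error_rng = _rng(seed, _STREAM_ERROR, 1, tag)
    clone_rng = _rng(seed, _STREAM_CLONE, 1, tag)
    obs = []
    for p in cfg.passages:
        depth = int(_draw_depths(depth_rng, 1, cfg.depth_mean, cfg.depth_dispersion)[0])
        err = float(
            expit(error_rng.normal(cfg.reference_logodds_mean, cfg.reference_logodds_sd))
        )
        f = true_fraction(cfg, p)
        combined = f + (1.0 - f) * err
        alt = int(clone_rng.binomial(depth, combined))
        obs.append((p, depth, alt))
    return PassageSeries(individual_id, tuple(obs))


def _series_to_samples(
    series: PassageSeries, cohort: Cohort, disease: Disease
) -> list[AmpliconSample]:
    return [
        AmpliconSample(
            sample_id=f"{series.individual_id}_p{p}",
            individual_id=series.individual_id,
            family_id="",
            cohort=cohort,
            disease=disease,
            component=Component.NONE,
            passage=p,
            total_reads=t,
            alt_reads=a,
        )
        for p, t, a in series.observations
    ]


def simulate_cohort_study(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Two labelled patient groups plus a reference set, ready for the
    threshold -> call -> associate pipeline.

    Each individual carries the mutant clone with their group's
    prevalence; carriers follow the logit-linear enrichment law, the rest
    produce error-only counts at every passage.
    """
    seed = config.seed if seed is None else seed
    samples: list[AmpliconSample] = list(simulate_reference(config, seed))

    group_meta = (
        (Cohort.WM_FAMILY, Disease.WM, "WM"),
        (Cohort.MM_FAMILY, Disease.MM, "MM"),
    )
    carrier_rng = _rng(seed, _STREAM_CLONE, 2)
    for g, (cohort, disease, label) in enumerate(group_meta):
        n = config.n_patients_per_group[g]
        prevalence = config.prevalence_per_group[g]
        carrier = carrier_rng.random(n) < prevalence
        for i in range(n):
            ind = f"{label}{i + 1:04d}"
            if carrier[i]:
                series = simulate_patient_series(config, ind, seed)
            else:
                # error-only individual: a zero-fitness clone of negligible size
                null_cfg = config.replace(
                    af0=1e-12, fitness_logodds_per_passage=0.0, plateau_passage=None
                )
                series = simulate_patient_series(null_cfg, ind, seed)
            samples.extend(_series_to_samples(series, cohort, disease))
    return CohortTable(tuple(samples), provenance=f"simulated cohort study (seed={seed})")
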