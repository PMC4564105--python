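import math

import pytest

import ampliclone as ac


@pytest.fixture(scope="session")
def table1():
    return ac.load_table1_fixture()


@pytest.fixture(scope="session")
def published_threshold_model():
    """Background model pinned to the published 0.47% detection threshold."""
    return ac.BackgroundModel.from_threshold(0.0047)


@pytest.fixture(scope="session")
def table1_series(table1):
    return ac.series_from_table(table1)


@pytest.fixture()
def tiny_table():
    samples = (
        ac.AmpliconSample(
            sample_id="X_p0",
            individual_id="X",
            family_id="7",
            cohort=ac.Cohort.WM_FAMILY,
            disease=ac.Disease.WM,
            component=ac.Component.NONE,
            passage=0,
            total_reads=10000,
            alt_reads=12,
        ),
        ac.AmpliconSample(
            sample_id="X_p4",
            individual_id="X",
            family_id="7",
            cohort=ac.Cohort.WM_FAMILY,
            disease=ac.Disease.WM,
            component=ac.Component.NONE,
            passage=4,
            total_reads=11000,
            alt_reads=80,
        ),
    )
    return ac.CohortTable(samples, provenance="tiny")


def make_reference_table(counts, depth=20000):
    """Reference-cohort table from a list of alt counts (or (total, alt) pairs)."""
    samples = []
    for i, c in enumerate(counts):
        total, alt = c if isinstance(c, tuple) else (depth, c)
        samples.append(
            ac.AmpliconSample(
                sample_id=f"R{i}_p9",
                individual_id=f"R{i}",
                family_id="",
                cohort=ac.Cohort.REFERENCE,
                disease=ac.Disease.OTHER,
                component=ac.Component.NONE,
                passage=9,
                total_reads=total,
                alt_reads=alt,
            )
        )
    return ac.CohortTable(tuple(samples))


@pytest.fixture()
def reference_table():
    # counts around a ~0.1% error rate at 20k depth
    return make_reference_table([15, 18, 20, 21, 22, 23, 25, 26, 28, 33])


def logit(f: float) -> float:
    return math.log(f / (1.0 - f))


def calibrated_reference_table(target_threshold=0.0046, n=55, depth=20000, seed=2024):
    """Synthetic reference table whose estimated trimmed 6-SD threshold is
    iteratively centred on ``target_threshold`` (Newton steps on the
    location parameter; deterministic for a fixed seed)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    mu = logit(0.001)
    sd = 0.15
    table = None
    for _ in range(12):
        fracs = 1.0 / (1.0 + np.exp(-(mu + sd * z)))
        alts = np.maximum(np.round(fracs * depth).astype(int), 0)
        table = make_reference_table([(depth, int(a)) for a in alts])
        thr = ac.estimate_background(table).threshold_fraction
        mu += logit(target_threshold) - logit(thr)
    return table


@pytest.fixture(scope="session")
def calibrated_reference():
    return calibrated_reference_table()
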