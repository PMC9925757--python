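"""Shared fixtures: synthetic records exercised by several test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ctgdecel.io import TraceRecord
from ctgdecel.synthetic import (
    PlantedContraction,
    PlantedDecel,
    SimulationSpec,
    simulate,
)


@pytest.fixture(scope="session")
def flat_record() -> TraceRecord:
    """20 minutes of constant 140 bpm FHR and zero UCP."""
    n = 20 * 60 * 4
    return TraceRecord("flat", np.full(n, 140.0), np.zeros(n))


@pytest.fixture(scope="session")
def single_dip_spec() -> SimulationSpec:
    """One identifiable deceleration (60 s, 20 bpm) with no contraction."""
    return SimulationSpec(
        baseline_bpm=140.0,
        duration_s=1800.0,
        noise_sd=0.0,
        decels=(
            PlantedDecel(
                type="Early",
                onset_time=900.0,
                descent_time=30.0,
                duration=60.0,
                depth=20.0,
            ),
        ),
        seed=0,
        record_id="single_dip",
    )


@pytest.fixture(scope="session")
def single_dip(single_dip_spec):
    return simulate(single_dip_spec)


@pytest.fixture(scope="session")
def early_pair_spec() -> SimulationSpec:
    """One Early deceleration with its paired contraction."""
    return SimulationSpec(
        baseline_bpm=140.0,
        duration_s=1800.0,
        noise_sd=0.0,
        decels=(
            PlantedDecel(
                type="Early",
                onset_time=900.0,
                descent_time=30.0,
                duration=60.0,
                depth=20.0,
            ),
        ),
        contractions=(
            PlantedContraction(
                start_time=900.0, peak_time=930.0, end_time=960.0, amplitude=60.0
            ),
        ),
        pairing={0: 0},
        seed=0,
        record_id="early_pair",
    )


@pytest.fixture(scope="session")
def early_pair(early_pair_spec):
    return simulate(early_pair_spec)


def make_class_record(seed: int = 5, per_class: int = 5):
    """Record planting `per_class` Early + Late + Variable decelerations."""
    rng = np.random.default_rng(seed)
    decels, contractions, pairing = [], [], {}
    k = 0
    for label in ("Early", "Late", "Variable") * per_class:
        onset = round((300.0 + k * 450.0) * 4) / 4
        depth = float(rng.uniform(16, 35))
        if label == "Variable":
            descent, extra, lag = 20.0, 50.0, float(rng.uniform(-20, 20))
        elif label == "Early":
            descent, extra, lag = 40.0, 40.0, float(rng.uniform(-8, 8))
        else:
            descent, extra, lag = 40.0, 40.0, float(rng.uniform(40, 80))
        decels.append(
            PlantedDecel(
                type=label,
                onset_time=onset,
                descent_time=descent,
                duration=descent + extra,
                depth=depth,
            )
        )
        peak = round((onset + descent - lag) * 4) / 4
        contractions.append(
            PlantedContraction(
                start_time=peak - 35.0,
                peak_time=peak,
                end_time=peak + 35.0,
                amplitude=60.0,
            )
        )
        pairing[k] = k
        k += 1
    return SimulationSpec(
        baseline_bpm=138.0,
        duration_s=300.0 + k * 450.0 + 300.0,
        noise_sd=0.0,
        decels=tuple(decels),
        contractions=tuple(contractions),
        pairing=pairing,
        seed=seed,
        record_id="classes",
    )


@pytest.fixture(scope="session")
def class_record():
    """Simulated record with 5 planted events of each NICHD class."""
    return simulate(make_class_record())


@pytest.fixture(scope="session")
def separable_features():
    """Well-separated 3-class 13-feature data (n = 300, seeded)."""
    rng = np.random.default_rng(1)
    n = 300
    centers = {"Early": 0.0, "Variable": 8.0, "Late": 16.0}
    labels = np.array([["Early", "Variable", "Late"][i % 3] for i in range(n)])
    X = np.vstack([rng.normal(centers[lbl], 1.0, size=13) for lbl in labels])
    return X, labels
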