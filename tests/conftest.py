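import numpy as np
import pytest

from cooplda import (
    AssayGroup,
    DilutionObservation,
    LDAExperiment,
    SimulationConfig,
    simulate_lda,
)


@pytest.fixture
def two_point_group():
    """The saturated textbook case: {(S=1, n=4, Y=2), (S=4, n=4, Y=1)}.

    Link-scale interpolation forces alpha = ln(ln 2) and b = 0.5 exactly.
    """
    return AssayGroup(
        "control",
        "rep1",
        (DilutionObservation(1, 4, 2), DilutionObservation(4, 4, 1)),
    )


@pytest.fixture
def standard_experiment():
    """One control + one treated condition, 2 replicates, 8 dilutions x 12 wells."""
    return simulate_lda(
        SimulationConfig(
            p=0.1,
            b=1.5,
            n_wells=12,
            n_replicates=2,
            treatments=(("control", 1.0), ("4Gy", 0.4)),
            seed=42,
        )
    )


@pytest.fixture
def all_negative_group():
    obs = tuple(DilutionObservation(2.0**k, 12, 12) for k in range(4))
    return AssayGroup("lethal", "rep1", obs)


def make_experiment(rows, reference="control"):
    """rows: list of (treatment, replicate, S, n, y)."""
    groups = {}
    for t, r, S, n, y in rows:
        groups.setdefault((t, r), []).append(DilutionObservation(S, n, y))
    return LDAExperiment(
        groups=[AssayGroup(t, r, tuple(obs)) for (t, r), obs in groups.items()],
        reference_treatment=reference,
    )
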