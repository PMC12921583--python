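import numpy as np
import pandas as pd
import pytest

from levitrace import features
from levitrace.simulate import (
    ParticleSpec,
    TrapParams,
    synthesize_trace,
)


@pytest.fixture(scope="session")
def standard_trace():
    """One 1-s detector trace of a standard 75 nm particle at 3.5 mbar."""
    particle = ParticleSpec()
    trap = TrapParams.from_particle(particle)
    return synthesize_trace(particle, trap, duration=1.0, sample_rate=1e6, seed=42)


def gaussian_table(
    n_per_class: int,
    class_shifts: dict[str, float],
    scale: float = 1.0,
    seed: int = 0,
    n_features: int = 6,
) -> pd.DataFrame:
    """Feature table of Gaussian clouds, one cloud per class.

    ``class_shifts`` maps label -> mean offset applied to every feature.
    ``scale`` is the within-class standard deviation.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for label, shift in class_shifts.items():
        x = rng.normal(loc=shift, scale=scale, size=(n_per_class, n_features))
        df = pd.DataFrame(x, columns=[f"feat_{i}" for i in range(n_features)])
        df[features.LABEL_COLUMN] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def null_table():
    """Three identically distributed classes: no separating signal."""
    return gaussian_table(20, {"a": 0.0, "b": 0.0, "c": 0.0}, seed=1)


@pytest.fixture
def separable_table():
    """Three classes with non-overlapping feature ranges."""
    return gaussian_table(20, {"a": 0.0, "b": 30.0, "c": 60.0}, scale=0.5, seed=2)
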