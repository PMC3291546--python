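import numpy as np
import pytest

from isoniche.samples import IsotopeSample, SampleSet


@pytest.fixture
def worked_example() -> SampleSet:
    """Two-individual muscle/collagen fixture with hand-computed metrics:
    TNW 2.9283, WIC 0.7071, WIC/TNW 0.2415, breadths {2.8284, 0},
    dispersion distances {1.4142, 1.4142}."""
    return SampleSet(
        (
            IsotopeSample("A", "P1", "coastal", "adult", "muscle", -20.0, 8.0),
            IsotopeSample("A", "P1", "coastal", "adult", "collagen", -18.0, 10.0),
            IsotopeSample("B", "P1", "coastal", "adult", "muscle", -24.0, 6.0),
            IsotopeSample("B", "P1", "coastal", "adult", "collagen", -24.0, 6.0),
        )
    )


def random_sample_set(rng: np.random.Generator, n_individuals: int = 20,
                      tissues=("fur", "muscle", "collagen")) -> SampleSet:
    """Random multi-group sample set for property/oracle tests."""
    samples = []
    k = 0
    for habitat in ("coastal", "inland"):
        for age in ("adult", "juvenile"):
            for _ in range(max(2, n_individuals // 4)):
                k += 1
                ind = f"i{k:03d}"
                base = rng.normal([-21.0, 8.5], [2.5, 2.0])
                for tissue in tissues:
                    jitter = rng.normal(0.0, 1.0, 2)
                    samples.append(
                        IsotopeSample(
                            ind, f"P{1 + k % 8}", habitat, age, tissue,
                            float(base[0] + jitter[0]), float(base[1] + jitter[1]),
                        )
                    )
    return SampleSet(tuple(samples))
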