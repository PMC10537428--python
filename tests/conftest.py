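import numpy as np
import pytest

from memchrom import BedSpec, BreakthroughCurve, SyntheticSpec, generate_breakthrough


@pytest.fixture
def bed():
    """Single-layer reference bed (115 um, 3.7 cm^2, 0.015 g adsorptive)."""
    return BedSpec(Z=115.0, A=3.7, epsilon=0.8367, W=0.015, layers=1)


@pytest.fixture
def logistic_curve(bed):
    """Noiseless logistic front with k = 1/min, t05 = 10 min."""
    spec = SyntheticSpec(
        model="yoon_nelson", params={"k_YN": 1.0, "t05": 10.0},
        C0=2.0, F=1.0, bed=bed,
    )
    return generate_breakthrough(spec)


@pytest.fixture
def make_curve(bed):
    """Factory for curves from explicit (t, c_ratio) arrays."""

    def _make(t, c_ratio, C0=2.0, F=1.0, bed_=None, label=""):
        return BreakthroughCurve(
            t=np.asarray(t, float), c_ratio=np.asarray(c_ratio, float),
            C0=C0, F=F, bed=bed_ or bed, label=label,
        )

    return _make
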