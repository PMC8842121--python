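import numpy as np
import pytest

from corepromoter import synth
from corepromoter.motifs import PositionProbabilityMatrix, ppm_to_pwm


@pytest.fixture(scope="session")
def motif_set():
    """Three well-separated synthetic motifs with calibrated thresholds."""
    specs = [
        synth.MotifSpec("INR", 7, 9.0, enriched_region=(-10, 10)),
        synth.MotifSpec("TATA-Box", 8, 10.0, enriched_region=(-45, -15)),
        synth.MotifSpec("DRE", 8, 10.0, enriched_region=(-80, -10)),
    ]
    return synth.gen_motifs(7, specs)


@pytest.fixture(scope="session")
def promoters(motif_set):
    specs = [
        synth.PromoterSpec("promA", "Ar1", (("TATA-Box", -30), ("INR", -2))),
        synth.PromoterSpec("promB", "Ar3.1", (("DRE", -60), ("INR", -2))),
        synth.PromoterSpec("motifless", "motif-less", ()),
    ]
    return {p.id: p for p in synth.gen_promoters(11, specs, motif_set)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def point_mass_ppm():
    m = np.zeros((4, 4))
    for j, b in enumerate("ACGT"):
        m[j, j] = 1.0
    return PositionProbabilityMatrix("pm", m)


@pytest.fixture
def uniform_ppm():
    return PositionProbabilityMatrix("uni", np.full((5, 4), 0.25))


@pytest.fixture
def simple_pwm(point_mass_ppm):
    return ppm_to_pwm(point_mass_ppm, pseudocount=0.01)
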