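import numpy as np
import pytest

from aquanir.spectra import SampleMeta, SpectraSet, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_spectra(seed: int = 0, n: int = 5, m: int = 50) -> SpectraSet:
    """Seeded random spectra set on a 1300+ nm grid with full metadata."""
    rng = np.random.default_rng(seed)
    grid = make_grid(1300.0, 1300.0 + 0.5 * (m - 1), 0.5)
    meta = [
        SampleMeta(
            sample_id=f"S{i}",
            class_label="a" if i % 2 == 0 else "b",
            dna_conc=5.0 * (i + 1),
            uvc_dose=5.0 * i,
            tt_conc=0.1 * i,
            batch=f"B{i % 2}",
        )
        for i in range(n)
    ]
    return SpectraSet(rng.normal(size=(n, m)), grid, meta)


@pytest.fixture
def small_spectra():
    return random_spectra(seed=11)
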