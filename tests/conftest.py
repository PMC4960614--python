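import numpy as np
import pytest

from pgstrend.scoring import GenotypePanel
from pgstrend.simulate import SimConfig, write_fixture


@pytest.fixture(scope="session")
def fixture_config() -> SimConfig:
    return SimConfig(
        n_samples=300,
        n_variants=120,
        beta0=0.5,
        beta1=0.02,
        gamma=0.01,
        noise_sd=0.5,
        wave_noise_sd=0.2,
        weight_noise_sd=0.05,
        spouse_fraction=0.5,
        spouse_score_corr=0.5,
        household_noise_sd=0.3,
        n_waves=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, fixture_config):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(out, fixture_config)


def make_panel(dosages, ref=None, alt=None, ids=None) -> GenotypePanel:
    """Hand-build a small panel; defaults to A/C (non-ambiguous) variants."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(n)],
        variant_ids=ids if ids is not None else [f"v{j}" for j in range(m)],
        ref=np.array(ref if ref is not None else ["A"] * m),
        alt=np.array(alt if alt is not None else ["C"] * m),
        dosages=dosages,
    )
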