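import numpy as np
import pytest

from nfkbinfo import (
    StimulusPanel,
    generate_ensemble,
    nominal_params,
    normalize_ensemble,
    simulate_expression_ensemble,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def panel():
    return StimulusPanel()


@pytest.fixture(scope="session")
def nfkb_cv25(panel):
    """Normalized 5-ligand NFkB ensemble at CV 25%, 300 cells per ligand."""
    return normalize_ensemble(generate_ensemble(panel, 300, 0.25, rng=11))


@pytest.fixture(scope="session")
def nfkb_cv10(panel):
    """Well-separated ensemble: CV 10%, 300 cells per ligand."""
    return normalize_ensemble(generate_ensemble(panel, 300, 0.10, rng=11))


@pytest.fixture(scope="session")
def gene_noiseless_cv25(nfkb_cv25):
    return simulate_expression_ensemble(nfkb_cv25, nominal_params(), noisy=False)


def separated_classes(n_per_class=1000, d=5, m=5, spread=1.0, separation=50.0, seed=0):
    """Gaussian clusters with means far apart relative to their spread."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i in range(m):
        mean = np.zeros(d)
        mean[i % d] = separation * (1 + i // d)
        pts.append(mean + spread * rng.standard_normal((n_per_class, d)))
        labels.extend([f"class{i}"] * n_per_class)
    return np.vstack(pts), np.array(labels)
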