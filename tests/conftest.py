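import numpy as np
import pytest

from digisort import (
    DesignSpec,
    ExpressionMatrix,
    FrequencyMatrix,
    MarkerSet,
    generate_truth,
)


@pytest.fixture
def tiny_expr():
    """3 genes x 2 samples, hand-checkable."""
    return ExpressionMatrix(
        np.array([[6.0, 4.0], [4.0, 6.0], [1.0, 0.0]]),
        ["g1", "g2", "g3"],
        ["s1", "s2"],
    )


@pytest.fixture
def two_type_freqs():
    """Invertible 2x2 frequency matrix used by the worked derivations."""
    return FrequencyMatrix(
        np.array([[0.5, 0.25], [0.5, 0.75]]), ["a", "b"], ["s1", "s2"]
    )


@pytest.fixture
def small_markers():
    return MarkerSet({"liver": ["g1"], "brain": ["g2"]}, ["liver", "brain"])


@pytest.fixture
def ideal_truth():
    """Noise-free three-tissue mixture with perfectly specific markers:
    the exact-recovery regime."""
    spec = DesignSpec(
        design="three_tissue",
        n_genes=300,
        markers_per_type=5,
        marker_fold=np.inf,
        noise_sd=0.0,
        seed=11,
    )
    return generate_truth(spec)


@pytest.fixture
def noisy_truth():
    """Small noisy 4-type mixture for integration-style tests."""
    spec = DesignSpec(
        design="custom",
        n_genes=400,
        k=4,
        markers_per_type=5,
        marker_fold=100.0,
        p=12,
        noise_sd=0.1,
        proportion_schedule=(0.35, 0.30, 0.20, 0.15),
        seed=5,
    )
    return generate_truth(spec)
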