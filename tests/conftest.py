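import numpy as np
import pytest

from enumap.genome import GenomeSpec, Lesion, Marker, Polymorphism


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 10-Mbp single-chromosome genome with one causal and one passenger lesion."""
    markers = [
        Marker(f"m{i}", "chr1", pos, "A", "G")
        for i, pos in enumerate(range(500_000, 10_000_000, 1_000_000))
    ]
    polymorphisms = [
        Polymorphism("chr1", 2_250_000, "C", "T", "rs100"),
        Polymorphism("chr1", 7_250_000, "C", "T", "rs200"),
    ]
    lesions = [
        Lesion("chr1", 5_000_123, "A", "G", "causal", causal=True),
        Lesion("chr1", 1_000_321, "G", "A", "passenger"),
    ]
    return GenomeSpec(
        chromosomes=[("chr1", 10_000_000)],
        recombination_rate=0.5,
        markers=markers,
        polymorphisms=polymorphisms,
        lesions=lesions,
    )
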