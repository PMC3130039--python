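import pytest

from dastrack.das_protocol import GenomicSegment
from dastrack.mock_source import FeatureClass, MockGenomeSpec, generate_annotation_set


@pytest.fixture(scope="session")
def default_spec():
    return MockGenomeSpec(seed=42)


@pytest.fixture(scope="session")
def annotation_set(default_spec):
    return generate_annotation_set(default_spec)


@pytest.fixture(scope="session")
def chr1_features(annotation_set):
    return annotation_set["chr1"][0]


@pytest.fixture(scope="session")
def chr1_segment():
    return GenomicSegment("chr1", 1, 1_000_000)


@pytest.fixture(scope="session")
def dense_layout_spec():
    """10^4 features on one segment, for layout stress tests."""
    return MockGenomeSpec(
        seed=42,
        segments=(("chr1", 1_000_000),),
        feature_classes=(
            FeatureClass("exon", count=10_000, min_len=100, max_len=5_000, stranded=True),
        ),
    )


@pytest.fixture(scope="session")
def dense_layout_features(dense_layout_spec):
    return generate_annotation_set(dense_layout_spec)["chr1"][0]


def small_spec(seed: int, count: int = 150, seg_len: int = 100_000) -> MockGenomeSpec:
    """A compact genome spec for oracle-driven property tests."""
    return MockGenomeSpec(
        seed=seed,
        segments=(("chr1", seg_len),),
        feature_classes=(
            FeatureClass("gene", count=count // 3, min_len=500, max_len=20_000, stranded=True),
            FeatureClass(
                "exon", count=count - count // 3, min_len=50, max_len=1_000,
                stranded=True, scored=True, grouped_fraction=0.5,
            ),
        ),
    )
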