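import pytest

from luxscreen import luxbox, synthetic_data


@pytest.fixture(scope="session")
def library():
    """Default 54-site lux-box library (seeded)."""
    return synthetic_data.generate_motif_library(seed=11)


@pytest.fixture(scope="session")
def model(library):
    return luxbox.build_motif(library)


@pytest.fixture(scope="session")
def community():
    """Default synthetic community under the study conditions (seeded)."""
    return synthetic_data.generate_community(synthetic_data.CommunityConfig(seed=1))


def make_region(sequence, orf_id="r1", strand="+", clipped=False):
    """Wrap a raw sequence as an upstream region at genomic positions 1..L."""
    return luxbox.UpstreamRegion(
        orf_id=orf_id,
        contig_id=orf_id,
        genomic_start=1,
        genomic_end=len(sequence),
        strand=strand,
        sequence=sequence,
        clipped=clipped,
    )
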