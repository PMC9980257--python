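import pytest

from splicecodes.simulate import make_fixture_transcript, curated_truth_fixture


@pytest.fixture(scope="session")
def tx_plus():
    """3 exons x 30 nt, 60-nt introns, plus strand.

    exon1 1001-1030, intron1 1031-1090, exon2 1091-1120,
    intron2 1121-1180, exon3 1181-1210.
    """
    return make_fixture_transcript(3, 30, 60, "+")


@pytest.fixture(scope="session")
def tx_minus():
    """Mirror of tx_plus on the minus strand (same genomic exons)."""
    return make_fixture_transcript(3, 30, 60, "-")


@pytest.fixture(scope="session")
def curated_records():
    return curated_truth_fixture()
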