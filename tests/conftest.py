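import pytest

from markerprof.model import ProteinHit


def make_hit(
    query_id="read1",
    marker="l2",
    query_start=1001,
    query_end=1450,
    subject_start=1,
    subject_end=150,
    subject_len_aa=150,
    evalue=1e-50,
    identity_pct=95.0,
    bitscore=300.0,
    query_len_nt=3000,
    subject_id=None,
    strand="+",
):
    return ProteinHit(
        query_id=query_id,
        subject_id=subject_id or f"{marker}|ref",
        marker=marker,
        query_start=query_start,
        query_end=query_end,
        subject_start=subject_start,
        subject_end=subject_end,
        evalue=evalue,
        identity_pct=identity_pct,
        bitscore=bitscore,
        subject_len_aa=subject_len_aa,
        query_len_nt=query_len_nt,
        strand=strand,
    )


@pytest.fixture
def hit_factory():
    return make_hit
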