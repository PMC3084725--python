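import pytest

from nclvkit.io_formats import GeneFeature, Genome, HitRecord


def make_hit(query, subject, evalue, bitscore=100.0, pid=40.0, length=150):
    return HitRecord(
        query_id=query,
        subject_id=subject,
        pct_identity=pid,
        aln_length=length,
        mismatches=int(length * (100 - pid) / 100),
        gap_opens=1,
        q_start=1,
        q_end=length,
        s_start=1,
        s_end=length,
        evalue=evalue,
        bitscore=bitscore,
    )


def make_genome(intervals, genome_id="g", length=None):
    """Genome from [(gene_id, start, end), ...]; strand '+' throughout."""
    feats = [
        GeneFeature(gid, genome_id, s, e, "+", rank=0) for gid, s, e in intervals
    ]
    total = length if length is not None else max((e for _, _, e in intervals), default=0)
    return Genome.from_features(genome_id, total, feats)


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture
def genome_factory():
    return make_genome
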