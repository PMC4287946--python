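import random

import pytest

from hgvskit.provider import (
    AlignmentSegment,
    Exon,
    FixtureProvider,
    TranscriptRecord,
)
from hgvskit.synth import LocusConfig, demo_locus, generate_locus


def make_record(exons, strand=1, cds=None, tx_ac="TX1", ref_ac="CTG1",
                gene="G1", aln_method="splign", pro_ac=None):
    """Shorthand for building a TranscriptRecord from (start, end, segs)."""
    return TranscriptRecord(
        tx_ac=tx_ac, gene=gene, strand=strand, ref_ac=ref_ac,
        exons=tuple(
            Exon(s, e, tuple(AlignmentSegment(op, ln) for op, ln in segs))
            for s, e, segs in exons),
        cds_start_n=cds[0] if cds else None,
        cds_end_n=cds[1] if cds else None,
        aln_method=aln_method, pro_ac=pro_ac,
    )


@pytest.fixture(scope="session")
def toy1():
    """Plus-strand, 3 gapless exons g.101-200/301-400/501-600, CDS n.21-260."""
    return make_record(
        [(101, 200, [("M", 100)]), (301, 400, [("M", 100)]),
         (501, 600, [("M", 100)])],
        cds=(21, 260))


@pytest.fixture(scope="session")
def demo_fixture():
    return demo_locus(seed=42)


@pytest.fixture(scope="session")
def demo_provider(demo_fixture):
    return FixtureProvider(demo_fixture)


def random_locus_config(rng: random.Random, coding_heavy: bool = False) -> LocusConfig:
    """A varied locus configuration covering the features mapping must
    handle: both strands, CDS start after exon 1, D/I discrepancies and
    alignment-method boundary shifts."""
    exons = rng.choice((2, 3, 4))
    indel_pool = ((), (("D", 3),), (("I", 2),), (("D", 3), ("I", 2)))
    return LocusConfig(
        n_transcripts=1 if coding_heavy else rng.choice((1, 2)),
        exons_per_tx=exons,
        exon_length=(80, 140) if coding_heavy else (60, 120),
        strand=rng.choice(("+", "-", "random")),
        indels=() if coding_heavy else rng.choice(indel_pool),
        cds_start_exon=rng.choice((1, min(2, exons))),
        alt_aln_shift=0 if coding_heavy else rng.choice((0, 0, 2)),
    )


@pytest.fixture()
def locus_for_seed():
    def build(seed: int, **overrides):
        rng = random.Random(seed)
        cfg = random_locus_config(rng, **overrides)
        return generate_locus(cfg, seed=seed)
    return build
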