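"""Context parsing, operon inference and inter-operon region extraction."""

import json

import pytest
from Bio import SeqIO
from hypothesis import given, strategies as st
from io import StringIO

from irfootprint.context import (
    GeneContext,
    GeneFeature,
    extract_interoperon_region,
    infer_operon,
    parse_context,
    reverse_complement,
)
from irfootprint.errors import (
    MalformedRecordError,
    NoFeaturesError,
    RegionTooShortError,
    RegulatorNotFoundError,
)

from conftest import fixture_record

GENBANK_3CDS = """\
LOCUS       TESTCTG                  300 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test contig.
ACCESSION   TESTCTG
FEATURES             Location/Qualifiers
     CDS             complement(11..70)
                     /protein_id="WP_AAA.1"
                     /product="upstream gene"
     gene            101..160
                     /locus_tag="reg_1"
     CDS             101..160
                     /protein_id="WP_REG.1"
                     /product="transcriptional regulator"
     CDS             201..260
                     /protein_id="WP_BBB.1"
                     /product="downstream gene"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      121 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      181 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      241 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


def _genbank_record():
    return SeqIO.read(StringIO(GENBANK_3CDS), "genbank")


class TestParseContext:
    def test_genbank_parse_sets_regulator_index(self):
        ctx = parse_context(_genbank_record(), "WP_REG.1")
        assert len(ctx.features) == 3  # gene+CDS merged
        assert ctx.regulator_index == 1
        # GenBank 1-based inclusive converted to 0-based half-open
        assert (ctx.regulator.start, ctx.regulator.end) == (100, 160)
        assert ctx.regulator.strand == "+"
        assert ctx.features[0].strand == "-"
        assert ctx.regulator.product == "transcriptional regulator"

    def test_gene_cds_merge_keeps_both_ids(self):
        ctx = parse_context(_genbank_record(), "reg_1")
        assert ctx.regulator_index == 1
        assert ctx.regulator.product == "transcriptional regulator"

    def test_regulator_absent_raises(self):
        with pytest.raises(RegulatorNotFoundError):
            parse_context(_genbank_record(), "WP_MISSING.1")

    def test_no_features_raises(self):
        rec = fixture_record([("r", 10, 40, "+")])
        rec["features"] = []
        with pytest.raises(NoFeaturesError):
            parse_context(rec, "r")

    def test_malformed_record_raises(self):
        with pytest.raises(MalformedRecordError):
            parse_context("{not json", "r")
        with pytest.raises(MalformedRecordError):
            parse_context({"contig_id": "c"}, "r")

    def test_fixture_json_roundtrip_matches_genbank(self):
        """Serializing a GenBank-parsed context to JSON and reparsing is lossless."""
        ctx = parse_context(_genbank_record(), "WP_REG.1")
        ctx2 = parse_context(json.dumps(ctx.to_fixture_dict()), "WP_REG.1")
        assert ctx2.contig_id == ctx.contig_id
        assert ctx2.sequence == ctx.sequence
        assert ctx2.regulator_index == ctx.regulator_index
        for a, b in zip(ctx.features, ctx2.features):
            assert (a.start, a.end, a.strand, a.product) == (
                b.start, b.end, b.strand, b.product)


class TestInferOperon:
    def test_same_strand_within_gap_joins(self):
        rec = fixture_record(
            [("R", 500, 1100, "+"), ("B", 1150, 1900, "+"), ("C", 2000, 2600, "-")],
            regulator_id="R",
        )
        ctx = parse_context(rec, "R")
        op = infer_operon(ctx, max_intergenic_gap=100)
        assert op.member_indices == (0, 1)
        assert (op.span_start, op.span_end) == (500, 1900)

    def test_singleton_operon(self):
        ctx = parse_context(fixture_record([("R", 500, 1100, "+")]), "R")
        op = infer_operon(ctx)
        assert op.member_indices == (0,)
        assert op.strand == "+"

    def test_gap_above_cap_breaks_operon(self):
        rec = fixture_record([("R", 500, 1100, "+"), ("B", 1400, 1900, "+")],
                             regulator_id="R")
        op = infer_operon(parse_context(rec, "R"), max_intergenic_gap=100)
        assert op.member_indices == (0,)

    def test_opposite_strand_breaks_operon(self):
        rec = fixture_record([("G", 100, 450, "-"), ("R", 500, 1100, "+")],
                             regulator_id="R")
        op = infer_operon(parse_context(rec, "R"))
        assert op.member_indices == (1,)

    def test_extends_both_directions_on_minus_strand(self):
        rec = fixture_record(
            [("A", 100, 400, "-"), ("R", 450, 900, "-"), ("B", 950, 1300, "-")],
            regulator_id="R",
        )
        op = infer_operon(parse_context(rec, "R"))
        assert op.member_indices == (0, 1, 2)
        assert op.strand == "-"


class TestExtractRegion:
    def test_divergent_upstream_region(self):
        rec = fixture_record([("G", 100, 450, "-"), ("R", 500, 1100, "+")],
                             regulator_id="R")
        ctx = parse_context(rec, "R")
        region = extract_interoperon_region(ctx, infer_operon(ctx))
        assert (region.start, region.end) == (450, 500)
        assert region.upstream_arrangement == "divergent"
        assert region.sequence == ctx.sequence[450:500]

    def test_contig_edge_is_too_short(self):
        ctx = parse_context(fixture_record([("R", 0, 600, "+")], seq_len=700), "R")
        with pytest.raises(RegionTooShortError) as exc:
            extract_interoperon_region(ctx, infer_operon(ctx))
        assert exc.value.arrangement == "contig-edge"
        assert (exc.value.start, exc.value.end) == (0, 0)

    def test_codirectional_neighbor_flagged_not_failed(self):
        rec = fixture_record([("G", 100, 450, "+"), ("R", 500, 1100, "+")],
                             regulator_id="R")
        ctx = parse_context(rec, "R")
        # gap 50 <= cap would merge G into the operon; force the break
        region = extract_interoperon_region(ctx, infer_operon(ctx, 10))
        assert (region.start, region.end) == (450, 500)
        assert region.upstream_arrangement == "co-directional"

    def test_minus_strand_promoter_is_downstream_side(self):
        rec = fixture_record([("R", 100, 700, "-"), ("G", 760, 1200, "+")],
                             regulator_id="R")
        ctx = parse_context(rec, "R")
        region = extract_interoperon_region(ctx, infer_operon(ctx))
        assert (region.start, region.end) == (700, 760)
        assert region.upstream_arrangement == "divergent"

    def test_max_len_clamps_toward_operon_boundary(self):
        rec = fixture_record([("G", 0, 100, "-"), ("R", 2000, 2600, "+")],
                             regulator_id="R")
        ctx = parse_context(rec, "R")
        region = extract_interoperon_region(ctx, infer_operon(ctx), max_len=800)
        assert (region.start, region.end) == (1200, 2000)


# -- properties --------------------------------------------------------------

@st.composite
def random_contexts(draw):
    """Random multi-gene contexts with non-overlapping features."""
    n_genes = draw(st.integers(2, 5))
    gaps = draw(st.lists(st.integers(0, 150), min_size=n_genes, max_size=n_genes))
    lengths = draw(st.lists(st.integers(60, 300), min_size=n_genes, max_size=n_genes))
    strands = draw(st.lists(st.sampled_from("+-"), min_size=n_genes, max_size=n_genes))
    feats, pos = [], 30
    for i in range(n_genes):
        pos += gaps[i]
        feats.append((f"g{i}", pos, pos + lengths[i], strands[i]))
        pos += lengths[i]
    seq = draw(st.text("ACGT", min_size=pos + 30, max_size=pos + 30))
    reg = draw(st.integers(0, n_genes - 1))
    return fixture_record(feats, sequence=seq, regulator_id=f"g{reg}")


@given(random_contexts())
def test_region_slice_roundtrip(rec):
    """Region coordinates sliced from the contig reproduce region.sequence."""
    ctx = parse_context(rec, rec["regulator_id"])
    op = infer_operon(ctx)
    try:
        region = extract_interoperon_region(ctx, op, min_len=1)
    except RegionTooShortError:
        return
    assert region.sequence == ctx.sequence[region.start:region.end]
    assert all(
        ctx.features[i].strand == op.strand for i in op.member_indices)


@given(random_contexts())
def test_operon_maximality(rec):
    """No same-strand neighbor within the gap cap is left out of the span."""
    ctx = parse_context(rec, rec["regulator_id"])
    op = infer_operon(ctx, 100)
    lo, hi = op.member_indices[0], op.member_indices[-1]
    if lo > 0:
        prev = ctx.features[lo - 1]
        assert (prev.strand != op.strand
                or ctx.features[lo].start - prev.end > 100)
    if hi < len(ctx.features) - 1:
        nxt = ctx.features[hi + 1]
        assert (nxt.strand != op.strand
                or nxt.start - ctx.features[hi].end > 100)


@given(random_contexts())
def test_strand_symmetry(rec):
    """Reverse-complementing the context mirrors the extracted region."""
    ctx = parse_context(rec, rec["regulator_id"])
    n = len(rec["sequence"])
    flipped = {
        "contig_id": rec["contig_id"],
        "sequence": reverse_complement(rec["sequence"]),
        "features": [
            {"id": f["id"], "start": n - f["end"], "end": n - f["start"],
             "strand": "+" if f["strand"] == "-" else "-", "product": ""}
            for f in rec["features"]
        ],
        "regulator_id": rec["regulator_id"],
    }
    ctx2 = parse_context(flipped, rec["regulator_id"])
    try:
        r1 = extract_interoperon_region(ctx, infer_operon(ctx), min_len=1)
    except RegionTooShortError:
        with pytest.raises(RegionTooShortError):
            extract_interoperon_region(ctx2, infer_operon(ctx2), min_len=1)
        return
    r2 = extract_interoperon_region(ctx2, infer_operon(ctx2), min_len=1)
    assert (r2.start, r2.end) == (n - r1.end, n - r1.start)
    assert r2.sequence == reverse_complement(r1.sequence)
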