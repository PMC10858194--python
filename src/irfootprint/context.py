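"""Genetic-context parsing, operon inference and inter-operon region extraction.

A bacterial regulator is usually autoregulatory: its operator sits in the
promoter it shares with the divergently transcribed neighboring operon.  This
module turns an annotated record (GenBank flat file via Biopython, or an
equivalent JSON fixture) into a :class:`GeneContext`, infers which adjacent
same-strand genes are co-transcribed with the regulator, and extracts the
intergenic sequence on the promoter side of that operon.

Coordinates are 0-based, half-open, on the contig forward strand throughout;
GenBank's 1-based inclusive convention is converted at the parser boundary
(Biopython already exposes 0-based half-open locations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Union

from Bio.SeqRecord import SeqRecord

from .errors import (
    MalformedRecordError,
    NoFeaturesError,
    RegionTooShortError,
    RegulatorNotFoundError,
)

DEFAULT_MAX_INTERGENIC_GAP = 100
DEFAULT_MIN_REGION_LEN = 20
DEFAULT_MAX_REGION_LEN = 800

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One oriented gene/CDS on the contig.

    ``start``/``end`` are 0-based half-open; ``strand`` is '+' or '-'.
    """

    feature_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise MalformedRecordError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )


@dataclass(frozen=True)
class GeneContext:
    """An annotated genomic segment centered on a focal regulator."""

    contig_id: str
    sequence: str
    features: tuple[GeneFeature, ...]
    regulator_index: int

    def __post_init__(self):
        if not self.features:
            raise NoFeaturesError(f"contig {self.contig_id!r} has no features")
        if not (0 <= self.regulator_index < len(self.features)):
            raise MalformedRecordError("regulator_index out of range")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise MalformedRecordError(
                    f"feature {f.feature_id!r} extends past the contig end"
                )
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise MalformedRecordError("features must be sorted by start")

    @property
    def regulator(self) -> GeneFeature:
        return self.features[self.regulator_index]

    def to_fixture_dict(self) -> dict:
        """Serialize to the JSON fixture schema (round-trips via parse_context)."""
        return {
            "contig_id": self.contig_id,
            "sequence": self.sequence,
            "features": [
                {
                    "id": f.feature_id,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "product": f.product,
                }
                for f in self.features
            ],
            "regulator_id": self.regulator.feature_id,
        }


@dataclass(frozen=True)
class OperonSpan:
    """A maximal run of same-strand features co-transcribed with the regulator."""

    member_indices: tuple[int, ...]
    strand: str
    span_start: int
    span_end: int


@dataclass(frozen=True)
class InterOperonRegion:
    """The promoter-side intergenic sequence, reported on the forward strand.

    ``upstream_arrangement`` records whether the neighboring operon is
    transcribed divergently (the canonical shared-promoter geometry),
    co-directionally (still extracted, but flagged as lower confidence), or
    whether the operon abuts the contig edge.
    """

    contig_id: str
    sequence: str
    start: int
    end: int
    upstream_arrangement: str  # {"divergent", "co-directional", "contig-edge"}


# ---------------------------------------------------------------------------
# parsing


def _features_from_seqrecord(record: SeqRecord) -> list[dict]:
    feats = []
    for feat in record.features:
        if feat.type not in ("gene", "CDS"):
            continue
        if feat.location is None or feat.location.strand not in (1, -1):
            raise MalformedRecordError(
                f"feature of type {feat.type} lacks an oriented location"
            )
        quals = feat.qualifiers
        ids = (
            quals.get("protein_id", [])
            + quals.get("locus_tag", [])
            + quals.get("gene", [])
        )
        feats.append(
            {
                "ids": [str(i) for i in ids],
                "type": feat.type,
                "start": int(feat.location.start),
                "end": int(feat.location.end),
                "strand": "+" if feat.location.strand == 1 else "-",
                "product": str(quals.get("product", [""])[0]),
            }
        )
    return feats


def _merge_identical_intervals(raw: list[dict]) -> list[dict]:
    """Merge gene+CDS pairs sharing an interval; CDS annotation preferred."""
    by_interval: dict[tuple, dict] = {}
    order: list[tuple] = []
    for f in raw:
        key = (f["start"], f["end"], f["strand"])
        if key not in by_interval:
            by_interval[key] = f
            order.append(key)
        else:
            kept = by_interval[key]
            # CDS wins for product/id richness; merge id lists either way
            if f.get("type") == "CDS" and kept.get("type") != "CDS":
                f["ids"] = f["ids"] + [i for i in kept["ids"] if i not in f["ids"]]
                by_interval[key] = f
            else:
                kept["ids"] = kept["ids"] + [
                    i for i in f["ids"] if i not in kept["ids"]
                ]
    return [by_interval[k] for k in order]


def parse_context(
    record: Union[SeqRecord, dict, str], regulator_id: str
) -> GeneContext:
    """Build a :class:`GeneContext` from an annotated record.

    ``record`` may be a Biopython :class:`SeqRecord` (parsed from GenBank), a
    fixture dict following the JSON schema ``{contig_id, sequence,
    features:[{id,start,end,strand,product}], regulator_id}``, or a JSON
    string of that schema.  ``regulator_id`` must match exactly one feature
    (protein_id / locus_tag / gene qualifier in GenBank, ``id`` in fixtures).
    """
    if isinstance(record, str):
        try:
            record = json.loads(record)
        except json.JSONDecodeError as exc:
            raise MalformedRecordError(f"unparseable JSON record: {exc}") from exc

    if isinstance(record, SeqRecord):
        contig_id = record.id
        sequence = str(record.seq).upper()
        raw = _features_from_seqrecord(record)
    elif isinstance(record, dict):
        try:
            contig_id = record["contig_id"]
            sequence = str(record["sequence"]).upper()
            raw = [
                {
                    "ids": [f["id"]],
                    "type": "CDS",
                    "start": int(f["start"]),
                    "end": int(f["end"]),
                    "strand": f["strand"],
                    "product": f.get("product", ""),
                }
                for f in record["features"]
            ]
        except (KeyError, TypeError) as exc:
            raise MalformedRecordError(f"fixture record missing field: {exc}") from exc
    else:
        raise MalformedRecordError(
            f"unsupported record type {type(record).__name__}"
        )

    if not raw:
        raise NoFeaturesError(f"record {contig_id!r} contains no gene/CDS features")

    merged = _merge_identical_intervals(raw)
    merged.sort(key=lambda f: (f["start"], f["end"]))

    matches = [i for i, f in enumerate(merged) if regulator_id in f["ids"]]
    if len(matches) != 1:
        raise RegulatorNotFoundError(
            f"regulator {regulator_id!r} matched {len(matches)} features "
            f"in record {contig_id!r} (need exactly 1)"
        )

    features = tuple(
        GeneFeature(
            feature_id=f["ids"][0],
            start=f["start"],
            end=f["end"],
            strand=f["strand"],
            product=f["product"],
        )
        for f in merged
    )
    return GeneContext(
        contig_id=contig_id,
        sequence=sequence,
        features=features,
        regulator_index=matches[0],
    )


# ---------------------------------------------------------------------------
# operon inference


def infer_operon(
    ctx: GeneContext, max_intergenic_gap: int = DEFAULT_MAX_INTERGENIC_GAP
) -> OperonSpan:
    """Maximal same-strand run around the regulator with bounded gaps.

    Adjacent genes on the regulator's strand are assumed co-transcribed as
    long as the intergenic gap between consecutive members does not exceed
    ``max_intergenic_gap``.  A single-gene operon is valid.
    """
    feats = ctx.features
    r = ctx.regulator_index
    strand = feats[r].strand

    lo = r
    while lo > 0:
        prev, cur = feats[lo - 1], feats[lo]
        if prev.strand != strand or cur.start - prev.end > max_intergenic_gap:
            break
        lo -= 1
    hi = r
    while hi < len(feats) - 1:
        cur, nxt = feats[hi], feats[hi + 1]
        if nxt.strand != strand or nxt.start - cur.end > max_intergenic_gap:
            break
        hi += 1

    members = tuple(range(lo, hi + 1))
    return OperonSpan(
        member_indices=members,
        strand=strand,
        span_start=min(feats[i].start for i in members),
        span_end=max(feats[i].end for i in members),
    )


def extract_interoperon_region(
    ctx: GeneContext,
    operon: OperonSpan,
    min_len: int = DEFAULT_MIN_REGION_LEN,
    max_len: int = DEFAULT_MAX_REGION_LEN,
) -> InterOperonRegion:
    """Extract the intergenic sequence on the operon's promoter side.

    For a '+'-strand operon the promoter side is upstream of the first operon
    gene (toward smaller coordinates); for a '-' operon it is downstream of
    the last gene.  The region runs from the operon's 5' boundary to the
    nearest neighboring feature boundary, clamped to ``max_len`` measured
    back from the operon boundary.  The sequence is always reported on the
    contig forward strand.

    Raises :class:`RegionTooShortError` when the region is shorter than
    ``min_len`` — the "operator not in extracted region" failure mode.
    """
    feats = ctx.features
    first, last = operon.member_indices[0], operon.member_indices[-1]

    if operon.strand == "+":
        boundary = operon.span_start
        if first == 0:
            start, end, arrangement = boundary, boundary, "contig-edge"
        else:
            neighbor = feats[first - 1]
            start = min(neighbor.end, boundary)
            end = boundary
            arrangement = "divergent" if neighbor.strand == "-" else "co-directional"
        start = max(start, end - max_len)
    else:
        boundary = operon.span_end
        if last == len(feats) - 1:
            start, end, arrangement = boundary, boundary, "contig-edge"
        else:
            neighbor = feats[last + 1]
            start = boundary
            end = max(neighbor.start, boundary)
            arrangement = "divergent" if neighbor.strand == "+" else "co-directional"
        end = min(end, start + max_len)

    if end - start < min_len:
        raise RegionTooShortError(
            f"inter-operon region [{start}, {end}) on {ctx.contig_id!r} is "
            f"{end - start} bp (< {min_len} bp); arrangement: {arrangement}",
            arrangement=arrangement,
            start=start,
            end=end,
        )

    return InterOperonRegion(
        contig_id=ctx.contig_id,
        sequence=ctx.sequence[start:end],
        start=start,
        end=end,
        upstream_arrangement=arrangement,
    )
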