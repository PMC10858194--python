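"""Phylogenetic footprinting: locate the seed operator across homolog
contexts, build the consensus motif and score its conservation.

The core assumption: a functional operator is under purifying selection and
therefore conserved across homologous inter-operon regions, while
surrounding promoter sequence drifts.  The seed operator (best inverted
repeat of the query's own region) is located in each homolog region by
ungapped sliding-window alignment on both strands; accepted instances are
columns-aligned by construction, so the consensus motif is a simple
per-column count matrix.  Conservation is summarized as

    c = (sum over positions of b^2) / x

where ``b`` is the relative frequency of the dominant base at a position and
``x`` the motif length; c = 1 for perfect conservation, 1/16 for uniform
noise (squaring rewards strongly dominated columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .context import (
    DEFAULT_MAX_INTERGENIC_GAP,
    DEFAULT_MAX_REGION_LEN,
    DEFAULT_MIN_REGION_LEN,
    GeneContext,
    InterOperonRegion,
    extract_interoperon_region,
    infer_operon,
    parse_context,
    reverse_complement,
)
from .errors import (
    EmptyMotifError,
    NoRepeatFoundError,
    RegionTooShortError,
    RegulatorNotFoundError,
    MalformedRecordError,
    TooFewInstancesError,
    ZeroHitsError,
)
from .homology import (
    AbsenceMarker,
    Backend,
    HomologFilters,
    collect_homologs,
    fetch_context,
)
from .irscan import RepeatScoreParams, SeedOperator, find_best_inverted_repeat

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# diagnostic codes, mirroring the observed failure-mode taxonomy
DIAG_OK = "ok"
DIAG_NOT_IN_REGION = "operator-not-in-region"
DIAG_SEARCH_MISS = "search-miss"
DIAG_TOO_FEW = "too-few-homologs"


@dataclass(frozen=True)
class LocateParams:
    """Ungapped seed-vs-region alignment parameters."""

    match_weight: int = 2
    mismatch_weight: int = -2
    accept_frac: float = 0.6  # of the seed's self-alignment score


@dataclass(frozen=True)
class OperatorInstance:
    """One putative operator occurrence, oriented to match the seed."""

    homolog_accession: str
    sequence: str
    alignment_score: float
    offset: int  # window start on the forward strand of its region
    strand: str = "+"


@dataclass
class ConsensusMotif:
    """Per-position base statistics over aligned operator instances."""

    length: int
    counts: np.ndarray  # 4 x length, rows in A,C,G,T order
    frequencies: np.ndarray  # 4 x length, columns sum to 1
    consensus: str
    dominant_freqs: np.ndarray  # length,
    n_instances: int

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "alphabet": _BASES,
            "counts": self.counts.tolist(),
            "frequencies": self.frequencies.tolist(),
            "consensus": self.consensus,
            "dominant_freqs": self.dominant_freqs.tolist(),
            "n_instances": self.n_instances,
        }


@dataclass
class PredictionReport:
    """End-to-end prediction output with quality metrics and diagnostics."""

    regulator_accession: str
    diagnostic: str
    seed: Optional[SeedOperator] = None
    motif: Optional[ConsensusMotif] = None
    conservation_score: Optional[float] = None
    inverted_repeat_score: Optional[int] = None
    n_homologs_used: int = 0
    instances: tuple[OperatorInstance, ...] = ()
    absences: tuple[AbsenceMarker, ...] = ()
    region_arrangement: Optional[str] = None
    config: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def predicted_operator(self) -> Optional[str]:
        return self.motif.consensus if self.motif is not None else None

    def to_dict(self) -> dict:
        seed = None
        if self.seed is not None:
            rep = self.seed.repeat
            seed = {
                "contig_id": self.seed.contig_id,
                "region_start": self.seed.region_start,
                "region_end": self.seed.region_end,
                "sequence": rep.sequence,
                "left_arm": [rep.left_start, rep.left_end],
                "right_arm": [rep.right_start, rep.right_end],
                "spacer": rep.spacer,
                "matches": rep.matches,
                "mismatches": rep.mismatches,
                "gap_adjustment": rep.gap_adjustment,
                "score": rep.score,
            }
        return {
            "regulator_accession": self.regulator_accession,
            "diagnostic": self.diagnostic,
            "seed": seed,
            "motif": self.motif.to_dict() if self.motif else None,
            "conservation_score": self.conservation_score,
            "inverted_repeat_score": self.inverted_repeat_score,
            "n_homologs_used": self.n_homologs_used,
            "instances": [asdict(i) for i in self.instances],
            "absences": [asdict(a) for a in self.absences],
            "region_arrangement": self.region_arrangement,
            "config": self.config,
            "version": self.version,
        }


@dataclass(frozen=True)
class PredictConfig:
    """Effective configuration of the whole pipeline (echoed into reports)."""

    max_intergenic_gap: int = DEFAULT_MAX_INTERGENIC_GAP
    min_region_len: int = DEFAULT_MIN_REGION_LEN
    max_region_len: int = DEFAULT_MAX_REGION_LEN
    repeat_params: RepeatScoreParams = RepeatScoreParams()
    homolog_filters: HomologFilters = HomologFilters()
    locate_params: LocateParams = LocateParams()
    min_instances: int = 4
    include_seed_instance: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["repeat_params"]["gap_table"] = [
            list(b) for b in self.repeat_params.gap_table
        ]
        return d


# ---------------------------------------------------------------------------
# instance location


def _window_scores(seed_arr, seed_len, region: str, lp: LocateParams):
    reg = np.frombuffer(region.upper().encode("ascii"), dtype=np.uint8)
    n_off = len(reg) - seed_len + 1
    if n_off <= 0:
        return None
    matches = np.zeros(n_off, dtype=np.int32)
    for k in range(seed_len):
        matches += (reg[k : k + n_off] == seed_arr[k]).astype(np.int32)
    return lp.match_weight * matches + lp.mismatch_weight * (seed_len - matches)


def locate_instance(
    seed_seq: str,
    region_seq: str,
    params: LocateParams = LocateParams(),
    accession: str = "",
) -> Optional[OperatorInstance]:
    """Best ungapped occurrence of the seed in a region, on either strand.

    The window scan is the exact maximizer of the ungapped local score at
    seed length.  The hit is accepted iff its score reaches
    ``accept_frac`` x the seed's self-alignment score; the instance sequence
    is reported in the seed's orientation.  Returns None for a miss
    (absence is a value, not an error).
    """
    seed = seed_seq.upper()
    L = len(seed)
    self_score = params.match_weight * L
    seed_arr = np.frombuffer(seed.encode("ascii"), dtype=np.uint8)

    best = None  # (score, strand_rank, offset, oriented_seq)
    fwd = _window_scores(seed_arr, L, region_seq, params)
    if fwd is not None:
        i = int(np.argmax(fwd))
        best = (float(fwd[i]), 0, i, region_seq[i : i + L].upper())
    rc_region = reverse_complement(region_seq)
    rev = _window_scores(seed_arr, L, rc_region, params)
    if rev is not None:
        i = int(np.argmax(rev))
        fwd_offset = len(region_seq) - L - i
        cand = (float(rev[i]), 1, fwd_offset, rc_region[i : i + L].upper())
        # prefer forward strand, then leftmost, on score ties
        if best is None or cand[0] > best[0]:
            best = cand

    if best is None or best[0] < params.accept_frac * self_score:
        return None
    score, strand_rank, offset, seq = best
    return OperatorInstance(
        homolog_accession=accession,
        sequence=seq,
        alignment_score=score,
        offset=offset,
        strand="+" if strand_rank == 0 else "-",
    )


# ---------------------------------------------------------------------------
# consensus + conservation


def build_consensus(
    instances: Sequence[OperatorInstance], min_instances: int = 4
) -> ConsensusMotif:
    """Per-column base counts over equal-length instances.

    Dominant-base ties break deterministically A < C < G < T.  Ambiguous
    (N) positions are excluded from the counts of their column.
    """
    if len(instances) < min_instances:
        raise TooFewInstancesError(
            f"{len(instances)} instances < min_instances ({min_instances})"
        )
    lengths = {len(i.sequence) for i in instances}
    if len(lengths) != 1:
        raise ValueError(f"instances have unequal lengths: {sorted(lengths)}")
    x = lengths.pop()
    if x == 0:
        raise EmptyMotifError("zero-length instances")

    counts = np.zeros((4, x), dtype=np.int64)
    for inst in instances:
        for j, base in enumerate(inst.sequence.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[idx, j] += 1

    n = len(instances)
    frequencies = counts / n
    dominant_idx = np.argmax(counts, axis=0)  # first max -> A<C<G<T tie-break
    consensus = "".join(_BASES[i] for i in dominant_idx)
    dominant_freqs = frequencies[dominant_idx, np.arange(x)]
    return ConsensusMotif(
        length=x,
        counts=counts,
        frequencies=frequencies,
        consensus=consensus,
        dominant_freqs=dominant_freqs,
        n_instances=n,
    )


def conservation_score(motif: ConsensusMotif) -> float:
    """Mean squared dominant-base frequency, c = (sum_o b_o^2) / x in (0, 1]."""
    if motif.length < 1:
        raise EmptyMotifError("conservation score needs at least one position")
    return float(np.sum(motif.dominant_freqs**2) / motif.length)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def extract_region_for_context(
    ctx: GeneContext, config: PredictConfig
) -> InterOperonRegion:
    operon = infer_operon(ctx, config.max_intergenic_gap)
    return extract_interoperon_region(
        ctx, operon, config.min_region_len, config.max_region_len
    )


def predict(
    regulator_accession: str,
    backend: Backend,
    config: PredictConfig = PredictConfig(),
) -> PredictionReport:
    """Full pipeline: context -> operon -> region -> seed -> homolog
    instances -> consensus -> scores.

    Data-shaped failures never crash; they end the run early with the
    matching diagnostic code on a partial report.
    """

    def fail(code: str, **kw) -> PredictionReport:
        return PredictionReport(
            regulator_accession=regulator_accession,
            diagnostic=code,
            config=config.to_dict(),
            **kw,
        )

    # 1. query context and inter-operon region
    record = backend.get_context_record(regulator_accession)
    if record is None:
        return fail(DIAG_NOT_IN_REGION)
    try:
        ctx = parse_context(record, regulator_accession)
        region = extract_region_for_context(ctx, config)
    except RegionTooShortError as exc:
        return fail(DIAG_NOT_IN_REGION, region_arrangement=exc.arrangement)
    except (RegulatorNotFoundError, MalformedRecordError):
        return fail(DIAG_NOT_IN_REGION)

    # 2. seed operator
    try:
        seed = find_best_inverted_repeat(region, config.repeat_params)
    except NoRepeatFoundError:
        return fail(DIAG_SEARCH_MISS, region_arrangement=region.upstream_arrangement)

    # 3. homologs and their regions
    protein = backend.get_protein(regulator_accession)
    try:
        hits = collect_homologs(protein, backend, config.homolog_filters)
    except ZeroHitsError:
        return fail(
            DIAG_TOO_FEW,
            seed=seed,
            inverted_repeat_score=seed.repeat.score,
            region_arrangement=region.upstream_arrangement,
        )

    instances: list[OperatorInstance] = []
    absences: list[AbsenceMarker] = []
    if config.include_seed_instance:
        instances.append(
            OperatorInstance(
                homolog_accession=regulator_accession,
                sequence=seed.repeat.sequence,
                alignment_score=float(
                    config.locate_params.match_weight * seed.repeat.length
                ),
                offset=seed.repeat.left_start,
                strand="+",
            )
        )
    n_homologs_used = 0
    for hit in hits:
        ctx_or_marker = fetch_context(hit, backend)
        if isinstance(ctx_or_marker, AbsenceMarker):
            absences.append(ctx_or_marker)
            continue
        try:
            hregion = extract_region_for_context(ctx_or_marker, config)
        except RegionTooShortError as exc:
            absences.append(AbsenceMarker("region-too-short", hit.accession))
            continue
        inst = locate_instance(
            seed.repeat.sequence,
            hregion.sequence,
            config.locate_params,
            accession=hit.accession,
        )
        if inst is None:
            absences.append(AbsenceMarker("instance-not-found", hit.accession))
            continue
        instances.append(inst)
        n_homologs_used += 1

    # 4. consensus + scores
    try:
        motif = build_consensus(instances, config.min_instances)
    except TooFewInstancesError:
        return fail(
            DIAG_TOO_FEW,
            seed=seed,
            inverted_repeat_score=seed.repeat.score,
            n_homologs_used=n_homologs_used,
            instances=tuple(instances),
            absences=tuple(absences),
            region_arrangement=region.upstream_arrangement,
        )

    return PredictionReport(
        regulator_accession=regulator_accession,
        diagnostic=DIAG_OK,
        seed=seed,
        motif=motif,
        conservation_score=conservation_score(motif),
        inverted_repeat_score=seed.repeat.score,
        n_homologs_used=n_homologs_used,
        instances=tuple(instances),
        absences=tuple(absences),
        region_arrangement=region.upstream_arrangement,
        config=config.to_dict(),
    )
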