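"""Synthetic regulon generator with known ground truth.

Emulates the statistical structure the footprinting algorithm assumes: a
regulator in a divergent-promoter arrangement whose inter-operon region
carries a perfect inverted-repeat operator, and N homolog contexts in which
the operator is conserved (low per-base substitution rate) while the
surrounding promoter sequence drifts (high rate).  Homolog regulator
proteins are mutated copies of an ancestral protein so the homology-filter
path is exercised realistically.

Substitutions only (no indels), so operator offsets are exact across the
archive.  All randomness flows from one integer seed; the emitted archive
is byte-identical for identical parameters.

The generated archive follows the homology fixture schema and is directly
loadable by :class:`irfootprint.homology.FixtureBackend`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .context import reverse_complement
from .errors import InfeasibleParamsError
from .footprint import PredictionReport

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

QUERY_ACCESSION = "SIM_QUERY.1"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated regulon.

    Defaults: 20 homologs; a 7+4+7 bp perfect inverted-repeat operator
    planted in a 150 bp inter-operon region; operator substitution rate
    0.05 per base across homologs versus 0.35 for background promoter
    sequence; 200-aa regulator proteins drifting at 0.2 per residue
    (~80% identity, inside the default homology identity window).
    """

    seed: int = 0
    n_homologs: int = 20
    operator_arm: int = 7
    operator_spacer: int = 4
    operator_mut_rate: float = 0.05
    background_mut_rate: float = 0.35
    region_len: int = 150
    protein_len: int = 200
    protein_mut_rate: float = 0.2
    gene_len_codons: int = 200  # regulator/neighbor gene length in codons
    intergenic_margin: int = 50

    def __post_init__(self):
        for r in (self.operator_mut_rate, self.background_mut_rate,
                  self.protein_mut_rate):
            if not (0.0 <= r <= 1.0):
                raise InfeasibleParamsError("mutation rates must lie in [0, 1]")
        if self.n_homologs < 1:
            raise InfeasibleParamsError("n_homologs must be >= 1")
        if self.operator_length > self.region_len:
            raise InfeasibleParamsError(
                f"operator ({self.operator_length} bp) longer than region "
                f"({self.region_len} bp)"
            )

    @property
    def operator_length(self) -> int:
        return 2 * self.operator_arm + self.operator_spacer


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for parameter-recovery scoring."""

    planted_operator: str
    region_offset: int  # operator start within the inter-operon region
    region_start: int  # region start on the contig
    per_homolog_offsets: dict
    ancestral_protein: str
    query_accession: str = QUERY_ACCESSION

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveryResult:
    identity: float  # matched planted positions / planted length
    offset_error: int  # |registration shift| of the best alignment
    strand: str  # orientation of the best registration


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate_dna(
    rng: np.random.Generator, seq: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Substitute each base with probability rates[i], to a uniform other base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rates
    base_idx = np.empty(len(seq), dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_idx[seq == b] = i
    shifts = rng.integers(1, 4, size=len(seq))
    out[hit] = _BASES[(base_idx[hit] + shifts[hit]) % 4]
    return out


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    chars = list(protein)
    for i, aa in enumerate(chars):
        if rng.random() < rate:
            choices = _AA.replace(aa, "")
            chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _context_record(
    contig_id: str,
    sequence: str,
    regulator_id: str,
    layout: dict,
) -> dict:
    return {
        "contig_id": contig_id,
        "sequence": sequence,
        "features": [
            {
                "id": f"{contig_id}_gdiv",
                "start": layout["g_start"],
                "end": layout["g_end"],
                "strand": "-",
                "product": "divergent neighbor protein",
            },
            {
                "id": regulator_id,
                "start": layout["r_start"],
                "end": layout["r_end"],
                "strand": "+",
                "product": "transcriptional regulator",
            },
            {
                "id": f"{contig_id}_gdown",
                "start": layout["b_start"],
                "end": layout["b_end"],
                "strand": "+",
                "product": "co-transcribed downstream protein",
            },
        ],
        "regulator_id": regulator_id,
    }


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def simulate_regulon(
    params: SimParams, out_dir: Union[str, Path]
) -> GroundTruth:
    """Write a fixture archive under ``out_dir``; return the ground truth.

    The contig layout is a divergent gene pair flanking the inter-operon
    region, plus one co-directional gene downstream of the regulator (close
    enough to be inferred into the same operon).  The query context is the
    unmutated ancestor; each homolog context is an independently mutated
    copy.
    """
    rng = np.random.default_rng(params.seed)
    out = Path(out_dir)
    (out / "contexts").mkdir(parents=True, exist_ok=True)

    gene_len = 3 * params.gene_len_codons
    m = params.intergenic_margin
    g_start, g_end = m, m + gene_len
    region_start, region_end = g_end, g_end + params.region_len
    r_start, r_end = region_end, region_end + gene_len
    b_start, b_end = r_end + 50, r_end + 50 + gene_len
    contig_len = b_end + m
    layout = {
        "g_start": g_start, "g_end": g_end,
        "r_start": r_start, "r_end": r_end,
        "b_start": b_start, "b_end": b_end,
    }

    # ancestral contig with a perfect inverted repeat planted in the region
    contig = _random_dna(rng, contig_len)
    left = _random_dna(rng, params.operator_arm)
    spacer = _random_dna(rng, params.operator_spacer)
    left_s = left.tobytes().decode()
    operator = left_s + spacer.tobytes().decode() + reverse_complement(left_s)
    region_offset = int(
        rng.integers(0, params.region_len - params.operator_length + 1)
    )
    op_start = region_start + region_offset
    contig[op_start : op_start + params.operator_length] = np.frombuffer(
        operator.encode(), dtype=np.uint8
    )

    ancestral_protein = "".join(
        _AA[i] for i in rng.integers(0, len(_AA), size=params.protein_len)
    )

    _write_json(
        out / "query.json",
        {"accession": QUERY_ACCESSION, "protein_sequence": ancestral_protein},
    )
    _write_json(
        out / "context.json",
        _context_record(
            "SIM_CONTIG_Q", contig.tobytes().decode(), QUERY_ACCESSION, layout
        ),
    )

    # per-position substitution rates: conserved operator, drifting elsewhere
    rates = np.full(contig_len, params.background_mut_rate)
    rates[op_start : op_start + params.operator_length] = params.operator_mut_rate

    hits = []
    per_homolog_offsets = {}
    for i in range(params.n_homologs):
        acc = f"SIM_HOM_{i:03d}.1"
        hcontig = _mutate_dna(rng, contig, rates)
        hprotein = _mutate_protein(rng, ancestral_protein, params.protein_mut_rate)
        identity = 100.0 * sum(
            a == b for a, b in zip(hprotein, ancestral_protein)
        ) / params.protein_len
        hits.append(
            {
                "accession": acc,
                "protein_sequence": hprotein,
                "percent_identity": round(identity, 2),
                "coverage": 100.0,
            }
        )
        per_homolog_offsets[acc] = region_offset
        _write_json(
            out / "contexts" / f"{acc}.json",
            _context_record(f"SIM_CONTIG_{i:03d}", hcontig.tobytes().decode(),
                            acc, layout),
        )

    _write_json(out / "hits.json", hits)

    truth = GroundTruth(
        planted_operator=operator,
        region_offset=region_offset,
        region_start=region_start,
        per_homolog_offsets=per_homolog_offsets,
        ancestral_protein=ancestral_protein,
    )
    _write_json(out / "ground_truth.json", truth.to_dict())
    return truth


def load_ground_truth(archive_dir: Union[str, Path]) -> GroundTruth:
    with open(Path(archive_dir) / "ground_truth.json") as fh:
        d = json.load(fh)
    return GroundTruth(**d)


def registration_identity(consensus: str, planted: str) -> RecoveryResult:
    """Best ungapped offset/strand registration of consensus vs planted.

    Identity is the fraction of PLANTED positions covered by an identical
    consensus base at the best registration, so a consensus that extends a
    correctly recovered operator into its flanks still scores 1.0.
    """
    planted = planted.upper()
    lp = len(planted)
    best = (-1, 0, "+")
    for strand, seq in (("+", consensus.upper()),
                        ("-", reverse_complement(consensus.upper()))):
        lc = len(seq)
        for d in range(-(lc - 1), lp):
            # consensus index i aligns planted index i + d
            matches = sum(
                1
                for i in range(lc)
                if 0 <= i + d < lp and seq[i] == planted[i + d]
            )
            if matches > best[0]:
                best = (matches, d, strand)
    return RecoveryResult(
        identity=best[0] / lp if lp else 0.0,
        offset_error=abs(best[1]),
        strand=best[2],
    )


def recovery_metrics(
    report: PredictionReport, truth: GroundTruth
) -> RecoveryResult:
    """Score a prediction against the planted operator.

    A report without a consensus (failed diagnostic) scores identity 0.
    """
    if report.motif is None:
        return RecoveryResult(identity=0.0, offset_error=0, strand="+")
    return registration_identity(report.motif.consensus, truth.planted_operator)
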