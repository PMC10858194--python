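"""Homolog acquisition: pluggable live / fixture backends.

Phylogenetic footprinting needs the genetic contexts of many regulator
homologs.  This module defines a small backend protocol with two
implementations: a :class:`FixtureBackend` reading a local JSON archive
(hermetic, deterministic — what the tests and the simulator use) and a
:class:`LiveBackend` talking to NCBI E-utilities/BLAST over HTTP.  Both feed
identical downstream types, so footprinting results are bit-identical for
identical payloads.

Fixture archive layout (one directory per query)::

    <archive>/
      query.json            # {"accession": ..., "protein_sequence": ...}
      context.json          # fixture context record for the query regulator
      hits.json             # [{"accession", "protein_sequence",
                            #   "percent_identity", "coverage"}, ...]
      contexts/<acc>.json   # fixture context record per homolog (may be absent)
"""

from __future__ import annotations

import abc
import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .context import GeneContext, parse_context
from .errors import (
    BackendUnavailableError,
    MalformedRecordError,
    RegulatorNotFoundError,
    ZeroHitsError,
)


@dataclass(frozen=True)
class HomologHit:
    accession: str
    protein_sequence: str
    percent_identity: float
    coverage: float
    source: str = "fixture"  # {"live", "fixture"}

    def __post_init__(self):
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity outside [0, 100]")
        if not (0 <= self.coverage <= 100):
            raise ValueError("coverage outside [0, 100]")


@dataclass(frozen=True)
class AbsenceMarker:
    """Why a per-hit payload is missing; never an exception."""

    reason: str  # {"no-genome-record", "regulator-not-locatable", "parse-failure"}
    detail: str = ""


@dataclass(frozen=True)
class HomologFilters:
    """Identity window, coverage floor and hit cap for homolog selection.

    Defaults exclude near-duplicates (>95% identity) and remote noise
    (<30%), keeping enough divergence for the conservation contrast to be
    informative while the operator stays homologous.
    """

    min_identity: float = 30.0
    max_identity: float = 95.0
    min_coverage: float = 70.0
    max_hits: int = 30
    exclude_self: bool = True


class Backend(abc.ABC):
    """Resolves accessions to proteins, contexts and homolog hits."""

    @abc.abstractmethod
    def get_protein(self, accession: str) -> str: ...

    @abc.abstractmethod
    def get_context_record(self, accession: str) -> Optional[dict]:
        """Fixture-schema context record for an accession, or None."""

    @abc.abstractmethod
    def search_homologs(self, protein_seq: str) -> list[HomologHit]:
        """Raw (unfiltered) homolog hits for a protein sequence."""


class FixtureBackend(Backend):
    """Reads a local archive directory; fully hermetic and deterministic."""

    def __init__(self, archive_dir: Union[str, Path]):
        self.root = Path(archive_dir)
        if not (self.root / "query.json").is_file():
            raise BackendUnavailableError(
                f"no query.json in archive {self.root}"
            )
        with open(self.root / "query.json") as fh:
            q = json.load(fh)
        self.query_accession: str = q["accession"]
        self._query_protein: str = q["protein_sequence"]

    def get_protein(self, accession: str) -> str:
        if accession == self.query_accession:
            return self._query_protein
        for hit in self.search_homologs(self._query_protein):
            if hit.accession == accession:
                return hit.protein_sequence
        raise BackendUnavailableError(f"protein {accession!r} not in archive")

    def get_context_record(self, accession: str) -> Optional[dict]:
        if accession == self.query_accession:
            path = self.root / "context.json"
        else:
            path = self.root / "contexts" / f"{accession}.json"
        if not path.is_file():
            return None
        with open(path) as fh:
            return json.load(fh)

    def search_homologs(self, protein_seq: str) -> list[HomologHit]:
        path = self.root / "hits.json"
        if not path.is_file():
            return []
        with open(path) as fh:
            raw = json.load(fh)
        return [
            HomologHit(
                accession=h["accession"],
                protein_sequence=h["protein_sequence"],
                percent_identity=float(h["percent_identity"]),
                coverage=float(h["coverage"]),
                source="fixture",
            )
            for h in raw
        ]


class LiveBackend(Backend):
    """NCBI adapter (efetch for records, BLAST URL API for homologs).

    Network path with retry/backoff; every payload should be cached to the
    fixture schema by callers so reruns are offline.  Not exercised by the
    test suite.
    """

    EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(self, email: str = "", max_retries: int = 3, delay: float = 0.5):
        self.email = email
        self.max_retries = max_retries
        self.delay = delay

    def _get(self, url: str) -> str:
        err: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(url, timeout=60) as resp:
                    return resp.read().decode()
            except Exception as exc:  # noqa: BLE001 - wrapped below
                err = exc
                time.sleep(self.delay * 2**attempt)
        raise BackendUnavailableError(f"remote fetch failed: {err}")

    def get_protein(self, accession: str) -> str:
        url = (
            f"{self.EUTILS}/efetch.fcgi?"
            + urllib.parse.urlencode(
                {"db": "protein", "id": accession, "rettype": "fasta",
                 "retmode": "text", "email": self.email}
            )
        )
        fasta = self._get(url)
        lines = [l for l in fasta.splitlines() if l and not l.startswith(">")]
        if not lines:
            raise BackendUnavailableError(f"empty FASTA for {accession!r}")
        return "".join(lines)

    def get_context_record(self, accession: str) -> Optional[dict]:
        # ipg gives the nucleotide placement of a protein; a full
        # implementation fetches the surrounding GenBank slice and converts
        # it with context.parse_context. Left minimal: live users are
        # expected to cache into the fixture schema first.
        raise BackendUnavailableError(
            "live context fetch requires caching to the fixture schema; "
            "see docs/methods.md"
        )

    def search_homologs(self, protein_seq: str) -> list[HomologHit]:
        raise BackendUnavailableError(
            "live homolog search requires caching to the fixture schema"
        )


@dataclass(frozen=True)
class HomologContextSet:
    """All per-homolog payloads for one query, markers included."""

    query_accession: str
    entries: tuple  # of (HomologHit, GeneContext|AbsenceMarker)


def collect_homologs(
    protein_seq: str,
    backend: Backend,
    filters: HomologFilters = HomologFilters(),
) -> list[HomologHit]:
    """Filtered, deduplicated homolog hits sorted by descending identity.

    Raises :class:`ZeroHitsError` when nothing survives — the "too few
    homologs" failure mode.
    """
    raw = backend.search_homologs(protein_seq)
    seen: set[str] = set()
    hits: list[HomologHit] = []
    for h in raw:
        if h.accession in seen:
            continue
        seen.add(h.accession)
        if filters.exclude_self and (
            h.protein_sequence == protein_seq or h.percent_identity >= 100.0
        ):
            continue
        if not (filters.min_identity <= h.percent_identity <= filters.max_identity):
            continue
        if h.coverage < filters.min_coverage:
            continue
        hits.append(h)
    hits.sort(key=lambda h: (-h.percent_identity, h.accession))
    if not hits:
        raise ZeroHitsError("no homolog hits survive the filters")
    return hits[: filters.max_hits]


def fetch_context(
    hit: HomologHit, backend: Backend
) -> Union[GeneContext, AbsenceMarker]:
    """Context for one hit; data gaps become absence markers, never raises
    for per-hit problems (only systemic backend failures propagate)."""
    record = backend.get_context_record(hit.accession)
    if record is None:
        return AbsenceMarker("no-genome-record", hit.accession)
    try:
        return parse_context(record, hit.accession)
    except RegulatorNotFoundError as exc:
        return AbsenceMarker("regulator-not-locatable", str(exc))
    except MalformedRecordError as exc:
        return AbsenceMarker("parse-failure", str(exc))
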