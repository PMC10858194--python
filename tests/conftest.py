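import json
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

REPO_ROOT = Path(__file__).resolve().parent.parent
DEMO_ARCHIVE = REPO_ROOT / "examples" / "demo_archive"


def fixture_record(features, seq_len=None, contig_id="ctg1", regulator_id=None,
                   sequence=None):
    """Build a fixture-schema context record from (id, start, end, strand) tuples."""
    if sequence is None:
        n = seq_len or max(f[2] for f in features) + 50
        sequence = ("ACGT" * (n // 4 + 1))[:n]
    return {
        "contig_id": contig_id,
        "sequence": sequence,
        "features": [
            {"id": f[0], "start": f[1], "end": f[2], "strand": f[3],
             "product": f[4] if len(f) > 4 else ""}
            for f in features
        ],
        "regulator_id": regulator_id or features[0][0],
    }


def write_archive(root: Path, query_accession: str, query_protein: str,
                  query_context: dict, hits: list, contexts: dict) -> Path:
    """Materialize a homology fixture archive for tests."""
    root.mkdir(parents=True, exist_ok=True)
    (root / "contexts").mkdir(exist_ok=True)
    (root / "query.json").write_text(json.dumps(
        {"accession": query_accession, "protein_sequence": query_protein}))
    (root / "context.json").write_text(json.dumps(query_context))
    (root / "hits.json").write_text(json.dumps(hits))
    for acc, rec in contexts.items():
        (root / "contexts" / f"{acc}.json").write_text(json.dumps(rec))
    return root


@pytest.fixture(scope="session")
def demo_archive() -> Path:
    assert DEMO_ARCHIVE.is_dir(), "packaged demo archive missing"
    return DEMO_ARCHIVE
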