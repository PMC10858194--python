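"""Report, motif and sequence writers (JSON, MEME minimal, FASTA, text)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .footprint import ConsensusMotif, PredictionReport

_BASES = "ACGT"


def write_report_json(report: PredictionReport, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_meme_motif(
    motif: ConsensusMotif, path: Union[str, Path], name: str = "predicted_operator"
) -> None:
    """MEME minimal motif format (letter-probability matrix)."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {name}",
        (
            f"letter-probability matrix: alength= 4 w= {motif.length} "
            f"nsites= {motif.n_instances} E= 0"
        ),
    ]
    for j in range(motif.length):
        col = motif.frequencies[:, j]
        lines.append(" ".join(f"{v:.6f}" for v in col))
    Path(path).write_text("\n".join(lines) + "\n")


def write_instances_fasta(report: PredictionReport, path: Union[str, Path]) -> None:
    lines = []
    for inst in report.instances:
        lines.append(
            f">{inst.homolog_accession} score={inst.alignment_score:g} "
            f"offset={inst.offset} strand={inst.strand}"
        )
        lines.append(inst.sequence)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_seed_fasta(report: PredictionReport, path: Union[str, Path]) -> None:
    if report.seed is None:
        Path(path).write_text("")
        return
    rep = report.seed.repeat
    Path(path).write_text(
        f">{report.regulator_accession}_seed score={rep.score} "
        f"arm={rep.arm_length} spacer={rep.spacer}\n{rep.sequence}\n"
    )


def render_summary(report: PredictionReport) -> str:
    """Human-readable one-screen summary of a prediction."""
    lines = [
        f"regulator:        {report.regulator_accession}",
        f"diagnostic:       {report.diagnostic}",
        f"arrangement:      {report.region_arrangement}",
    ]
    if report.seed is not None:
        rep = report.seed.repeat
        lines += [
            f"seed operator:    {rep.sequence}",
            (
                f"  arms {rep.arm_length} bp, spacer {rep.spacer} bp, "
                f"matches {rep.matches}, mismatches {rep.mismatches}, "
                f"gap adj {rep.gap_adjustment:+d}, score s = {rep.score}"
            ),
        ]
    if report.motif is not None:
        lines += [
            f"consensus:        {report.motif.consensus}",
            f"conservation c:   {report.conservation_score:.4f}",
            f"instances:        {report.motif.n_instances} "
            f"({report.n_homologs_used} homolog hits)",
        ]
    lines.append(f"version:          {report.version}")
    return "\n".join(lines) + "\n"


def write_summary_text(report: PredictionReport, path: Union[str, Path]) -> None:
    Path(path).write_text(render_summary(report))
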