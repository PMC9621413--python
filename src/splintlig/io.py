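"""Readers and writers for templates, reads and reports.

A library template is stored as a single-record FASTA (the sense strand,
degenerate IUPAC letters at randomized positions) plus a YAML sidecar
naming the spans and randomized codons, e.g.::

    name: my-library
    promoter: [0, 20]
    rbs: [40, 46]
    orf: [62, 578]
    three_prime_constant: [578, 620]
    cr_tail: ""
    randomized_codons:
      - {index: 30, code: NNK}
      - {index: 31, code: NNK}

All template invariants are enforced at load time; violations raise
``ValueError`` with coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .codon_math import DegenerateCodon
from .design import LibraryTemplate, OligoSet, render_order_sheet

__all__ = [
    "read_template",
    "write_template",
    "write_fastq",
    "read_fastq",
    "write_design_report",
    "write_provenance",
]

_CONFIG_KEYS = {
    "name",
    "promoter",
    "rbs",
    "orf",
    "three_prime_constant",
    "cr_tail",
    "randomized_codons",
}


def read_template(fasta_path: str | Path, config_path: str | Path) -> LibraryTemplate:
    """Load and validate a template from FASTA + YAML sidecar."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"template FASTA must contain exactly 1 record, found {len(records)}")
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("template config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"promoter", "rbs", "orf", "three_prime_constant", "randomized_codons"} - set(cfg)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")

    def span(key: str) -> tuple[int, int]:
        v = cfg[key]
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise ValueError(f"{key} must be a [start, end] pair, got {v!r}")
        return int(v[0]), int(v[1])

    rand = []
    for item in cfg["randomized_codons"]:
        rand.append((int(item["index"]), DegenerateCodon(str(item["code"]))))
    return LibraryTemplate(
        full_sequence=str(records[0].seq),
        promoter_span=span("promoter"),
        rbs_span=span("rbs"),
        orf_span=span("orf"),
        randomized_codons=rand,
        three_prime_constant_span=span("three_prime_constant"),
        cr_tail=str(cfg.get("cr_tail", "") or ""),
        name=str(cfg.get("name", records[0].id)),
    )


def write_template(
    template: LibraryTemplate, fasta_path: str | Path, config_path: str | Path
) -> None:
    """Write a template back to FASTA + YAML (inverse of :func:`read_template`)."""
    rec = SeqRecord(Seq(template.full_sequence), id=template.name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    cfg = {
        "name": template.name,
        "promoter": list(template.promoter_span),
        "rbs": list(template.rbs_span),
        "orf": list(template.orf_span),
        "three_prime_constant": list(template.three_prime_constant_span),
        "cr_tail": template.cr_tail,
        "randomized_codons": [
            {"index": i, "code": c.letters} for i, c in template.randomized_codons
        ],
    }
    Path(config_path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_fastq(records, path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path):
    return list(SeqIO.parse(str(path), "fastq"))


def write_design_report(oligos: OligoSet, out_dir: str | Path) -> dict[str, Path]:
    """Order sheet CSV + JSON design report (constraints echoed for provenance)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = render_order_sheet(oligos)
    sheet_path = out / "order_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    report = {
        "template": oligos.template_name,
        "n_sense_oligos": len(oligos.sense),
        "n_splints": len(oligos.splints),
        "n_groups": oligos.n_groups(),
        "junction_positions": oligos.junction_positions,
        "bridging_splints": [sp.name for sp in oligos.splints if sp.stage == "bridging"],
        "constraints": asdict(oligos.constraints),
        "oligo_lengths": {o.name: o.length for o in oligos.sense},
        "splint_arm_tms": {sp.name: list(sp.arm_tms) for sp in oligos.splints},
    }
    report_path = out / "design_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return {"order_sheet": sheet_path, "report": report_path}


def write_provenance(out_dir: str | Path, config: dict) -> Path:
    """Echo the effective run configuration and tool version into the output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = out / "provenance.json"
    p.write_text(json.dumps({"tool": "splintlig", "version": __version__, "config": config},
                            indent=2, sort_keys=True, default=str))
    return p
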