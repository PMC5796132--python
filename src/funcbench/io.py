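"""FASTA reading/writing and dataset-triple serialization.

FASTA parsing is strict: an entry with an empty sequence or sequence text
before any header is a :class:`FastaParseError` naming the offending line.
Triples are written as three FASTA files plus a TSV manifest with columns
``id, set, class, family_id, group_id``.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .records import DatasetTriple, ProteinRecord


class FastaParseError(ValueError):
    """Malformed FASTA input (line number included in the message)."""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    The identifier is the header token before the first whitespace; the
    remainder of the header line is kept as ``description``.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: entry {header.split()[0]!r} starting at line "
                f"{header_line} has an empty sequence"
            )
        name, _, desc = header.partition(" ")
        records.append(ProteinRecord(id=name, sequence=seq, description=desc.strip()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_triple(triple: DatasetTriple, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a triple as three FASTA files plus a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest = out / f"{triple.family_id}.manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "set", "class", "family_id", "group_id"])
        for name, part in triple.parts():
            fasta = out / f"{triple.family_id}.{name}.fasta"
            write_fasta([rec for rec, _ in part], fasta)
            paths[name] = fasta
            for rec, label in part:
                w.writerow([rec.id, name, label, triple.family_id, rec.group_id or ""])
    paths["manifest"] = manifest
    return paths


def read_triple(family_id: str, in_dir: str | Path) -> DatasetTriple:
    """Inverse of :func:`write_triple`."""
    in_dir = Path(in_dir)
    meta: dict[str, tuple[str, str, str]] = {}
    with open(in_dir / f"{family_id}.manifest.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["id"]] = (row["set"], row["class"], row["group_id"])
    parts: dict[str, list[tuple[ProteinRecord, str]]] = {
        "training": [], "testing": [], "independent": []
    }
    for name in parts:
        for rec in read_fasta(in_dir / f"{family_id}.{name}.fasta"):
            set_name, label, group_id = meta[rec.id]
            rec.group_id = group_id or None
            if label == "positive":
                rec.family_labels.add(family_id)
            parts[set_name].append((rec, label))
    return DatasetTriple(family_id=family_id, **parts)
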