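"""Shared I/O: FASTA/FASTQ round-trips, flat config files, run manifests.

Sequence parsing is delegated to Biopython; the wrappers here add the
package's normalization policy (uppercase bases, warning on lowercase)
and error messages that carry the offending file.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Lowercase bases are normalized to uppercase with a warning, matching
    the convention that all downstream sequence comparisons are
    case-insensitive DNA.
    """
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            if seq != seq.upper():
                warnings.warn(f"{path}: lowercase bases in record {rec.id!r} "
                              "normalized to uppercase")
                seq = seq.upper()
            records.append((rec.id, seq))
    except ValueError as exc:  # malformed record
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) triples; sequences uppercased."""
    try:
        with open(path) as fh:
            for name, seq, qual in FastqGeneralIterator(fh):
                yield name, seq.upper(), qual
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# flat key = value configuration files


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file. '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, val = line.split("=", 1)
        key = key.strip()
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = val.strip()
    return out


def coerce_config(raw: dict[str, str], cls):
    """Build a dataclass ``cls`` from string values, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        ftype = fields[key].type
        kwargs[key] = _coerce(val, ftype)
    return cls(**kwargs)


def _coerce(val: str, ftype) -> object:
    ftype = str(ftype)
    if "int" in ftype:
        return int(val)
    if "float" in ftype:
        return float(val)
    if "bool" in ftype:
        return val.lower() in ("1", "true", "yes")
    return val


def write_config(path: str | Path, obj) -> None:
    lines = [f"{f.name} = {getattr(obj, f.name)}"
             for f in dataclasses.fields(obj)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
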