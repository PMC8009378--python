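"""FASTA / BED / YAML round-tripping for references and derivatives."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Feature, GenomeConfig, ReferenceGenome


class FastaParseError(ValueError):
    pass


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into {name: sequence}; malformed input raises with a line
    number."""
    _validate_fasta_lines(path)
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def _validate_fasta_lines(path: str | Path) -> None:
    valid = set("ACGTNacgtn")
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                continue
            if not seen_header:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence before any '>' header"
                )
            if not set(line) <= valid:
                raise FastaParseError(
                    f"{path}: line {lineno}: invalid sequence characters"
                )
        if not seen_header:
            raise FastaParseError(f"{path}: line 1: no FASTA header found")


def write_bed(features: Iterable[Feature], path: str | Path,
              chrom: str = "chrIII") -> None:
    """Export features as BED (internal 1-based inclusive -> 0-based
    half-open)."""
    with open(path, "w") as fh:
        for f in features:
            start0 = f.interval[0] - 1
            end0 = f.interval[1]
            fh.write(
                f"{chrom}\t{start0}\t{end0}\t{f.name}\t0\t{f.strand}\t{f.kind}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader returning (chrom, start0, end0, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]),
                        parts[3] if len(parts) > 3 else ""))
    return out


def write_config(config: GenomeConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path: str | Path) -> GenomeConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["ty2_span"] = tuple(d["ty2_span"])
    d["gene_annotations"] = tuple(
        (name, tuple(iv), ess) for name, iv, ess in d["gene_annotations"]
    )
    return GenomeConfig(**d)


def write_reference(ref: ReferenceGenome, fasta_path: str | Path,
                    bed_path: str | Path | None = None,
                    name: str = "chrIII") -> None:
    write_fasta({name: ref.sequence}, fasta_path)
    if bed_path is not None:
        write_bed(ref.features, bed_path, chrom=name)
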