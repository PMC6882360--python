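"""Readers and writers for the on-disk formats the pipeline touches.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GTF files (1-based inclusive) are converted at the boundary, in
both directions, so no other module ever handles 1-based coordinates.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "Transcript",
    "AnnotationSet",
    "RepeatFeature",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_annotation",
    "write_annotation",
    "read_repeats",
    "write_repeats_bed",
    "alu_subfamily",
    "circ_id",
    "parse_circ_id",
]

_VALID_STRANDS = {"+", "-"}
# Unicode minus signs occasionally appear in hand-edited tables.
_STRAND_ALIASES = {"−": "-", "–": "-", "C": "-"}

_FASTA_ALPHABET = set("ACGTN")


def _normalize_strand(strand: str) -> str:
    strand = _STRAND_ALIASES.get(strand, strand)
    if strand not in _VALID_STRANDS:
        raise ValueError(f"invalid strand {strand!r}; expected '+' or '-'")
    return strand


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    """A transcript: sorted, non-overlapping exons sharing chrom and strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def splice_junctions(self) -> list[tuple[int, int]]:
        """(donor_exon_end, acceptor_exon_start) pairs in genomic order."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class AnnotationSet:
    """All transcripts of a toy annotation, indexed by id."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, transcript: Transcript) -> None:
        if transcript.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript {transcript.transcript_id}")
        self.transcripts[transcript.transcript_id] = transcript

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat element from a RepeatMasker-style annotation."""

    interval: GenomicInterval
    name: str
    subfamily: str

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError(f"repeat {self.name}: empty subfamily")

    @property
    def is_alu(self) -> bool:
        return self.name.startswith("Alu")


# --------------------------------------------------------------------------
# FASTA / FASTQ
# --------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into {name: sequence}; uppercase, U mapped to T.

    Raises on duplicate names, empty files, and characters outside
    A, C, G, T, N after normalization.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name!r}: invalid characters {sorted(bad)}")
        sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                if name in sequences:
                    raise ValueError(f"duplicate FASTA name {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA data before first header")
                chunks.append(line)
    _flush()
    if not sequences:
        raise ValueError(f"empty FASTA file: {path}")
    return sequences


def write_fasta(path: str | os.PathLike, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTQ into a list of (read_name, sequence); qualities dropped."""
    reads: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4 != 0:
        raise ValueError(f"truncated FASTQ file: {path}")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ record near line {i + 1}")
        if len(qual) != len(seq):
            raise ValueError(f"quality/sequence length mismatch near line {i + 1}")
        reads.append((header[1:].split()[0], seq.upper().replace("U", "T")))
    return reads


def write_fastq(path: str | os.PathLike, reads: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------------
# GTF annotation
# --------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> AnnotationSet:
    """Read exon features from a GTF file.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open.  Exons are grouped by transcript_id and sorted; missing
    transcript_id or invalid coordinates raise.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks transcript_id")
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        if feat.end < feat.start:
            raise ValueError(f"exon with end < start at {feat.seqid}:{feat.start}")
        entry = by_transcript.setdefault(tid, {"gene_id": gid, "exons": []})
        entry["exons"].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    annotation = AnnotationSet()
    for tid, entry in by_transcript.items():
        annotation.add(Transcript(tid, entry["gene_id"], entry["exons"]))
    return annotation


def write_annotation(path: str | os.PathLike, annotation: AnnotationSet) -> None:
    """Write exon features as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in annotation:
            for exon in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "circskin",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# --------------------------------------------------------------------------
# Repeats (BED6 or RepeatMasker .out)
# --------------------------------------------------------------------------

_ALU_PREFIX_RE = re.compile(r"^Alu([JSY])")
_KNOWN_PREFIXES = ("AluJ", "AluS", "AluY", "Alu", "SVA", "MIR", "L1", "L2")


def alu_subfamily(name: str) -> str:
    """Subfamily label from a repeat name by prefix rule.

    AluJb -> AluJ, AluSx -> AluS, AluYb8 -> AluY; L1MA4 -> L1; unknown
    names fall back to the full name as their own subfamily.
    """
    m = _ALU_PREFIX_RE.match(name)
    if m:
        return "Alu" + m.group(1)
    for prefix in _KNOWN_PREFIXES:
        if name.startswith(prefix):
            return prefix
    return name


def read_repeats(path: str | os.PathLike) -> list[RepeatFeature]:
    """Read repeats from BED6 or RepeatMasker .out.

    The dialect is sniffed from the first data line: BED6 rows have a
    numeric 0-based start in column 2; RepeatMasker .out starts with the
    "SW score" header banner.  Unknown layouts raise an error naming both
    accepted dialects.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    first = lines[0].split()
    if first and first[0].lower() in {"sw", "score"}:
        return _parse_repeatmasker_out(lines)
    if len(first) >= 6 and first[1].isdigit() and first[2].isdigit():
        return _parse_bed6(lines)
    raise ValueError(
        f"unrecognized repeat file dialect in {path}: expected 6-column BED "
        "or RepeatMasker .out"
    )


def _parse_bed6(lines: list[str]) -> list[RepeatFeature]:
    repeats = []
    for ln in lines:
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if len(fields) < 6:
            raise ValueError(f"BED6 row with fewer than 6 columns: {ln!r}")
        chrom, start, end, name, _score, strand = fields[:6]
        interval = GenomicInterval(chrom, int(start), int(end), strand)
        repeats.append(RepeatFeature(interval, name, alu_subfamily(name)))
    return repeats


def _parse_repeatmasker_out(lines: list[str]) -> list[RepeatFeature]:
    repeats = []
    for ln in lines:
        fields = ln.split()
        if not fields or not fields[0].replace(".", "").isdigit():
            continue  # header banner lines
        # columns: score div del ins query qstart qend qleft strand name class...
        chrom = fields[4]
        start = int(fields[5]) - 1  # .out is 1-based inclusive
        end = int(fields[6])
        strand = fields[8]  # '+' or 'C'
        name = fields[9]
        interval = GenomicInterval(chrom, start, end, strand)
        repeats.append(RepeatFeature(interval, name, alu_subfamily(name)))
    return repeats


def write_repeats_bed(path: str | os.PathLike, repeats: list[RepeatFeature]) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rep.name}\t0\t{iv.strand}\n"
            )


# --------------------------------------------------------------------------
# circRNA identifiers
# --------------------------------------------------------------------------

_CIRC_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)\|(?P<end>\d+):(?P<strand>.+)$")


def circ_id(interval: GenomicInterval) -> str:
    """Text identifier "chrom:start|end:strand" (0-based half-open)."""
    return f"{interval.chrom}:{interval.start}|{interval.end}:{interval.strand}"


def parse_circ_id(text: str) -> GenomicInterval:
    m = _CIRC_ID_RE.match(text)
    if m is None:
        raise ValueError(f"malformed circRNA identifier {text!r}")
    return GenomicInterval(
        m.group("chrom"), int(m.group("start")), int(m.group("end")), m.group("strand")
    )
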