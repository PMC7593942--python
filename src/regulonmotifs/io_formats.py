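"""File formats and the shared sequence/coordinate conventions.

Every coordinate held in memory is 0-based, half-open, on the forward strand
of its contig.  GFF3 (1-based inclusive) and the MEME minimal motif format
convert at the boundary, never inside the pipeline.  Genomes are plain
FASTA over ``{A, C, G, T, N}``; lowercase is normalised on read and any other
symbol is rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
VALID_GENOME_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Full IUPAC nucleotide complement table (used for consensus palindromy).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# byte -> base index lookup; 255 marks N / anything non-ACGT
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_ALPHABET):
    _ENCODE[ord(_b)] = _i


class FormatError(ValueError):
    """An input file violates its format contract."""


class EmptyInputError(ValueError):
    """An input file or collection is empty where content is required."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC consensus string.

    Raises
    ------
    FormatError
        If *seq* contains a symbol outside the IUPAC nucleotide alphabet.
    """
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise FormatError(f"non-IUPAC symbol {exc.args[0]!r} in consensus {seq!r}") from None


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ``ACGTN`` text as uint8 indices (A=0..T=3, N and others=255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomeRecord:
    """A contig: identifier, uppercase ACGTN sequence, circularity flag."""

    contig_id: str
    sequence: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.contig_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene with its operon assignment.

    ``start``/``end`` are 0-based half-open genomic offsets; ``operon_index``
    is the 1-based position in transcription order within the operon, so
    ``operon_index == 1`` marks the gene whose promoter drives the operon.
    """

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    operon_id: str
    operon_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"gene {self.locus_tag}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.locus_tag}: strand must be '+' or '-'")
        if self.operon_index < 1:
            raise FormatError(f"gene {self.locus_tag}: operon_index must be >= 1")


@dataclasses.dataclass(frozen=True)
class ExpressionRecord:
    """One differential-expression measurement for one gene and condition."""

    locus_tag: str
    condition: str
    fold_change: float
    q_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise FormatError(
                f"{self.locus_tag}/{self.condition}: q_value {self.q_value} outside [0, 1]")
        if self.fold_change < 0:
            raise FormatError(
                f"{self.locus_tag}/{self.condition}: negative fold_change {self.fold_change}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, is_circular: bool = False) -> list[GenomeRecord]:
    """Read a genome FASTA into :class:`GenomeRecord` objects.

    Lowercase is normalised to uppercase; any symbol outside ``ACGTN`` is a
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    raw = path.read_text()
    if not raw.strip():
        raise EmptyInputError(f"{path}: empty FASTA file")
    header_seen = False
    for lineno, line in enumerate(raw.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            header_seen = True
            continue
        if not header_seen:
            raise FormatError(f"{path}:{lineno}: sequence before first FASTA header")
        bad = set(stripped.upper()) - VALID_GENOME_CHARS
        if bad:
            raise FormatError(
                f"{path}:{lineno}: invalid genome symbol(s) {sorted(bad)!r}")
    if not header_seen:
        raise FormatError(f"{path}:1: not a FASTA file (no '>' header found)")
    records = [
        GenomeRecord(rec.id, str(rec.seq).upper(), is_circular=is_circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"{path}: FASTA contains no records")
    return records


def write_genome(records: Sequence[GenomeRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 + operon TSV
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, operon_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 plus an operon-assignment TSV.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open.  The TSV maps ``locus_tag -> (operon_id, operon_index)``; a
    gene missing from the TSV becomes a singleton operon with index 1 (a
    warning is logged).  ``##sequence-region`` pragmas, when present, bound
    the coordinates.
    """
    import gffutils

    path, operon_path = Path(path), Path(operon_path)
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)

    contig_lengths: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                contig_lengths[parts[1]] = int(parts[3])

    operons = pd.read_csv(operon_path, sep="\t", dtype={"locus_tag": str, "operon_id": str})
    required = {"locus_tag", "operon_id", "operon_index"}
    if not required <= set(operons.columns):
        raise FormatError(
            f"{operon_path}: operon TSV needs columns {sorted(required)}, "
            f"got {list(operons.columns)}")
    operon_map = {
        row.locus_tag: (row.operon_id, int(row.operon_index))
        for row in operons.itertuples()
    }

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feature in db.features_of_type("gene", order_by=("seqid", "start")):
        locus = feature.attributes.get("locus_tag", feature.attributes.get("ID", [feature.id]))[0]
        if locus in seen:
            raise FormatError(f"{path}: duplicate locus_tag {locus!r}")
        seen.add(locus)
        start0, end0 = feature.start - 1, feature.end  # 1-based incl -> 0-based half-open
        length = contig_lengths.get(feature.seqid)
        if length is not None and (start0 < 0 or end0 > length):
            raise FormatError(
                f"{path}: gene {locus} [{feature.start}, {feature.end}] outside "
                f"contig {feature.seqid} of length {length}")
        if locus in operon_map:
            operon_id, operon_index = operon_map[locus]
        else:
            logger.warning("locus %s absent from operon table; treating as singleton operon", locus)
            operon_id, operon_index = f"operon_{locus}", 1
        genes.append(GeneModel(
            locus_tag=locus, contig_id=feature.seqid,
            start=start0, end=end0, strand=feature.strand,
            operon_id=operon_id, operon_index=operon_index,
        ))
    return genes


def write_annotations(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    operon_path: str | Path | None = None,
) -> None:
    """Write gene models as GFF3 (1-based inclusive) and optionally the operon TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            fh.write(
                f"{g.contig_id}\tregulonmotifs\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n")
    if operon_path is not None:
        write_operons(genes, operon_path)


def write_operons(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus_tag": [g.locus_tag for g in genes],
            "operon_id": [g.operon_id for g in genes],
            "operon_index": [g.operon_index for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str, "condition": str})
    required = {"locus_tag", "condition", "fold_change", "q_value"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: expression TSV needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        ExpressionRecord(row.locus_tag, row.condition, float(row.fold_change), float(row.q_value))
        for row in df.itertuples()
    ]


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus_tag": [r.locus_tag for r in records],
            "condition": [r.condition for r in records],
            "fold_change": [r.fold_change for r in records],
            "q_value": [r.q_value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_motifs(motifs: Sequence, path: str | Path,
                 background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format.

    Each motif must expose ``motif_id``, ``probs`` (width x 4, rows summing
    to 1), ``nsites`` and ``significance``.  A round-trip through
    :func:`read_motifs` reproduces the matrices to six decimal places.
    """
    path = Path(path)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(DNA_ALPHABET, bg)),
        "",
    ]
    for motif in motifs:
        probs = np.asarray(motif.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise FormatError(f"motif {motif.motif_id}: probs must be width x 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(probs.sum(axis=1) - 1.0)))
            raise FormatError(
                f"motif {motif.motif_id}: probability row {bad} sums to "
                f"{probs[bad].sum():.6f}, not 1")
        lines.append(f"MOTIF {motif.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {probs.shape[0]} "
            f"nsites= {float(motif.nsites):g} E= {float(motif.significance):.3g}")
        for row in probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motifs(path: str | Path) -> list["MotifMatrix"]:
    """Read a MEME-minimal motif file back into matrix records."""
    path = Path(path)
    motifs: list[MotifMatrix] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            header = lines[i].strip()
            if not header.startswith("letter-probability matrix:"):
                raise FormatError(f"{path}: MOTIF {motif_id} lacks a matrix header")
            tokens = header.split()
            fields = {tokens[k]: tokens[k + 1]
                      for k in range(len(tokens) - 1) if tokens[k].endswith("=")}
            width = int(fields["w="])
            nsites = float(fields.get("nsites=", 20))
            evalue = float(fields.get("E=", 1.0))
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            motifs.append(MotifMatrix(motif_id, np.array(rows), nsites, evalue))
        i += 1
    return motifs


@dataclasses.dataclass
class MotifMatrix:
    """Minimal motif record as stored in MEME-format files."""

    motif_id: str
    probs: np.ndarray
    nsites: float
    significance: float


# ---------------------------------------------------------------------------
# site output: BED6 + companion TSV
# ---------------------------------------------------------------------------

def write_sites(sites: Sequence, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write motif occurrences as BED6 plus a TSV with p/q-values.

    BED intervals are 0-based half-open; the BED score column carries the
    log-odds score.  Output is sorted by (contig, start, strand).
    """
    ordered = sorted(sites, key=lambda s: (s.contig_id, s.start, s.strand, s.motif_id))
    with Path(bed_path).open("w") as fh:
        for s in ordered:
            fh.write(
                f"{s.contig_id}\t{s.start}\t{s.start + s.width}\t{s.motif_id}\t"
                f"{s.score:.4f}\t{s.strand}\n")
    df = pd.DataFrame(
        {
            "motif_id": [s.motif_id for s in ordered],
            "contig_id": [s.contig_id for s in ordered],
            "start": [s.start for s in ordered],
            "end": [s.start + s.width for s in ordered],
            "strand": [s.strand for s in ordered],
            "score": [s.score for s in ordered],
            "p_value": [s.p_value for s in ordered],
            "q_value": [s.q_value for s in ordered],
            "region_locus": [s.region_locus or "" for s in ordered],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def read_sites(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", dtype={"motif_id": str, "contig_id": str},
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# promoter-region FASTA (coordinates carried in the header)
# ---------------------------------------------------------------------------

def write_regions_fasta(regions: Sequence, path: str | Path) -> None:
    """Write promoter regions as FASTA with ``locus contig:start-end(strand)`` headers."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f">{r.locus_tag} {r.contig_id}:{r.start}-{r.end}({r.strand})\n")
            fh.write(r.sequence + "\n")


def read_regions_fasta(path: str | Path) -> list:
    from .regions import PromoterRegion

    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(maxsplit=1)
        if len(desc) == 2 and ":" in desc[1]:
            loc = desc[1]
            contig, rest = loc.rsplit(":", 1)
            coords, strand = rest[:-1].rsplit("(", 1)
            start, end = (int(x) for x in coords.split("-"))
        else:
            contig, start, strand = rec.id, 0, "+"
            end = len(rec.seq)
        regions.append(PromoterRegion(
            locus_tag=rec.id, contig_id=contig, start=start, end=end,
            strand=strand, sequence=str(rec.seq).upper()))
    return regions
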