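"""Sequence and gene-model I/O.

Reads the two standard formats the pipeline touches (FASTA, GFF3) and derives
the two sequence universes the analysis runs over: gene bodies (spliced
transcripts or genomic spans) and fixed-width genome fragments.

Coordinate convention: GFF3 is 1-based inclusive on disk; everything in memory
is 0-based half-open. The conversion happens exactly once, in
:func:`read_gff_genes`.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (including duplicate ids)."""


class GffFormatError(ValueError):
    """Raised for malformed GFF3 input."""


class ExtractionError(ValueError):
    """Raised when gene bodies cannot be extracted from a genome."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T} plus IUPAC ambiguity codes.

    Residues are upper-cased on construction; ids must be non-empty.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        res = self.residues.upper()
        bad = set(res) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC letters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        rc = str(Seq(self.residues).reverse_complement())
        return SequenceRecord(self.id, rc)


@dataclass(frozen=True)
class GeneModel:
    """A gene's location: scaffold, strand, and ordered exon intervals.

    Exons are 0-based half-open, sorted by start, non-overlapping.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id!r}: exon list is empty")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(
                    f"gene {self.gene_id!r}: invalid exon interval [{s}, {e})"
                )
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            raise ValueError(
                f"gene {self.gene_id!r}: exons must be sorted and non-overlapping"
            )
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file (plain or gzipped) into SequenceRecords.

    The header token up to the first whitespace becomes the record id.
    Raises :class:`FastaFormatError` for sequence data appearing before the
    first header (naming the offending line) and for duplicate ids.
    """
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(";"):
            continue
        if stripped.startswith(">"):
            break
        raise FastaFormatError(
            f"{path}: sequence data before first FASTA header at line {lineno}"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    duplicates: list[str] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            duplicates.append(rec.id)
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if duplicates:
        raise FastaFormatError(
            f"{path}: duplicate sequence ids: {sorted(set(duplicates))}"
        )
    if not records:
        logger.warning("%s: no FASTA records found (empty input)", path)
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    width: int = 60,
    descriptions: dict[str, str] | None = None,
) -> None:
    """Write records to FASTA (gzipped when the path ends in .gz)."""
    descriptions = descriptions or {}
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=descriptions.get(r.id, ""))
        for r in records
    ]
    path = Path(path)
    if path.suffix == ".gz":
        with io.TextIOWrapper(gzip.open(path, "wb")) as fh:
            _write_wrapped(bio, fh, width)
    else:
        with open(path, "wt") as fh:
            _write_wrapped(bio, fh, width)


def _write_wrapped(bio_records, fh, width: int) -> None:
    writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
    writer.write_file(bio_records)


def _validate_gff_lines(path: str | Path) -> None:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GffFormatError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GffFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise GffFormatError(
                    f"{path}: line {lineno}: end ({end}) < start ({start})"
                )


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, grouping exons under their gene.

    Exons are resolved to a gene id by walking Parent relationships (exon ->
    mRNA -> gene); exons whose parent cannot be resolved are skipped with a
    logged warning and count. GFF3 1-based inclusive coordinates are converted
    to 0-based half-open.
    """
    _validate_gff_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_gene: dict[str, dict] = {}
    n_skipped = 0
    for exon in db.features_of_type("exon"):
        gene_id = None
        gene_strand = None
        for parent in db.parents(exon.id):
            if parent.featuretype == "gene":
                gene_id = parent.id
                gene_strand = parent.strand
        if gene_id is None:
            attrs = exon.attributes
            for key in ("Parent", "gene_id", "gene"):
                if key in attrs:
                    gene_id = attrs[key][0]
                    break
        if gene_id is None:
            n_skipped += 1
            logger.warning(
                "exon at %s:%d-%d has no resolvable parent; skipped",
                exon.seqid,
                exon.start,
                exon.end,
            )
            continue
        entry = by_gene.setdefault(
            gene_id,
            {"scaffold": exon.seqid, "strand": gene_strand or exon.strand, "exons": []},
        )
        if entry["scaffold"] != exon.seqid:
            raise GffFormatError(
                f"gene {gene_id!r}: exons on multiple scaffolds "
                f"({entry['scaffold']!r}, {exon.seqid!r})"
            )
        entry["exons"].append((exon.start - 1, exon.end))
    if n_skipped:
        logger.warning("%d exon(s) skipped for unresolvable parents", n_skipped)
    models = []
    for gene_id, entry in by_gene.items():
        exons = tuple(sorted(entry["exons"]))
        strand = entry["strand"] if entry["strand"] in {"+", "-"} else "+"
        models.append(GeneModel(gene_id, entry["scaffold"], strand, exons))
    return models


def write_gff_genes(models: Sequence[GeneModel], path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write gene models back to GFF3 (gene -> mRNA -> exon), 1-based inclusive."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for comment in header_comments:
            fh.write(f"#{comment}\n")
        for g in models:
            start, end = g.span
            fh.write(
                f"{g.scaffold_id}\tcpgoe\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            rna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold_id}\tcpgoe\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={rna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.scaffold_id}\tcpgoe\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={rna_id}.exon{i};Parent={rna_id}\n"
                )


def extract_gene_bodies(
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    mode: str = "spliced",
    truncate_to: int | None = None,
) -> list[SequenceRecord]:
    """Extract gene-body sequences from a genome.

    mode="spliced" concatenates exon sequences in genomic order; mode="span"
    takes the contiguous first-exon-start to last-exon-end region. Minus-strand
    genes are reverse-complemented afterwards so output reads 5'->3' in the
    gene's sense. With ``truncate_to``, longer sequences are cut to their first
    ``truncate_to`` bases (5'-anchored); shorter ones are kept full-length.
    """
    if mode not in {"spliced", "span"}:
        raise ValueError(f"mode must be 'spliced' or 'span', got {mode!r}")
    if truncate_to is not None and truncate_to < 1:
        raise ValueError("truncate_to must be >= 1")
    index = {r.id: r for r in genome}
    out: list[SequenceRecord] = []
    for gene in genes:
        scaffold = index.get(gene.scaffold_id)
        if scaffold is None:
            raise ExtractionError(
                f"gene {gene.gene_id!r}: scaffold {gene.scaffold_id!r} not in genome"
            )
        if gene.span[1] > len(scaffold):
            raise ExtractionError(
                f"gene {gene.gene_id!r}: span {gene.span} exceeds scaffold "
                f"{gene.scaffold_id!r} length {len(scaffold)}"
            )
        if mode == "spliced":
            seq = "".join(scaffold.residues[s:e] for s, e in gene.exons)
        else:
            s, e = gene.span
            seq = scaffold.residues[s:e]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if truncate_to is not None:
            seq = seq[:truncate_to]
        out.append(SequenceRecord(gene.gene_id, seq))
    return out


class TilingResult(NamedTuple):
    windows: list[SequenceRecord]
    n_discarded_ambiguous: int
    n_partial_dropped: int


def tile_genome(
    genome: Sequence[SequenceRecord],
    window: int = 1000,
    max_ambiguous_frac: float = 0.2,
) -> TilingResult:
    """Cut each scaffold into non-overlapping windows from position 0.

    Trailing partial windows are dropped; windows whose ambiguous-base fraction
    exceeds ``max_ambiguous_frac`` are discarded and counted. Window ids encode
    scaffold and 0-based start as ``<scaffold>:<start>``.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    windows: list[SequenceRecord] = []
    n_ambiguous = 0
    n_partial = 0
    for scaffold in genome:
        n_full = len(scaffold) // window
        if len(scaffold) % window:
            n_partial += 1
        for i in range(n_full):
            start = i * window
            chunk = scaffold.residues[start : start + window]
            ambiguous = sum(1 for b in chunk if b not in UNAMBIGUOUS)
            if ambiguous / window > max_ambiguous_frac:
                n_ambiguous += 1
                continue
            windows.append(SequenceRecord(f"{scaffold.id}:{start}", chunk))
    return TilingResult(windows, n_ambiguous, n_partial)
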