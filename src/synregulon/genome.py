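"""Genome and annotation handling: FASTA/GFF3 input, operon calling and
promoter-set construction.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based inclusive convention is converted on read.  Promoters are the
upstream intergenic windows of operon leader genes: for a ``+`` strand gene
``[s, e)`` the window is ``[max(0, s - window), s)``, for a ``-`` strand
gene the reverse complement of ``[e, min(L, e + window))``, so the returned
sequence always reads 5'->3' relative to the downstream gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


class AnnotationError(ValueError):
    """Raised for GFF3 features that do not fit the loaded contigs."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the {A,C,G,T,N} alphabet.

    N maps to N.  Characters outside the alphabet raise ``ValueError``
    rather than being silently passed through.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene, 0-based half-open on its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class Genome:
    """Contig sequences plus sorted, strand-aware gene annotations."""

    contigs: dict[str, str]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"contig {cid}: characters outside A/C/G/T/N: {sorted(bad)}"
                )
        seen: set[str] = set()
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise AnnotationError(
                    f"gene {g.gene_id} placed on unknown contig {g.contig_id!r}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise AnnotationError(
                    f"gene {g.gene_id}: end {g.end} beyond contig "
                    f"{g.contig_id} length {len(self.contigs[g.contig_id])}"
                )
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown locus {gene_id!r}")


@dataclass(frozen=True)
class Promoter:
    """Upstream window of an operon leader, 5'->3' relative to the gene."""

    locus_id: str
    sequence: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    empty: bool = False


@dataclass(frozen=True)
class PromoterConfig:
    """Parameters of operon grouping and promoter extraction.

    window
        upstream window size in bases (the 400-bp convention for
        CodY-box promoter work).
    clip_at_upstream_gene
        truncate the window at the nearest annotated gene boundary; off for
        fixed-window extraction of a single locus, on for genome-wide scans.
    operon_max_gap
        maximum intergenic gap (bases) joining same-strand neighbours into
        one operon.
    """

    window: int = 400
    clip_at_upstream_gene: bool = True
    operon_max_gap: int = 50
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.operon_max_gap < 0:
            raise ValueError("operon_max_gap must be >= 0")


@dataclass(frozen=True)
class Operon:
    """Ordered run of co-transcribed genes; ``leader`` owns the promoter."""

    gene_ids: tuple[str, ...]
    leader: str
    contig_id: str
    strand: str


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (no genes attached).

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced
    by N with a logged warning count.  An empty file, or a file whose first
    non-blank line is not a header, is a :class:`FastaFormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file (no records)")

    contigs: dict[str, str] = {}
    n_replaced = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in DNA_ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_replaced += 1
        if record.id in contigs:
            raise FastaFormatError(f"{path}: duplicate contig id {record.id!r}")
        contigs[record.id] = "".join(cleaned)
    if not contigs:
        raise FastaFormatError(f"{path}: empty FASTA file (no records)")
    if n_replaced:
        logger.warning(
            "%s: replaced %d non-ACGTN characters with N", path, n_replaced
        )
    return Genome(contigs=contigs)


def read_gff3(path: str | Path, genome: Genome) -> Genome:
    """Attach gene annotations from a GFF3 file to ``genome``.

    Features of type ``gene`` are used (``CDS`` as fallback when the file
    has no gene features).  GFF3 1-based inclusive coordinates become
    0-based half-open.  Features on contigs absent from the genome, or with
    coordinates outside their contig, raise :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feature_types = set(db.featuretypes())
    ftype = "gene" if "gene" in feature_types else "CDS"
    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type(ftype):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in genome.contigs:
            raise AnnotationError(
                f"gene {gene_id}: unknown contig {feat.seqid!r}"
            )
        start0, end0 = feat.start - 1, feat.end
        contig_len = len(genome.contigs[feat.seqid])
        if not (0 <= start0 < end0 <= contig_len):
            raise AnnotationError(
                f"gene {gene_id}: interval [{start0}, {end0}) outside contig "
                f"{feat.seqid} of length {contig_len}"
            )
        product = feat.attributes.get("product", [None])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand,
                product=product,
            )
        )
    return Genome(contigs=dict(genome.contigs), genes=genes)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Write gene annotations back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted(genome.contigs):
            fh.write(f"##sequence-region {cid} 1 {len(genome.contigs[cid])}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tsynregulon\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def call_operons(genome: Genome, config: PromoterConfig | None = None) -> list[Operon]:
    """Group genes into operons with a same-strand distance heuristic.

    Consecutive genes on one contig and strand whose intergenic gap is at
    most ``operon_max_gap`` share an operon.  The leader (promoter-bearing
    gene) is the leftmost gene of a ``+`` strand operon and the rightmost
    gene of a ``-`` strand operon.  Single genes form singleton operons.
    """
    config = config or PromoterConfig()
    operons: list[Operon] = []
    run: list[GeneAnnotation] = []

    def flush() -> None:
        if not run:
            return
        strand = run[0].strand
        leader = run[0].gene_id if strand == "+" else run[-1].gene_id
        operons.append(
            Operon(
                gene_ids=tuple(g.gene_id for g in run),
                leader=leader,
                contig_id=run[0].contig_id,
                strand=strand,
            )
        )

    for g in genome.genes:
        if run:
            prev = run[-1]
            same_contig = g.contig_id == prev.contig_id
            same_strand = (not config.require_same_strand) or g.strand == prev.strand
            gap = g.start - prev.end
            if same_contig and same_strand and gap <= config.operon_max_gap:
                run.append(g)
                continue
            flush()
            run = []
        run.append(g)
    flush()
    return operons


def extract_upstream(
    genome: Genome, locus_id: str, config: PromoterConfig | None = None
) -> Promoter:
    """Extract the upstream window of one locus.

    With ``clip_at_upstream_gene`` the window is truncated at the nearest
    boundary of another annotated gene so that promoters do not run into
    coding sequence.  A zero-length region yields an empty Promoter flagged
    ``empty=True`` rather than an error.
    """
    config = config or PromoterConfig()
    gene = genome.gene(locus_id)
    contig = genome.contigs[gene.contig_id]
    if gene.strand == "+":
        lo, hi = max(0, gene.start - config.window), gene.start
        if config.clip_at_upstream_gene:
            for other in genome.genes:
                if other.gene_id == locus_id or other.contig_id != gene.contig_id:
                    continue
                if lo < other.end <= hi:
                    lo = other.end
        seq = contig[lo:hi]
    else:
        lo, hi = gene.end, min(len(contig), gene.end + config.window)
        if config.clip_at_upstream_gene:
            for other in genome.genes:
                if other.gene_id == locus_id or other.contig_id != gene.contig_id:
                    continue
                if lo <= other.start < hi:
                    hi = other.start
        seq = reverse_complement(contig[lo:hi])
    return Promoter(
        locus_id=locus_id,
        sequence=seq,
        contig_id=gene.contig_id,
        interval=(lo, hi),
        strand=gene.strand,
        empty=(hi <= lo),
    )


def build_promoter_set(
    genome: Genome, config: PromoterConfig | None = None
) -> list[Promoter]:
    """One promoter per operon leader; empty windows are dropped.

    Output order follows the sorted gene order of the genome and is
    therefore stable across runs.
    """
    config = config or PromoterConfig()
    promoters = []
    for operon in call_operons(genome, config):
        p = extract_upstream(genome, operon.leader, config)
        if not p.empty:
            promoters.append(p)
    return promoters


_PROMOTER_COLUMNS = ["locus_id", "contig", "start", "end", "strand", "sequence"]


def write_promoters_tsv(promoters: Iterable[Promoter], path: str | Path) -> None:
    rows = [
        (p.locus_id, p.contig_id, p.interval[0], p.interval[1], p.strand, p.sequence)
        for p in promoters
    ]
    pd.DataFrame(rows, columns=_PROMOTER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_promoters_tsv(path: str | Path) -> list[Promoter]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = set(_PROMOTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing promoter columns {sorted(missing)}")
    return [
        Promoter(
            locus_id=str(r.locus_id),
            sequence=str(r.sequence),
            contig_id=str(r.contig),
            interval=(int(r.start), int(r.end)),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
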