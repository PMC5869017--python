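"""Genome, annotation and 3'-end coverage I/O.

All coordinates inside the package are 0-based half-open on the plus
strand of the reference, regardless of gene strand.  GTF input follows
its 1-based closed convention and is converted on load; BED/bedgraph
output is 0-based half-open.  Strand-aware sequence access (fetching a
window in transcript orientation) lives on :class:`GenomeSequence`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (uppercase)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase nucleotide string."""

    def __init__(self, chroms: Dict[str, str]):
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) in transcript orientation.

        On the minus strand the plus-strand slice is reverse-complemented,
        so the returned string reads 5'->3' along the transcript.
        """
        if start < 0 or end > len(self.chroms[chrom]) or start > end:
            raise ValueError(
                f"window [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(self.chroms[chrom])})"
            )
        s = self.chroms[chrom][start:end]
        return reverse_complement(s) if strand == "-" else s

    def base_frequencies(self) -> Dict[str, float]:
        """Genome-wide mononucleotide frequencies over A/C/G/T (N excluded).

        These are the background frequencies g_i of the PAS scoring matrix.
        Both strands contribute equally, so A/T and C/G are averaged.
        """
        counts = {b: 0 for b in "ACGT"}
        for seq in self.chroms.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        plus = {b: counts[b] / total for b in "ACGT"}
        return {
            "A": (plus["A"] + plus["T"]) / 2,
            "T": (plus["A"] + plus["T"]) / 2,
            "C": (plus["C"] + plus["G"]) / 2,
            "G": (plus["C"] + plus["G"]) / 2,
        }


def load_genome(path: str) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Chromosome names are the header up to the first whitespace.  Duplicate
    names and empty files are hard errors.
    """
    chroms: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name in FASTA: {rec.id}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chroms)


def write_genome(genome: GenomeSequence, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class GeneAnnotation:
    """One gene, reduced to a single representative transcript.

    Intervals are genomic 0-based half-open.  ``cds_intervals`` are stored
    in ascending genomic order; use :meth:`cds_in_transcript_order` for
    5'->3' traversal on either strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: List[Tuple[int, int]]
    tx_start: int
    tx_end: int
    utr3_interval: Tuple[int, int]
    utr5_intervals: List[Tuple[int, int]] = field(default_factory=list)
    intron_intervals: List[Tuple[int, int]] = field(default_factory=list)
    frame_invalid: bool = False
    transcript_id: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def cds_start(self) -> int:
        return self.cds_intervals[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds_intervals[-1][1]

    @property
    def annotated_3p_end(self) -> int:
        """Genomic coordinate of the annotated transcript 3' end.

        Plus strand: half-open end of the transcript.  Minus strand: its
        (0-based) start, i.e. the first base in genomic coordinates.
        """
        return self.tx_end if self.strand == "+" else self.tx_start

    def cds_in_transcript_order(self) -> List[Tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds_intervals)
        return list(reversed(self.cds_intervals))

    def cds_sequence(self, genome: GenomeSequence) -> str:
        """Spliced CDS 5'->3'."""
        parts = [
            genome.fetch(self.chrom, s, e, self.strand)
            for s, e in self.cds_in_transcript_order()
        ]
        return "".join(parts)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 0-based offset within the spliced CDS.

        Returns None if the position is not inside a CDS exon.
        """
        offset = 0
        for s, e in self.cds_in_transcript_order():
            if s <= pos < e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - 1 - pos)
            offset += e - s
        return None

    def contains_in_cds(self, start: int, end: int) -> bool:
        """True iff the genomic interval [start, end) lies fully inside the
        CDS exon union (no intron crossing)."""
        for s, e in self.cds_intervals:
            if s <= start and end <= e:
                return True
        return False


def _derive_intervals(
    strand: str,
    chrom_len: Optional[int],
    cds: List[Tuple[int, int]],
    tx_start: int,
    tx_end: int,
    utr_extension: int,
) -> Tuple[Tuple[int, int], List[Tuple[int, int]], List[Tuple[int, int]]]:
    """3'UTR search interval, 5'UTR intervals and introns for one gene."""
    introns = [
        (cds[i][1], cds[i + 1][0]) for i in range(len(cds) - 1) if cds[i][1] < cds[i + 1][0]
    ]
    hi = chrom_len if chrom_len is not None else tx_end + utr_extension
    if strand == "+":
        utr3 = (cds[-1][1], min(hi, tx_end + utr_extension))
        utr5 = [(tx_start, cds[0][0])] if tx_start < cds[0][0] else []
    else:
        utr3 = (max(0, tx_start - utr_extension), cds[0][0])
        utr5 = [(cds[-1][1], tx_end)] if cds[-1][1] < tx_end else []
    return utr3, introns, utr5


def load_annotation(
    path: str,
    utr_extension: int = 1000,
    genome: Optional[GenomeSequence] = None,
) -> List[GeneAnnotation]:
    """Load gene models from a GTF/GFF file.

    One :class:`GeneAnnotation` per gene, using the representative transcript
    with the longest CDS (ties broken by lexicographically smallest
    transcript id).  The 3'UTR search interval runs from the CDS end to the
    annotated transcript 3' end plus ``utr_extension`` (default 1 kb),
    clipped at chromosome bounds when a genome is supplied.

    Genes whose CDS length is not a multiple of 3 are flagged
    ``frame_invalid``: they still participate in site classification but are
    excluded from codon statistics.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneAnnotation] = []
    # Group CDS by transcript; transcripts by gene.
    tx_cds: Dict[str, List[Tuple[int, int]]] = {}
    tx_gene: Dict[str, str] = {}
    tx_meta: Dict[str, Tuple[str, str]] = {}
    for cds in db.features_of_type("CDS"):
        tid = cds.attributes.get("transcript_id", [None])[0]
        if tid is None:
            parents = cds.attributes.get("Parent", [])
            tid = parents[0] if parents else None
        if tid is None:
            raise ValueError(f"CDS feature without transcript_id/Parent at {cds.seqid}:{cds.start}")
        gid = cds.attributes.get("gene_id", [tid])[0]
        tx_cds.setdefault(tid, []).append((cds.start - 1, cds.end))
        tx_gene[tid] = gid
        tx_meta[tid] = (cds.seqid, cds.strand)

    # Transcript extents: explicit transcript/mRNA features, else exon union,
    # else CDS union.
    tx_extent: Dict[str, Tuple[int, int]] = {}
    explicit: set = set()
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            tid = f.attributes.get("transcript_id", [f.id])[0]
            tx_extent[tid] = (f.start - 1, f.end)
            explicit.add(tid)
    for ex in db.features_of_type("exon"):
        tid = ex.attributes.get("transcript_id", [None])[0]
        if tid is None:
            parents = ex.attributes.get("Parent", [])
            tid = parents[0] if parents else None
        if tid is None or tid in explicit:
            continue
        s, e = ex.start - 1, ex.end
        cur = tx_extent.get(tid)
        tx_extent[tid] = (min(cur[0], s), max(cur[1], e)) if cur else (s, e)

    by_gene: Dict[str, List[str]] = {}
    for tid, gid in tx_gene.items():
        by_gene.setdefault(gid, []).append(tid)

    for gid in sorted(by_gene):
        # representative transcript: longest CDS, tie -> lexicographic id
        tid = min(
            by_gene[gid],
            key=lambda t: (-sum(e - s for s, e in tx_cds[t]), t),
        )
        cds = sorted(tx_cds[tid])
        chrom, strand = tx_meta[tid]
        ts, te = tx_extent.get(tid, (cds[0][0], cds[-1][1]))
        chrom_len = genome.length(chrom) if genome is not None and chrom in genome else None
        utr3, introns, utr5 = _derive_intervals(strand, chrom_len, cds, ts, te, utr_extension)
        length = sum(e - s for s, e in cds)
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                cds_intervals=cds,
                tx_start=ts,
                tx_end=te,
                utr3_interval=utr3,
                utr5_intervals=utr5,
                intron_intervals=introns,
                frame_invalid=(length % 3 != 0),
                transcript_id=tid,
            )
        )
    return genes


class EndCoverage:
    """Read 3'-end counts per (chromosome, strand) -> {position: count}."""

    def __init__(self):
        self.data: Dict[Tuple[str, str], Dict[int, int]] = {}

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if count <= 0:
            raise ValueError("counts must be positive")
        d = self.data.setdefault((chrom, strand), {})
        d[pos] = d.get(pos, 0) + count

    def get(self, chrom: str, strand: str) -> Dict[int, int]:
        return self.data.get((chrom, strand), {})

    def keys(self):
        return self.data.keys()

    @property
    def total_reads(self) -> int:
        return sum(c for d in self.data.values() for c in d.values())

    def positions(self) -> Iterable[Tuple[str, str, int, int]]:
        for (chrom, strand), d in sorted(self.data.items()):
            for pos in sorted(d):
                yield chrom, strand, pos, d[pos]


def load_end_coverage(
    plus_bedgraph: Optional[str] = None,
    minus_bedgraph: Optional[str] = None,
    bed: Optional[str] = None,
) -> EndCoverage:
    """Load 3'-end coverage from per-strand bedgraphs or a 6-column BED.

    bedgraph intervals may span several bases (each base gets the interval's
    count); BED records must be single-base 3'-end intervals, anything longer
    is rejected with the offending line.
    """
    cov = EndCoverage()
    if bed is not None:
        with open(bed) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"{bed}:{lineno}: 6 columns required for 3'-end BED")
                chrom, start, end, _name, score, strand = f[:6]
                start, end = int(start), int(end)
                if end - start != 1:
                    raise ValueError(
                        f"{bed}:{lineno}: 3'-end BED interval must be 1 bp, got "
                        f"{end - start} ({line})"
                    )
                cov.add(chrom, strand, start, int(float(score)) if score != "." else 1)
        return cov
    for path, strand in ((plus_bedgraph, "+"), (minus_bedgraph, "-")):
        if path is None:
            continue
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, count = line.split("\t")[:4]
                c = int(float(count))
                if c <= 0:
                    continue
                for pos in range(int(start), int(end)):
                    cov.add(chrom, strand, pos, c)
    return cov


def write_end_coverage(cov: EndCoverage, plus_path: str, minus_path: str) -> None:
    """Write per-strand bedgraph files (single-base intervals, sorted)."""
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        for chrom, strand, pos, count in cov.positions():
            handles[strand].write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")
    finally:
        for h in handles.values():
            h.close()


def upstream_window(summit: int, strand: str, up: int, down: int) -> Tuple[int, int]:
    """Genomic half-open interval of positions -up..-down upstream of a summit.

    ``up`` and ``down`` are positive offsets in transcript orientation
    (e.g. up=30, down=10 gives the 21-nt A-rich PAS window).
    """
    if up < down:
        raise ValueError("expected up >= down")
    if strand == "+":
        return summit - up, summit - down + 1
    return summit + down, summit + up + 1


def flank_window(summit: int, strand: str, upstream: int, downstream: int) -> Tuple[int, int]:
    """Genomic half-open interval covering -upstream..+downstream around a
    position, in transcript orientation."""
    if strand == "+":
        return summit - upstream, summit + downstream + 1
    return summit - downstream, summit + upstream + 1
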