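"""Codon usage indices and codon enrichment around ORF poly(A) sites.

Genome-wide codon counts give each codon its relative synonymous codon
adaptiveness (RSCA: count divided by the count of the most abundant
synonymous codon, so every family's top codon has RSCA 1).  Per-gene
indices follow: the codon bias index

    CBI = (N_opt - N_ran) / (N_tot - N_ran)

with optimal / random / rare codon classes at RSCA thresholds 0.9 and
0.3, and the codon adaptation index CAI, the geometric mean of RSCA over
a gene's codons.

Enrichment statistics compare the in-frame codons (and adjacent codon
pairs) of ORF PAS regions against matched random stretches of the same
genes (NCUF / NCPF), and the 15-codon flanks of true versus false ORF
PAS motif occurrences (RCUF); all are log2 frequency ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GeneAnnotation, GenomeSequence

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: Dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = set(_TABLE.stop_codons)
ALL_CODONS = sorted(CODON_TO_AA)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
FAMILIES: Dict[str, List[str]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_c], []).append(_c)
SINGLE_CODON = {c for aa, fam in FAMILIES.items() if len(fam) == 1 for c in fam}  # ATG, TGG


@dataclass
class CodonUsageTable:
    counts: Dict[str, int]
    rsca: Dict[str, float]  # per sense codon; NaN for families with zero total

    def codon_class(self, codon: str) -> Optional[str]:
        """optimal (RSCA >= 0.9) | random (0.3 < RSCA < 0.9) | rare (< 0.3)."""
        w = self.rsca.get(codon)
        if w is None or math.isnan(w):
            return None
        if w >= 0.9:
            return "optimal"
        if w > 0.3:
            return "random"
        return "rare"


def count_codons(cds_sequences: Sequence[str]) -> Dict[str, int]:
    """Codon counts over in-frame CDS sequences; stop codons counted but
    excluded from index computation downstream; codons with N skipped."""
    counts = {c: 0 for c in ALL_CODONS}
    for cds in cds_sequences:
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            cod = cds[i : i + 3]
            if cod in counts:
                counts[cod] += 1
    return counts


def compute_rsca(counts: Dict[str, int], pseudo_floor: float = 0.5) -> CodonUsageTable:
    """Per-family max-normalized codon adaptiveness.

    Codons absent genome-wide get a pseudo-floor count so that RSCA stays in
    (0, 1] and the geometric mean of CAI is defined; families with zero
    total get NaN.
    """
    rsca: Dict[str, float] = {}
    for fam in FAMILIES.values():
        mx = max(counts.get(c, 0) for c in fam)
        for c in fam:
            if mx == 0:
                rsca[c] = float("nan")
            else:
                rsca[c] = max(counts.get(c, 0), pseudo_floor) / mx
    return CodonUsageTable(counts=dict(counts), rsca=rsca)


def genome_usage_table(genes: Sequence[GeneAnnotation], genome: GenomeSequence) -> CodonUsageTable:
    """RSCA table from all frame-valid annotated ORFs of a genome."""
    seqs = [g.cds_sequence(genome) for g in genes if not g.frame_invalid]
    return compute_rsca(count_codons(seqs))


@dataclass
class GeneCodonIndices:
    gene_id: str
    cbi: float
    cai: float
    n_opt: int
    n_ran: int
    n_tot: int


def _gene_codons(cds: str) -> List[str]:
    cds = cds.upper()
    return [
        cds[i : i + 3]
        for i in range(0, len(cds) - len(cds) % 3, 3)
        if cds[i : i + 3] in CODON_TO_AA and cds[i : i + 3] not in STOP_CODONS
    ]


def compute_cbi(cds: str, table: CodonUsageTable) -> Tuple[float, int, int, int]:
    """(CBI, N_opt, N_ran, N_tot) for one CDS.

    Codons with no synonymous alternative (Met, Trp) and stop codons carry
    no usage information and are excluded from the counts; CBI is NaN when
    N_tot == N_ran.
    """
    n_opt = n_ran = n_tot = 0
    for cod in _gene_codons(cds):
        if cod in SINGLE_CODON:
            continue
        cls = table.codon_class(cod)
        if cls is None:
            continue
        n_tot += 1
        if cls == "optimal":
            n_opt += 1
        elif cls == "random":
            n_ran += 1
    if n_tot == n_ran or n_tot == 0:
        return float("nan"), n_opt, n_ran, n_tot
    return (n_opt - n_ran) / (n_tot - n_ran), n_opt, n_ran, n_tot


def cbi_from_counts(n_opt: int, n_ran: int, n_tot: int) -> float:
    """CBI = (N_opt - N_ran)/(N_tot - N_ran) from precomputed class counts."""
    if n_tot == n_ran:
        return float("nan")
    return (n_opt - n_ran) / (n_tot - n_ran)


def compute_cai(cds: str, table: CodonUsageTable) -> float:
    """Geometric mean of RSCA over the gene's (non-stop) codons, computed in
    log domain; NaN if no codon has a defined RSCA."""
    logs = []
    for cod in _gene_codons(cds):
        w = table.rsca.get(cod)
        if w is not None and not math.isnan(w):
            logs.append(math.log(w))
    if not logs:
        return float("nan")
    return math.exp(sum(logs) / len(logs))


def gene_codon_indices(
    genes: Sequence[GeneAnnotation], genome: GenomeSequence, table: Optional[CodonUsageTable] = None
) -> List[GeneCodonIndices]:
    """Per-gene CBI and CAI for all frame-valid genes."""
    valid = [g for g in genes if not g.frame_invalid]
    if table is None:
        table = compute_rsca(count_codons([g.cds_sequence(genome) for g in valid]))
    out = []
    for g in valid:
        cds = g.cds_sequence(genome)
        cbi, n_opt, n_ran, n_tot = compute_cbi(cds, table)
        out.append(GeneCodonIndices(g.gene_id, cbi, compute_cai(cds, table), n_opt, n_ran, n_tot))
    return out


# ---------------------------------------------------------------------------
# PAS-region codon enrichment (NCUF / NCPF)
# ---------------------------------------------------------------------------

def _window_cds_codons(gene: GeneAnnotation, genome: GenomeSequence, window: Tuple[int, int]) -> Optional[Tuple[List[str], int, int]]:
    """In-frame codons fully inside a genomic window within the CDS.

    Returns (codons, first_codon_index, n_codons) in CDS coordinates, or
    None if the window does not map cleanly into the CDS exon union.
    """
    a, b = window
    if gene.strand == "+":
        lo, hi = gene.genomic_to_cds(a), gene.genomic_to_cds(b - 1)
    else:
        lo, hi = gene.genomic_to_cds(b - 1), gene.genomic_to_cds(a)
    if lo is None or hi is None:
        return None
    local_start, local_end = lo, hi + 1
    first = (local_start + 2) // 3
    last_end = local_end // 3
    if last_end <= first:
        return None
    cds = gene.cds_sequence(genome)
    codons = [cds[i * 3 : i * 3 + 3] for i in range(first, last_end)]
    return codons, first, last_end - first


def _log2_ratio_table(
    fg: Dict[str, int], bg: Dict[str, int], keys: Sequence[str], column: str
) -> pd.DataFrame:
    fg_tot = sum(fg.values())
    bg_tot = sum(bg.values())
    rows = []
    for k in keys:
        f, b = fg.get(k, 0), bg.get(k, 0)
        ff = f / fg_tot if fg_tot else 0.0
        bf = b / bg_tot if bg_tot else 0.0
        flagged = f == 0 or b == 0
        rows.append(
            {
                column: k,
                "fg_count": f,
                "fg_freq": ff,
                "bg_count": b,
                "bg_freq": bf,
                "log2_ratio": math.log2(ff / bf) if not flagged else float("nan"),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def _pas_enrichment(
    orf_sites,
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    n_random: int,
    seed: Optional[int],
    pairs: bool,
) -> pd.DataFrame:
    """Shared worker for NCUF (codons) and NCPF (adjacent in-frame pairs)."""
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    fg: Dict[str, int] = {}
    bg: Dict[str, int] = {}

    sense = set(SENSE_CODONS)

    def tally(d: Dict[str, int], codons: List[str]) -> None:
        # stop codons and N-containing triplets carry no usage information
        if pairs:
            items = [
                codons[i] + codons[i + 1]
                for i in range(len(codons) - 1)
                if codons[i] in sense and codons[i + 1] in sense
            ]
        else:
            items = [c for c in codons if c in sense]
        for it in items:
            d[it] = d.get(it, 0) + 1

    for site in orf_sites:
        gene = by_id.get(site.gene_id)
        if gene is None or gene.frame_invalid or site.pas_window is None:
            continue
        mapped = _window_cds_codons(gene, genome, site.pas_window)
        if mapped is None:
            continue
        codons, first, n_cod = mapped
        if pairs and n_cod < 2:
            continue
        tally(fg, codons)
        cds = gene.cds_sequence(genome)
        n_gene_codons = len(cds) // 3
        valid_starts = [
            j
            for j in range(0, n_gene_codons - n_cod + 1)
            if j + n_cod <= first or j >= first + n_cod  # avoid the PAS window itself
        ]
        if not valid_starts:
            continue
        for j in rng.choice(valid_starts, size=n_random, replace=True):
            stretch = [cds[(j + k) * 3 : (j + k) * 3 + 3] for k in range(n_cod)]
            tally(bg, stretch)
    keys = (
        [a + b for a in SENSE_CODONS for b in SENSE_CODONS]
        if pairs
        else list(SENSE_CODONS)
    )
    # restrict the report to items seen in either set to keep tables small
    seen = [k for k in keys if fg.get(k, 0) or bg.get(k, 0)]
    col = "codon_pair" if pairs else "codon"
    return _log2_ratio_table(fg, bg, seen if pairs else keys, col)


def ncuf(
    orf_sites,
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    n_random: int = 10,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Normalized codon usage frequency of ORF PAS regions.

    Foreground: in-frame codons fully inside each site's PAS window.
    Background: ``n_random`` random same-codon-count stretches per site drawn
    from the same ORF (outside the window).  log2(fg/bg) per codon; zero
    counts are flagged rather than reported as infinite.
    """
    return _pas_enrichment(orf_sites, genes, genome, n_random, seed, pairs=False)


def ncpf(
    orf_sites,
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    n_random: int = 10,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Normalized codon *pair* usage frequency (adjacent in-frame pairs) of
    ORF PAS regions; same scheme as :func:`ncuf`."""
    return _pas_enrichment(orf_sites, genes, genome, n_random, seed, pairs=True)


# ---------------------------------------------------------------------------
# True/false PAS occurrences, RCUF and A/T content
# ---------------------------------------------------------------------------

@dataclass
class PASOccurrence:
    motif: str  # DNA alphabet
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic half-open interval of the hexamer
    end: int
    context: str  # ORF | UTR3
    is_true: bool

    @property
    def motif_end_genomic(self) -> int:
        """Genomic coordinate of the motif's last base in transcript
        orientation."""
        return self.end - 1 if self.strand == "+" else self.start


def _scan_region(seq: str, motif: str) -> List[int]:
    """Start offsets of every motif occurrence in a string (overlapping)."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def classify_true_false_pas(
    motifs: Sequence[str],
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    summits: Sequence[Tuple[str, str, int]],
    window_min: int = 5,
    window_max: int = 35,
) -> List[PASOccurrence]:
    """Locate PAS motif occurrences in ORFs and 3'UTRs and label them true
    or false.

    A motif occurrence is *true* when at least one called poly(A) summit on
    the same strand lies ``window_min``..``window_max`` nt (default 5-35)
    downstream of the motif's 3' end in transcript orientation.  ORF
    occurrences must lie fully inside a single CDS exon; 3'UTR occurrences
    inside the gene's 3'UTR search interval.  Motifs are given in DNA
    alphabet (T, not U).
    """
    summit_set: Dict[Tuple[str, str], List[int]] = {}
    for chrom, strand, pos in summits:
        summit_set.setdefault((chrom, strand), []).append(pos)
    for v in summit_set.values():
        v.sort()

    def is_true(chrom: str, strand: str, motif_end: int) -> bool:
        arr = summit_set.get((chrom, strand))
        if not arr:
            return False
        if strand == "+":
            lo, hi = motif_end + window_min, motif_end + window_max
        else:
            lo, hi = motif_end - window_max, motif_end - window_min
        i = int(np.searchsorted(arr, lo))
        return bool(i < len(arr) and arr[i] <= hi)

    out: List[PASOccurrence] = []
    motifs = [m.upper().replace("U", "T") for m in motifs]
    for g in genes:
        regions: List[Tuple[str, Tuple[int, int]]] = [
            ("ORF", iv) for iv in g.cds_intervals
        ]
        s, e = g.utr3_interval
        s, e = max(0, s), min(genome.length(g.chrom), e)
        if e - s >= 6:
            regions.append(("UTR3", (s, e)))
        for context, (rs, re_) in regions:
            if re_ - rs < 6:
                continue
            seq = genome.fetch(g.chrom, rs, re_, g.strand)
            for m in motifs:
                for off in _scan_region(seq, m):
                    if g.strand == "+":
                        start = rs + off
                    else:
                        start = re_ - off - 6
                    end = start + 6
                    me = end - 1 if g.strand == "+" else start
                    out.append(
                        PASOccurrence(
                            motif=m,
                            gene_id=g.gene_id,
                            chrom=g.chrom,
                            strand=g.strand,
                            start=start,
                            end=end,
                            context=context,
                            is_true=is_true(g.chrom, g.strand, me),
                        )
                    )
    return out


def rcuf(
    occurrences: Sequence[PASOccurrence],
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    flank_codons: int = 15,
) -> pd.DataFrame:
    """Relative codon usage frequency around true vs false ORF PAS motifs.

    For every ORF occurrence the in-frame codons fully inside the 15-codon
    flanks upstream and downstream of the motif (clipped at CDS bounds) are
    pooled per truth class; RCUF = log2(freq_true / freq_false) per codon.
    Raises if either truth class is empty.
    """
    by_id = {g.gene_id: g for g in genes}
    counts = {True: {}, False: {}}
    n_occ = {True: 0, False: 0}
    for occ in occurrences:
        if occ.context != "ORF":
            continue
        gene = by_id.get(occ.gene_id)
        if gene is None or gene.frame_invalid:
            continue
        if gene.strand == "+":
            lo = gene.genomic_to_cds(occ.start)
            hi = gene.genomic_to_cds(occ.end - 1)
        else:
            lo = gene.genomic_to_cds(occ.end - 1)
            hi = gene.genomic_to_cds(occ.start)
        if lo is None or hi is None:
            continue
        cds = gene.cds_sequence(genome)
        n_cod = len(cds) // 3
        flank_nt = flank_codons * 3
        up_start = max(0, lo - flank_nt)
        first_up = (up_start + 2) // 3
        last_up = lo // 3  # codons fully upstream of the motif start
        down_end = min(len(cds), hi + 1 + flank_nt)
        first_down = (hi + 1 + 2) // 3
        last_down = down_end // 3
        codons = [cds[i * 3 : i * 3 + 3] for i in range(first_up, last_up)] + [
            cds[i * 3 : i * 3 + 3] for i in range(first_down, min(last_down, n_cod))
        ]
        d = counts[occ.is_true]
        n_occ[occ.is_true] += 1
        for c in codons:
            if c in CODON_TO_AA and c not in STOP_CODONS:
                d[c] = d.get(c, 0) + 1
    if n_occ[True] == 0 or n_occ[False] == 0:
        raise ValueError("both true and false ORF PAS occurrences are required for RCUF")
    df = _log2_ratio_table(counts[True], counts[False], SENSE_CODONS, "codon")
    return df.rename(
        columns={
            "fg_count": "true_count",
            "fg_freq": "true_freq",
            "bg_count": "false_count",
            "bg_freq": "false_freq",
        }
    )


def at_content_profile(
    occurrences: Sequence[PASOccurrence],
    genome: GenomeSequence,
    flank_nt: int = 80,
):
    """A/T content of the flanks of PAS motif occurrences, per truth class.

    Returns {True/False: (NucleotideProfile, mean_at)} over windows of
    ``flank_nt`` on each side of the hexamer (edge-clipped windows are
    excluded).  Positions are relative to the motif's 3' end.
    """
    from .pas_motifs import nucleotide_profile

    out = {}
    for truth in (True, False):
        sites = [
            (o.chrom, o.strand, o.motif_end_genomic)
            for o in occurrences
            if o.is_true is truth
        ]
        prof = nucleotide_profile(sites, genome, upstream=flank_nt + 5, downstream=flank_nt)
        at = prof.at_content()
        mean_at = float(np.mean(at)) if prof.n_sequences else float("nan")
        out[truth] = (prof, mean_at)
    return out
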