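"""Poly(A)-site calling: clustering of 3'-end positions, summit calls,
genomic classification, and per-gene premature-termination quantities.

Occupied 3'-end positions on one chromosome strand are chained
transitively while consecutive positions are at most ``merge_gap``
(default 24) nt apart; clusters with fewer than ``min_reads`` (default 5)
reads are dropped and each retained cluster's summit (highest-count
position, ties resolved 5'-most in transcript orientation) is the called
poly(A) site.  Sites are then classified against gene models with
precedence 3'UTR > ORF > intron > 5'UTR > intergenic; the ORF class
additionally requires the species' PAS window upstream of the summit to
lie entirely within the CDS exon union.  Gene-level output is the
normalized ORF/3'UTR termination ratio

    ratio = N_ORF * 1000 / (N_3'UTR * L)

with L the CDS length in nt, together with the 3'UTR signal in reads per
million (RPM) for expression filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_io import EndCoverage, GeneAnnotation, upstream_window


@dataclass
class PolyACluster:
    chrom: str
    strand: str
    start: int  # first occupied position
    end: int  # last occupied position (inclusive)
    count: int  # total reads
    summit: int  # called pA site
    summit_count: int


@dataclass
class ClassifiedSite:
    cluster: PolyACluster
    gene_id: Optional[str]
    site_class: str  # UTR3 | ORF | intron | UTR5 | intergenic
    pas_window: Optional[Tuple[int, int]] = None
    ambiguous: bool = False


@dataclass
class GeneTermination:
    gene_id: str
    n_orf_reads: int
    n_utr3_reads: int
    n_orf_events: int
    n_utr3_events: int
    cds_length: int
    rpm: float
    ratio: float
    log10_ratio: float  # NaN when ratio == 0


def cluster_ends(
    coverage: EndCoverage, merge_gap: int = 24, min_reads: int = 5
) -> List[PolyACluster]:
    """Cluster occupied 3'-end positions into peaks and call summits.

    Returns retained clusters (count >= ``min_reads``) sorted by
    (chrom, strand, start).
    """
    clusters: List[PolyACluster] = []
    for (chrom, strand), posmap in sorted(coverage.data.items()):
        positions = sorted(posmap)
        if not positions:
            continue
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= merge_gap:
                run.append(p)
            else:
                clusters.append(_make_cluster(chrom, strand, run, posmap))
                run = [p]
        clusters.append(_make_cluster(chrom, strand, run, posmap))
    return [c for c in clusters if c.count >= min_reads]


def _make_cluster(chrom: str, strand: str, run: List[int], posmap: Dict[int, int]) -> PolyACluster:
    total = sum(posmap[p] for p in run)
    best = max(posmap[p] for p in run)
    candidates = [p for p in run if posmap[p] == best]
    # summit tie-break: 5'-most in transcript orientation
    summit = min(candidates) if strand == "+" else max(candidates)
    return PolyACluster(chrom, strand, run[0], run[-1], total, summit, posmap[summit])


def _interval_contains(intervals: Sequence[Tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_site(
    cluster: PolyACluster,
    genes: Sequence[GeneAnnotation],
    pas_window_up: int = 30,
    pas_window_down: int = 10,
) -> ClassifiedSite:
    """Assign a called site to a gene and genomic class.

    ``pas_window_up``/``pas_window_down`` give the species PAS region
    (-up..-down nt upstream of the summit).  Class precedence within a gene
    is UTR3 > ORF > intron > UTR5; a summit claimable by two or more
    same-strand genes at its winning class keeps the class but is marked
    ambiguous and excluded from gene-level statistics.
    """
    summit = cluster.summit
    win = upstream_window(summit, cluster.strand, pas_window_up, pas_window_down)
    order = {"UTR3": 0, "ORF": 1, "intron": 2, "UTR5": 3}
    claims: List[Tuple[int, str]] = []  # (precedence, gene_id)
    for g in genes:
        if g.chrom != cluster.chrom or g.strand != cluster.strand:
            continue
        cls = None
        s, e = g.utr3_interval
        if s <= summit < e:
            cls = "UTR3"
        elif _interval_contains(g.cds_intervals, summit) and g.contains_in_cds(*win):
            cls = "ORF"
        elif _interval_contains(g.intron_intervals, summit):
            cls = "intron"
        elif _interval_contains(g.utr5_intervals, summit):
            cls = "UTR5"
        if cls is not None:
            claims.append((order[cls], g.gene_id))
    if not claims:
        return ClassifiedSite(cluster, None, "intergenic")
    best = min(c[0] for c in claims)
    winners = sorted(g for o, g in claims if o == best)
    cls = {v: k for k, v in order.items()}[best]
    return ClassifiedSite(
        cluster,
        winners[0],
        cls,
        pas_window=win if cls == "ORF" else None,
        ambiguous=len(winners) > 1,
    )


def major_utr3_site(utr3_clusters: Sequence[PolyACluster]) -> Optional[PolyACluster]:
    """The gene's major poly(A) site: the 3'UTR cluster with the highest
    summit count; ties resolved to the most 3' summit in transcript
    orientation.  Returns None for an empty input."""
    if not utr3_clusters:
        return None
    best = max(c.summit_count for c in utr3_clusters)
    cands = [c for c in utr3_clusters if c.summit_count == best]
    if cands[0].strand == "+":
        return max(cands, key=lambda c: c.summit)
    return min(cands, key=lambda c: c.summit)


def gene_termination_table(
    sites: Sequence[ClassifiedSite],
    genes: Sequence[GeneAnnotation],
    library_size: int,
    count_mode: str = "reads",
) -> List[GeneTermination]:
    """Per-gene ORF/3'UTR termination quantities.

    ``library_size`` is the total number of filtered pA-supporting reads and
    sets the RPM scale.  ``count_mode`` selects whether the normalized ratio
    uses read counts (default) or pA-event (cluster) counts.  Genes with no
    3'UTR signal are omitted (the ratio is undefined); ambiguous sites are
    skipped.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count_mode not in ("reads", "events"):
        raise ValueError("count_mode must be 'reads' or 'events'")
    per_gene: Dict[str, Dict[str, int]] = {}
    for s in sites:
        if s.gene_id is None or s.ambiguous or s.site_class not in ("UTR3", "ORF"):
            continue
        d = per_gene.setdefault(
            s.gene_id, {"orf_reads": 0, "utr3_reads": 0, "orf_events": 0, "utr3_events": 0}
        )
        if s.site_class == "ORF":
            d["orf_reads"] += s.cluster.count
            d["orf_events"] += 1
        else:
            d["utr3_reads"] += s.cluster.count
            d["utr3_events"] += 1
    gene_len = {g.gene_id: g.cds_length for g in genes}
    out: List[GeneTermination] = []
    for gid, d in sorted(per_gene.items()):
        if d["utr3_reads"] == 0 or gid not in gene_len:
            continue
        L = gene_len[gid]
        if count_mode == "reads":
            n_orf, n_utr3 = d["orf_reads"], d["utr3_reads"]
        else:
            n_orf, n_utr3 = d["orf_events"], d["utr3_events"]
        ratio = n_orf * 1000 / (n_utr3 * L)
        out.append(
            GeneTermination(
                gene_id=gid,
                n_orf_reads=d["orf_reads"],
                n_utr3_reads=d["utr3_reads"],
                n_orf_events=d["orf_events"],
                n_utr3_events=d["utr3_events"],
                cds_length=L,
                rpm=1e6 * d["utr3_reads"] / library_size,
                ratio=ratio,
                log10_ratio=math.log10(ratio) if ratio > 0 else float("nan"),
            )
        )
    return out
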