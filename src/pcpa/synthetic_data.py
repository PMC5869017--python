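"""Seed-deterministic synthetic genomes, annotations and 3'-end reads.

The generator emulates the statistical structure the analysis assumes:
protein-coding genes whose synonymous-codon choice is governed by a
per-gene wobble-position G/C bias beta (the probability of picking a
G/C-ending codon within a family), a 3'UTR cleavage site with a PAS
hexamer implanted a fixed distance upstream, an optional premature
cleavage site inside the ORF whose in-frame implanted hexamer mimics a
PAS formed by rare codons, read 3'-ends dispersed around each site by a
two-sided geometric, and internal-priming artifacts: reads whose 3' ends
sit immediately upstream of implanted genomic A-runs.

In the default ``inverse_bias`` mode the relative usage of the ORF site
scales with (1 - beta), so rare-codon-rich (AT-wobble) genes terminate
prematurely more often — the condition under which codon bias and
premature termination are negatively correlated.  True cleavage sites
are given downstream sequence that does not itself trigger the
internal-priming rule; a genuine site inside a genomic A-run would be
indistinguishable from an artifact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import EndCoverage, GeneAnnotation, GenomeSequence, _derive_intervals
from .read_processing import is_internal_priming

from .codon_stats import FAMILIES

_GC_ENDING = {aa: [c for c in fam if c[2] in "GC"] for aa, fam in FAMILIES.items()}
_AT_ENDING = {aa: [c for c in fam if c[2] in "AT"] for aa, fam in FAMILIES.items()}
_AA_UNIFORM = sorted(a for a in FAMILIES if a != "*")
# AT-rich preset: enrich Ile/Lys/Asn/Tyr, whose codons are A/T-heavy
_AA_AT_RICH = _AA_UNIFORM + ["I", "K", "N", "Y"] * 3


@dataclass
class SyntheticSpec:
    """Parameters of the simulated genome and read set."""

    n_genes: int = 80
    cds_codons: Tuple[int, int] = (150, 350)  # uniform range, codons (excl. start/stop)
    utr5_len: Tuple[int, int] = (20, 60)
    utr3_len: Tuple[int, int] = (150, 300)
    intergenic: Tuple[int, int] = (300, 600)
    beta: Tuple[float, float] = (0.2, 0.9)  # per-gene wobble G/C bias range
    aa_preset: str = "uniform"  # uniform | at_rich
    expression_mean: float = 400.0  # mean reads at the major 3'UTR site
    expression_sigma: float = 0.5  # lognormal spread of per-gene expression
    utr3_motif: str = "AATAAA"
    pas_offset: int = 18  # nt from motif 3' end to the cleavage site
    orf_sites_per_gene: int = 1
    orf_rel_usage: float = 0.08  # ORF site usage relative to the 3'UTR site
    orf_usage_mode: str = "inverse_bias"  # inverse_bias | uniform | none
    dispersion: float = 2.0  # mean |3'-end offset| (two-sided geometric)
    artifact_rate: float = 0.5  # expected artifact positions per gene
    artifact_site_reads: float = 8.0  # mean reads per artifact position
    artifact_run_len: int = 8
    seed: int = 0


@dataclass
class TrueSite:
    gene_id: str
    site_class: str  # UTR3 | ORF
    chrom: str
    strand: str
    position: int  # genomic coordinate of the last transcribed base
    usage: float  # relative usage (3'UTR major site = 1.0)
    beta: float
    drawn_count: int = 0


@dataclass
class MotifImplant:
    gene_id: str
    context: str  # UTR3 | ORF
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class GroundTruth:
    sites: List[TrueSite] = field(default_factory=list)
    motifs: List[MotifImplant] = field(default_factory=list)
    artifact_positions: List[Tuple[str, str, int]] = field(default_factory=list)
    gene_beta: Dict[str, float] = field(default_factory=dict)
    gene_expression: Dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _sample_codon(rng: np.random.Generator, aa: str, beta: float) -> str:
    gc, at = _GC_ENDING[aa], _AT_ENDING[aa]
    if gc and at:
        pool = gc if rng.random() < beta else at
    else:
        pool = gc or at
    return pool[rng.integers(0, len(pool))]


def _sample_cds(rng: np.random.Generator, n_codons: int, beta: float, preset: str) -> str:
    aas = _AA_AT_RICH if preset == "at_rich" else _AA_UNIFORM
    body = "".join(
        _sample_codon(rng, aas[rng.integers(0, len(aas))], beta) for _ in range(n_codons)
    )
    return "ATG" + body + "TAA"


def _clean_downstream(rng: np.random.Generator, first_base_non_a: bool = True) -> str:
    """A 20-mer that does not trigger the internal-priming rule (and, by
    default, does not start with A, so at least one simulated tail A is
    always untemplated)."""
    for _ in range(1000):
        s = _random_seq(rng, 20)
        if first_base_non_a and s[0] == "A":
            continue
        if not is_internal_priming(s):
            return s
    raise RuntimeError("could not sample a clean downstream 20-mer")


def generate_genome(
    spec: SyntheticSpec,
) -> Tuple[GenomeSequence, List[GeneAnnotation], GroundTruth]:
    """Build the synthetic chromosome, gene models and ground truth.

    Deterministic under ``spec.seed``: identical specs yield byte-identical
    FASTA/GTF output.  Genes alternate between the two strands and never
    overlap.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    genes: List[GeneAnnotation] = []
    chrom = "chr1"
    parts: List[str] = []
    intergenic_ivs: List[Tuple[int, int]] = []
    offset = 0

    def spacer() -> None:
        nonlocal offset
        n = int(rng.integers(spec.intergenic[0], spec.intergenic[1] + 1))
        parts.append(_random_seq(rng, n))
        intergenic_ivs.append((offset, offset + n))
        offset += n

    lo_b, hi_b = spec.beta
    for gi in range(spec.n_genes):
        spacer()
        gid = f"g{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        beta = float(rng.uniform(lo_b, hi_b))
        n_cod = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
        utr5 = _random_seq(rng, int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1)))
        utr3_n = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
        utr3 = list(_random_seq(rng, utr3_n))
        cds = list(_sample_cds(rng, n_cod, beta, spec.aa_preset))
        cds_len = len(cds)
        m = len(spec.utr3_motif)

        # 3'UTR cleavage site: last transcribed base at local (UTR3) index c.
        c = int(rng.integers(60, utr3_n - 40))
        ms = c - spec.pas_offset - m + 1  # motif start (local); 3' end pas_offset nt upstream of c
        utr3[ms : ms + m] = list(spec.utr3_motif)
        clean = _clean_downstream(rng)
        utr3[c + 1 : c + 21] = list(clean)[: utr3_n - c - 1]

        # optional ORF site: implant the hexamer in frame (2 codons) and
        # place the cleavage site pas_offset nt downstream of the motif end.
        orf_local: Optional[int] = None
        orf_usage = 0.0
        if spec.orf_usage_mode != "none" and spec.orf_sites_per_gene > 0 and m == 6:
            j = int(rng.integers(20, n_cod - 30))  # codon index within body
            mstart = 3 + j * 3  # in-frame nt offset inside CDS
            cds[mstart : mstart + 6] = list(spec.utr3_motif)
            orf_local = mstart + 6 + spec.pas_offset - 1  # last transcribed base
            if spec.orf_usage_mode == "inverse_bias":
                orf_usage = spec.orf_rel_usage * 2.0 * (1.0 - beta)
            else:
                orf_usage = spec.orf_rel_usage
            dclean = _clean_downstream(rng)
            cds[orf_local + 1 : orf_local + 21] = list(dclean)[: cds_len - orf_local - 1]

        tx = utr5 + "".join(cds) + "".join(utr3)
        tx_len = len(tx)
        cds_lo_local, cds_hi_local = len(utr5), len(utr5) + cds_len

        def to_genomic(local: int) -> int:
            return offset + local if strand == "+" else offset + tx_len - 1 - local

        seg = tx if strand == "+" else _revcomp(tx)
        parts.append(seg)

        cds_iv = (
            (offset + cds_lo_local, offset + cds_hi_local)
            if strand == "+"
            else (offset + tx_len - cds_hi_local, offset + tx_len - cds_lo_local)
        )
        ts, te = offset, offset + tx_len
        utr3_iv, introns, utr5_ivs = _derive_intervals(
            strand, None, [cds_iv], ts, te, 1000
        )
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                cds_intervals=[cds_iv],
                tx_start=ts,
                tx_end=te,
                utr3_interval=utr3_iv,
                utr5_intervals=utr5_ivs,
                intron_intervals=introns,
                frame_invalid=False,
                transcript_id=f"{gid}.1",
            )
        )
        truth.gene_beta[gid] = beta
        utr3_site_local = cds_hi_local + c
        truth.sites.append(
            TrueSite(gid, "UTR3", chrom, strand, to_genomic(utr3_site_local), 1.0, beta)
        )
        mg0, mg1 = to_genomic(cds_hi_local + ms), to_genomic(cds_hi_local + ms + m - 1)
        truth.motifs.append(
            MotifImplant(gid, "UTR3", chrom, strand, min(mg0, mg1), max(mg0, mg1) + 1)
        )
        if orf_local is not None:
            truth.sites.append(
                TrueSite(
                    gid, "ORF", chrom, strand, to_genomic(cds_lo_local + orf_local), orf_usage, beta
                )
            )
            og0 = to_genomic(cds_lo_local + mstart)
            og1 = to_genomic(cds_lo_local + mstart + 5)
            truth.motifs.append(
                MotifImplant(gid, "ORF", chrom, strand, min(og0, og1), max(og0, og1) + 1)
            )
        offset += tx_len
    spacer()

    seq = "".join(parts)
    # implant internal-priming artifact positions in intergenic space
    n_art = int(rng.poisson(spec.artifact_rate * spec.n_genes))
    seq_list = list(seq)
    run = spec.artifact_run_len
    occupied: List[Tuple[int, int]] = []
    for _ in range(n_art):
        iv = intergenic_ivs[rng.integers(0, len(intergenic_ivs))]
        if iv[1] - iv[0] < run + 10:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        s = int(rng.integers(iv[0] + 4, iv[1] - run - 4))
        # overlapping implants would overwrite each other's runs
        if any(s - run - 22 < e and b < s + run + 22 for b, e in occupied):
            continue
        occupied.append((s, s + run))
        if strand == "+":
            seq_list[s : s + run] = ["A"] * run
            end_pos = s - 1  # downstream 20-mer starts inside the run
        else:
            seq_list[s : s + run] = ["T"] * run
            end_pos = s + run
        truth.artifact_positions.append((chrom, strand, end_pos))

    genome = GenomeSequence({chrom: "".join(seq_list)})
    return genome, genes, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_reads(
    genome: GenomeSequence,
    truth: GroundTruth,
    spec: SyntheticSpec,
    seed: Optional[int] = None,
) -> EndCoverage:
    """Draw read 3'-ends around the true sites and at artifact positions.

    Per-site counts are Poisson(expression * usage); each read's offset
    from the site is a signed two-sided geometric with mean magnitude
    ``spec.dispersion`` (0 = every end exactly at the site).  Drawn counts
    are recorded back into ``truth``.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    cov = EndCoverage()
    expr = truth.gene_expression
    for site in truth.sites:
        if site.gene_id not in expr:
            expr[site.gene_id] = float(
                spec.expression_mean * rng.lognormal(0.0, spec.expression_sigma)
            )
    p = 1.0 / (1.0 + spec.dispersion)
    chrom_lens = {c: genome.length(c) for c in genome.chroms}
    for site in truth.sites:
        lam = expr[site.gene_id] * site.usage
        n = int(rng.poisson(lam))
        site.drawn_count = n
        for _ in range(n):
            mag = int(rng.geometric(p)) - 1
            if mag and rng.random() < 0.5:
                mag = -mag
            pos = site.position + (mag if site.strand == "+" else -mag)
            pos = min(max(pos, 0), chrom_lens[site.chrom] - 1)
            cov.add(site.chrom, site.strand, pos)
    for chrom, strand, pos in truth.artifact_positions:
        n = int(rng.poisson(spec.artifact_site_reads))
        if n > 0:
            cov.add(chrom, strand, pos, n)
    return cov


def write_fastq(
    coverage: EndCoverage,
    genome: GenomeSequence,
    path: str,
    read_length: int = 50,
    protocol: str = "2pseq",
    tail_length: int = 12,
    adapter: str = "AGATCGGAAGAGC",
) -> int:
    """Expand an :class:`EndCoverage` into raw 3'-end reads with poly(A)
    tails (and adapter remnant for the 2P-seq protocol); returns the number
    of reads written.  Reads too close to the chromosome start are skipped."""
    n_written = 0
    with open(path, "w") as fh:
        for chrom, strand, pos, count in coverage.positions():
            if strand == "+":
                a, b = pos - read_length + 1, pos + 1
            else:
                a, b = pos, pos + read_length
            if a < 0 or b > genome.length(chrom):
                continue
            body = genome.fetch(chrom, a, b, strand)
            if protocol == "2pseq":
                read = body + "A" * max(tail_length, 10) + adapter
            else:
                read = body + "A" * max(tail_length, 1)
            for i in range(count):
                n_written += 1
                fh.write(f"@r{n_written}_{chrom}_{strand}_{pos}_{i}\n{read}\n+\n{'I' * len(read)}\n")
    return n_written


def write_gtf(genes: Sequence[GeneAnnotation], path: str, source: str = "pcpa_sim") -> None:
    """Write gene/transcript/exon/CDS features (GTF, 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            rows = [
                ("gene", g.tx_start + 1, g.tx_end, f'gene_id "{g.gene_id}";'),
                ("transcript", g.tx_start + 1, g.tx_end, attrs),
                ("exon", g.tx_start + 1, g.tx_end, attrs),
            ]
            for s, e in g.cds_intervals:
                rows.append(("CDS", s + 1, e, attrs))
            for ftype, s1, e1, a in rows:
                fh.write(
                    f"{g.chrom}\t{source}\t{ftype}\t{s1}\t{e1}\t.\t{g.strand}\t"
                    f"{'0' if ftype == 'CDS' else '.'}\t{a}\n"
                )


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("record\tgene_id\tclass\tchrom\tstrand\tstart\tend\tusage\tbeta\tdrawn_count\n")
        for s in truth.sites:
            fh.write(
                f"site\t{s.gene_id}\t{s.site_class}\t{s.chrom}\t{s.strand}\t"
                f"{s.position}\t{s.position + 1}\t{s.usage:.4f}\t{s.beta:.4f}\t{s.drawn_count}\n"
            )
        for m in truth.motifs:
            fh.write(
                f"motif\t{m.gene_id}\t{m.context}\t{m.chrom}\t{m.strand}\t"
                f"{m.start}\t{m.end}\t.\t.\t.\n"
            )
        for chrom, strand, pos in truth.artifact_positions:
            fh.write(f"artifact\t.\t.\t{chrom}\t{strand}\t{pos}\t{pos + 1}\t.\t.\t.\n")


def write_genome_files(
    spec: SyntheticSpec, out_dir: str, with_fastq: bool = False
) -> Dict[str, str]:
    """Generate and write the full simulated dataset into ``out_dir``.

    Emits FASTA, GTF, per-strand bedgraphs and the ground-truth TSV
    (plus a 2P-seq-style FASTQ on request); returns the file paths.
    """
    import os

    from .genome_io import write_end_coverage, write_genome

    os.makedirs(out_dir, exist_ok=True)
    genome, genes, truth = generate_genome(spec)
    coverage = simulate_reads(genome, truth, spec)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gtf": os.path.join(out_dir, "annotation.gtf"),
        "plus_bedgraph": os.path.join(out_dir, "ends.plus.bedgraph"),
        "minus_bedgraph": os.path.join(out_dir, "ends.minus.bedgraph"),
        "truth": os.path.join(out_dir, "ground_truth.tsv"),
    }
    write_genome(genome, paths["fasta"])
    write_gtf(genes, paths["gtf"])
    write_end_coverage(coverage, paths["plus_bedgraph"], paths["minus_bedgraph"])
    write_ground_truth(truth, paths["truth"])
    if with_fastq:
        paths["fastq"] = os.path.join(out_dir, "reads.fastq")
        write_fastq(coverage, genome, paths["fastq"])
    return paths


def end_to_end_recovery(
    spec: SyntheticSpec,
    seed: Optional[int] = None,
    match_tolerance: int = 5,
    min_reads: int = 5,
    merge_gap: int = 24,
    rpm_min: float = 1.0,
    n_shuffles: int = 1000,
) -> Dict[str, object]:
    """Run the full pipeline on simulated data and score it against truth.

    Reports poly(A)-site recall and precision at +/- ``match_tolerance`` nt
    (recall over truth sites that drew at least ``min_reads`` reads, the
    recoverable set under the peak threshold), the discovered PAS hexamers
    versus the implanted one, the artifact-removal rate of the
    internal-priming filter, and the Pearson correlation between the log10
    normalized ORF/3'UTR termination ratio and gene CBI / CAI.
    """
    from scipy import stats as _stats

    from .codon_stats import gene_codon_indices, genome_usage_table
    from .pas_motifs import build_pssm, discover_pas_hexamers, extract_site_windows, to_rna
    from .read_processing import filter_coverage
    from .site_calling import classify_site, cluster_ends, gene_termination_table

    if seed is not None:
        spec = replace(spec, seed=seed)
    genome, genes, truth = generate_genome(spec)
    coverage = simulate_reads(genome, truth, spec)
    total_reads = coverage.total_reads
    kept, discarded = filter_coverage(coverage, genome)

    artifact_reads = 0
    kept_artifact_reads = 0
    for chrom, strand, pos in truth.artifact_positions:
        c = coverage.get(chrom, strand).get(pos, 0)
        artifact_reads += c
        kept_artifact_reads += kept.get(chrom, strand).get(pos, 0)

    clusters = cluster_ends(kept, merge_gap=merge_gap, min_reads=min_reads)
    sites = [classify_site(c, genes) for c in clusters]

    # site recovery at +/- match_tolerance
    truth_recoverable = [s for s in truth.sites if s.drawn_count >= min_reads]
    matched_truth = 0
    truth_by_key: Dict[Tuple[str, str], List[int]] = {}
    for s in truth.sites:
        truth_by_key.setdefault((s.chrom, s.strand), []).append(s.position)
    for s in truth_recoverable:
        if any(
            c.chrom == s.chrom and c.strand == s.strand and abs(c.summit - s.position) <= match_tolerance
            for c in clusters
        ):
            matched_truth += 1
    matched_calls = 0
    for c in clusters:
        positions = truth_by_key.get((c.chrom, c.strand), [])
        if any(abs(c.summit - p) <= match_tolerance for p in positions):
            matched_calls += 1
    recall = matched_truth / len(truth_recoverable) if truth_recoverable else float("nan")
    precision = matched_calls / len(clusters) if clusters else float("nan")

    # motif discovery on the 3'UTR PAS windows of called UTR3 sites
    utr3_sites = [s for s in sites if s.site_class == "UTR3"]
    pas_windows = extract_site_windows(
        [s.cluster for s in utr3_sites], genome, upstream=30, downstream=-10
    )
    motifs = discover_pas_hexamers(pas_windows, n_shuffles=n_shuffles, seed=spec.seed + 7)
    accepted = [m for m in motifs if m.accepted]
    implant_rna = to_rna(spec.utr3_motif)
    implant_rank = next((m.rank for m in accepted if m.hexamer == implant_rna), None)

    # PAS scores: foreground (-30..+10 windows of UTR3 sites) vs random windows
    score_windows = extract_site_windows([s.cluster for s in utr3_sites], genome, 30, 10)
    bg = genome.base_frequencies()
    report_scores: Dict[str, float] = {}
    if score_windows:
        pssm = build_pssm(score_windows, bg)
        fg_scores = [pssm.score(w) for w in score_windows]
        rng = np.random.default_rng(spec.seed + 11)
        L = pssm.length
        rand_scores = []
        chrom = next(iter(genome.chroms))
        n = genome.length(chrom)
        for _ in range(len(score_windows)):
            a = int(rng.integers(0, n - L))
            rand_scores.append(pssm.score(genome.fetch(chrom, a, a + L, "+")))
        report_scores = {
            "mean_fg_pas_score": float(np.nanmean(fg_scores)),
            "mean_random_pas_score": float(np.nanmean(rand_scores)),
        }

    # codon usage vs termination
    table = genome_usage_table(genes, genome)
    indices = {gi.gene_id: gi for gi in gene_codon_indices(genes, genome, table)}
    term = gene_termination_table(sites, genes, library_size=kept.total_reads)
    xs, ys_cbi, ys_cai = [], [], []
    for t in term:
        gi = indices.get(t.gene_id)
        if gi is None or t.rpm < rpm_min or not (t.ratio > 0):
            continue
        if math.isnan(gi.cbi) or math.isnan(gi.cai):
            continue
        xs.append(t.log10_ratio)
        ys_cbi.append(gi.cbi)
        ys_cai.append(gi.cai)
    r_cbi = float(_stats.pearsonr(xs, ys_cbi)[0]) if len(xs) >= 3 else float("nan")
    r_cai = float(_stats.pearsonr(xs, ys_cai)[0]) if len(xs) >= 3 else float("nan")

    report: Dict[str, object] = {
        "n_truth_sites": len(truth.sites),
        "n_recoverable_sites": len(truth_recoverable),
        "n_called_sites": len(clusters),
        "site_recall": recall,
        "site_precision": precision,
        "total_reads": total_reads,
        "reads_discarded_by_priming_filter": discarded,
        "artifact_reads": artifact_reads,
        "artifact_removal_rate": (
            1.0 - kept_artifact_reads / artifact_reads if artifact_reads else float("nan")
        ),
        "n_accepted_motifs": len(accepted),
        "accepted_motifs": [m.hexamer for m in accepted],
        "implanted_motif": implant_rna,
        "implanted_motif_rank": implant_rank,
        "n_genes_in_correlation": len(xs),
        "pearson_r_log10ratio_cbi": r_cbi,
        "pearson_r_log10ratio_cai": r_cai,
    }
    report.update(report_scores)
    return report
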