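"""End-to-end orchestration: configuration, staged execution, manifest.

``run_pipeline`` chains the post-mapping stages on real or simulated
inputs: internal-priming filtering of 3'-end coverage, poly(A)-site
calling and classification, the gene termination table, PAS hexamer
discovery, PSSM construction and scoring, codon usage indices, NCUF /
NCPF, true/false PAS classification, and RCUF.  Every stage logs its
input/output counts and all products are listed in a JSON manifest, so a
rerun with the same configuration reproduces the same files.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import codon_stats, genome_io, pas_motifs, read_processing, site_calling
from .species import SpeciesProfile, get_profile

logger = logging.getLogger("pcpa")


@dataclass
class RunConfig:
    genome: str
    gtf: str
    out_dir: str
    species: str = "ncrassa"
    coverage_plus: Optional[str] = None
    coverage_minus: Optional[str] = None
    coverage_bed: Optional[str] = None
    rpm_min: float = 1.0
    rpm_strict: float = 10.0
    n_shuffles: int = 1000
    n_random_background: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("genome", "gtf", "out_dir"):
            if not getattr(self, name):
                raise ValueError(f"config field '{name}' is required")
        if self.coverage_bed is None and self.coverage_plus is None:
            raise ValueError("either coverage_bed or coverage_plus/coverage_minus is required")
        for name in ("genome", "gtf", "coverage_plus", "coverage_minus", "coverage_bed"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise ValueError(f"config field '{name}': file not found: {p}")
        get_profile(self.species)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all analysis stages; returns the run report (also written to
    ``out_dir/manifest.json``)."""
    config.validate()
    profile = get_profile(config.species)
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict[str, object] = {"config": asdict(config), "stages": {}, "files": []}

    def emit(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest["files"].append(name)
        return path

    with open(emit("config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    logger.info("stage load: genome=%s gtf=%s", config.genome, config.gtf)
    genome = genome_io.load_genome(config.genome)
    genes = genome_io.load_annotation(config.gtf, utr_extension=profile.utr3_extension, genome=genome)
    coverage = genome_io.load_end_coverage(
        plus_bedgraph=config.coverage_plus,
        minus_bedgraph=config.coverage_minus,
        bed=config.coverage_bed,
    )
    n_in = coverage.total_reads

    kept, discarded = read_processing.filter_coverage(coverage, genome, profile.priming_window)
    manifest["stages"]["priming_filter"] = {"reads_in": n_in, "reads_out": kept.total_reads, "discarded": discarded}
    logger.info("stage priming_filter: %d in, %d discarded", n_in, discarded)
    genome_io.write_end_coverage(kept, emit("filtered.plus.bedgraph"), emit("filtered.minus.bedgraph"))

    clusters = site_calling.cluster_ends(kept, merge_gap=profile.merge_gap, min_reads=profile.min_reads)
    up, down = profile.pas_window
    sites = [site_calling.classify_site(c, genes, up, down) for c in clusters]
    manifest["stages"]["site_calling"] = {
        "clusters": len(clusters),
        "by_class": _class_counts(sites),
    }
    logger.info("stage site_calling: %d clusters %s", len(clusters), _class_counts(sites))
    _write_sites_bed(sites, emit("sites.bed"))

    term = site_calling.gene_termination_table(sites, genes, library_size=kept.total_reads)
    _write_termination_tsv(term, emit("gene_termination.tsv"))
    manifest["stages"]["gene_termination"] = {
        "genes": len(term),
        f"genes_rpm_gt_{config.rpm_min:g}": sum(1 for t in term if t.rpm > config.rpm_min),
        f"genes_rpm_gt_{config.rpm_strict:g}": sum(1 for t in term if t.rpm > config.rpm_strict),
    }

    utr3_sites = [s for s in sites if s.site_class == "UTR3"]
    orf_sites = [s for s in sites if s.site_class == "ORF"]
    pas_windows = pas_motifs.extract_site_windows(
        [s.cluster for s in utr3_sites], genome, up, -down
    )
    motifs = pas_motifs.discover_pas_hexamers(
        pas_windows, n_shuffles=config.n_shuffles, seed=config.seed
    )
    pas_motifs.write_motif_table(motifs, emit("pas_motifs.tsv"))
    accepted = [m for m in motifs if m.accepted]
    manifest["stages"]["motif_discovery"] = {
        "windows": len(pas_windows),
        "accepted": [m.hexamer for m in accepted],
    }
    logger.info("stage motif_discovery: %d accepted", len(accepted))

    pu, pd_ = profile.pssm_window
    score_windows = pas_motifs.extract_site_windows([s.cluster for s in utr3_sites], genome, pu, pd_)
    scores_summary = {}
    if score_windows:
        pssm = pas_motifs.build_pssm(score_windows, genome.base_frequencies(), offset=-pu)
        pssm.write(emit("pas_pssm.tsv"))
        utr3_scores = [pssm.score(w) for w in score_windows]
        orf_windows = pas_motifs.extract_site_windows([s.cluster for s in orf_sites], genome, pu, pd_)
        orf_scores = [pssm.score(w) for w in orf_windows]
        scores_summary = {
            "utr3_mean_score": float(np.nanmean(utr3_scores)) if utr3_scores else None,
            "orf_mean_score": float(np.nanmean(orf_scores)) if orf_scores else None,
        }
        _write_scores_tsv(utr3_sites, utr3_scores, orf_sites, orf_scores, emit("pas_scores.tsv"))
    manifest["stages"]["pas_score"] = scores_summary

    table = codon_stats.genome_usage_table(genes, genome)
    indices = codon_stats.gene_codon_indices(genes, genome, table)
    _write_indices_tsv(indices, emit("gene_codon_indices.tsv"))

    ncuf_df = codon_stats.ncuf(orf_sites, genes, genome, config.n_random_background, config.seed)
    ncuf_df.to_csv(emit("ncuf.tsv"), sep="\t", index=False)
    ncpf_df = codon_stats.ncpf(orf_sites, genes, genome, config.n_random_background, config.seed)
    ncpf_df.to_csv(emit("ncpf.tsv"), sep="\t", index=False)

    # motif list for the true/false comparison
    if profile.motif_selection == "named":
        motif_list = list(profile.named_motifs)
    else:
        motif_list = [m.hexamer.replace("U", "T") for m in accepted[: profile.motif_top_n]]
    occurrences: List[codon_stats.PASOccurrence] = []
    rcuf_path = None
    if motif_list:
        summits = [(c.chrom, c.strand, c.summit) for c in clusters]
        occurrences = codon_stats.classify_true_false_pas(motif_list, genes, genome, summits)
        _write_occurrences_bed(occurrences, emit("pas_occurrences.bed"))
        orf_occ = [o for o in occurrences if o.context == "ORF"]
        if any(o.is_true for o in orf_occ) and any(not o.is_true for o in orf_occ):
            rcuf_df = codon_stats.rcuf(occurrences, genes, genome)
            rcuf_df.to_csv(emit("rcuf.tsv"), sep="\t", index=False)
            rcuf_path = "rcuf.tsv"
    manifest["stages"]["pas_truth"] = {
        "motifs": motif_list,
        "occurrences": len(occurrences),
        "true": sum(1 for o in occurrences if o.is_true),
        "rcuf": rcuf_path,
    }

    # correlation summary (the headline quantity)
    gi = {i.gene_id: i for i in indices}
    xs, ys = [], []
    for t in term:
        i = gi.get(t.gene_id)
        if i is None or t.rpm < config.rpm_min or not (t.ratio > 0) or math.isnan(i.cbi):
            continue
        xs.append(t.log10_ratio)
        ys.append(i.cbi)
    if len(xs) >= 3:
        from scipy import stats

        r, p = stats.pearsonr(xs, ys)
        manifest["stages"]["correlation"] = {"pearson_r_log10ratio_cbi": float(r), "p": float(p), "n": len(xs)}

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["files"].append("manifest.json")
    return manifest


def empirical_pas_window_scan(
    orf_sites,
    genome: genome_io.GenomeSequence,
    candidates: Sequence[Tuple[int, int]] = ((30, 10), (25, 12), (35, 15), (20, 5)),
) -> Dict[str, object]:
    """Mean A/T content of candidate PAS windows at called ORF sites.

    Reports every candidate window's mean AT fraction and the AT-maximizing
    window; selection is reported, never silently applied.  With no ORF
    sites, or no window clearly AT-enriched over the flanking baseline, the
    report says so.
    """
    rows = []
    for up, down in candidates:
        windows = pas_motifs.extract_site_windows(
            [s.cluster for s in orf_sites], genome, up, -down
        )
        ats = [
            (w.count("A") + w.count("T")) / len(w) for w in windows if w and "N" not in w
        ]
        rows.append(
            {
                "window": f"-{up}..-{down}",
                "up": up,
                "down": down,
                "n": len(ats),
                "mean_at": float(np.mean(ats)) if ats else float("nan"),
            }
        )
    usable = [r for r in rows if r["n"] > 0]
    best = max(usable, key=lambda r: r["mean_at"]) if usable else None
    genome_at = genome.base_frequencies()["A"] * 2
    enriched = False
    if best is not None:
        # enrichment margin: two standard errors of the window AT estimate,
        # floored at 2 percentage points for very large site sets
        total_nt = best["n"] * (best["up"] - best["down"] + 1)
        margin = max(0.02, 2.0 * math.sqrt(0.25 / max(total_nt, 1)))
        enriched = best["mean_at"] > genome_at + margin
    return {
        "candidates": rows,
        "selected": best["window"] if enriched else None,
        "note": (
            "selected window maximizes mean AT content"
            if enriched
            else "no candidate window is AT-enriched over the genomic baseline"
        ),
    }


def _class_counts(sites) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for s in sites:
        out[s.site_class] = out.get(s.site_class, 0) + 1
    return out


def _write_sites_bed(sites, path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            c = s.cluster
            name = f"{s.gene_id or '.'}|{s.site_class}" + ("|ambiguous" if s.ambiguous else "")
            fh.write(f"{c.chrom}\t{c.summit}\t{c.summit + 1}\t{name}\t{c.count}\t{c.strand}\n")


def _write_termination_tsv(term, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tn_orf_reads\tn_utr3_reads\tn_orf_events\tn_utr3_events\t"
            "cds_length\trpm\tratio\tlog10_ratio\n"
        )
        for t in term:
            fh.write(
                f"{t.gene_id}\t{t.n_orf_reads}\t{t.n_utr3_reads}\t{t.n_orf_events}\t"
                f"{t.n_utr3_events}\t{t.cds_length}\t{t.rpm:.4f}\t{t.ratio:.6g}\t"
                f"{t.log10_ratio:.4f}\n"
            )


def _write_indices_tsv(indices, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcbi\tcai\tn_opt\tn_ran\tn_tot\n")
        for i in indices:
            fh.write(f"{i.gene_id}\t{i.cbi:.4f}\t{i.cai:.4f}\t{i.n_opt}\t{i.n_ran}\t{i.n_tot}\n")


def _write_scores_tsv(utr3_sites, utr3_scores, orf_sites, orf_scores, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsummit\tstrand\tgene_id\tclass\tpas_score\n")
        for group, scores in ((utr3_sites, utr3_scores), (orf_sites, orf_scores)):
            for s, score in zip(group, scores):
                c = s.cluster
                fh.write(
                    f"{c.chrom}\t{c.summit}\t{c.strand}\t{s.gene_id or '.'}\t"
                    f"{s.site_class}\t{score:.4f}\n"
                )


def _write_occurrences_bed(occurrences, path: str) -> None:
    with open(path, "w") as fh:
        for o in occurrences:
            name = f"{o.motif}|{o.gene_id}|{o.context}|{'true' if o.is_true else 'false'}"
            fh.write(f"{o.chrom}\t{o.start}\t{o.end}\t{name}\t0\t{o.strand}\n")
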