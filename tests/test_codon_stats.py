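import math
import random
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pytest

from pcpa.codon_stats import (
    FAMILIES,
    SENSE_CODONS,
    PASOccurrence,
    at_content_profile,
    cbi_from_counts,
    classify_true_false_pas,
    compute_cai,
    compute_cbi,
    compute_rsca,
    count_codons,
    gene_codon_indices,
    ncpf,
    ncuf,
    rcuf,
)
from pcpa.genome_io import GenomeSequence, upstream_window
from pcpa.synthetic_data import SyntheticSpec, generate_genome

from conftest import make_gene


@dataclass
class FakeSite:
    gene_id: str
    pas_window: Optional[Tuple[int, int]]


class TestRSCA:
    def test_family_max_normalization(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts.update({"GCC": 100, "GCT": 50})
        t = compute_rsca(counts)
        assert t.rsca["GCC"] == 1.0
        assert t.rsca["GCT"] == 0.5

    def test_single_codon_families_are_one(self):
        counts = {"ATG": 10, "TGG": 3}
        t = compute_rsca(counts)
        assert t.rsca["ATG"] == 1.0 and t.rsca["TGG"] == 1.0

    def test_matches_per_family_oracle(self):
        rng = random.Random(50)
        counts = {c: rng.randrange(1, 500) for c in SENSE_CODONS}
        t = compute_rsca(counts)
        for fam in FAMILIES.values():
            mx = max(counts[c] for c in fam)
            for c in fam:
                assert t.rsca[c] == pytest.approx(counts[c] / mx)

    def test_zero_family_is_nan_and_absent_codon_floored(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts["GCC"] = 100  # Ala family present, others zero
        t = compute_rsca(counts)
        assert math.isnan(t.rsca["TTT"])  # Phe family has no counts at all
        assert t.rsca["GCT"] == pytest.approx(0.5 / 100)  # floored, not zero

    def test_classes(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts.update({"GCC": 100, "GCT": 95, "GCA": 50, "GCG": 10})
        t = compute_rsca(counts)
        assert t.codon_class("GCC") == "optimal"
        assert t.codon_class("GCT") == "optimal"  # 0.95 >= 0.9
        assert t.codon_class("GCA") == "random"
        assert t.codon_class("GCG") == "rare"  # 0.1 < 0.3


def biased_table():
    """Usage table where GCC/AAG-style C/G-ending codons dominate."""
    counts = {}
    for fam in FAMILIES.values():
        gc = [c for c in fam if c[2] in "GC"]
        for c in fam:
            counts[c] = 100 if (gc and c == gc[0]) else (20 if len(fam) > 1 else 100)
    return compute_rsca(counts)


class TestCBI:
    def test_all_optimal_gives_one(self):
        t = biased_table()
        opt = [c for c in SENSE_CODONS if t.codon_class(c) == "optimal" and c not in ("ATG", "TGG")]
        cds = "ATG" + "".join(opt[:10]) + "TAA"
        cbi, n_opt, n_ran, n_tot = compute_cbi(cds, t)
        assert cbi == 1.0 and n_ran == 0 and n_opt == n_tot == 10

    def test_closed_form_counts(self):
        assert cbi_from_counts(60, 30, 100) == pytest.approx(30 / 70)

    def test_all_rare_gives_zero(self):
        t = biased_table()
        rare = [c for c in SENSE_CODONS if t.codon_class(c) == "rare"]
        cds = "".join(rare[:8])
        cbi, n_opt, n_ran, n_tot = compute_cbi(cds, t)
        assert cbi == 0.0 and n_opt == 0 and n_ran == 0

    def test_undefined_when_all_random(self):
        t = biased_table()
        ran = [c for c in SENSE_CODONS if t.codon_class(c) == "random"]
        cbi, *_ = compute_cbi("".join(ran[:5]), t)
        assert math.isnan(cbi)

    def test_matches_direct_classification_oracle(self):
        t = biased_table()
        rng = random.Random(51)
        for _ in range(200):
            codons = [rng.choice(SENSE_CODONS) for _ in range(rng.randrange(5, 80))]
            cbi, n_opt, n_ran, n_tot = compute_cbi("".join(codons), t)
            cls = [
                t.codon_class(c)
                for c in codons
                if c not in ("ATG", "TGG") and t.codon_class(c) is not None
            ]
            o, r, n = cls.count("optimal"), cls.count("random"), len(cls)
            assert (n_opt, n_ran, n_tot) == (o, r, n)
            if n != r:
                assert cbi == pytest.approx((o - r) / (n - r), abs=1e-12)


class TestCAI:
    def test_all_unit_rsca(self):
        t = biased_table()
        opt = [c for c in SENSE_CODONS if t.rsca[c] == 1.0]
        assert compute_cai("".join(opt[:6]), t) == pytest.approx(1.0)

    def test_geometric_mean_two_codons(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts.update({"GCC": 100, "GCT": 25})
        t = compute_rsca(counts)
        # RSCA 1.0 and 0.25 -> geometric mean 0.5
        assert compute_cai("GCCGCT", t) == pytest.approx(0.5)

    def test_matches_log_domain_oracle(self):
        t = biased_table()
        rng = random.Random(52)
        codons = [rng.choice(SENSE_CODONS) for _ in range(100)]
        cai = compute_cai("".join(codons), t)
        ws = [t.rsca[c] for c in codons]
        oracle = float(np.exp(np.mean(np.log(ws))))
        assert cai == pytest.approx(oracle, abs=1e-12)

    def test_gene_indices_skip_frame_invalid(self):
        g_ok = make_gene("g1", cds_intervals=[(0, 30)], tx_start=0, tx_end=40)
        g_bad = make_gene("g2", cds_intervals=[(50, 70)], tx_start=50, tx_end=80)
        genome = GenomeSequence({"chr1": "GCC" * 10 + "GCTGCTGCTGCTGCTGCTGC" + "G" * 30})
        out = gene_codon_indices([g_ok, g_bad], genome)
        assert [i.gene_id for i in out] == ["g1"]


def fake_orf_sites(genes, truth):
    """ORF FakeSites with -30..-10 PAS windows at the implanted truth sites."""
    sites = []
    by_id = {g.gene_id: g for g in genes}
    for s in truth.sites:
        if s.site_class != "ORF":
            continue
        g = by_id[s.gene_id]
        sites.append(FakeSite(s.gene_id, upstream_window(s.position, g.strand, 30, 10)))
    return sites


class TestNCUF:
    def test_self_test_near_zero(self):
        # foreground windows drawn by the background sampler: NCUF ~ 0
        spec = SyntheticSpec(n_genes=60, orf_usage_mode="none", seed=5)
        genome, genes, truth = generate_genome(spec)
        rng = np.random.default_rng(6)
        sites = []
        for g in genes:
            for _ in range(12):
                n_cod = g.cds_length // 3
                j = int(rng.integers(2, n_cod - 10))
                a = g.cds_intervals[0][0] + j * 3
                win = (a, a + 21) if g.strand == "+" else (
                    g.cds_intervals[0][1] - j * 3 - 21,
                    g.cds_intervals[0][1] - j * 3,
                )
                sites.append(FakeSite(g.gene_id, win))
        df = ncuf(sites, genes, genome, n_random=10, seed=7)
        # sampling error of log2(fg/bg) at fg >= 100 is ~0.15; the mean over
        # codons and the worst case stay within a few standard errors
        big = df[(df.fg_count >= 100) & (df.bg_count >= 100)]
        assert len(big) > 5
        assert big.log2_ratio.abs().mean() < 0.2
        assert big.log2_ratio.abs().max() < 0.6

    def test_implanted_motif_codons_enriched(self):
        spec = SyntheticSpec(n_genes=60, seed=8)
        genome, genes, truth = generate_genome(spec)
        df = ncuf(fake_orf_sites(genes, truth), genes, genome, seed=9)
        row = df.set_index("codon")
        # AATAAA implanted in frame as AAT|AAA upstream of every ORF site
        assert row.loc["AAT", "log2_ratio"] > 0.5
        assert row.loc["AAA", "log2_ratio"] > 0.5

    def test_frequencies_sum_to_one(self):
        spec = SyntheticSpec(n_genes=30, seed=10)
        genome, genes, truth = generate_genome(spec)
        df = ncuf(fake_orf_sites(genes, truth), genes, genome, seed=11)
        assert df.fg_freq.sum() == pytest.approx(1.0)
        assert df.bg_freq.sum() == pytest.approx(1.0)


class TestNCPF:
    def test_implanted_pair_is_top_ranked(self):
        spec = SyntheticSpec(n_genes=60, seed=12)
        genome, genes, truth = generate_genome(spec)
        df = ncpf(fake_orf_sites(genes, truth), genes, genome, seed=13)
        ranked = df.dropna(subset=["log2_ratio"]).sort_values("log2_ratio", ascending=False)
        assert ranked.iloc[0]["codon_pair"] == "AATAAA"

    def test_single_codon_windows_skipped(self):
        spec = SyntheticSpec(n_genes=10, seed=14)
        genome, genes, truth = generate_genome(spec)
        g = genes[0]
        a = g.cds_intervals[0][0] + 9
        df = ncpf([FakeSite(g.gene_id, (a, a + 4))], genes, genome, seed=15)
        assert df.empty or df.fg_count.sum() == 0


class TestTrueFalsePAS:
    def _setup(self, summit_offsets, strand="+"):
        """Plus-strand gene whose CDS carries one AATAAA; summits placed at
        given distances downstream of the motif's 3' end."""
        rng = random.Random(60)
        body = "".join(rng.choice("CCGG") for _ in range(300))
        cds = body[:150] + "AATAAA" + body[150:294]  # length 450
        chrom = "G" * 50 + cds + "G" * 400
        gene = make_gene("g1", strand="+", cds_intervals=[(50, 500)], tx_start=0, tx_end=600)
        genome = GenomeSequence({"chr1": chrom})
        motif_end = 50 + 150 + 5  # genomic position of the motif's last base
        summits = [("chr1", strand, motif_end + d) for d in summit_offsets]
        occ = classify_true_false_pas(["AATAAA"], [gene], genome, summits)
        orf = [o for o in occ if o.context == "ORF" and o.motif == "AATAAA"]
        assert len(orf) == 1
        return orf[0]

    @pytest.mark.parametrize("distance,expected", [(18, True), (5, True), (35, True), (4, False), (36, False)])
    def test_downstream_window_semantics(self, distance, expected):
        assert self._setup([distance]).is_true is expected

    def test_opposite_strand_summit_does_not_count(self):
        assert self._setup([18], strand="-").is_true is False

    def test_order_independence_and_idempotence(self):
        spec = SyntheticSpec(n_genes=20, seed=16)
        genome, genes, truth = generate_genome(spec)
        summits = [(s.chrom, s.strand, s.position) for s in truth.sites]
        occ1 = classify_true_false_pas(["AATAAA", "TGTAAC"], genes, genome, summits)
        occ2 = classify_true_false_pas(["TGTAAC", "AATAAA"], genes, genome, summits)
        key = lambda o: (o.chrom, o.strand, o.start, o.motif, o.context, o.is_true)
        assert sorted(map(key, occ1)) == sorted(map(key, occ2))

    def test_implanted_motifs_recovered_as_true(self):
        spec = SyntheticSpec(n_genes=20, dispersion=0.0, seed=17)
        genome, genes, truth = generate_genome(spec)
        summits = [(s.chrom, s.strand, s.position) for s in truth.sites]
        occ = classify_true_false_pas(["AATAAA"], genes, genome, summits)
        implanted = {(m.chrom, m.strand, m.start) for m in truth.motifs}
        hits = [o for o in occ if (o.chrom, o.strand, o.start) in implanted]
        # every implanted hexamer sits 18 nt upstream of a true site
        assert hits and all(o.is_true for o in hits)


class TestRCUF:
    def _genome_with_pair(self):
        """Two identical genes; a summit downstream of the motif only in g1."""
        rng = random.Random(61)
        cds = "".join(rng.choice(["GCC", "GAA", "TAT"]) for _ in range(100))
        cds = cds[:150] + "AATAAA" + cds[156:]
        chrom = "T" * 30 + cds + "T" * 30 + cds + "T" * 30
        g1 = make_gene("g1", cds_intervals=[(30, 330)], tx_start=30, tx_end=340)
        g2 = make_gene("g2", cds_intervals=[(360, 660)], tx_start=360, tx_end=670)
        return GenomeSequence({"chr1": chrom}), [g1, g2]

    def test_identical_flanks_give_zero(self):
        genome, genes = self._genome_with_pair()
        summits = [("chr1", "+", 30 + 155 + 18)]
        occ = classify_true_false_pas(["AATAAA"], genes, genome, summits)
        orf = [o for o in occ if o.context == "ORF"]
        assert {o.is_true for o in orf} == {True, False}
        df = rcuf(occ, genes, genome).set_index("codon")
        present = df[~df.flagged]
        assert len(present) >= 2
        assert present.log2_ratio.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_absent_codon_flagged_not_infinite(self):
        genome, genes = self._genome_with_pair()
        summits = [("chr1", "+", 30 + 155 + 18)]
        occ = classify_true_false_pas(["AATAAA"], genes, genome, summits)
        df = rcuf(occ, genes, genome)
        assert not np.isinf(df.log2_ratio.dropna()).any()
        assert df[df.true_count == 0].flagged.all()

    def test_empty_truth_class_rejected(self):
        genome, genes = self._genome_with_pair()
        occ = classify_true_false_pas(["AATAAA"], genes, genome, [])
        with pytest.raises(ValueError):
            rcuf(occ, genes, genome)

    def test_truth_flank_enrichment_detected(self):
        # true occurrences flanked by TAT repeats, false by GCC repeats
        flank_t = "TAT" * 30
        flank_f = "GCC" * 30
        cds_t = flank_t + "AATAAA" + flank_t
        cds_f = flank_f + "AATAAA" + flank_f
        chrom = cds_t + "G" * 20 + cds_f
        g1 = make_gene("g1", cds_intervals=[(0, len(cds_t))], tx_start=0, tx_end=len(cds_t))
        start_f = len(cds_t) + 20
        g2 = make_gene("g2", cds_intervals=[(start_f, start_f + len(cds_f))],
                       tx_start=start_f, tx_end=start_f + len(cds_f))
        genome = GenomeSequence({"chr1": chrom})
        summits = [("chr1", "+", 95 + 18)]  # true only for g1's motif (end at 95)
        occ = classify_true_false_pas(["AATAAA"], [g1, g2], genome, summits)
        df = rcuf(occ, [g1, g2], genome).set_index("codon")
        assert df.loc["TAT", "true_count"] > 0 and df.loc["TAT", "false_count"] == 0
        assert df.loc["TAT", "flagged"]  # zero denominator -> flagged


class TestATContent:
    def test_all_a_flanks(self):
        genome = GenomeSequence({"c": "A" * 400})
        occ = [
            PASOccurrence("AATAAA", "g", "c", "+", 200, 206, "ORF", True),
            PASOccurrence("AATAAA", "g", "c", "+", 210, 216, "ORF", False),
        ]
        prof = at_content_profile(occ, genome, flank_nt=80)
        assert prof[True][1] == pytest.approx(1.0)
        assert prof[False][1] == pytest.approx(1.0)

    def test_edge_clipped_windows_excluded(self):
        genome = GenomeSequence({"c": "A" * 100})
        occ = [PASOccurrence("AATAAA", "g", "c", "+", 2, 8, "ORF", True)]
        prof = at_content_profile(occ, genome, flank_nt=80)
        assert prof[True][0].n_sequences == 0

    def test_true_class_more_at_rich(self):
        genome = GenomeSequence({"c": "AT" * 150 + "GC" * 150})
        occ = [
            PASOccurrence("AATAAA", "g", "c", "+", 150, 156, "ORF", True),
            PASOccurrence("AATAAA", "g", "c", "+", 450, 456, "ORF", False),
        ]
        prof = at_content_profile(occ, genome, flank_nt=80)
        assert prof[True][1] > prof[False][1]
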