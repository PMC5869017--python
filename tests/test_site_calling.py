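import math
import random

import pytest

from pcpa.genome_io import EndCoverage
from pcpa.site_calling import (
    PolyACluster,
    classify_site,
    cluster_ends,
    gene_termination_table,
    major_utr3_site,
)

from conftest import make_gene


def oracle_cluster(posmap, strand, merge_gap, min_reads):
    """O(n^2) transitive-closure merge over occupied positions."""
    positions = sorted(posmap)
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for p in positions:
        for q in positions:
            if p < q and q - p <= merge_gap:
                parent[find(q)] = find(p)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    out = []
    for members in groups.values():
        members.sort()
        total = sum(posmap[p] for p in members)
        if total < min_reads:
            continue
        best = max(posmap[p] for p in members)
        cands = [p for p in members if posmap[p] == best]
        summit = min(cands) if strand == "+" else max(cands)
        out.append((members[0], members[-1], total, summit))
    return sorted(out)


def coverage_from(posmap, strand="+", chrom="chr1"):
    cov = EndCoverage()
    for p, c in posmap.items():
        cov.add(chrom, strand, p, c)
    return cov


class TestClusterEnds:
    def test_merge_and_summit_example(self):
        cov = coverage_from({100: 3, 110: 4, 200: 6})
        c1, c2 = cluster_ends(cov)
        assert (c1.start, c1.end, c1.count, c1.summit) == (100, 110, 7, 110)
        assert (c2.start, c2.end, c2.count, c2.summit) == (200, 200, 6, 200)

    def test_below_min_reads_dropped(self):
        assert cluster_ends(coverage_from({500: 4})) == []

    def test_empty_coverage(self):
        assert cluster_ends(EndCoverage()) == []

    def test_gap_boundary_is_inclusive(self):
        cov = coverage_from({100: 3, 124: 3})  # 24 apart: one cluster
        (c,) = cluster_ends(cov)
        assert (c.start, c.end, c.count) == (100, 124, 6)
        cov = coverage_from({100: 5, 125: 5})  # 25 apart: two clusters
        assert len(cluster_ends(cov)) == 2

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_summit_tie_breaks_5prime_most(self, strand):
        (c,) = cluster_ends(coverage_from({100: 5, 110: 5}, strand))
        assert c.summit == (100 if strand == "+" else 110)

    def test_matches_bruteforce_transitive_merge(self):
        rng = random.Random(77)
        for _ in range(200):
            strand = rng.choice("+-")
            posmap = {
                rng.randrange(0, 600): rng.randrange(1, 10)
                for _ in range(rng.randrange(1, 40))
            }
            got = [
                (c.start, c.end, c.count, c.summit)
                for c in cluster_ends(coverage_from(posmap, strand))
            ]
            assert sorted(got) == oracle_cluster(posmap, strand, 24, 5)

    def test_read_count_conservation(self):
        rng = random.Random(8)
        posmap = {rng.randrange(0, 2000): rng.randrange(1, 8) for _ in range(150)}
        cov = coverage_from(posmap)
        retained = cluster_ends(cov, min_reads=5)
        all_clusters = cluster_ends(cov, min_reads=1)
        dropped = sum(c.count for c in all_clusters) - sum(c.count for c in retained)
        assert sum(c.count for c in retained) + dropped == cov.total_reads


def cluster_at(summit, strand="+", chrom="chr1", count=10):
    return PolyACluster(chrom, strand, summit, summit, count, summit, count)


class TestClassifySite:
    # gene: 5'UTR [0,50), CDS [50,350), 3'UTR search [350, 1500)
    @pytest.fixture
    def gene(self):
        return make_gene(cds_intervals=[(50, 350)], tx_start=0, tx_end=500)

    def test_utr3_by_definition(self, gene):
        s = classify_site(cluster_at(400), [gene])
        assert (s.site_class, s.gene_id) == ("UTR3", "g1")

    def test_orf_when_pas_window_inside_cds(self, gene):
        # summit at 200: -30..-10 window = [170, 191) inside CDS
        s = classify_site(cluster_at(200), [gene])
        assert s.site_class == "ORF"
        assert s.pas_window == (170, 191)

    def test_not_orf_when_window_leaves_cds(self, gene):
        # summit at 60: window [30, 51) crosses the CDS start
        s = classify_site(cluster_at(60), [gene])
        assert s.site_class != "ORF"

    def test_intron_beats_utr5(self):
        gene = make_gene(cds_intervals=[(100, 160), (200, 260)], tx_start=0, tx_end=400)
        assert classify_site(cluster_at(180), [gene]).site_class == "intron"
        assert classify_site(cluster_at(50), [gene]).site_class == "UTR5"

    def test_intergenic_and_wrong_strand(self, gene):
        assert classify_site(cluster_at(5000), [gene]).site_class == "intergenic"
        assert classify_site(cluster_at(400, strand="-"), [gene]).site_class == "intergenic"

    def test_ambiguous_when_two_genes_claim_summit(self):
        g1 = make_gene("g1", cds_intervals=[(50, 350)], tx_start=0, tx_end=400)
        g2 = make_gene("g2", cds_intervals=[(360, 660)], tx_start=355, tx_end=800)
        # summit at 420 is in g1's extended 3'UTR and deep in g2's CDS with a
        # clean PAS window: UTR3 outranks ORF
        s = classify_site(cluster_at(420), [g1, g2])
        assert s.site_class == "UTR3" and s.gene_id == "g1" and not s.ambiguous
        # summit claimed as UTR3 by two genes -> ambiguous
        g3 = make_gene("g3", cds_intervals=[(30, 330)], tx_start=0, tx_end=400)
        s = classify_site(cluster_at(380), [g1, g3])
        assert s.site_class == "UTR3" and s.ambiguous

    def test_strand_antisymmetry(self):
        # mirroring all coordinates and flipping strand preserves the class
        N = 2000
        plus = make_gene(strand="+", cds_intervals=[(50, 350)], tx_start=0, tx_end=500)
        minus = make_gene(
            strand="-", cds_intervals=[(N - 350, N - 50)], tx_start=N - 500, tx_end=N
        )
        for summit in (200, 400, 30, 60):
            a = classify_site(cluster_at(summit, "+"), [plus])
            b = classify_site(cluster_at(N - 1 - summit, "-"), [minus])
            assert a.site_class == b.site_class


class TestMajorSite:
    def test_highest_summit_wins(self):
        cs = [cluster_at(10, count=10), cluster_at(50, count=30), cluster_at(90, count=7)]
        assert major_utr3_site(cs).summit == 50

    def test_single_cluster_and_empty(self):
        c = cluster_at(10)
        assert major_utr3_site([c]) is c
        assert major_utr3_site([]) is None

    def test_tie_breaks_most_3prime(self):
        cs = [cluster_at(50, count=10), cluster_at(90, count=10)]
        assert major_utr3_site(cs).summit == 90
        cs = [cluster_at(50, "-", count=10), cluster_at(90, "-", count=10)]
        assert major_utr3_site(cs).summit == 50


class TestGeneTermination:
    def _sites(self, gene, orf_counts, utr3_counts):
        out = []
        for c in orf_counts:
            out.append(classify_site(cluster_at(200, count=c), [gene]))
        for c in utr3_counts:
            out.append(classify_site(cluster_at(1100, count=c), [gene]))
        return out

    def test_normalized_ratio_arithmetic(self):
        gene = make_gene(cds_intervals=[(50, 1050)], tx_start=0, tx_end=1200)
        sites = self._sites(gene, [2], [100])
        (t,) = gene_termination_table(sites, [gene], library_size=1000)
        assert t.cds_length == 1000
        assert t.ratio == pytest.approx(2 * 1000 / (100 * 1000))
        assert t.rpm == pytest.approx(1e6 * 100 / 1000)
        assert t.log10_ratio == pytest.approx(math.log10(0.02))

    def test_zero_orf_gives_zero_ratio(self):
        gene = make_gene(cds_intervals=[(50, 1050)], tx_start=0, tx_end=1200)
        (t,) = gene_termination_table(self._sites(gene, [], [50]), [gene], 100)
        assert t.ratio == 0 and math.isnan(t.log10_ratio)

    def test_gene_without_utr3_signal_omitted(self):
        gene = make_gene(cds_intervals=[(50, 1050)], tx_start=0, tx_end=1200)
        assert gene_termination_table(self._sites(gene, [7], []), [gene], 100) == []

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            gene_termination_table([], [], 0)

    def test_event_counts_mode(self):
        gene = make_gene(cds_intervals=[(50, 1050)], tx_start=0, tx_end=1200)
        sites = self._sites(gene, [6, 8], [100])
        (t,) = gene_termination_table(sites, [gene], 1000, count_mode="events")
        assert t.n_orf_events == 2 and t.ratio == pytest.approx(2 * 1000 / (1 * 1000))
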