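import textwrap

import pytest

from pcpa.genome_io import GeneAnnotation, GenomeSequence


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="genome.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return str(path)

    return _write


@pytest.fixture
def write_gtf(tmp_path):
    def _write(lines, name="ann.gtf"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return str(path)

    return _write


def gtf_gene(chrom, gid, tid, strand, tx_start1, tx_end1, cds_list):
    """GTF lines (1-based closed) for one single-transcript gene."""
    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
    lines = [
        f'{chrom}\tt\tgene\t{tx_start1}\t{tx_end1}\t.\t{strand}\t.\tgene_id "{gid}";',
        f"{chrom}\tt\ttranscript\t{tx_start1}\t{tx_end1}\t.\t{strand}\t.\t{attrs}",
        f"{chrom}\tt\texon\t{tx_start1}\t{tx_end1}\t.\t{strand}\t.\t{attrs}",
    ]
    for s1, e1 in cds_list:
        lines.append(f"{chrom}\tt\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\t{attrs}")
    return lines


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    cds_intervals=((50, 350),),
    tx_start=0,
    tx_end=500,
    utr_extension=1000,
    chrom_len=None,
):
    """Build a GeneAnnotation directly, deriving UTR/intron intervals."""
    from pcpa.genome_io import _derive_intervals

    cds = sorted(tuple(iv) for iv in cds_intervals)
    utr3, introns, utr5 = _derive_intervals(
        strand, chrom_len, cds, tx_start, tx_end, utr_extension
    )
    length = sum(e - s for s, e in cds)
    return GeneAnnotation(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_intervals=cds,
        tx_start=tx_start,
        tx_end=tx_end,
        utr3_interval=utr3,
        utr5_intervals=utr5,
        intron_intervals=introns,
        frame_invalid=(length % 3 != 0),
        transcript_id=f"{gene_id}.1",
    )
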