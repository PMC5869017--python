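"""Pre- and post-mapping read filters for 3'-end sequencing protocols.

Two trimming protocols are supported: the stringent nuclear 2P-seq rule
(a read must carry a run of at least 10 consecutive adenosines) and the
generic poly(A)-seq rule (at least one 3'-terminal A).  After mapping,
two orthogonal filters remove internal-priming artifacts: an A-richness
scan of the 20 nt genomic sequence downstream of the mapped 3' end, and
the untemplated-A test comparing the read's recorded tail length with
the templated genomic A-run at the mapping position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .genome_io import GenomeSequence

_POLYA_RE = re.compile(r"A{10,}")


@dataclass
class TailTrimResult:
    retained: bool
    trimmed: str
    tail_length: int
    reason: Optional[str] = None  # no_tail | too_short


def _trim_at_tail(read: str, min_tail: int, min_length: int, terminal_only: bool) -> TailTrimResult:
    read = read.upper()
    if terminal_only:
        # tail must end the read (3'-terminal A-run)
        n = len(read)
        i = n
        while i > 0 and read[i - 1] == "A":
            i -= 1
        tail = n - i
        if tail < min_tail:
            return TailTrimResult(False, "", 0, "no_tail")
        trimmed = read[:i]
    else:
        # first qualifying internal run; everything from the run onward
        # (tail + adapter remnant) is removed
        m = re.search(rf"A{{{min_tail},}}", read)
        if m is None:
            return TailTrimResult(False, "", 0, "no_tail")
        tail = m.end() - m.start()
        trimmed = read[: m.start()]
    if len(trimmed) < min_length:
        return TailTrimResult(False, trimmed, tail, "too_short")
    return TailTrimResult(True, trimmed, tail)


def trim_polya_2pseq(
    read: str, min_tail: int = 10, min_length: int = 20, terminal_only: bool = False
) -> TailTrimResult:
    """2P-seq trim: require a run of >= ``min_tail`` (default 10) consecutive
    A, remove it and everything distal, discard trimmed reads shorter than
    ``min_length`` (default 20).

    With ``terminal_only`` the A-run must end the read; by default the first
    qualifying run anywhere in the read marks the tail (adapter sequence may
    follow it).
    """
    return _trim_at_tail(read, min_tail, min_length, terminal_only)


def trim_polya_generic(read: str, min_tail: int = 1, min_length: int = 20) -> TailTrimResult:
    """Poly(A)-seq trim: strip the 3'-terminal A-stretch (>= ``min_tail`` A,
    default 1), recording its length; discard reads shorter than
    ``min_length`` after trimming."""
    return _trim_at_tail(read, min_tail, min_length, terminal_only=True)


def is_internal_priming(
    downstream: str,
    max_run: int = 6,
    window: int = 12,
    window_max_a: int = 7,
) -> bool:
    """A-richness rule on a downstream genomic sequence (transcript
    orientation): True if it contains >= ``max_run`` consecutive A, or any
    ``window``-nt window with >= ``window_max_a`` A.

    Only windows fully inside the sequence are scanned; a sequence shorter
    than ``window`` is tested for the consecutive-run rule alone.
    """
    downstream = downstream.upper()
    if "A" * max_run in downstream:
        return True
    n = len(downstream)
    if n < window:
        return False
    a_count = downstream[:window].count("A")
    if a_count >= window_max_a:
        return True
    for i in range(n - window):
        a_count += (downstream[i + window] == "A") - (downstream[i] == "A")
        if a_count >= window_max_a:
            return True
    return False


def internal_priming_filter(
    chrom: str,
    strand: str,
    end_position: int,
    genome: GenomeSequence,
    window: int = 20,
) -> bool:
    """Keep/discard decision for a mapped 3'-end position.

    Returns True (keep) unless the 20 nt genomic sequence immediately
    downstream of the 3' end, read in transcript orientation, is A-rich
    (>=6 consecutive A or >=7 A in any 12-nt window).  Windows truncated by
    the chromosome end are scanned as-is.
    """
    chrom_len = genome.length(chrom)
    if strand == "+":
        start = end_position + 1
        seq = genome.fetch(chrom, min(start, chrom_len), min(start + window, chrom_len), "+")
    else:
        end = end_position
        seq = genome.fetch(chrom, max(0, end - window), max(0, end), "-")
    return not is_internal_priming(seq)


def untemplated_a_filter(tail_length: int, genomic_downstream: str) -> bool:
    """Keep a read only if at least one tail A is untemplated.

    ``genomic_downstream`` is the genomic sequence just downstream of the
    mapped 3' end in transcript orientation; its leading A-run is the
    templated part of the observed tail.
    """
    seq = genomic_downstream.upper()
    templated = 0
    while templated < len(seq) and seq[templated] == "A":
        templated += 1
    return tail_length > templated


def filter_coverage(coverage, genome: GenomeSequence, window: int = 20):
    """Apply the internal-priming filter to every position of an
    :class:`~pcpa.genome_io.EndCoverage`; returns (kept, n_discarded_reads)."""
    from .genome_io import EndCoverage

    kept = EndCoverage()
    discarded = 0
    for chrom, strand, pos, count in coverage.positions():
        if internal_priming_filter(chrom, strand, pos, genome, window):
            kept.add(chrom, strand, pos, count)
        else:
            discarded += count
    return kept, discarded
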