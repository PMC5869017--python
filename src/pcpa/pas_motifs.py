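"""PAS hexamer discovery, PSSM construction and scoring, nucleotide profiles.

Hexamer discovery follows an iterative greedy scheme: the most common
hexamer among the remaining PAS-region sequences is tested against a
null of dinucleotide-shuffled replicates (1000 per sequence by default)
and accepted when it is at least two-fold enriched with a binomial
p < 0.05; sequences containing an accepted hexamer are removed and the
loop repeats until the top hexamer occurs in fewer than 1% of the
remaining sequences.  The shuffle preserves exact dinucleotide counts
(random Eulerian path on the dinucleotide multigraph).

The PAS scoring matrix is M_ij = log2(f_ij / g_i) over a fixed window
around the poly(A) site (e.g. -30..+10), with f_ij the per-position
nucleotide frequencies of 3'UTR PAS windows and g_i the genomic
background; a window's PAS score is the sum of its per-position entries.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genome_io import GenomeSequence, flank_window

_DNA = set("ACGT")


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def dinucleotide_shuffle(seq: str, rng: Optional[random.Random] = None, seed: Optional[int] = None) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Uses a random Eulerian path on the dinucleotide multigraph
    (Altschul-Erickson): for every non-terminal vertex a random final
    outgoing edge is drawn until the final-edge graph forms an arborescence
    into the terminal base, then the remaining edges are permuted and the
    path is walked from the original first base.  Deterministic under a
    given ``rng``/``seed``.
    """
    if rng is None:
        rng = random.Random(seed)
    s = seq.upper()
    if len(s) < 2:
        raise ValueError("sequence must have length >= 2")
    if set(s) - _DNA:
        raise ValueError("sequence contains non-ACGT characters")
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    verts = [u for u in edges if u != last]
    finals: Dict[str, str] = {}
    if verts:
        for _ in range(10000):
            finals = {u: rng.choice(edges[u]) for u in verts}
            ok = True
            for u in verts:
                seen = set()
                v = u
                while v != last:
                    if v in seen or v not in finals:
                        ok = False
                        break
                    seen.add(v)
                    v = finals[v]
                if not ok:
                    break
            if ok:
                break
        else:  # pragma: no cover - arborescence always found for real inputs
            raise RuntimeError("failed to sample an Eulerian arrangement")
    order: Dict[str, List[str]] = {}
    for u, lst in edges.items():
        rest = list(lst)
        if u in finals:
            rest.remove(finals[u])
        rng.shuffle(rest)
        if u in finals:
            rest.append(finals[u])
        order[u] = rest
    out = [s[0]]
    idx = {u: 0 for u in order}
    u = s[0]
    for _ in range(len(s) - 1):
        v = order[u][idx[u]]
        idx[u] += 1
        out.append(v)
        u = v
    return "".join(out)


@dataclass
class HexamerResult:
    hexamer: str  # RNA alphabet
    count: int  # foreground sequences containing the hexamer
    expected: float  # mean count of this hexamer across shuffled replicate sets
    fold: float  # count / expected
    p_value: float  # binomial upper tail against the modal-count null
    rank: Optional[int]
    accepted: bool
    n_sequences: int
    expected_top: float = 0.0  # null mean of the most-common-hexamer count


def _hexamers_in(seq: str) -> Iterable[str]:
    for i in range(len(seq) - 5):
        yield seq[i : i + 6]


def discover_pas_hexamers(
    pas_sequences: Sequence[str],
    n_shuffles: int = 1000,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    stop_fraction: float = 0.01,
    seed: Optional[int] = None,
    remove_on_reject: bool = False,
    max_iterations: int = 200,
) -> List[HexamerResult]:
    """Iterative enriched-hexamer discovery against a dinucleotide-shuffle null.

    Occurrence is counted at the sequence level (a hexamer is present in a
    sequence or not), matching the removal step.  Each round the most common
    hexamer among the remaining sequences is compared with ``n_shuffles``
    replicate sets, each one dinucleotide shuffle of every remaining
    sequence.  Two filters apply: the candidate's observed count must be at
    least ``min_fold`` times its mean count in the shuffled sets, and a
    binomial upper-tail p-value must fall below ``alpha``.  Because the
    candidate is the *maximum* over all hexamers, the binomial success
    probability is calibrated against the null distribution of that maximum
    (the mean count of each replicate set's own most common hexamer) rather
    than the per-hexamer shuffle frequency, which would be anti-conservative
    for the selected top candidate.  Accepted hexamers remove every sequence
    containing them and the null is re-shuffled; rejected hexamers are
    masked from further candidacy without removing sequences
    (``remove_on_reject`` flips that).  Motifs are reported in RNA alphabet.
    """
    rng = random.Random(seed)
    remaining = [s.upper() for s in pas_sequences if s and not (set(s.upper()) - _DNA)]
    masked: set = set()
    results: List[HexamerResult] = []
    rank = 0
    for _ in range(max_iterations):
        n = len(remaining)
        if n == 0:
            break
        counts: Counter = Counter()
        for s in remaining:
            counts.update(set(_hexamers_in(s)))
        candidates = sorted(counts, key=lambda h: (-counts[h], h))
        # Null statistics for the current sequence set, shared by every
        # candidate evaluated before the next removal; built lazily because
        # the stop rule may fire first.
        pool_counts: Optional[Counter] = None
        modal_mean = 0.0
        accepted_one = False
        for top in candidates:
            if top in masked:
                continue
            k = counts[top]
            if k / n < stop_fraction:
                return results
            if pool_counts is None:
                pool_counts = Counter()
                modal_total = 0
                for _r in range(n_shuffles):
                    set_counts: Counter = Counter()
                    for s in remaining:
                        set_counts.update(set(_hexamers_in(dinucleotide_shuffle(s, rng=rng))))
                    pool_counts.update(set_counts)
                    modal_total += max(set_counts.values(), default=0)
                modal_mean = modal_total / n_shuffles
            expected = pool_counts[top] / n_shuffles
            fold = k / expected if expected > 0 else math.inf
            p0_sel = min(1.0, modal_mean / n)
            p_value = float(stats.binom.sf(k - 1, n, p0_sel)) if p0_sel > 0 else 0.0
            accepted = fold >= min_fold and p_value < alpha
            if accepted:
                rank += 1
            results.append(
                HexamerResult(
                    hexamer=to_rna(top),
                    count=k,
                    expected=expected,
                    fold=fold,
                    p_value=p_value,
                    rank=rank if accepted else None,
                    accepted=accepted,
                    n_sequences=n,
                    expected_top=modal_mean,
                )
            )
            if accepted or remove_on_reject:
                remaining = [s for s in remaining if top not in s]
                accepted_one = True
                break
            masked.add(top)
        if not accepted_one:
            return results
    return results


@dataclass
class PSSM:
    """log2 frequency-ratio matrix over a window around the poly(A) site."""

    offset: int  # position of matrix column 0 relative to the pA site
    matrix: Dict[str, List[float]]  # base -> per-position M_ij
    foreground: Dict[str, List[float]]  # f_ij
    background: Dict[str, float]  # g_i
    pseudocount: float
    n_windows: int

    @property
    def length(self) -> int:
        return len(self.matrix["A"])

    def score(self, window: str) -> float:
        """PAS score S = sum_j M[base_j, j]; NaN if the window contains N."""
        window = window.upper()
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != PSSM length {self.length}")
        if set(window) - _DNA:
            return float("nan")
        return sum(self.matrix[b][j] for j, b in enumerate(window))

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            positions = [self.offset + j for j in range(self.length)]
            fh.write("base\t" + "\t".join(str(p) for p in positions) + "\n")
            for b in "ACGT":
                fh.write(b + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[b]) + "\n")


def build_pssm(
    windows: Sequence[str],
    background: Dict[str, float],
    pseudocount: float = 0.5,
    offset: int = -30,
) -> PSSM:
    """Build the PAS scoring matrix from aligned windows and genomic
    background frequencies.  Windows containing N are dropped; an empty
    usable set is an error."""
    usable = [w.upper() for w in windows if w and not (set(w.upper()) - _DNA)]
    if not usable:
        raise ValueError("no usable (N-free) windows to build a PSSM from")
    lengths = {len(w) for w in usable}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths: {sorted(lengths)}")
    L = lengths.pop()
    n = len(usable)
    fg: Dict[str, List[float]] = {b: [0.0] * L for b in "ACGT"}
    for w in usable:
        for j, b in enumerate(w):
            fg[b][j] += 1
    denom = n + 4 * pseudocount
    for b in "ACGT":
        fg[b] = [(c + pseudocount) / denom for c in fg[b]]
    matrix = {
        b: [
            math.log2(fg[b][j] / background[b]) if fg[b][j] > 0 else -math.inf
            for j in range(L)
        ]
        for b in "ACGT"
    }
    return PSSM(
        offset=offset,
        matrix=matrix,
        foreground=fg,
        background=dict(background),
        pseudocount=pseudocount,
        n_windows=n,
    )


def pas_score(window: str, pssm: PSSM) -> float:
    return pssm.score(window)


def extract_site_windows(
    sites,
    genome: GenomeSequence,
    upstream: int = 30,
    downstream: int = 10,
) -> List[str]:
    """Transcript-orientation windows -upstream..+downstream around summits.

    ``sites`` may be PolyACluster objects or (chrom, strand, summit) tuples.
    Windows truncated by chromosome bounds are skipped.
    """
    out = []
    for s in sites:
        chrom, strand, summit = _site_fields(s)
        a, b = flank_window(summit, strand, upstream, downstream)
        if a < 0 or b > genome.length(chrom):
            continue
        out.append(genome.fetch(chrom, a, b, strand))
    return out


def _site_fields(s) -> Tuple[str, str, int]:
    if isinstance(s, tuple):
        return s
    return s.chrom, s.strand, s.summit


@dataclass
class NucleotideProfile:
    """Per-position base frequencies around aligned poly(A) sites (RNA
    alphabet: T is reported as U)."""

    upstream: int
    downstream: int
    frequencies: Dict[str, List[float]]  # base (A/C/G/U) -> per-position freq
    n_sequences: int

    @property
    def positions(self) -> List[int]:
        return list(range(-self.upstream, self.downstream + 1))

    def at_content(self) -> List[float]:
        return [
            self.frequencies["A"][j] + self.frequencies["U"][j]
            for j in range(self.upstream + self.downstream + 1)
        ]


def nucleotide_profile(
    sites,
    genome: GenomeSequence,
    upstream: int = 50,
    downstream: int = 50,
) -> NucleotideProfile:
    """Positional nucleotide composition around poly(A) sites.

    Windows running off the chromosome or containing N are excluded.
    Position 0 is the mapped 3' end.
    """
    windows = [
        w for w in extract_site_windows(sites, genome, upstream, downstream)
        if not (set(w) - _DNA)
    ]
    L = upstream + downstream + 1
    freqs = {b: [0.0] * L for b in "ACGT"}
    for w in windows:
        for j, b in enumerate(w):
            freqs[b][j] += 1
    n = len(windows)
    if n:
        for b in "ACGT":
            freqs[b] = [c / n for c in freqs[b]]
    freqs["U"] = freqs.pop("T")
    return NucleotideProfile(upstream, downstream, freqs, n)


def write_motif_table(results: Sequence[HexamerResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "hexamer\tcount\texpected\tfold\tp_value\trank\taccepted\t"
            "n_sequences\texpected_top\n"
        )
        for r in results:
            fh.write(
                f"{r.hexamer}\t{r.count}\t{r.expected:.4f}\t{r.fold:.4f}\t"
                f"{r.p_value:.3e}\t{r.rank if r.rank is not None else '.'}\t"
                f"{int(r.accepted)}\t{r.n_sequences}\t{r.expected_top:.4f}\n"
            )
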