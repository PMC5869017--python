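# Methods

This note documents the models, procedures, parameter choices and known
limitations of `pcpa`.  Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted
from memory.

## Coordinate model

All internal coordinates are 0-based half-open on the plus strand of the
reference.  GTF input (1-based closed) is converted on load; BED and
bedgraph output are 0-based half-open.  A read 3'-end, cleavage site or
summit is the position of the last transcribed base.  "Downstream"
always means transcript orientation: increasing coordinates on the plus
strand, decreasing on the minus strand, with minus-strand sequence
fetches reverse-complemented.

Genes are reduced to one representative transcript: the one with the
longest CDS, ties broken by lexicographically smallest transcript id
(annotations rarely say which isoform to use; this choice is
deterministic and favours the most complete reading frame).  The 3'UTR
*search interval* runs from the CDS end to the annotated transcript 3'
end plus a 1 kb extension, because annotated 3'UTR ends are often
unreliable; the extension is a `SpeciesProfile` field.  Genes whose CDS
length is not a multiple of 3 are flagged `frame_invalid`: they still
anchor site classification but are excluded from every codon statistic.

## Read filters

Two trimming protocols: the 2P-seq rule requires a run of ≥10
consecutive A (the first qualifying run marks the tail; a
`terminal_only` switch restricts it to the read's 3' end, since the
protocol's read orientation relative to the tail can differ between
library preparations), the generic poly(A)-seq rule strips the 3'
terminal A-stretch (≥1 A) and records its length.  Both discard reads
shorter than 20 nt after trimming.

Internal priming: a mapped 3'-end is discarded when the 20 nt of genomic
sequence immediately downstream (transcript orientation) contains ≥6
consecutive A or ≥7 A in any 12-nt window.  Only the nine 12-nt windows
fully inside the 20-mer are scanned; windows truncated by a chromosome
end are scanned as-is (conservative; affects only chromosome-terminal
positions).  The untemplated-A filter keeps a read only if its recorded
tail is longer than the genomic A-run at the mapping position, i.e. at
least one tail A cannot be templated.

## Site calling

Occupied 3'-end positions on one chromosome strand chain transitively
while consecutive positions are ≤24 nt apart; clusters with <5 reads are
dropped; the summit (called poly(A) site) is the highest-count position,
ties resolved to the 5'-most position in transcript orientation.  Note
that a literal `bedtools merge -d 24` on 1-bp intervals would chain
positions up to 25 apart because it measures the gap between intervals;
this package measures the distance between occupied positions.  The
difference only matters at exactly 25 nt separation.

Classification precedence is 3'UTR > ORF > intron > 5'UTR > intergenic.
The ORF class requires the species PAS window upstream of the summit
(−30..−10 nt for the Neurospora/mouse presets, −25..−12 for fission
yeast) to lie entirely within one CDS exon — a window crossing an intron
boundary is not a coding-region PAS.  A summit claimed by two or more
same-strand genes at its winning class keeps the class but is marked
ambiguous and excluded from gene-level statistics.

The normalized ORF/3'UTR termination ratio is
`N_ORF × 1000 / (N_3'UTR × L)` with L the CDS length in nt.  Reads are
the default counting unit; cluster (event) counts are also emitted.
Genes with no 3'UTR signal are omitted (undefined ratio); the log10
ratio is NaN for genes with zero ORF signal and such genes are excluded
from correlations on the log scale.  RPM normalizes a gene's 3'UTR read
count to the total of filtered pA-supporting reads genome-wide.

## Motif discovery

The discovery loop: (1) find the most common hexamer among the remaining
PAS-region sequences (presence/absence per sequence, matching the
removal step); (2) build 1000 replicate sets, each one dinucleotide
shuffle of every remaining sequence (random Eulerian path on the
dinucleotide multigraph, so dinucleotide counts are preserved exactly);
(3) accept the candidate if its observed count is ≥2× its mean count
across replicate sets *and* a binomial upper-tail p-value is <0.05;
(4) remove all sequences containing an accepted hexamer and re-shuffle.
Stop when the top hexamer occurs in <1% of remaining sequences.
Rejected hexamers are masked from future candidacy without removing
sequences; replicate sets are reused across candidates within one
removal epoch (shuffling is only redone after sequences are removed, so
masking does not change the null).

**Calibration of the binomial test.**  The candidate in step 1 is the
*maximum* over ~4096 hexamer counts.  Testing that maximum against a
single hexamer's shuffle frequency is anti-conservative: at a few
hundred sequences the modal count of a random set sits severalfold above
any fixed hexamer's null mean, so a per-hexamer binomial would accept
most pure-null candidates.  The binomial success probability is
therefore taken as (mean modal-hexamer count across replicate sets)/n —
the null distribution of the statistic actually selected — while the
fold filter keeps the candidate's own shuffled expectation.  For a fixed
hexamer this test is conservative (the modal mean dominates every
per-hexamer mean), so the fixed-hexamer false-positive rate stays below
α; at a large number of input sequences the modal count converges to
the top per-hexamer expectation and the two formulations coincide.
Under this calibration a pure-null input (sequences that are their own
dinucleotide-matched noise) accepts no motif in ≥19 of 20 seeded runs
(`tests/test_acceptance.py`), while a 40% implanted hexamer in 1000
windows is recovered at rank 1.

Sequences containing N are excluded from discovery and from PSSM
columns.  Motifs are matched in DNA alphabet and reported in RNA
alphabet.

## PAS score

The PSSM is built from the −30..+10 windows of called 3'UTR sites:
f_ij = (count + 0.5) / (n + 2) per column (pseudocount 0.5 per cell
prevents −∞ for bases unseen in a column), g_i = genome-wide
mononucleotide frequency averaged over both strands.  M_ij =
log2(f_ij/g_i); a window's PAS score is the sum over positions of the
entry for its base, NaN if the window contains N.  With a zero
pseudocount an unseen base yields −inf, which is the mathematically
honest value for "never observed"; the default avoids it.

## Codon statistics

RSCA divides each codon's genome-wide count (over frame-valid ORFs,
stop codons excluded) by the count of its most abundant synonymous
codon.  Codons absent genome-wide receive a floor count of 0.5 before
normalization so RSCA stays in (0, 1] and the geometric mean of CAI is
defined; families with zero total get NaN.  CBI classifies codons at
RSCA ≥0.9 (optimal), 0.3–0.9 (random) and <0.3 (rare); methionine,
tryptophan and stop codons carry no synonymous choice and are excluded
from the CBI counts, as in the classical index.  CAI is the geometric
mean of RSCA over a gene's non-stop codons, computed in log domain.

NCUF/NCPF: the foreground pools the in-frame codons (or adjacent
in-frame codon pairs) lying entirely inside each ORF site's PAS window —
at most 6 complete codons for a 21-nt window.  The background pools 10
random stretches per site with the same codon count, drawn uniformly
from in-frame start positions of the same ORF outside the PAS window
(overlaps among background stretches are allowed; the sampler is
seeded).  The statistic is log2(foreground frequency / background
frequency) per codon (pair); any zero numerator or denominator is
flagged and reported as missing rather than ±∞ — missingness is more
honest than an arbitrary pseudocount.  Codon pairs are adjacent in-frame
pairs only; out-of-frame hexamers are not codon pairs.

True/false PAS: motif occurrences are located strand-specifically, ORF
occurrences fully inside one CDS exon, 3'UTR occurrences inside the
3'UTR search interval.  An occurrence is true when ≥1 called summit lies
5–35 nt downstream of the motif's 3' end on the same strand.  RCUF
pools the in-frame codons fully inside the 15-codon flanks on both sides
of each ORF occurrence (clipped at CDS bounds) per truth class and
reports log2(freq_true/freq_false) with the same zero-flagging.  A/T
content uses 80-nt flanks; edge-clipped windows are excluded.

## Synthetic data

The generator emulates the features the analysis depends on:

- **Genes.** 80 genes by default (enough for stable correlations while
  keeping a full pipeline run under a second), alternating strands,
  never overlapping; CDS length uniform 150–350 codons, 3'UTR 150–300
  nt, 5'UTR 20–60 nt, intergenic spacers 300–600 nt.
- **Codon bias.** Amino acids drawn uniformly (an AT-rich preset
  enriches Ile/Lys/Asn/Tyr); within a family the wobble base is G/C with
  per-gene probability β, drawn from U(0.2, 0.9) so the gene set spans
  rare-codon-rich to optimized genes with a G/C-preferring genome
  average, as in a C/G-biased organism.
- **Sites.** Every gene has one 3'UTR cleavage site with the PAS hexamer
  (default AAUAAA) implanted so its 3' end is 18 nt upstream of the
  site, and one ORF site whose hexamer is implanted *in frame*
  (AAT|AAA), mimicking a signal formed by rare codons.  ORF site usage
  is `0.08 × 2(1−β)` relative to the 3'UTR site in the default
  `inverse_bias` mode — premature termination concentrated in
  rare-codon genes, the condition under which the termination/codon-bias
  correlation is negative.  Per-site read counts are
  Poisson(expression × usage) with lognormal per-gene expression (mean
  400 reads, σ=0.5 — comfortably above the 5-read peak threshold so
  recovery measures the caller, not Poisson dropout).
- **Dispersion.** Read 3'-end offsets are signed two-sided geometric
  with mean magnitude 2 nt by default, producing the clustered ends the
  merge rule is designed for.
- **Artifacts.** Implanted A-runs (8 nt) in intergenic space with reads
  ending 1 nt upstream, Poisson mean 8 reads each — enough to be called
  as peaks were they not filtered.  Artifact implants never overlap each
  other, and the 20 nt downstream of every *true* site is resampled to
  fail the internal-priming trigger (and to start with a non-A, so
  simulated tails always carry an untemplated A): a genuine site inside
  a genomic A-run is indistinguishable from an artifact by construction,
  so leaving such sites in would conflate generator ambiguity with
  filter error.

Determinism: identical spec + seed give byte-identical FASTA/GTF/
bedgraph/truth output.

**What the generator does not emulate:** introns (an intron mode exists
but is off by default, so the mouse intronic-PAS path is exercised only
structurally), sequencing errors and quality variation, multi-isoform
genes, overlapping genes, heteroscedastic 3'-end chemistry, U-rich
downstream elements, and differential A/U flank composition around true
vs false motifs.  Passing tests therefore demonstrate the correctness
of the pipeline's mechanics and statistics under controlled conditions,
not the biological claims on real data.

## Problem sizes and numerical choices

Full-scale checks use 1000 PAS windows with 1000 shuffles for motif
discovery, 10⁵ random 20-mers for the priming-filter truth table, 1000
random coverages for the clustering oracle, and five independent
simulations for the correlation sign; the end-to-end recovery runs used
inside multi-seed loops reduce the shuffle count to 200, which does not
affect the quantities those loops measure.  Site recovery is scored at
±5 nt over truth sites that drew ≥5 reads — sites below the peak
threshold are unrecoverable by definition.  Pearson correlations are
computed over genes with positive ratio, RPM above threshold and
defined CBI/CAI.  Summit ties break 5'-most; major-site ties break
3'-most; both are documented deterministic choices on questions the
procedure leaves open.

## Known limitations

- The empirical PAS-window scan reports the AT-maximizing candidate
  window with a 2-standard-error enrichment margin; it never silently
  changes the species preset.
- The `-d 24` vs ≤24-apart merge discrepancy above.
- RCUF and NCUF/NCPF require frame-valid single-frame genes; genes with
  programmed frameshifts would be silently treated by annotation frame.
- With very few ORF occurrences the RCUF denominator class can be empty;
  this is an error, not a silent zero.
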