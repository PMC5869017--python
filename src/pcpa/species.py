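"""Species presets for the three analysis tracks.

Each profile bundles the protocol-dependent settings: the empirically
determined A-rich PAS window upstream of the poly(A) site, the read
protocol, the 3'UTR search extension, clustering parameters, the
internal-priming rule, and how motifs are selected for the true/false
PAS comparison (top-40 discovered hexamers, or a fixed named list as for
mouse where AAUAAA/AUUAAA dominate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    pas_window: Tuple[int, int]  # (up, down): -up..-down nt upstream of the pA site
    pssm_window: Tuple[int, int]  # (upstream, downstream) around the site, e.g. -30..+10
    protocol: str  # 2pseq | polya_seq
    utr3_extension: int = 1000
    merge_gap: int = 24
    min_reads: int = 5
    priming_window: int = 20
    priming_max_run: int = 6
    priming_window_len: int = 12
    priming_window_max_a: int = 7
    motif_selection: str = "top_n"  # top_n | named
    motif_top_n: int = 40
    named_motifs: Tuple[str, ...] = ()


NCRASSA = SpeciesProfile(
    name="ncrassa",
    pas_window=(30, 10),
    pssm_window=(30, 10),
    protocol="2pseq",
    motif_selection="top_n",
    motif_top_n=40,
)

SPOMBE = SpeciesProfile(
    name="spombe",
    pas_window=(25, 12),
    pssm_window=(30, 10),
    protocol="polya_seq",
    motif_selection="top_n",
    motif_top_n=40,
)

MOUSE = SpeciesProfile(
    name="mouse",
    pas_window=(30, 10),
    pssm_window=(30, 10),
    protocol="polya_seq",
    motif_selection="named",
    named_motifs=("AATAAA", "ATTAAA"),
)

PROFILES = {"ncrassa": NCRASSA, "spombe": SPOMBE, "mouse": MOUSE}


def get_profile(name: str) -> SpeciesProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown species profile: {name!r} (choose from {sorted(PROFILES)})")
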