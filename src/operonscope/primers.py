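"""Universal 16S primer set and IUPAC-aware matching.

The canonical primer names from the heatmap protocol (27F, 343F, 519F,
907F, 1392F, 1492F) are bundled with their standard sequences, all
stored in the forward orientation of the rRNA operon; matching tries
both orientations of a read, so forward/reverse naming of a primer is
immaterial.  A hit requires identity >= 85% over the full primer span
(ungapped, IUPAC-aware).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import revcomp

#: canonical universal primers, forward-operon orientation
DEFAULT_PRIMERS: dict[str, str] = {
    "27F": "AGAGTTTGATCMTGGCTCAG",
    "343F": "TACGGRAGGCAGCAG",
    "519F": "CAGCMGCCGCGGTAA",
    "907F": "AAACTYAAAKGAATTGACGG",
    "1392F": "GYACACACCGCCCGT",
    "1492F": "AAGTCGTAACAAGGTARCCGTA",
}

#: where each primer site is planted in the synthetic 1550 nt 16S gene
#: (kept clear of the variable intervals so sites survive divergence)
PLANT_POSITIONS: dict[str, int] = {
    "27F": 27, "343F": 343, "519F": 519, "907F": 945, "1392F": 1335, "1492F": 1490,
}

_IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_BITS = np.zeros(256, dtype=np.uint8)
for _c, _v in _IUPAC.items():
    _BITS[ord(_c)] = _v
    _BITS[ord(_c.lower())] = _v


@dataclass
class PrimerSet:
    primers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    min_identity: float = 0.85

    def __post_init__(self):
        if not 0.5 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0.5, 1]")
        for name, seq in self.primers.items():
            if not 15 <= len(seq) <= 25:
                raise ValueError(f"primer {name} must be 15-25 nt")


def iupac_bits(seq: str) -> np.ndarray:
    return _BITS[np.frombuffer(seq.encode(), dtype=np.uint8)]


def scan_primer(primer: str, seq: str, min_identity: float) -> tuple[int, float] | None:
    """Best ungapped occurrence of *primer* in *seq* at >= min_identity.

    IUPAC codes on either side count as a match when their base sets
    intersect.  Returns (position, identity) or None.
    """
    L = len(primer)
    if len(seq) < L:
        return None
    sb = iupac_bits(seq)
    pb = iupac_bits(primer)
    windows = np.lib.stride_tricks.sliding_window_view(sb, L)
    matches = ((windows & pb) != 0).sum(axis=1)
    best = int(matches.argmax())
    ident = matches[best] / L
    if ident < min_identity:
        return None
    return best, float(ident)


def resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes with a concrete base (for planting sites)."""
    out = []
    for c in seq:
        bits = _IUPAC[c.upper()]
        choices = [b for b, v in (("A", 1), ("C", 2), ("G", 4), ("T", 8)) if bits & v]
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def plant_primer_sites(s16: str, rng: np.random.Generator) -> str:
    """Overwrite the synthetic 16S backbone with concrete primer sites."""
    arr = list(s16)
    for name, pos in PLANT_POSITIONS.items():
        site = resolve_iupac(DEFAULT_PRIMERS[name], rng)
        arr[pos:pos + len(site)] = site
    return "".join(arr)


__all__ = ["DEFAULT_PRIMERS", "PLANT_POSITIONS", "PrimerSet", "scan_primer",
           "plant_primer_sites", "resolve_iupac", "iupac_bits", "revcomp"]
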