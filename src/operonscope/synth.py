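"""Synthetic rRNA-operon reference panels, communities, and noisy long reads.

The generator emulates the data a MinION 2D amplicon run of full-length
16S-ITS-23S operons produces, with ground truth attached, so that every
downstream stage (best-hit assignment, community ecology, similarity
heatmaps, consensus reconstruction, species calling) can be exercised
and verified without any external download.

Model, briefly: a random "genus backbone" operon is drawn once; each
additional species is created by substituting bases only inside a fixed
set of variable intervals (mimicking 16S V-regions and variable 23S
stretches), so realized species-vs-backbone identity is exact by
construction and a conserved 275 bp window inside 16S stays untouched.
Within a species, operon copies differ by a small substitution load,
optional ITS length polymorphism (0-150 nt indel blocks) and planted
76 nt tRNA-Ala / tRNA-Ile marker sequences inside the ITS.  Reads are
drawn multinomially per sample from configured abundances, assigned a
strand with probability 1/2, and corrupted by i.i.d. per-base
substitution / insertion / deletion errors whose rates are scaled by a
per-strand multiplier (a uniform stand-in for the direction-dependent
error structure 2D chemistry can show).
"""

from __future__ import annotations

import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from ._align import revcomp

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# planted 76 nt tRNA marker sequences (stand-ins for real tRNA genes in the ITS)
TRNA_ALA = "CAAAGGGGTACGCGAGCAGCGCGTTATTCCGTCTGCAAAAGCAAGCAATAGGTAGAGTAGTCCGAACGGGGTTATT"
TRNA_ILE = "GGCGGTCTATCGATCAGTAATATCGCGACCTTGCAGATTAAGACAACAGAGCTGACCCCGAACGGTGTCCGCAACG"

LEN_16S = 1550
LEN_ITS = 620
LEN_23S = 2900
ANCHOR_LEN = 40

#: conserved window inside 16S (0-based, half-open, 16S coordinates) that no
#: between-species substitution may touch; 275 bp, the width the short-read
#: species-identity comparison uses
CONSERVED_WINDOW_16S = (280, 555)

#: variable intervals in 16S coordinates (V-region-like; avoid the anchors and
#: the conserved window)
VARIABLE_16S = [
    (60, 120), (140, 230), (580, 680), (740, 820), (860, 940),
    (990, 1060), (1100, 1180), (1240, 1330), (1380, 1460),
]

#: variable intervals in 23S coordinates
VARIABLE_23S = [(s, s + 100) for s in range(60, LEN_23S - 160, 200)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n)]).decode()


@dataclass
class DivergenceSpec:
    """Target identity of a derived species relative to the panel backbone.

    ``target_identity`` is enforced exactly (by substitution count) over
    the 16S gene and applied at the same per-base rate inside the
    variable 23S intervals.  ``variable_mask`` holds the 16S intervals
    where substitutions may land; ``indel_rate`` adds per-base indels in
    the ITS interior only, so gene identities stay exact.
    """

    target_identity: float = 0.94
    variable_mask: Sequence[tuple[int, int]] = field(default_factory=lambda: list(VARIABLE_16S))
    indel_rate: float = 0.0

    def __post_init__(self):
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must be in (0, 1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be non-negative")


@dataclass
class ErrorModel:
    """Per-base read error rates with a strand-asymmetric component.

    ``strand_bias`` scales the i.i.d. rates per strand.  ``strand_profile``
    is the systematic component: that fraction of template positions
    (drawn once per template from ``seed``) is substituted identically in
    every reverse-direction read.  Independent noise alone cannot make
    reverse reads cluster together — noisier reads are farther from each
    other than from cleaner ones — whereas shared systematic miscalls
    reproduce the observed forward/reverse similarity split.
    """

    sub_rate: float = 0.05
    ins_rate: float = 0.015
    del_rate: float = 0.015
    strand_bias: tuple[float, float] = (1.0, 1.0)  # (fwd_factor, rev_factor)
    strand_profile: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.25:
                raise ValueError("error rates must lie in [0, 0.25]")
        if any(f <= 0 for f in self.strand_bias):
            raise ValueError("strand_bias factors must be positive")
        if not 0 <= self.strand_profile <= 0.25:
            raise ValueError("strand_profile must lie in [0, 0.25]")


@dataclass
class SampleDesign:
    """One mouse sample: group labels, taxon weights, and read depth."""

    sample_id: str
    genotype: str
    activity: str
    abundance: dict[str, float]
    n_reads: int

    def __post_init__(self):
        if self.genotype not in ("AC5KO", "WT"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.activity not in ("exercise", "sedentary"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if sum(self.abundance.values()) <= 0:
            raise ValueError("abundance weights must sum > 0")
        if any(w < 0 for w in self.abundance.values()):
            raise ValueError("abundance weights must be non-negative")


@dataclass
class ReadRecord:
    read_id: str
    sample_id: str
    sequence: str
    direction: str = "unknown"  # fwd | rev | unknown
    truth: tuple[str, int, str] | None = None  # (species_id, copy_id, direction)


@dataclass
class OperonTemplate:
    species_id: str
    copy_id: int
    sequence: str
    region_map: dict[str, tuple[int, int]]  # 16S / ITS / 23S, 0-based half-open
    trna_flags: dict[str, bool]
    its_length: int

    def __post_init__(self):
        s16, its, s23 = self.region_map["16S"], self.region_map["ITS"], self.region_map["23S"]
        if not (s16[0] == 0 and s16[1] == its[0] and its[1] == s23[0] and s23[1] == len(self.sequence)):
            raise ValueError("regions must be ordered 16S<ITS<23S and tile the sequence")
        if not 3700 <= len(self.sequence) <= 5700:
            raise ValueError("operon length outside [3700, 5700]")
        if self.its_length != its[1] - its[0]:
            raise ValueError("its_length inconsistent with ITS interval")

    def region(self, name: str) -> str:
        a, b = self.region_map[name]
        return self.sequence[a:b]


class ReferencePanel:
    """Species-labelled multi-copy operon templates with region annotations."""

    def __init__(self, templates: list[OperonTemplate]):
        if not templates:
            raise ValueError("empty panel")
        self.templates = templates
        backbone = templates[0]
        s16a, s16b = backbone.region_map["16S"]
        s23a, s23b = backbone.region_map["23S"]
        seq = backbone.sequence
        #: conserved motifs flanking the genes, used downstream to locate
        #: 16S/23S boundaries in reads and consensus sequences
        self.anchors = {
            "16S_start": seq[s16a:s16a + ANCHOR_LEN],
            "16S_end": seq[s16b - ANCHOR_LEN:s16b],
            "23S_start": seq[s23a:s23a + ANCHOR_LEN],
            "23S_end": seq[s23b - ANCHOR_LEN:s23b],
        }

    @property
    def species_ids(self) -> list[str]:
        seen: list[str] = []
        for t in self.templates:
            if t.species_id not in seen:
                seen.append(t.species_id)
        return seen

    def copies(self, species_id: str) -> list[OperonTemplate]:
        return [t for t in self.templates if t.species_id == species_id]

    def template(self, species_id: str, copy_id: int) -> OperonTemplate:
        for t in self.templates:
            if t.species_id == species_id and t.copy_id == copy_id:
                return t
        raise KeyError((species_id, copy_id))

    def ref_16s(self) -> list[tuple[str, str]]:
        """One 16S per species (first copy) — the best-hit reference db."""
        return [(s, self.copies(s)[0].region("16S")) for s in self.species_ids]

    def ref_operons(self) -> list[tuple[str, str]]:
        return [(f"{t.species_id}|c{t.copy_id}", t.sequence) for t in self.templates]


def _interval_positions(intervals: Sequence[tuple[int, int]], offset: int = 0) -> np.ndarray:
    pos = [np.arange(a + offset, b + offset) for a, b in intervals]
    return np.concatenate(pos) if pos else np.array([], dtype=int)


def _substitute(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Replace each position with a different base, in place."""
    shift = rng.integers(1, 4, positions.size).astype(np.uint8)
    codes = np.searchsorted(BASES, arr[positions])  # BASES is sorted (A<C<G<T)
    arr[positions] = BASES[(codes + shift) % 4]


def make_reference_panel(
    n_species: int,
    copies_per_species: int = 1,
    divergence: DivergenceSpec | Sequence[DivergenceSpec] | None = None,
    seed: int = 0,
    copy_sub_rate: float = 0.003,
    its_polymorphism: bool = True,
) -> ReferencePanel:
    """Generate a panel: species 1 is the backbone, species k>1 diverge from it.

    Divergence targets are enforced by counting: a species at target
    identity ``t`` carries exactly ``round((1-t)*1550)`` substitutions in
    its 16S, all inside the variable mask, plus proportional substitutions
    in variable 23S intervals.  Within a species, copies differ by
    ``copy_sub_rate`` substitutions (outside anchors and the conserved
    window), ITS indel blocks of up to 150 nt, and alternating tRNA-Ile
    markers (tRNA-Ala is present in every copy).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 1 <= copies_per_species <= 5:
        raise ValueError("copies_per_species must be in [1, 5]")
    if divergence is None:
        divergence = DivergenceSpec()
    if isinstance(divergence, DivergenceSpec):
        specs = [divergence] * max(n_species - 1, 0)
    else:
        specs = list(divergence)
        if len(specs) != n_species - 1:
            raise ValueError("need one DivergenceSpec per non-backbone species")

    rng = np.random.default_rng(seed)

    # backbone: 16S + ITS(with both markers + anchored ends) + 23S;
    # universal primer sites are planted at canonical-like 16S positions
    from .primers import plant_primer_sites

    s16 = plant_primer_sites(_random_seq(rng, LEN_16S), rng)
    its_core = _random_seq(rng, LEN_ITS - len(TRNA_ALA) - len(TRNA_ILE))
    pad = len(its_core) // 3
    its = its_core[:pad] + TRNA_ALA + its_core[pad:2 * pad] + TRNA_ILE + its_core[2 * pad:]
    s23 = _random_seq(rng, LEN_23S)
    backbone = s16 + its + s23

    window = (CONSERVED_WINDOW_16S[0], CONSERVED_WINDOW_16S[1])

    species_bases: list[tuple[str, str]] = [("sp01", backbone)]
    for k, spec in enumerate(specs, start=2):
        mask16 = [iv for iv in spec.variable_mask
                  if iv[1] <= window[0] or iv[0] >= window[1]]
        if mask16 != list(spec.variable_mask):
            raise ValueError("variable_mask overlaps the conserved 16S window")
        n_sub_16s = int(round((1 - spec.target_identity) * LEN_16S))
        cap16 = sum(b - a for a, b in mask16)
        if n_sub_16s > cap16:
            raise ValueError(
                f"divergence target {spec.target_identity} needs {n_sub_16s} "
                f"substitutions but the 16S mask holds only {cap16} positions")
        n_sub_23s = int(round((1 - spec.target_identity) * LEN_23S))
        cap23 = sum(b - a for a, b in VARIABLE_23S)
        if n_sub_23s > cap23:
            raise ValueError("divergence target exceeds 23S variable capacity")

        arr = np.frombuffer(backbone.encode(), dtype=np.uint8).copy()
        p16 = rng.choice(_interval_positions(mask16), n_sub_16s, replace=False)
        _substitute(arr, p16, rng)
        p23 = rng.choice(_interval_positions(VARIABLE_23S, offset=LEN_16S + len(its)),
                         n_sub_23s, replace=False)
        _substitute(arr, p23, rng)
        seq = bytes(arr).decode()
        if spec.indel_rate > 0:
            seq = _its_indels(seq, LEN_16S, LEN_16S + len(its), spec.indel_rate, rng)
        species_bases.append((f"sp{k:02d}", seq))

    templates: list[OperonTemplate] = []
    for species_id, base_seq in species_bases:
        its_len0 = len(base_seq) - LEN_16S - LEN_23S
        for c in range(1, copies_per_species + 1):
            seq = base_seq
            its_len = its_len0
            flags = {"ala": True, "ile": c % 2 == 1}
            if c > 1:
                # ITS-structure changes first (marker removal, indel block),
                # then point substitutions, so the region map stays exact
                if not flags["ile"]:
                    seq = seq.replace(TRNA_ILE, "", 1)
                    its_len -= len(TRNA_ILE)
                if its_polymorphism:
                    block = int(rng.integers(0, 151))
                    lo = LEN_16S + ANCHOR_LEN + 10
                    hi = LEN_16S + its_len - ANCHOR_LEN - 10
                    if block and hi > lo:
                        at = int(rng.integers(lo, hi))
                        if rng.random() < 0.5 and its_len - block > 200:
                            seq = seq[:at] + seq[at + block:]
                            its_len -= block
                        else:
                            seq = seq[:at] + _random_seq(rng, block) + seq[at:]
                            its_len += block
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                # copy-level substitutions outside anchors + conserved window
                allowed = np.ones(len(seq), dtype=bool)
                allowed[:ANCHOR_LEN] = False
                allowed[len(seq) - ANCHOR_LEN:] = False
                allowed[LEN_16S - ANCHOR_LEN:LEN_16S + ANCHOR_LEN] = False
                allowed[LEN_16S + its_len - ANCHOR_LEN:LEN_16S + its_len + ANCHOR_LEN] = False
                allowed[window[0]:window[1]] = False
                cand = np.flatnonzero(allowed)
                n_sub = int(round(copy_sub_rate * len(seq)))
                psub = rng.choice(cand, min(n_sub, cand.size), replace=False)
                _substitute(arr, psub, rng)
                seq = bytes(arr).decode()
            templates.append(OperonTemplate(
                species_id=species_id,
                copy_id=c,
                sequence=seq,
                region_map={"16S": (0, LEN_16S),
                            "ITS": (LEN_16S, LEN_16S + its_len),
                            "23S": (LEN_16S + its_len, len(seq))},
                trna_flags=flags,
                its_length=its_len,
            ))
    return ReferencePanel(templates)


def _its_indels(seq: str, its_a: int, its_b: int, rate: float, rng: np.random.Generator) -> str:
    n = int(round(rate * (its_b - its_a - 2 * ANCHOR_LEN)))
    for _ in range(n):
        at = int(rng.integers(its_a + ANCHOR_LEN, its_b - ANCHOR_LEN))
        if rng.random() < 0.5:
            seq = seq[:at] + seq[at + 1:]
            its_b -= 1
        else:
            seq = seq[:at] + _random_seq(rng, 1) + seq[at:]
            its_b += 1
    return seq


def apply_errors(sequence: str, sub: float, ins: float, dele: float,
                 rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n = arr.size
    smask = rng.random(n) < sub
    if smask.any():
        _substitute(arr, np.flatnonzero(smask), rng)
    keep = rng.random(n) >= dele
    arr = arr[keep]
    imask = rng.random(arr.size + 1) < ins
    if imask.any():
        where = np.flatnonzero(imask)
        arr = np.insert(arr, where, BASES[rng.integers(0, 4, where.size)])
    return bytes(arr).decode()


def simulate_reads(
    panel: ReferencePanel,
    designs: Sequence[SampleDesign],
    error_model: ErrorModel | None = None,
) -> list[ReadRecord]:
    """Draw reads multinomially per sample and corrupt them per strand.

    Reverse-direction reads receive errors at rates scaled by the reverse
    strand factor and are emitted reverse-complemented.  Deterministic for
    a fixed ``error_model.seed``.
    """
    if error_model is None:
        error_model = ErrorModel()
    rng = np.random.default_rng(error_model.seed)
    species = set(panel.species_ids)
    rev_templates: dict[tuple[str, int], str] = {}
    if error_model.strand_profile > 0:
        # deterministic strand-specific miscall profile, fixed per template
        for t in panel.templates:
            prng = np.random.default_rng(
                (error_model.seed, zlib.crc32(t.species_id.encode()), t.copy_id))
            arr = np.frombuffer(t.sequence.encode(), dtype=np.uint8).copy()
            k = int(round(error_model.strand_profile * arr.size))
            posn = prng.choice(arr.size, k, replace=False)
            _substitute(arr, posn, prng)
            rev_templates[(t.species_id, t.copy_id)] = bytes(arr).decode()
    reads: list[ReadRecord] = []
    for design in designs:
        unknown = set(design.abundance) - species
        if unknown:
            raise KeyError(f"abundance keys not in panel: {sorted(unknown)}")
        if design.n_reads == 0:
            logger.warning("sample %s has n_reads=0; no reads generated", design.sample_id)
            continue
        taxa = sorted(design.abundance)
        w = np.array([design.abundance[t] for t in taxa], dtype=float)
        counts = rng.multinomial(design.n_reads, w / w.sum())
        idx = 0
        for t, c in zip(taxa, counts):
            copies = panel.copies(t)
            for _ in range(c):
                tmpl = copies[int(rng.integers(0, len(copies)))]
                direction = "fwd" if rng.random() < 0.5 else "rev"
                factor = error_model.strand_bias[0 if direction == "fwd" else 1]
                source = tmpl.sequence
                if direction == "rev" and rev_templates:
                    source = rev_templates[(t, tmpl.copy_id)]
                seq = apply_errors(source,
                                   min(error_model.sub_rate * factor, 0.75),
                                   min(error_model.ins_rate * factor, 0.75),
                                   min(error_model.del_rate * factor, 0.75),
                                   rng)
                if direction == "rev":
                    seq = revcomp(seq)
                reads.append(ReadRecord(
                    read_id=f"{design.sample_id}_r{idx:05d}",
                    sample_id=design.sample_id,
                    sequence=seq,
                    direction="unknown",
                    truth=(t, tmpl.copy_id, direction),
                ))
                idx += 1
    return reads


def default_cohort(
    panel: ReferencePanel,
    n_reads: int = 200,
    group_sizes: tuple[int, int, int, int] = (3, 4, 4, 6),
    exercise_enriched: str | None = None,
    exercise_fold: float = 3.0,
    wt_sed_species: str | None = None,
) -> list[SampleDesign]:
    """Build the study's cohort design (AC5KO-ex n=3, AC5KO-sed n=4,
    WT-ex n=4, WT-sed n=6) with optional group-structured effects.

    ``exercise_enriched`` names a taxon whose weight is multiplied by
    ``exercise_fold`` in exercise samples; ``wt_sed_species`` names a
    taxon present only in WT sedentary samples (replacing the backbone
    weight there), mirroring a group-exclusive cryptic variant.
    """
    groups = [("AC5KO", "exercise", group_sizes[0]), ("AC5KO", "sedentary", group_sizes[1]),
              ("WT", "exercise", group_sizes[2]), ("WT", "sedentary", group_sizes[3])]
    taxa = panel.species_ids
    designs = []
    for genotype, activity, n in groups:
        for i in range(1, n + 1):
            ab = {t: 1.0 for t in taxa}
            if exercise_enriched and activity == "exercise":
                ab[exercise_enriched] = ab.get(exercise_enriched, 1.0) * exercise_fold
            if wt_sed_species:
                if genotype == "WT" and activity == "sedentary":
                    # the WT-sed population of this taxon IS the sister species
                    ab[wt_sed_species] = ab.get(taxa[0], 1.0)
                    ab[taxa[0]] = 0.0
                else:
                    ab[wt_sed_species] = 0.0
            ab = {t: w for t, w in ab.items() if w > 0}
            designs.append(SampleDesign(
                sample_id=f"{genotype}_{activity[:3]}_{i}",
                genotype=genotype, activity=activity,
                abundance=ab, n_reads=n_reads))
    return designs


def write_fixture(
    reads: Sequence[ReadRecord],
    panel: ReferencePanel,
    designs: Sequence[SampleDesign],
    out_dir: str | os.PathLike,
    fastq: bool = False,
) -> dict[str, str]:
    """Write reads, references, metadata and truth to *out_dir*.

    Emits reads.fasta (optionally reads.fastq), refs_16s.fasta,
    refs_operon.fasta, metadata.tsv and truth.tsv; all round-trip
    losslessly through this module's readers.
    """
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "reads": os.path.join(out, "reads.fasta"),
        "refs_16s": os.path.join(out, "refs_16s.fasta"),
        "refs_operon": os.path.join(out, "refs_operon.fasta"),
        "metadata": os.path.join(out, "metadata.tsv"),
        "truth": os.path.join(out, "truth.tsv"),
    }
    _io.write_fasta([(r.read_id, r.sequence) for r in reads], paths["reads"])
    if fastq:
        paths["reads_fastq"] = os.path.join(out, "reads.fastq")
        _io.write_fastq([(r.read_id, r.sequence) for r in reads], paths["reads_fastq"])
    _io.write_fasta(panel.ref_16s(), paths["refs_16s"])
    _io.write_fasta(panel.ref_operons(), paths["refs_operon"])
    meta = pd.DataFrame([{"sample_id": d.sample_id, "genotype": d.genotype,
                          "activity": d.activity} for d in designs],
                        columns=_io.METADATA_COLUMNS)
    _io.write_metadata(meta, paths["metadata"])
    truth = pd.DataFrame(
        [{"read_id": r.read_id, "species_id": r.truth[0], "copy_id": r.truth[1],
          "direction": r.truth[2]} for r in reads if r.truth is not None],
        columns=_io.TRUTH_COLUMNS)
    _io.write_truth(truth, paths["truth"])
    return paths
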