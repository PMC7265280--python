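"""Iterative consensus reconstruction of rRNA operons from noisy reads.

Because a genome carries several slightly different operon copies,
reads of one taxon are first annotated for the planted tRNA markers
(Ala / Ile, >= 80% identity) and for ITS length (distance between the
3' 16S anchor and the 5' 23S anchor), grouped by (tRNA flags, binned
ITS length), and each sufficiently covered group is polished
separately: the medoid read seeds the template, all reads are
star-aligned to it, columns are voted by majority (deletion is a
votable symbol, insertions are voted per gap position, ties keep the
template base), and the vote iterates until the template is a fixed
point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._align import edit_distance, locate_motif
from .msa import star_align
from .synth import TRNA_ALA, TRNA_ILE, ReadRecord, ReferencePanel

logger = logging.getLogger(__name__)


@dataclass
class ReadFeatures:
    read_id: str
    trna_ala: bool
    trna_ile: bool
    its_length: int | None


@dataclass
class FeatureGroup:
    taxon: str
    group_key: tuple[bool, bool, int | None]  # (ala, ile, its_length_bin)
    read_ids: list[str]


@dataclass
class ConsensusOperon:
    name: str
    sequence: str
    coverage: np.ndarray  # per-position supporting reads
    n_reads: int
    iterations_used: int
    converged: bool = True

    def __post_init__(self):
        if len(self.coverage) != len(self.sequence):
            raise ValueError("coverage length must equal sequence length")


def annotate_read_features(read: ReadRecord, panel: ReferencePanel,
                           marker_identity: float = 0.8) -> ReadFeatures:
    """tRNA marker flags and ITS length estimate for an oriented read."""
    seq = read.sequence
    ala = locate_motif(TRNA_ALA, seq, marker_identity) is not None
    ile = locate_motif(TRNA_ILE, seq, marker_identity) is not None
    a16 = locate_motif(panel.anchors["16S_end"], seq, marker_identity)
    a23 = locate_motif(panel.anchors["23S_start"], seq, marker_identity)
    its_len: int | None = None
    if a16 is not None and a23 is not None and a23[0] >= a16[1]:
        its_len = a23[0] - a16[1]
    else:
        logger.warning("read %s: ITS anchors not found; length unavailable", read.read_id)
    return ReadFeatures(read.read_id, ala, ile, its_len)


def group_reads(features: list[ReadFeatures], taxon: str = "",
                its_bin_width: int = 25, min_reads: int = 5) -> list[FeatureGroup]:
    """Partition reads by (ala, ile, ITS-length bin); drop thin groups.

    Reads without an ITS estimate share a bin of ``None`` (they remain
    usable for tRNA grouping).  Groups below ``min_reads`` are dropped
    with a logged reason — the generator of inadequate-coverage operons.
    """
    buckets: dict[tuple, list[str]] = {}
    for f in features:
        b = None if f.its_length is None else f.its_length // its_bin_width
        buckets.setdefault((f.trna_ala, f.trna_ile, b), []).append(f.read_id)
    groups = []
    for key in sorted(buckets, key=lambda k: (-len(buckets[k]), str(k))):
        ids = sorted(buckets[key])
        if len(ids) < min_reads:
            logger.info("group %s of taxon %s dropped: %d reads < min_reads=%d "
                        "(inadequate coverage)", key, taxon, len(ids), min_reads)
            continue
        groups.append(FeatureGroup(taxon, key, ids))
    return groups


def _medoid(seqs: list[str]) -> int:
    n = len(seqs)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i], seqs[j])
            total[i] += d
            total[j] += d
    return int(total.argmin())


def _vote(template: str, seqs: list[str]) -> tuple[str, np.ndarray]:
    """One star-alignment + majority-vote round against the template."""
    rows = star_align(template, seqs)
    tmpl_row, read_rows = rows[0], rows[1:]
    ncol = len(tmpl_row)
    mat = np.frombuffer("".join(read_rows).encode(), dtype=np.uint8).reshape(len(read_rows), ncol)
    tarr = np.frombuffer(tmpl_row.encode(), dtype=np.uint8)
    out = []
    cov = []
    symbols = np.frombuffer(b"ACGT-", dtype=np.uint8)
    counts = (mat[:, :, None] == symbols[None, None, :]).sum(axis=0)
    n_half = len(read_rows) / 2
    for c in range(ncol):
        col = counts[c]
        best = int(col.argmax())
        # tie -> keep the template's symbol at this column
        ties = np.flatnonzero(col == col[best])
        if len(ties) > 1 and tarr[c] in symbols[ties]:
            best = int(np.flatnonzero(symbols == tarr[c])[0])
        if tarr[c] == ord("-"):
            # insertion column: emit only if a majority of reads support it
            if col[best] <= n_half or symbols[best] == ord("-"):
                continue
        if symbols[best] == ord("-"):
            continue
        out.append(chr(symbols[best]))
        cov.append(int(col[:4].sum()))
    return "".join(out), np.array(cov)


def build_consensus(reads: list[ReadRecord], name: str = "consensus",
                    max_iter: int = 10, min_reads: int = 5) -> ConsensusOperon:
    """Iterative star-alignment consensus of one feature group.

    The medoid read (smallest summed edit distance to the others) seeds
    the template; voting and realignment repeat until the sequence is
    unchanged or ``max_iter`` rounds have run (then the last consensus
    is returned flagged unconverged).  Deterministic.
    """
    if len(reads) < min_reads:
        raise ValueError(f"need at least {min_reads} reads, got {len(reads)}")
    seqs = [r.sequence for r in reads]
    template = seqs[_medoid(seqs)]
    cov = np.full(len(template), len(seqs))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new, cov = _vote(template, seqs)
        if new == template:
            converged = True
            break
        template = new
    if not converged:
        logger.warning("consensus %s did not converge in %d iterations", name, max_iter)
    return ConsensusOperon(name, template, cov, len(seqs), it, converged)


def reconstruct_taxon(
    reads: list[ReadRecord],
    taxon: str,
    panel: ReferencePanel,
    metadata=None,
    its_bin_width: int = 25,
    min_reads: int = 5,
    max_iter: int = 10,
) -> list[ConsensusOperon]:
    """Group oriented reads of one taxon (optionally per genotype x
    activity sample-group) and build one consensus per kept group.

    Variant names carry the taxon, sample-group, and an _A/_B/... suffix
    assigned by descending group size.
    """
    by_id = {r.read_id: r for r in reads}
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        group_of = {rid: f"{meta.loc[r.sample_id, 'genotype']}-{meta.loc[r.sample_id, 'activity']}"
                    for rid, r in by_id.items()}
    else:
        group_of = {rid: "all" for rid in by_id}
    out = []
    for sg in sorted(set(group_of.values())):
        sg_reads = [r for r in reads if group_of[r.read_id] == sg]
        feats = [annotate_read_features(r, panel) for r in sg_reads]
        groups = group_reads(feats, taxon, its_bin_width, min_reads)
        for vi, g in enumerate(groups):
            suffix = chr(ord("A") + vi)
            members = [by_id[i] for i in g.read_ids]
            cons = build_consensus(members, f"{taxon}|{sg}|rRNA_{suffix}",
                                   max_iter=max_iter, min_reads=min_reads)
            out.append(cons)
    return out
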