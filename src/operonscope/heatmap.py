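"""Similarity-ordered heatmaps: the cryptic-variant detector.

For one best-hit taxon, the top reads of every sample are pooled,
oriented by universal-primer annotation (reads without any primer hit
are discarded), compared all-against-all to build a pairwise identity
matrix, reordered by average-linkage dendrogram leaf order so block
structure becomes visible, cut into clusters (at a threshold, or
automatically at the largest gap in the sorted merge heights), and
each cluster is attributed to its sample-group and read-direction
sources.  A cluster dominated by one genotype x activity group is
flagged group-exclusive — the machine analogue of reading the pie
charts next to the heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

from ._align import global_identity, revcomp
from .primers import PrimerSet, scan_primer
from .synth import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class PrimerAnnotation:
    read_id: str
    hits: list[tuple[str, int, str, float]]  # (primer, position, strand, identity)
    inferred_direction: str  # fwd | rev | none


def annotate_and_orient(read: ReadRecord, primers: PrimerSet | None = None
                        ) -> tuple[ReadRecord, PrimerAnnotation]:
    """Annotate universal primers and orient the read forward.

    Every primer is scanned against the read and its reverse complement;
    the direction is the majority strand of the hits (ties or zero hits
    give ``none``, and such reads are discarded downstream).  The
    returned read carries the forward-orientation sequence when a
    direction was inferred.
    """
    primers = primers or PrimerSet()
    rc = revcomp(read.sequence)
    hits = []
    votes = {"+": 0, "-": 0}
    for name, pseq in sorted(primers.primers.items()):
        for strand, target in (("+", read.sequence), ("-", rc)):
            hit = scan_primer(pseq, target, primers.min_identity)
            if hit is not None:
                hits.append((name, hit[0], strand, hit[1]))
                votes[strand] += 1
    if votes["+"] == votes["-"]:
        direction = "none"
        oriented = read
    elif votes["+"] > votes["-"]:
        direction = "fwd"
        oriented = ReadRecord(read.read_id, read.sample_id, read.sequence, "fwd", read.truth)
    else:
        direction = "rev"
        oriented = ReadRecord(read.read_id, read.sample_id, rc, "rev", read.truth)
    return oriented, PrimerAnnotation(read.read_id, hits, direction)


def orient_reads(reads: list[ReadRecord], primers: PrimerSet | None = None
                 ) -> tuple[list[ReadRecord], list[PrimerAnnotation]]:
    """Orient a read set; reads with no inferrable direction are dropped."""
    oriented, annotations = [], []
    for r in reads:
        o, ann = annotate_and_orient(r, primers)
        annotations.append(ann)
        if ann.inferred_direction == "none":
            logger.warning("read %s lacks primer annotation; discarded", r.read_id)
            continue
        oriented.append(o)
    return oriented, annotations


def select_top_reads(records: pd.DataFrame, reads: list[ReadRecord], taxon: str,
                     n_per_sample: int = 15) -> list[ReadRecord]:
    """Per sample, the n best reads of one taxon by identity x alignment length.

    Ties break by read id; samples with fewer hits contribute all of them.
    """
    sub = records[records["ref_id"] == taxon].copy()
    if sub.empty:
        logger.warning("taxon %s has no best-hit records", taxon)
        return []
    sub["rank_score"] = sub["identity"] * sub["aln_length"]
    sub = sub.sort_values(["sample_id", "rank_score", "read_id"],
                          ascending=[True, False, True], kind="stable")
    keep = sub.groupby("sample_id", sort=False).head(n_per_sample)
    wanted = set(keep["read_id"])
    return [r for r in reads if r.read_id in wanted]


def pairwise_identity_matrix(reads: list[ReadRecord]) -> DistanceMatrix:
    """All-pairs global-alignment distance (1 - identity) of oriented reads.

    Pairs whose lengths differ by more than 2x are not aligned; they are
    flagged and assigned the maximum observed distance plus epsilon.
    """
    n = len(reads)
    if n < 3:
        raise ValueError("need at least 3 reads")
    d = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i].sequence, reads[j].sequence
            if max(len(a), len(b)) > 2 * min(len(a), len(b)):
                flagged.append((i, j))
                continue
            m, c = global_identity(a, b)
            d[i, j] = d[j, i] = 1.0 - m / c
    if flagged:
        mx = d.max()
        for i, j in flagged:
            d[i, j] = d[j, i] = mx + 0.01
        logger.warning("%d read pair(s) differ >2x in length; distance set to max+eps",
                       len(flagged))
    return DistanceMatrix(d, ids=[r.read_id for r in reads])


@dataclass
class SeriationResult:
    ordering: list[str]  # read ids in dendrogram leaf order
    clusters: list[list[str]]  # contiguous blocks partitioning the ordering
    merge_heights: list[float]
    cut_height: float | None  # None when no significant gap (single cluster)
    silhouette: float | None = None
    linkage: np.ndarray | None = field(default=None, repr=False)


def seriate_and_cluster(d: DistanceMatrix, linkage: str = "average",
                        cut: float | None = None, gap_factor: float = 8.0,
                        max_auto_clusters: int = 8) -> SeriationResult:
    """Average-linkage seriation and cluster extraction.

    The ordering is the dendrogram leaf order.  With ``cut=None`` the
    tree is cut at the largest gap between consecutive sorted merge
    heights, restricted to cuts yielding at most ``max_auto_clusters``
    clusters, and only when that gap exceeds ``gap_factor`` times the
    mean of the remaining gaps — otherwise the matrix is reported as a
    single cluster (the no-structure reading of a uniform heatmap).
    """
    ids = list(d.ids)
    n = len(ids)
    Z = sch.linkage(squareform(d.data, checks=False), method=linkage)
    leaf_order = sch.leaves_list(Z)
    ordering = [ids[i] for i in leaf_order]
    heights = np.sort(Z[:, 2])

    threshold = cut
    if threshold is None:
        m = len(heights)
        gaps = np.diff(heights)
        # cutting between heights[i] and heights[i+1] yields m - i clusters
        cand = [i for i in range(m - 1) if (m - i) <= max_auto_clusters]
        if cand and gaps.max() > 1e-12:
            i = max(cand, key=lambda i: gaps[i])
            rest = np.delete(gaps, i)
            mean_rest = rest.mean() if len(rest) else 0.0
            if gaps[i] > gap_factor * mean_rest:
                threshold = float((heights[i] + heights[i + 1]) / 2)

    if threshold is None:
        labels = np.ones(n, dtype=int)
    else:
        labels = sch.fcluster(Z, t=threshold, criterion="distance")

    # clusters as contiguous blocks in leaf order
    blocks: list[list[str]] = []
    prev = None
    for pos in leaf_order:
        lab = labels[pos]
        if lab != prev:
            blocks.append([])
            prev = lab
        blocks[-1].append(ids[pos])

    sil = None
    if threshold is not None and 1 < len(set(labels)) < n:
        sil = float(silhouette_score(d.data, labels, metric="precomputed"))
    return SeriationResult(ordering, blocks, heights.tolist(), threshold, sil, Z)


def source_composition(result: SeriationResult, reads: list[ReadRecord],
                       metadata: pd.DataFrame, truth: pd.DataFrame | None = None,
                       exclusive_threshold: float = 0.9) -> list[dict]:
    """Per-cluster source attribution: sample-group and read-direction
    fractions, a group-exclusive flag, and (with truth) species purity."""
    meta = metadata.set_index("sample_id")
    by_id = {r.read_id: r for r in reads}
    truth_species = truth.set_index("read_id")["species_id"] if truth is not None else None
    truth_dir = truth.set_index("read_id")["direction"] if truth is not None else None
    report = []
    for ci, block in enumerate(result.clusters):
        groups: dict[str, int] = {}
        dirs: dict[str, int] = {}
        species: dict[str, int] = {}
        for rid in block:
            r = by_id[rid]
            g = f"{meta.loc[r.sample_id, 'genotype']}_{meta.loc[r.sample_id, 'activity']}"
            groups[g] = groups.get(g, 0) + 1
            dr = r.direction
            if truth_dir is not None and rid in truth_dir.index:
                dr = truth_dir[rid]
            dirs[dr] = dirs.get(dr, 0) + 1
            if truth_species is not None and rid in truth_species.index:
                sp = truth_species[rid]
                species[sp] = species.get(sp, 0) + 1
        total = len(block)
        gfrac = {g: c / total for g, c in sorted(groups.items())}
        entry = {
            "cluster": ci,
            "n_reads": total,
            "group_fractions": gfrac,
            "direction_fractions": {k: c / total for k, c in sorted(dirs.items())},
            "exclusive_group": next((g for g, f in gfrac.items()
                                     if f >= exclusive_threshold), None),
        }
        if species:
            top = max(sorted(species), key=lambda s: species[s])
            entry["majority_species"] = top
            entry["purity"] = species[top] / total
        report.append(entry)
    return report
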