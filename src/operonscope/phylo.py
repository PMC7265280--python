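"""Species-level verification of consensus operons.

Extracts 16S/23S gene regions by conserved anchor motifs, aligns
consensus and reference operons (star alignment), restricts every
comparison to unambiguously aligned columns (gap-free, ACGT-only in
all rows), computes identity matrices over the full region or a short
window, applies the conventional 97% 16S species threshold (strictly
"above 97%" means same species), and builds neighbor-joining trees
from Jukes-Cantor distances with column-resampling bootstrap supports.

The tree method is deliberately a distance method: the study question
is whether operon copies and group-specific variants resolve into
species/strain clusters, which NJ answers at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from ._align import locate_motif, revcomp
from .msa import star_align

logger = logging.getLogger(__name__)


def extract_region(sequence: str, anchors: dict[str, str], region: str,
                   min_identity: float = 0.8) -> str:
    """Cut the 16S or 23S gene out of an operon-scale sequence.

    The region spans from the start-anchor hit to the end-anchor hit
    (anchor motifs included).  Orientation-invariant: when the anchors
    are not found forward, the reverse complement is tried.
    """
    if region not in ("16S", "23S"):
        raise ValueError("region must be '16S' or '23S'")
    for seq in (sequence, revcomp(sequence)):
        a = locate_motif(anchors[f"{region}_start"], seq, min_identity)
        b = locate_motif(anchors[f"{region}_end"], seq, min_identity)
        if a is not None and b is not None and b[1] > a[0]:
            return seq[a[0]:b[1]]
    raise ValueError(f"{region} anchors not found at >={min_identity:.0%} identity")


@dataclass
class RegionAlignment:
    names: list[str]
    rows: list[str]  # aligned, equal length
    mask: np.ndarray  # True at unambiguous columns (gap-free, ACGT in all rows)
    region: str
    #: column index in the alignment of each position of the center (longest)
    #: sequence — lets windows given in center coordinates be mapped
    center_columns: np.ndarray | None = None
    center_name: str | None = None

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_matrix(self) -> np.ndarray:
        mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return mat.reshape(len(self.rows), -1)[:, self.mask]


def align_and_mask(seqs: dict[str, str], region: str = "16S") -> RegionAlignment:
    """Star-align sequences to the longest one and mask ambiguous columns."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    names = list(seqs)
    center_name = max(names, key=lambda n: (len(seqs[n]), n))
    others = [n for n in names if n != center_name]
    rows = star_align(seqs[center_name], [seqs[n] for n in others])
    ordered_names = [center_name] + others
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    ok = np.zeros(mat.shape[1], dtype=bool)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok = np.isin(mat, acgt).all(axis=0)
    if not ok.any():
        raise ValueError("no unambiguously aligned columns")
    center_cols = np.flatnonzero(
        np.frombuffer(rows[0].encode(), dtype=np.uint8) != ord("-"))
    return RegionAlignment(ordered_names, rows, ok, region, center_cols, center_name)


def identity_matrix(aln: RegionAlignment,
                    window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Pairwise identity over unambiguous columns.

    ``window = (start, length)`` restricts the comparison to the slice of
    the center sequence's coordinates (the short-read emulation); the
    window must retain at least one unambiguous column.
    """
    mask = aln.mask.copy()
    if window is not None:
        start, length = window
        if start < 0 or start + length > len(aln.center_columns):
            raise ValueError("window outside the center sequence")
        wmask = np.zeros_like(mask)
        wmask[aln.center_columns[start:start + length]] = True
        mask &= wmask
        if not mask.any():
            raise ValueError("window contains no unambiguous columns")
    mat = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8)
    mat = mat.reshape(len(aln.rows), -1)[:, mask]
    eq = (mat[:, None, :] == mat[None, :, :]).mean(axis=2)
    return pd.DataFrame(eq, index=aln.names, columns=aln.names)


def call_species(matrix: pd.DataFrame, threshold: float = 0.97) -> pd.DataFrame:
    """Pairwise species calls: same species iff identity > threshold (strict)."""
    rows = []
    names = list(matrix.index)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ident = float(matrix.loc[a, b])
            rows.append({"seq_a": a, "seq_b": b, "identity": ident,
                         "same_species": ident > threshold})
    return pd.DataFrame(rows)


def jukes_cantor(aln: RegionAlignment) -> DistanceMatrix:
    """Jukes-Cantor distances over unambiguous columns."""
    mat = aln.masked_matrix()
    p = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    if (p >= 0.75).any():
        i, j = np.argwhere(p >= 0.75)[0]
        raise ValueError(f"saturated distance between {aln.names[i]} and {aln.names[j]}")
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2, ids=aln.names)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, canonicalized to the side not
    containing the lexicographically smallest taxon."""
    ref = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


@dataclass
class PhyloTree:
    newick: str
    n_bootstrap: int
    tree: TreeNode

    def supports(self) -> dict[frozenset, float]:
        taxa = frozenset(t.name for t in self.tree.tips())
        ref = min(taxa)
        out = {}
        for node in self.tree.non_tips(include_self=False):
            if node.name is None:
                continue
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = taxa - side
            out[side] = float(node.name)
        return out


def nj_bootstrap_tree(aln: RegionAlignment, n_bootstrap: int = 100,
                      seed: int = 0) -> PhyloTree:
    """Neighbor-joining tree with column-resampling bootstrap supports.

    Supports (percent of replicates containing each internal
    bipartition) are written as internal node labels; negative NJ branch
    lengths are clamped to zero by the NJ implementation.
    """
    if len(aln.names) < 4:
        raise ValueError("need at least 4 sequences")
    tree = nj(jukes_cantor(aln))
    taxa = frozenset(aln.names)
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(tree, taxa)}

    mat = aln.masked_matrix()
    m = mat.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_bootstrap):
        cols = rng.integers(0, m, m)
        sub = mat[:, cols]
        p = (sub[:, None, :] != sub[None, :, :]).mean(axis=2)
        p = np.minimum(p, 0.7499)  # saturation guard inside replicates
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
        bt = nj(DistanceMatrix((d + d.T) / 2, ids=aln.names))
        bps = _bipartitions(bt, taxa)
        for bp in counts:
            if bp in bps:
                counts[bp] += 1

    ref = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if side in counts:
            node.name = str(round(100.0 * counts[side] / n_bootstrap))
    newick = str(tree).strip()
    return PhyloTree(newick, n_bootstrap, tree)
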