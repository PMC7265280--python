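"""Community-level statistics for the sample x taxon count table.

Implements the study's ecology stack: fourth-root transform,
Bray-Curtis dissimilarity, non-metric multidimensional scaling (SMACOF
iterations with Kruskal stress-1 and primary tie handling), a
two-factor sequential PERMANOVA in the style of vegan's ``adonis``
(terms activity, genotype, activity x genotype), alpha diversity
(bias-corrected Chao1, Shannon with natural log, exact hypergeometric
rarefaction) and group-enrichment ranking by difference of group means.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.diversity import alpha as _alpha

from .bbh import CountTable

logger = logging.getLogger(__name__)


def fourth_root(table: CountTable) -> CountTable:
    """Element-wise x**(1/4); rejects negative entries."""
    if (table.counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    return CountTable(table.counts ** 0.25, normalized=False)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y).

    A pair of all-zero samples gets distance 0 with a warning.
    """
    X = table.counts.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    if (den == 0).any():
        logger.warning("all-zero sample pair(s); Bray-Curtis set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=list(table.counts.index))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # n x k
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int


def kruskal_stress(config_d: np.ndarray, disparities: np.ndarray) -> float:
    ss = float((config_d ** 2).sum())
    if ss == 0:
        return 0.0
    return math.sqrt(float(((config_d - disparities) ** 2).sum()) / ss)


def _disparities(diss: np.ndarray, cd: np.ndarray) -> np.ndarray:
    """Monotone (PAVA) fit of configuration distances against
    dissimilarity order, with Kruskal's primary treatment of ties:
    tied dissimilarities are sub-ordered by current distance, so ties
    impose no constraint."""
    order = np.lexsort((cd, diss))
    fit = isotonic_regression(cd[order]).x
    out = np.empty_like(cd)
    out[order] = fit
    return out


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 16,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    The first start is the classical-scaling (PCoA) configuration; the
    remaining ``n_starts - 1`` are seeded random configurations, so the
    start set for a larger ``n_starts`` nests the smaller one and the
    best stress is monotone non-increasing in ``n_starts``.
    """
    n = d.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    diss = squareform(d.data, checks=False)
    if np.allclose(diss, diss[0]):
        logger.warning("all dissimilarities equal; NMDS configuration is degenerate")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)

    best_X, best_stress = None, np.inf
    for start in range(max(n_starts, 1)):
        if start == 0:
            X = _classical_mds(d.data, k)
        else:
            X = rng.standard_normal((n, k))
        prev = np.inf
        stress = np.inf
        for _ in range(max_iter):
            full = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
            cd = full[iu]
            dhat = _disparities(diss, cd)
            stress = kruskal_stress(cd, dhat)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(full > 0, 1.0, 0.0)
                W = np.zeros_like(full)
                W[iu] = np.where(cd > 0, dhat / np.maximum(cd, 1e-300), 0.0)
                W = W + W.T
            B = -W
            np.fill_diagonal(B, W.sum(axis=1))
            X = B @ X / n
        if stress < best_stress:
            best_stress, best_X = stress, X.copy()

    coords = pd.DataFrame(best_X, index=list(d.ids),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coords, float(best_stress), n_starts, seed)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms + Residual + Total; cols df, SS, pseudo_F, R2, p_value
    n_permutations: int | None
    seed: int | None

    def __post_init__(self):
        r2 = self.table.loc[self.table.index != "Total", "R2"].sum()
        if abs(r2 - 1.0) > 1e-9:
            raise ValueError("term + residual R2 must sum to 1")


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    return pd.get_dummies(cats, drop_first=True).values.astype(float)


def _hat(M: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(M)
    rank = int((np.abs(np.diag(R)) > 1e-10).sum())
    Q = Q[:, :rank]
    return Q @ Q.T, rank


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("activity", "genotype", "activity:genotype"),
    n_perm: int | None = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA of a distance matrix, adonis-style.

    Squared distances are Gower-centered; each term's SS is the trace
    increment of its sequential hat projector; pseudo-F uses the
    residual mean square; the p-value is (1 + #{permuted F >= observed})
    / (1 + n_perm) under raw-label permutation.  ``n_perm=None``
    enumerates all n! index permutations exactly (small n only) and
    reports p = #{F >= observed}/n!.
    """
    ids = list(d.ids)
    meta = metadata.set_index("sample_id").loc[ids]
    n = len(ids)
    D2 = d.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J

    design_cols = [np.ones((n, 1))]
    dfs = []
    prev_hat, prev_rank = _hat(np.ones((n, 1)))
    hats = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            A, B = _dummy(meta[a]), _dummy(meta[b])
            cols = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
        else:
            if meta[term].nunique() < 2:
                raise ValueError(f"term {term} has a single level")
            if meta[term].value_counts().min() < 2:
                raise ValueError(f"term {term} has a level with <2 samples")
            cols = _dummy(meta[term])
        design_cols.append(cols)
        M = np.hstack(design_cols)
        H, rank = _hat(M)
        df = rank - prev_rank
        if df < 1:
            raise ValueError(f"term {term} is aliased (no residual df)")
        hats.append(H - prev_hat)
        dfs.append(df)
        prev_hat, prev_rank = H, rank
    resid_proj = np.eye(n) - prev_hat
    df_res = n - prev_rank
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    ss_total_ref = float(np.trace(G))

    def stats(Gp):
        ss = np.array([float((Hk * Gp).sum()) for Hk in hats])
        ss_res = float((resid_proj * Gp).sum())
        # floor the residual mean square so a (near-)perfect fit yields a
        # stable, comparable F instead of floating-point noise
        ms_res = max(ss_res / df_res, 1e-12 * max(ss_total_ref, 1e-300))
        F = (ss / np.array(dfs)) / ms_res
        return ss, ss_res, F

    ss, ss_res, F_obs = stats(G)
    ss_total = float(np.trace(G))

    if n_perm is None:
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            _, _, F = stats(G[np.ix_(p, p)])
            count += F >= F_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = None
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, _, F = stats(G[np.ix_(p, p)])
            count += F >= F_obs - 1e-12
        pvals = (1 + count) / (1 + n_perm)
        n_used = n_perm

    rows = []
    for i, term in enumerate(terms):
        rows.append({"df": dfs[i], "SS": ss[i], "pseudo_F": F_obs[i],
                     "R2": ss[i] / ss_total, "p_value": pvals[i]})
    rows.append({"df": df_res, "SS": ss_res, "pseudo_F": np.nan,
                 "R2": ss_res / ss_total, "p_value": np.nan})
    rows.append({"df": n - 1, "SS": ss_total, "pseudo_F": np.nan,
                 "R2": 1.0, "p_value": np.nan})
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table, n_used, seed if n_perm is not None else None)


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample bias-corrected Chao1 and Shannon (natural log).

    Counts are rounded to integers for Chao1 (normalization produces
    non-integers); Shannon uses the relative abundances as given.
    """
    rows = {}
    for s in table.samples:
        x = table.counts.loc[s].values
        if x.sum() == 0:
            raise ValueError(f"sample {s} is empty")
        xi = np.round(x).astype(int)
        rows[s] = {"chao1": float(_alpha.chao1(xi, bias_corrected=True)),
                   "shannon": float(_alpha.shannon(x, base=math.e))}
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(counts: np.ndarray | pd.Series, depths: list[int]) -> pd.DataFrame:
    """Expected richness at each subsampling depth (exact hypergeometric).

    E[S | depth] = sum_i (1 - C(N - n_i, depth) / C(N, depth)).
    """
    x = np.round(np.asarray(counts, dtype=float)).astype(int)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample")
    N = int(x.sum())
    rows = []
    for depth in depths:
        if depth > N or depth < 0:
            raise ValueError(f"depth {depth} outside [0, {N}]")
        # log C(N - n_i, d) - log C(N, d), defined when N - n_i >= d
        ok = (N - x) >= depth
        logp = np.full(x.shape, -np.inf)
        ni = x[ok]
        logp[ok] = (gammaln(N - ni + 1) - gammaln(depth + 1) - gammaln(N - ni - depth + 1)
                    - (gammaln(N + 1) - gammaln(depth + 1) - gammaln(N - depth + 1)))
        rows.append({"depth": depth, "expected_richness": float((1 - np.exp(logp)).sum())})
    return pd.DataFrame(rows)


def enrichment(table: CountTable, metadata: pd.DataFrame, by: str, top_k: int = 10) -> pd.DataFrame:
    """Top-k taxa by |difference of group means| for a two-level grouping.

    The within-group mean and SD are reported for the enriched group
    (the one with the larger mean for that taxon).
    """
    groups = metadata.set_index("sample_id").loc[table.samples, by]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {by} must have exactly two levels, got {levels}")
    a, b = levels
    mean_a = table.counts[groups.values == a].mean()
    mean_b = table.counts[groups.values == b].mean()
    diff = mean_a - mean_b
    rows = []
    for taxon in table.taxa:
        enriched = a if diff[taxon] >= 0 else b
        sub = table.counts.loc[groups.values == enriched, taxon]
        rows.append({"taxon": taxon, f"mean_{a}": mean_a[taxon], f"mean_{b}": mean_b[taxon],
                     "difference": diff[taxon], "enriched_group": enriched,
                     "sd_within_enriched_group": float(sub.std(ddof=1))})
    df = pd.DataFrame(rows)
    df = df.sort_values(["difference", "taxon"],
                        key=lambda c: -c.abs() if c.name == "difference" else c,
                        kind="stable").reset_index(drop=True)
    return df.head(top_k)
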