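"""Network-weighted pathway enrichment: scores, permutation p-values, z features.

The enrichment statistic treats a pathway as a network rather than a bag of
genes.  For measured pathway nodes V with non-negative gene-level
perturbation scores s(v), topological weights w(v) and undirected
shortest-path distances d(u, v):

    score = [ sum_v w(v) s(v) / sum_v w(v) ]
            * [ 1 + sum_{u<v} s(u) s(v) k(d(u,v)) / sum_{u<v} s(u) s(v) ]

with proximity kernel k(d) = 1 / (1 + d) and k(inf) = 0.  The first bracket
rewards perturbation concentrated near the transcription-triggering end of
the pathway; the second rewards perturbed genes that cluster on the network.
Significance comes from a permutation null that reassigns the observed
score multiset over the measured gene universe, and each p-value is turned
into the feature z = Phi^{-1}(1 - p).

Two variants: continuous gene scores (expression studies) and a 0/1
indicator for membership in a gene set (polymorphism-style gene lists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pathways import DistanceTable, NodeWeighting, PathwayNetwork

__all__ = [
    "ExpressionMatrix",
    "GeneScoreTable",
    "EnrichmentResult",
    "PathwaySkipped",
    "quantile_normalize",
    "gene_scores",
    "sepea_score",
    "sepea_nt3_score",
    "permutation_pvalue",
    "p_to_z",
    "feature_vector",
    "pathway_feature_matrix",
    "read_expression_tsv",
    "write_expression_tsv",
]

DEFAULT_PERMUTATIONS = 50_000


class PathwaySkipped(ValueError):
    """Raised when a pathway has no node measured in the gene universe."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with treated/control labels.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``groups``: Series mapping sample id -> 'treated' | 'control'.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {"treated", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class GeneScoreTable:
    """Per-gene perturbation magnitudes over a measured gene universe."""

    scores: Mapping[str, float]
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        stray = set(self.scores) - self.universe
        if stray:
            raise ValueError(f"scored genes outside the universe: {sorted(stray)[:5]}")
        for g, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for gene {g!r}")

    def get(self, gene: str) -> float:
        return float(self.scores.get(gene, 0.0))


@dataclass
class EnrichmentResult:
    pathway_id: str
    score: float
    p_value: float
    z: float
    n_permutations: int


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization across samples.

    Each sample's values are replaced by the mean of the sorted values
    across samples at the same rank; ties within a sample get the mean of
    the reference values over the tied rank span, so column value-multisets
    become identical.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n, m = vals.shape
    if m < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return matrix
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = reference.copy()
        # average the reference over runs of tied values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for a, b in zip(starts, ends):
            if b - a > 1:
                assigned[a:b] = reference[a:b].mean()
        out[order, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups,
    )


def gene_scores(matrix: ExpressionMatrix) -> GeneScoreTable:
    """Absolute pooled-variance two-sample t statistic per gene.

    Zero-variance genes with equal group means score 0; zero pooled
    variance with unequal means scores the maximum finite score in the
    table (assigned after all finite scores are known).
    """
    treated = matrix.samples_in("treated")
    control = matrix.samples_in("control")
    for name, grp in (("treated", treated), ("control", control)):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 {name} samples, got {len(grp)}")
    xt = matrix.values[treated].to_numpy(dtype=float)
    xc = matrix.values[control].to_numpy(dtype=float)
    nt, nc = xt.shape[1], xc.shape[1]
    mt, mc = xt.mean(axis=1), xc.mean(axis=1)
    vt, vc = xt.var(axis=1, ddof=1), xc.var(axis=1, ddof=1)
    pooled = ((nt - 1) * vt + (nc - 1) * vc) / (nt + nc - 2)
    denom = np.sqrt(pooled * (1.0 / nt + 1.0 / nc))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mt - mc) / denom
    zero_var = denom == 0
    equal_means = np.abs(mt - mc) == 0
    t[zero_var & equal_means] = 0.0
    degenerate = zero_var & ~equal_means
    finite = t[~degenerate]
    t[degenerate] = finite.max(initial=0.0)
    genes = matrix.values.index
    return GeneScoreTable(dict(zip(genes, t.astype(float))), frozenset(genes))


def _kappa_matrix(nodes: Sequence, dist: DistanceTable) -> np.ndarray:
    """Proximity kernel matrix k(d) = 1/(1+d), zero diagonal, 0 when disconnected."""
    m = len(nodes)
    kap = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = dist.get(nodes[i], nodes[j])
            k = 0.0 if np.isinf(d) else 1.0 / (1.0 + d)
            kap[i, j] = kap[j, i] = k
    return kap


def _bulk_scores(S: np.ndarray, w: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Enrichment scores for many score assignments at once.

    S is (draws, m): each row assigns scores to the m measured nodes.
    """
    first = S @ w / w.sum()
    m = S.shape[1]
    if m < 2:
        return first
    num = 0.5 * np.einsum("ij,ij->i", S @ kappa, S)
    tot = 0.5 * (S.sum(axis=1) ** 2 - (S**2).sum(axis=1))
    second = np.where(tot > 0, 1.0 + num / np.where(tot > 0, tot, 1.0), 1.0)
    return first * second


def _measured_nodes(net: PathwayNetwork, universe: Iterable) -> list:
    nodes = sorted(net.nodes & set(universe))
    if not nodes:
        raise PathwaySkipped(
            f"pathway {net.pathway_id!r}: no node measured in the gene universe"
        )
    return nodes


def sepea_score(
    net: PathwayNetwork,
    weights: NodeWeighting,
    dist: DistanceTable,
    scores: GeneScoreTable,
) -> float:
    """Network-weighted enrichment score for continuous gene scores."""
    nodes = _measured_nodes(net, scores.universe)
    s = np.array([scores.get(v) for v in nodes], dtype=float)
    w = np.array([weights.weights[v] for v in nodes], dtype=float)
    kap = _kappa_matrix(nodes, dist)
    return float(_bulk_scores(s[None, :], w, kap)[0])


def sepea_nt3_score(
    net: PathwayNetwork,
    weights: NodeWeighting,
    dist: DistanceTable,
    gene_set: Iterable,
    universe: Iterable,
) -> float:
    """Gene-set variant: indicator scores s(v) = 1 if v is in the set."""
    gene_set = set(gene_set)
    table = GeneScoreTable(
        {g: 1.0 for g in gene_set if g in set(universe)}, frozenset(universe)
    )
    nodes = _measured_nodes(net, table.universe)
    if not any(table.get(v) for v in nodes):
        raise PathwaySkipped(
            f"pathway {net.pathway_id!r}: gene set does not intersect the pathway"
        )
    return sepea_score(net, weights, dist, table)


def p_to_z(p: float) -> float:
    """z = Phi^{-1}(1 - p): smaller p, larger feature value.

    p must lie in (0, 1]; p = 1 maps to -inf, so permutation p-values are
    clamped to their achievable floor before conversion elsewhere.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return float(stats.norm.isf(p))


def _clamped_z(p: float, n_perm: int) -> float:
    return p_to_z(min(p, 1.0 - 1.0 / (n_perm + 1)))


def _null_score_draws(
    rng: np.random.Generator,
    score_array: np.ndarray,
    m: int,
    k_draws: int,
) -> np.ndarray:
    """k_draws without-replacement samples of m scores from the score multiset."""
    n = score_array.size
    keys = rng.random((k_draws, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    return score_array[idx]


def permutation_pvalue(
    net: PathwayNetwork,
    weights: NodeWeighting,
    dist: DistanceTable,
    scores: GeneScoreTable,
    K: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    gene_set: Iterable | None = None,
) -> EnrichmentResult:
    """Permutation p-value and z feature for one pathway.

    The null reassigns the observed gene-score multiset over the measured
    universe (for the gene-set variant: draws |gene_set| genes uniformly
    without replacement), recomputing the pathway score each time.
    p = (1 + #{null >= observed}) / (K + 1), deterministic given ``seed``.
    """
    if K < 100:
        raise ValueError("K must be >= 100 for a usable permutation null")
    rng = np.random.default_rng(seed)
    nodes = _measured_nodes(net, scores.universe)
    m = len(nodes)
    w = np.array([weights.weights[v] for v in nodes], dtype=float)
    kap = _kappa_matrix(nodes, dist)

    if gene_set is None:
        observed = sepea_score(net, weights, dist, scores)
        universe = sorted(scores.universe)
        score_array = np.array([scores.get(g) for g in universe], dtype=float)
        exceed = 0
        for chunk in _chunks(K):
            S = _null_score_draws(rng, score_array, m, chunk)
            exceed += int((_bulk_scores(S, w, kap) >= observed).sum())
    else:
        gene_set = set(gene_set)
        observed = sepea_nt3_score(net, weights, dist, gene_set, scores.universe)
        universe = sorted(scores.universe)
        g_size = len(gene_set & set(universe))
        n = len(universe)
        node_pos = np.array([universe.index(v) for v in nodes])
        exceed = 0
        for chunk in _chunks(K):
            keys = rng.random((chunk, n))
            thr = np.partition(keys, g_size - 1, axis=1)[:, g_size - 1]
            S = (keys[:, node_pos] <= thr[:, None]).astype(float)
            exceed += int((_bulk_scores(S, w, kap) >= observed).sum())

    p = (1.0 + exceed) / (K + 1.0)
    return EnrichmentResult(net.pathway_id, observed, p, _clamped_z(p, K), K)


def _chunks(total: int, chunk: int = 2000):
    done = 0
    while done < total:
        step = min(chunk, total - done)
        yield step
        done += step


def feature_vector(
    panel: Sequence,
    results: Mapping[str, EnrichmentResult | None],
) -> np.ndarray:
    """z values in panel order; skipped pathways impute the null-median z = 0."""
    out = np.zeros(len(panel))
    for i, pid in enumerate(panel):
        res = results.get(pid)
        if res is not None:
            out[i] = res.z
    return out


def pathway_feature_matrix(
    collection: Mapping[str, PathwayNetwork],
    weightings: Mapping[str, NodeWeighting],
    dist_tables: Mapping[str, DistanceTable],
    score_tables: Mapping[str, GeneScoreTable],
    panel: Sequence,
    K: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Treatments x pathways matrix of z features.

    For each treatment (row), one set of K global permutations of its
    gene-score assignment is shared across the whole pathway panel: each
    permutation is still an exact without-replacement reassignment of the
    score multiset, and sharing keeps a 216-pathway x 5e4-permutation run
    tractable.  Pathways with no measured node are imputed z = 0.
    """
    rows = {}
    for treatment, scores in score_tables.items():
        rng = np.random.default_rng(_derive_seed(seed, treatment))
        universe = sorted(scores.universe)
        score_array = np.array([scores.get(g) for g in universe], dtype=float)
        pos = {g: i for i, g in enumerate(universe)}

        prepared = {}
        for pid in panel:
            net = collection.get(pid)
            if net is None:
                continue
            try:
                nodes = _measured_nodes(net, scores.universe)
            except PathwaySkipped:
                continue
            w = np.array([weightings[pid].weights[v] for v in nodes])
            kap = _kappa_matrix(nodes, dist_tables[pid])
            idx = np.array([pos[v] for v in nodes])
            obs = float(
                _bulk_scores(score_array[idx][None, :], w, kap)[0]
            )
            prepared[pid] = (idx, w, kap, obs)

        exceed = {pid: 0 for pid in prepared}
        for chunk in _chunks(K):
            perm = rng.permuted(
                np.broadcast_to(score_array, (chunk, score_array.size)), axis=1
            )
            for pid, (idx, w, kap, obs) in prepared.items():
                null = _bulk_scores(perm[:, idx], w, kap)
                exceed[pid] += int((null >= obs).sum())

        results = {
            pid: EnrichmentResult(
                pid,
                prepared[pid][3],
                (1.0 + exceed[pid]) / (K + 1.0),
                _clamped_z((1.0 + exceed[pid]) / (K + 1.0), K),
                K,
            )
            for pid in prepared
        }
        rows[treatment] = feature_vector(panel, results)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(panel))


def _derive_seed(seed: int, token) -> int:
    ss = np.random.SeedSequence([seed, abs(hash(str(token))) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def read_expression_tsv(values_path, groups_path) -> ExpressionMatrix:
    """Expression TSV (first column gene id, header = sample ids) plus a
    two-column sample -> group file."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    groups.index = groups.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, groups)


def write_expression_tsv(matrix: ExpressionMatrix, values_path, groups_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    matrix.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample_id")
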