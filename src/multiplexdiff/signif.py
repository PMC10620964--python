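"""Phase II — significance assessment of between-layer node distances.

Scenario I compares each node's observed between-layer distance against an
empirical null of distances from permuted networks that were embedded
jointly with the real layers. Scenario II associates each node's
per-individual distance with a phenotype (Wilcoxon rank-sum for binary,
Kendall's tau for continuous phenotypes).

Because training starts from random initializations, the whole procedure is
repeated R times (default 50) and the per-repeat p-values are aggregated
with Fisher's combined probability; the combined p-values are then adjusted
for multiple testing across nodes (Benjamini-Hochberg by default). Repeat
p-values are computed from the same data and are positively dependent, so
Fisher combination is anti-conservative; this is the stated procedure and
is documented as a caveat rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .embed import (
    DistanceTable,
    EmbeddingConfig,
    build_training_rows,
    fit_ednn,
    node_distances,
    NodeEmbedding,
)
from .netio import MultiplexNetwork, PhenotypeTable

logger = logging.getLogger("multiplexdiff")

PermMethod = Literal["weight_shuffle", "degree_preserving"]
AdjustMethod = Literal["bh", "bonferroni", "holm", "none"]

DEFAULT_N_PERM = 100
DEFAULT_REPEATS = 50


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Pooled distances of permuted-network nodes."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if self.distances.size < 1:
            raise ValueError("null distribution must contain at least one distance")
        if not np.isfinite(self.distances).all() or (self.distances < 0).any():
            raise ValueError("null distances must be finite and >= 0")

    @property
    def m(self) -> int:
        return int(self.distances.size)


@dataclass
class SignificanceTable:
    """Per-node significance results, sorted by combined p-value.

    ``p_per_repeat`` has one column per node and one row per repeat.
    Row order: p_combined ascending, ties broken by mean_distance
    descending, then node id.
    """

    node_ids: list[str]
    mean_distance: np.ndarray
    p_per_repeat: np.ndarray  # (R, n)
    p_combined: np.ndarray
    p_adjusted: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.mean_distance = np.asarray(self.mean_distance, dtype=float)
        self.p_per_repeat = np.atleast_2d(np.asarray(self.p_per_repeat, dtype=float))
        self.p_combined = np.asarray(self.p_combined, dtype=float)
        self.p_adjusted = np.asarray(self.p_adjusted, dtype=float)
        for arr, name in [
            (self.mean_distance, "mean_distance"),
            (self.p_combined, "p_combined"),
            (self.p_adjusted, "p_adjusted"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per node")
        if self.p_per_repeat.shape[1] != n:
            raise ValueError("p_per_repeat must have one column per node")
        for p in (self.p_per_repeat, self.p_combined, self.p_adjusted):
            if (p <= 0).any() or (p > 1).any():
                raise ValueError("p-values must lie in (0, 1]")

    @property
    def n_repeats(self) -> int:
        return self.p_per_repeat.shape[0]

    def sorted(self) -> "SignificanceTable":
        order = sorted(
            range(len(self.node_ids)),
            key=lambda i: (self.p_combined[i], -self.mean_distance[i], self.node_ids[i]),
        )
        return SignificanceTable(
            [self.node_ids[i] for i in order],
            self.mean_distance[order],
            self.p_per_repeat[:, order],
            self.p_combined[order],
            self.p_adjusted[order],
            dict(self.metadata),
        )

    def to_frame(self, verbose_repeats: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "node": self.node_ids,
                "mean_distance": self.mean_distance,
                "p_combined": self.p_combined,
                "p_adjusted": self.p_adjusted,
            }
        )
        if verbose_repeats:
            for r in range(self.n_repeats):
                df[f"p_repeat{r + 1}"] = self.p_per_repeat[r]
        return df

    def write_tsv(self, path: str | Path, verbose_repeats: bool = False) -> None:
        self.to_frame(verbose_repeats).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Permutation null models
# ---------------------------------------------------------------------------


def permute_network(
    W: np.ndarray, method: PermMethod = "weight_shuffle", seed: int | None = 0
) -> np.ndarray:
    """Randomize a symmetric weight matrix.

    weight_shuffle permutes the upper-triangle weights over all node pairs
    (the weight multiset is preserved exactly). degree_preserving performs
    10 x |E| double-edge swaps on the nonzero edges, carrying weights, so
    the degree sequence of the binarized graph is preserved exactly.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if np.abs(W - W.T).max(initial=0.0) > 1e-9 or np.any(np.diag(W) != 0):
        raise ValueError("permute_network needs a symmetric, zero-diagonal matrix")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(W)
    if method == "weight_shuffle":
        iu = np.triu_indices(n, k=1)
        weights = rng.permutation(W[iu])
        out[iu] = weights
        out += out.T
        return out
    if method == "degree_preserving":
        iu, ju = np.triu_indices(n, k=1)
        nz = W[iu, ju] > 0
        edges = [[int(a), int(b)] for a, b in zip(iu[nz], ju[nz])]
        wts = list(W[iu, ju][nz])
        if len(edges) < 2:
            raise ValueError("degree_preserving needs at least 2 edges")
        present = {frozenset(e) for e in edges}
        target_swaps = 10 * len(edges)
        swaps = 0
        consecutive_failures = 0
        # a (near-)complete graph admits no legal swap: give up after a
        # sustained run of failed proposals and point at weight_shuffle
        failure_budget = 200 + 20 * len(edges)
        while swaps < target_swaps:
            if consecutive_failures > failure_budget:
                raise ValueError(
                    "degree-preserving rewiring found no legal edge swaps "
                    "(graph too dense / complete); use method='weight_shuffle'"
                )
            e1, e2 = rng.integers(0, len(edges), size=2)
            if e1 == e2:
                consecutive_failures += 1
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.random() < 0.5:
                c, d = d, c
            if len({a, b, c, d}) < 4:
                consecutive_failures += 1
                continue
            new1, new2 = frozenset((a, d)), frozenset((c, b))
            if new1 in present or new2 in present:
                consecutive_failures += 1
                continue
            present.discard(frozenset((a, b)))
            present.discard(frozenset((c, d)))
            present.add(new1)
            present.add(new2)
            edges[e1] = [a, d]
            edges[e2] = [c, b]
            swaps += 1
            consecutive_failures = 0
        for (a, b), w in zip(edges, wts):
            out[a, b] = w
            out[b, a] = w
        return out
    raise ValueError(f"unknown permutation method '{method}'")


# ---------------------------------------------------------------------------
# p-value machinery
# ---------------------------------------------------------------------------


def empirical_p(d: float, null: NullDistribution) -> float:
    """One-sided add-one empirical p-value: P(null >= d).

    p = (1 + #{null_i >= d}) / (1 + m); never 0, so Fisher combination is
    always defined.
    """
    if not np.isfinite(d):
        raise ValueError("observed distance must be finite")
    m = null.m
    return float((1 + int(np.sum(null.distances >= d))) / (1 + m))


def fisher_combine(pvals) -> float:
    """Fisher's combined probability: X = -2 sum(ln p) ~ chi2(2R)."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(X, df=2 * p.size))


def adjust_p(pvals, method: AdjustMethod = "bh") -> np.ndarray:
    """Multiple-testing adjustment across nodes (BH default), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    mapping = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment method '{method}'")
    return multipletests(p, method=mapping[method])[1]


# ---------------------------------------------------------------------------
# Scenario I — permutation null
# ---------------------------------------------------------------------------


def _embed_real_and_permuted(
    A: np.ndarray,
    B: np.ndarray,
    node_ids: list[str],
    n_perm: int,
    config: EmbeddingConfig,
    method: PermMethod,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One repeat: joint embedding of the real pair and n_perm permuted pairs.

    Returns (observed per-node distances, (n_perm, n) null distance matrix).
    """
    n = A.shape[0]
    perm_rng = np.random.default_rng(seed)
    mats = [A, B]
    for _ in range(n_perm):
        # each layer permuted independently
        mats.append(permute_network(A, method, seed=int(perm_rng.integers(2**31))))
        mats.append(permute_network(B, method, seed=int(perm_rng.integers(2**31))))
    features, targets = build_training_rows(mats, config)
    trained = fit_ednn(features, targets, replace(config, seed=seed))
    vecs = trained.embed_rows(features).reshape(len(mats), n, config.k)
    emb = NodeEmbedding(
        node_ids, [f"inst{i}" for i in range(len(mats))], vecs
    )
    observed = node_distances(emb, "inst0", "inst1", config.distance_metric).d
    null = np.empty((n_perm, n))
    for p in range(n_perm):
        null[p] = node_distances(
            emb, f"inst{2 * p + 2}", f"inst{2 * p + 3}", config.distance_metric
        ).d
    return observed, null


def build_null(
    net: MultiplexNetwork,
    n_perm: int,
    config: EmbeddingConfig,
    method: PermMethod = "weight_shuffle",
    seed: int = 0,
    layer_pair: tuple[str, str] | None = None,
) -> NullDistribution:
    """Pooled null distances from n_perm permuted two-layer networks.

    The permuted pairs are embedded jointly with the real layers in a single
    training run; all n_perm x n within-pair node distances are pooled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    la, lb = layer_pair if layer_pair is not None else tuple(net.layer_names[:2])
    _, null = _embed_real_and_permuted(
        net.layer(la), net.layer(lb), net.node_ids, n_perm, config, method, seed
    )
    return NullDistribution(null.ravel())


def scenario1(
    net: MultiplexNetwork,
    config: EmbeddingConfig | None = None,
    n_perm: int = DEFAULT_N_PERM,
    repeats: int = DEFAULT_REPEATS,
    null_method: PermMethod = "weight_shuffle",
    adjust_method: AdjustMethod = "bh",
    seed: int = 0,
    layer_pair: tuple[str, str] | None = None,
    null_scope: Literal["pooled", "per_node"] = "pooled",
) -> SignificanceTable:
    """Detect nodes whose neighborhood changes between two conditions.

    For each repeat r (seeded seed + r) the two real layers and n_perm
    independently permuted layer pairs are embedded jointly; each node's
    observed between-layer distance is referred to the null distances
    (pooled over all permuted nodes by default, or per node). The R repeat
    p-values are Fisher-combined per node and adjusted across nodes.
    """
    if config is None:
        config = EmbeddingConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    la, lb = layer_pair if layer_pair is not None else tuple(net.layer_names[:2])
    A, B = net.layer(la), net.layer(lb)
    n = net.n_nodes
    pvals = np.empty((repeats, n))
    dists = np.empty((repeats, n))
    for r in range(repeats):
        observed, null = _embed_real_and_permuted(
            A, B, net.node_ids, n_perm, config, null_method, seed + r
        )
        dists[r] = observed
        if null_scope == "pooled":
            nd = NullDistribution(null.ravel())
            pvals[r] = [empirical_p(d, nd) for d in observed]
        elif null_scope == "per_node":
            pvals[r] = [
                empirical_p(observed[i], NullDistribution(null[:, i]))
                for i in range(n)
            ]
        else:
            raise ValueError(f"unknown null_scope '{null_scope}'")
        logger.info("scenario I repeat %d/%d done", r + 1, repeats)
    p_combined = np.array([fisher_combine(pvals[:, i]) for i in range(n)])
    p_adjusted = adjust_p(p_combined, adjust_method)
    table = SignificanceTable(
        list(net.node_ids),
        dists.mean(axis=0),
        pvals,
        p_combined,
        p_adjusted,
        metadata={
            "scenario": 1,
            "layers": [la, lb],
            "null_method": null_method,
            "null_scope": null_scope,
            "n_perm": n_perm,
            "m": n_perm * n,
            "repeats": repeats,
            "adjust_method": adjust_method,
            "seed": seed,
        },
    )
    return table.sorted()


# ---------------------------------------------------------------------------
# Scenario II — phenotype association
# ---------------------------------------------------------------------------


def wilcoxon_test(distances, groups) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a binary grouping.

    Exact distribution when the smaller group has <= 10 members and there
    are no ties; otherwise normal approximation with tie and continuity
    corrections.
    """
    d = np.asarray(distances, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    x = d[g == levels[0]]
    y = d[g == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 members")
    if np.all(d == d[0]):
        return 1.0  # no separation possible
    has_ties = len(np.unique(d)) < len(d)
    method = "exact" if (not has_ties and min(len(x), len(y)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def kendall_test(distances, phenotype) -> tuple[float, float]:
    """Kendall's tau-b and two-sided p against a continuous phenotype.

    Exact p for n <= 8 without ties, otherwise the normal approximation
    with tie correction.
    """
    d = np.asarray(distances, dtype=float)
    ph = np.asarray(phenotype, dtype=float)
    if d.size < 4:
        raise ValueError("Kendall test needs >= 4 individuals")
    if np.all(ph == ph[0]):
        raise ValueError("constant phenotype: Kendall's tau undefined")
    if np.all(d == d[0]):
        return 0.0, 1.0  # constant distances carry no association
    has_ties = len(np.unique(d)) < d.size or len(np.unique(ph)) < ph.size
    method = "exact" if (d.size <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(d, ph, method=method, variant="b")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def individual_distances(
    nets: list[MultiplexNetwork],
    config: EmbeddingConfig,
    seed: int,
    layer_pair: tuple[str, str] | None = None,
    joint: bool = True,
) -> np.ndarray:
    """Per-individual, per-node between-layer distances d_i.

    With ``joint=True`` (default) all individuals' layers are stacked into
    one training run so every d_i is measured in a single shared embedding
    space — required for rank tests across individuals to be meaningful.
    ``joint=False`` embeds each individual separately.
    """
    node_ids = nets[0].node_ids
    bad = [i for i, net in enumerate(nets) if net.node_ids != node_ids]
    if bad:
        raise ValueError(f"node sets differ from individual 0 for individuals: {bad}")
    la, lb = layer_pair if layer_pair is not None else tuple(nets[0].layer_names[:2])
    n = len(node_ids)
    n_ind = len(nets)
    cfg = replace(config, seed=seed)
    D = np.empty((n_ind, n))
    if joint:
        mats: list[np.ndarray] = []
        for net in nets:
            mats.append(net.layer(la))
            mats.append(net.layer(lb))
        features, targets = build_training_rows(mats, cfg)
        trained = fit_ednn(features, targets, cfg)
        vecs = trained.embed_rows(features).reshape(2 * n_ind, n, cfg.k)
        for i in range(n_ind):
            emb = NodeEmbedding(list(node_ids), ["a", "b"], vecs[2 * i : 2 * i + 2])
            D[i] = node_distances(emb, "a", "b", cfg.distance_metric).d
    else:
        for i, net in enumerate(nets):
            mats = [net.layer(la), net.layer(lb)]
            features, targets = build_training_rows(mats, cfg)
            trained = fit_ednn(features, targets, replace(cfg, seed=seed + i))
            vecs = trained.embed_rows(features).reshape(2, n, cfg.k)
            emb = NodeEmbedding(list(node_ids), ["a", "b"], vecs)
            D[i] = node_distances(emb, "a", "b", cfg.distance_metric).d
    return D


def scenario2(
    nets: list[MultiplexNetwork],
    phenotype: PhenotypeTable,
    individual_ids: list[str] | None = None,
    config: EmbeddingConfig | None = None,
    repeats: int = DEFAULT_REPEATS,
    adjust_method: AdjustMethod = "bh",
    seed: int = 0,
    layer_pair: tuple[str, str] | None = None,
    joint_embedding: bool = True,
) -> SignificanceTable:
    """Detect nodes whose per-individual neighborhood variation tracks a phenotype.

    Each individual contributes a two-layer multiplex; per repeat, all
    layers are embedded jointly, each node's per-individual distance d_i is
    computed, and its association with the phenotype is tested (Wilcoxon
    rank-sum for binary, Kendall's tau for continuous). Repeat p-values are
    Fisher-combined and adjusted across nodes.
    """
    if config is None:
        config = EmbeddingConfig()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if len(nets) < 4:
        raise ValueError("scenario II needs >= 4 individuals")
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(len(nets))]
    pheno = phenotype.aligned_to(individual_ids)
    node_ids = nets[0].node_ids
    n = len(node_ids)
    pvals = np.empty((repeats, n))
    mean_d = np.zeros(n)
    for r in range(repeats):
        D = individual_distances(
            nets, config, seed + r, layer_pair, joint=joint_embedding
        )
        mean_d += D.mean(axis=0) / repeats
        for i in range(n):
            if phenotype.kind == "binary":
                pvals[r, i] = wilcoxon_test(D[:, i], pheno)
            else:
                _, pvals[r, i] = kendall_test(D[:, i], pheno)
        logger.info("scenario II repeat %d/%d done", r + 1, repeats)
    np.clip(pvals, np.nextafter(0.0, 1.0), 1.0, out=pvals)
    p_combined = np.array([fisher_combine(pvals[:, i]) for i in range(n)])
    p_adjusted = adjust_p(p_combined, adjust_method)
    table = SignificanceTable(
        list(node_ids),
        mean_d,
        pvals,
        p_combined,
        p_adjusted,
        metadata={
            "scenario": 2,
            "phenotype_kind": phenotype.kind,
            "n_individuals": len(nets),
            "repeats": repeats,
            "adjust_method": adjust_method,
            "seed": seed,
            "joint_embedding": joint_embedding,
        },
    )
    return table.sorted()
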