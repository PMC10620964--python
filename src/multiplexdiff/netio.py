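"""Input/output and network construction.

Reads gene-expression matrices, builds weighted gene co-expression
networks (GCNs) and LIONESS individual-specific networks (ISNs), and
reads/writes multiplex networks in adjacency-CSV or edge-list-TSV form.

Conventions: expression files carry genes in rows (first column = gene id,
header = sample ids); edge weights are absolute correlations in [0, 1];
all matrices are 0-indexed internally while files carry node names.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("multiplexdiff")

SYMMETRY_TOL = 1e-9

CorrMethod = Literal["pearson", "spearman"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (log-normalized expected).

    Invariants: unique gene and sample ids, dimensions consistent with
    ``values``, and no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {sorted(dup_s)}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite expression value at gene "
                f"'{self.gene_ids[bad[0]]}', sample '{self.sample_ids[bad[1]]}'"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the column submatrix for the given samples (order kept)."""
        missing = [s for s in sample_ids if s not in self.sample_ids]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx]
        )


@dataclass
class MultiplexNetwork:
    """A shared node set with one symmetric weight matrix per layer.

    All layers are defined on the identical ordered node list; weights lie
    in [0, 1]; diagonals are exactly zero; matrices are symmetric within
    ``SYMMETRY_TOL``.
    """

    node_ids: list[str]
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dup = _duplicates(self.node_ids)
        if dup:
            raise ValueError(f"duplicate node ids: {sorted(dup)}")
        if len(self.layers) < 1:
            raise ValueError("a multiplex network needs at least one layer")
        n = len(self.node_ids)
        for name, W in self.layers.items():
            W = np.asarray(W, dtype=float)
            if W.shape != (n, n):
                raise ValueError(f"layer '{name}' has shape {W.shape}, expected ({n}, {n})")
            asym = np.abs(W - W.T)
            if asym.max(initial=0.0) > SYMMETRY_TOL:
                i, j = np.unravel_index(np.argmax(asym), asym.shape)
                raise ValueError(
                    f"layer '{name}' is asymmetric at "
                    f"({self.node_ids[i]}, {self.node_ids[j]}): "
                    f"{W[i, j]} vs {W[j, i]}"
                )
            if np.any(np.diag(W) != 0):
                raise ValueError(f"layer '{name}' has a nonzero diagonal")
            if W.min() < 0 or W.max(initial=0.0) > 1:
                i, j = divmod(int(np.argmax((W < 0) | (W > 1))), n)
                raise ValueError(
                    f"layer '{name}' weight outside [0, 1] at edge "
                    f"({self.node_ids[i]}, {self.node_ids[j]}): {W[i, j]}"
                )
            self.layers[name] = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers.keys())

    def layer(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(
                f"unknown layer '{name}'; available: {self.layer_names}"
            )
        return self.layers[name]


@dataclass
class PhenotypeTable:
    """Per-sample phenotype, binary or continuous."""

    sample_ids: list[str]
    values: np.ndarray
    kind: Literal["binary", "continuous"] = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample ids and values differ in length")
        if self.kind == "binary":
            uniq, counts = np.unique(self.values, return_counts=True)
            if len(uniq) != 2:
                raise ValueError(
                    f"binary phenotype must have exactly 2 distinct values, got {len(uniq)}"
                )
            if counts.min() < 2:
                raise ValueError("binary phenotype needs >= 2 samples per group")

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Phenotype values reordered to the given sample id order."""
        missing = [s for s in sample_ids if s not in self.sample_ids]
        if missing:
            raise KeyError(f"phenotype missing sample ids: {missing}")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.values[[pos[s] for s in sample_ids]]


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Expression io and gene selection
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-in-rows expression table (first column gene ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     float_precision="round_trip")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, gene in enumerate(gene_ids):
            for j, sample in enumerate(sample_ids):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric expression value {df.iat[i, j]!r} at "
                        f"gene '{gene}' (row {i + 2}), sample '{sample}'"
                    ) from None
        raise
    if df.isna().any().any():
        raise ValueError(f"missing values in expression file {path}")
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter)


def read_phenotype(path: str | Path, kind: str | None = None) -> PhenotypeTable:
    """Read a 2-column TSV (sample_id, value).

    ``kind`` may be 'binary' or 'continuous'; if None it is inferred:
    exactly two distinct values means binary.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"phenotype file must have 2 columns, got {df.shape[1]}")
    # tolerate a header row
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    values = df.iloc[:, 1].astype(float).to_numpy()
    if kind is None:
        kind = "binary" if len(np.unique(values)) == 2 else "continuous"
    return PhenotypeTable(sample_ids, values, kind=kind)  # type: ignore[arg-type]


def select_top_variance_genes(expr: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with the largest sample variance.

    The original row order of retained genes is preserved.
    """
    if n_top > expr.n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds the number of genes ({expr.n_genes})"
        )
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    variances = expr.values.var(axis=1, ddof=1)
    # stable selection: ties broken by original order
    order = np.argsort(-variances, kind="stable")[:n_top]
    keep = np.sort(order)
    return ExpressionMatrix(
        [expr.gene_ids[i] for i in keep], list(expr.sample_ids), expr.values[keep]
    )


# ---------------------------------------------------------------------------
# Co-expression networks
# ---------------------------------------------------------------------------


def build_gcn(expr: ExpressionMatrix, method: CorrMethod = "pearson") -> np.ndarray:
    """Weighted co-expression network: |correlation| across samples.

    Weight(i, j) = |corr(gene_i, gene_j)|; diagonal 0. Gene pairs involving
    a zero-variance gene get weight 0 (correlation undefined) with a warning.
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >= 3 samples to estimate correlations, got {expr.n_samples}")
    if expr.n_genes < 2:
        raise ValueError("need >= 2 genes")
    X = expr.values
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method '{method}'")
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        names = [expr.gene_ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance gene(s) {names}: correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("zero-variance gene(s) %s: correlations set to 0", names)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    W = np.abs(C)
    W[~np.isfinite(W)] = 0.0
    W[degenerate, :] = 0.0
    W[:, degenerate] = 0.0
    np.fill_diagonal(W, 0.0)
    np.clip(W, 0.0, 1.0, out=W)
    W = (W + W.T) / 2.0  # exact symmetry against float noise
    return W


def build_isns(
    expr: ExpressionMatrix,
    method: CorrMethod = "pearson",
    clip: bool = True,
) -> list[np.ndarray]:
    """LIONESS individual-specific networks, one per sample.

    ISN_q = N * agg - (N - 1) * agg_minus_q, where agg is the aggregate
    co-expression network over all N samples and agg_minus_q leaves sample
    q out. With ``clip=True`` (the embedding-facing default) values are
    clipped to [0, 1]; ``clip=False`` returns the raw LIONESS values.
    """
    N = expr.n_samples
    if N < 4:
        raise ValueError(f"LIONESS needs >= 4 samples, got {N}")
    agg = build_gcn(expr, method=method)
    isns: list[np.ndarray] = []
    mask = np.ones(N, dtype=bool)
    for q in range(N):
        mask[q] = False
        loo = ExpressionMatrix(
            list(expr.gene_ids),
            [s for i, s in enumerate(expr.sample_ids) if i != q],
            expr.values[:, mask],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agg_minus_q = build_gcn(loo, method=method)
        mask[q] = True
        isn = N * agg - (N - 1) * agg_minus_q
        if clip:
            np.clip(isn, 0.0, 1.0, out=isn)
            np.fill_diagonal(isn, 0.0)
        isns.append(isn)
    return isns


def lioness_edge(agg_weight: float, loo_weight: float, n_samples: int) -> float:
    """Raw LIONESS interpolation for a single edge (pre-clip)."""
    return n_samples * agg_weight - (n_samples - 1) * loo_weight


def complete_edge_count(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2 — edges of a complete GCN."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# Multiplex io
# ---------------------------------------------------------------------------


def _read_edgelist(path: Path) -> dict[tuple[str, str], float]:
    edges: dict[tuple[str, str], float] = {}
    seen_edge = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            a, b, w = parts
            try:
                weight = float(w)
            except ValueError:
                if not seen_edge:
                    continue  # header row
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {w!r}"
                ) from None
            seen_edge = True
            if not 0.0 <= weight <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: weight {weight} outside [0, 1] for edge ({a}, {b})"
                )
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on node '{a}'")
            key = (a, b) if a <= b else (b, a)
            if key in edges and edges[key] != weight:
                raise ValueError(
                    f"{path}:{lineno}: conflicting weights for edge {key}"
                )
            edges[key] = weight
    return edges


def _read_adjacency(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    nodes = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != nodes:
        raise ValueError(f"{path}: adjacency header and first column disagree")
    W = df.to_numpy(dtype=float)
    asym = np.abs(W - W.T)
    if asym.max(initial=0.0) > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: asymmetric adjacency at ({nodes[i]}, {nodes[j]}): "
            f"{W[i, j]} vs {W[j, i]}"
        )
    bad = (W < 0) | (W > 1)
    if bad.any():
        i, j = np.unravel_index(int(np.argmax(bad)), bad.shape)
        raise ValueError(
            f"{path}: weight {W[i, j]} outside [0, 1] at edge ({nodes[i]}, {nodes[j]})"
        )
    return nodes, W


def read_multiplex(
    paths: Sequence[str | Path],
    format: Literal["adjacency_csv", "edgelist_tsv"] = "edgelist_tsv",
    layer_names: Sequence[str] | None = None,
) -> MultiplexNetwork:
    """Assemble a multiplex network from one file per layer.

    Layers are aligned to the union of node ids, sorted lexicographically;
    absent edges get weight 0.
    """
    if len(paths) < 2:
        raise ValueError("a multiplex network needs >= 2 layer files")
    paths = [Path(p) for p in paths]
    if layer_names is None:
        layer_names = [p.stem for p in paths]
        if len(set(layer_names)) != len(layer_names):
            layer_names = [f"layer{i + 1}" for i in range(len(paths))]

    if format == "edgelist_tsv":
        per_layer = [_read_edgelist(p) for p in paths]
        node_set: set[str] = set()
        for edges in per_layer:
            for a, b in edges:
                node_set.update((a, b))
        nodes = sorted(node_set)
        idx = {v: i for i, v in enumerate(nodes)}
        layers: dict[str, np.ndarray] = {}
        for name, edges in zip(layer_names, per_layer):
            W = np.zeros((len(nodes), len(nodes)))
            for (a, b), w in edges.items():
                W[idx[a], idx[b]] = w
                W[idx[b], idx[a]] = w
            layers[name] = W
    elif format == "adjacency_csv":
        parsed = [_read_adjacency(p) for p in paths]
        nodes = sorted({v for ns, _ in parsed for v in ns})
        layers = {}
        for name, (ns, W0) in zip(layer_names, parsed):
            pos = {v: i for i, v in enumerate(ns)}
            W = np.zeros((len(nodes), len(nodes)))
            sel = [pos[v] for v in nodes if v in pos]
            present = [i for i, v in enumerate(nodes) if v in pos]
            W[np.ix_(present, present)] = W0[np.ix_(sel, sel)]
            layers[name] = W
    else:
        raise ValueError(f"unknown multiplex format '{format}'")

    for W in layers.values():
        np.fill_diagonal(W, 0.0)
    return MultiplexNetwork(nodes, layers)


def write_multiplex(
    net: MultiplexNetwork,
    paths: Sequence[str | Path],
    format: Literal["adjacency_csv", "edgelist_tsv"] = "edgelist_tsv",
) -> None:
    """Write one file per layer; round-trips bit-exactly via read_multiplex."""
    if len(paths) != len(net.layers):
        raise ValueError("need exactly one output path per layer")
    for path, (name, W) in zip(paths, net.layers.items()):
        path = Path(path)
        if format == "edgelist_tsv":
            n = net.n_nodes
            with open(path, "w") as fh:
                fh.write(f"# layer: {name}\n")
                fh.write("node_a\tnode_b\tweight\n")
                iu, ju = np.triu_indices(n, k=1)
                for i, j in zip(iu, ju):
                    w = float(W[i, j])
                    if w == 0.0:
                        continue
                    fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{w!r}\n")
                # keep isolated nodes in the file so the node set round-trips
                iso = np.flatnonzero(W.sum(axis=0) == 0)
                for i in iso:
                    j = (i + 1) % n
                    fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t0.0\n")
        elif format == "adjacency_csv":
            with open(path, "w") as fh:
                fh.write("," + ",".join(net.node_ids) + "\n")
                for i, node in enumerate(net.node_ids):
                    fh.write(node + "," + ",".join(repr(float(x)) for x in W[i]) + "\n")
        else:
            raise ValueError(f"unknown multiplex format '{format}'")
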