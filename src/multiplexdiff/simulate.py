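"""Synthetic two-layer multiplex networks with planted neighborhood changes.

The generator draws a random weighted graph as layer 1 and copies it to
layer 2, then rewires the neighborhood of a chosen subset of "planted"
nodes: a fraction ``perturbation_strength`` of each planted node's incident
edges are deleted and the same number of new incident edges (with freshly
drawn weights) are created at previously empty pairs. The planted node's
degree is therefore preserved exactly and its expected weighted degree is
unchanged (weights are i.i.d.), so detectors that compare node centralities
between layers see nothing — only the composition of the neighborhood
changes. This is exactly the regime the embedding-based method targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .netio import MultiplexNetwork, write_multiplex
from .signif import SignificanceTable


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the planted-perturbation generator.

    n : node count (default 100).
    n_planted : number of perturbed nodes (default 10).
    perturbation_strength : fraction of each planted node's incident edges
        that are rewired between the layers, in [0, 1].
    edge_density : probability that a node pair is connected in layer 1.
    weight_distribution : 'uniform01', or ('beta', a, b).
    seed : generator seed; output is bit-reproducible for equal parameters.
    """

    n: int = 100
    n_planted: int = 10
    perturbation_strength: float = 0.8
    edge_density: float = 0.2
    weight_distribution: str | tuple = "uniform01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 <= self.n_planted < self.n:
            raise ValueError("n_planted must satisfy 0 <= n_planted < n")
        if not 0.0 <= self.perturbation_strength <= 1.0:
            raise ValueError("perturbation_strength must lie in [0, 1]")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: which nodes were perturbed."""

    planted_node_ids: frozenset[str]

    def mask(self, node_ids: Sequence[str]) -> np.ndarray:
        unknown = self.planted_node_ids - set(node_ids)
        if unknown:
            raise ValueError(f"planted nodes not in network: {sorted(unknown)}")
        return np.array([v in self.planted_node_ids for v in node_ids])


def _draw_weights(rng: np.random.Generator, size: int, dist: str | tuple) -> np.ndarray:
    if dist == "uniform01":
        return rng.uniform(0.0, 1.0, size=size)
    if isinstance(dist, (tuple, list)) and len(dist) == 3 and dist[0] == "beta":
        return rng.beta(float(dist[1]), float(dist[2]), size=size)
    raise ValueError(f"unknown weight distribution {dist!r}")


def generate_multiplex(
    spec: SimulationSpec,
    planted: Sequence[str] | None = None,
) -> tuple[MultiplexNetwork, PlantedTruth]:
    """Generate a two-layer multiplex with planted differential nodes.

    ``planted`` optionally fixes the perturbed node ids (e.g., to share one
    ground truth across a simulated cohort); by default they are drawn at
    random from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    width = len(str(n - 1))
    node_ids = [f"n{i:0{width}d}" for i in range(n)]

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < spec.edge_density
    W1 = np.zeros((n, n))
    w = _draw_weights(rng, int(present.sum()), spec.weight_distribution)
    W1[iu[present], ju[present]] = w
    W1 += W1.T

    if planted is None:
        planted_idx = rng.choice(n, size=spec.n_planted, replace=False)
        planted_ids = [node_ids[i] for i in sorted(planted_idx)]
    else:
        planted_ids = list(planted)
        missing = set(planted_ids) - set(node_ids)
        if missing:
            raise ValueError(f"unknown planted node ids: {sorted(missing)}")
        planted_idx = np.array([node_ids.index(v) for v in planted_ids])

    W2 = W1.copy()
    for v in planted_idx:
        neighbors = np.flatnonzero(W2[v] > 0)
        non_neighbors = np.setdiff1d(np.flatnonzero(W2[v] == 0), [v])
        n_rewire = int(round(spec.perturbation_strength * len(neighbors)))
        n_rewire = min(n_rewire, len(non_neighbors))
        if n_rewire == 0:
            continue
        drop = rng.choice(neighbors, size=n_rewire, replace=False)
        add = rng.choice(non_neighbors, size=n_rewire, replace=False)
        W2[v, drop] = 0.0
        W2[drop, v] = 0.0
        new_w = _draw_weights(rng, n_rewire, spec.weight_distribution)
        W2[v, add] = new_w
        W2[add, v] = new_w

    net = MultiplexNetwork(node_ids, {"layer1": W1, "layer2": W2})
    return net, PlantedTruth(frozenset(planted_ids))


def generate_cohort(
    spec: SimulationSpec,
    n_individuals: int,
    perturbed_individuals: Sequence[int],
    planted: Sequence[str] | None = None,
) -> tuple[list[MultiplexNetwork], PlantedTruth]:
    """Per-individual two-layer multiplexes sharing one planted node set.

    Individuals listed in ``perturbed_individuals`` carry the planted
    perturbation between their layers; the others' layer 2 is an unplanted
    redraw (strength applied to zero nodes), so only phenotype-linked
    individuals show differential neighborhoods at the planted nodes.
    """
    rng = np.random.default_rng(spec.seed)
    base, truth = generate_multiplex(spec, planted=planted)
    planted_ids = sorted(truth.planted_node_ids)
    perturbed = set(perturbed_individuals)
    nets = []
    for i in range(n_individuals):
        ind_spec = SimulationSpec(
            n=spec.n,
            n_planted=spec.n_planted if i in perturbed else 0,
            perturbation_strength=spec.perturbation_strength,
            edge_density=spec.edge_density,
            weight_distribution=spec.weight_distribution,
            seed=int(rng.integers(2**31)),
        )
        net, _ = generate_multiplex(
            ind_spec, planted=planted_ids if i in perturbed else []
        )
        nets.append(net)
    return nets, truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def ranking_auc(scores, truth_mask, larger_is_better: bool = True) -> float:
    """ROC AUC of a score ranking against a boolean truth, by pair counting.

    Ties contribute 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth_mask, dtype=bool)
    pos = s[t]
    neg = s[~t]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one planted and one unplanted node")
    if not larger_is_better:
        pos, neg = -pos, -neg
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def evaluate_detection(
    table: SignificanceTable, truth: PlantedTruth, alpha: float = 0.05
) -> dict[str, float]:
    """Power, type-I error and ranking AUC of a significance table.

    power: fraction of planted nodes with p_adjusted < alpha.
    type_i: fraction of unplanted nodes with p_adjusted < alpha.
    auc: ROC AUC of the p_combined ranking (smaller p ranks higher).
    """
    mask = truth.mask(table.node_ids)
    if mask.sum() == 0:
        raise ValueError("truth contains no planted nodes present in the table")
    power = float((table.p_adjusted[mask] < alpha).mean())
    type_i = float((table.p_adjusted[~mask] < alpha).mean())
    auc = ranking_auc(table.p_combined, mask, larger_is_better=False)
    return {"power": power, "type_i": type_i, "auc": auc}


def write_simulation(
    net: MultiplexNetwork, truth: PlantedTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the two layers as edge lists plus a truth TSV (node, planted)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: out_dir / f"{name}.tsv" for name in net.layer_names
    }
    write_multiplex(net, list(paths.values()), format="edgelist_tsv")
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("node\tplanted\n")
        for v in net.node_ids:
            fh.write(f"{v}\t{int(v in truth.planted_node_ids)}\n")
    paths["truth"] = truth_path
    return paths
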