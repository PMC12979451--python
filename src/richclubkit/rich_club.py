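"""Rich-club coefficient, degree-preserving nulls, hubs, and edge classes.

The rich-club coefficient Phi(k) asks whether high-degree nodes are more
densely interconnected than chance: nodes with degree below k are removed
(degrees taken on the full network) and Phi(k) is the density of the induced
subgraph on the S survivors, E_sub / (S(S-1)/2). Because Phi rises with k in
any network with a heavy degree tail, it is normalized against an ensemble of
degree-preserving random networks (Maslov-Sneppen pairwise edge swaps):
Phi_norm(k) = Phi(k) / mean Phi_random(k). Phi_norm > 1 over a range of k is
the signature of rich-club organization.

Hubs are the top fraction of nodes by binary degree on a group-averaged
network; every existing edge is then classed rich (hub-hub), feeder
(hub-nonhub) or local (nonhub-nonhub), and class-wise connectivity strength
(sum of streamline counts) and density (class strength / whole-network
strength) summarize each subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from richclubkit.core_network import (
    BinaryNetwork,
    ConnectivityMatrix,
    GroupAverageNetwork,
    node_degree,
)

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("rich", "feeder", "local")

#: Sentinel for "Phi undefined at this k" (fewer than 2 survivors, or an
#: empty null average). Callers test with numpy.isnan.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class RichClubProfile:
    """Phi(k), null-averaged Phi_random(k), and Phi_norm(k) over the k sweep."""

    k_values: np.ndarray
    phi: np.ndarray
    phi_random: np.ndarray
    phi_norm: np.ndarray
    n_random: int
    seed: int


@dataclass(frozen=True)
class HubPartition:
    """Rich-club node set plus the induced classification of existing edges."""

    hub_nodes: frozenset[str]
    edge_class: dict[tuple[str, str], str] = field(repr=False)
    hub_fraction: float = 0.0


@dataclass(frozen=True)
class ClassMetrics:
    """Connectivity strength and density per edge class for one subject.

    Strength sums each undirected edge's weight once; density is the class
    strength divided by whole-network strength, so the three densities sum to
    1 whenever total strength is positive (NaN sentinels otherwise).
    """

    strength_rich: float
    strength_feeder: float
    strength_local: float
    density_rich: float
    density_feeder: float
    density_local: float
    subject_id: str = ""


def _survivor_mask(degrees: np.ndarray, k: int, survivor_rule: str) -> np.ndarray:
    if survivor_rule == "ge":
        return degrees >= k
    if survivor_rule == "gt":
        return degrees > k
    raise ValueError(f"survivor_rule must be 'ge' or 'gt', got {survivor_rule!r}")


def rich_club_coefficient(
    net: BinaryNetwork, k: int, survivor_rule: str = "ge"
) -> float:
    """Rich-club coefficient Phi at level k.

    Nodes failing the survivor rule (degree < k under the default ``"ge"``
    rule; degree <= k under ``"gt"``) are removed, with degrees computed on
    the full network. Phi is the edge density among survivors; NaN when fewer
    than two nodes survive.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    keep = _survivor_mask(node_degree(net), k, survivor_rule)
    s = int(keep.sum())
    if s < 2:
        return UNDEFINED
    e_sub = int(net.adjacency[np.ix_(keep, keep)].sum()) // 2
    return e_sub / (s * (s - 1) / 2)


def rich_club_curve(net: BinaryNetwork, survivor_rule: str = "ge") -> dict[int, float]:
    """Phi(k) for every integer k from the minimum non-isolated degree to the
    maximum degree; undefined entries carried as NaN sentinels."""
    deg = node_degree(net)
    nonzero = deg[deg > 0]
    if nonzero.size == 0:
        raise ValueError("network has no edges; rich-club curve undefined")
    k_min, k_max = int(nonzero.min()), int(deg.max())
    return {
        k: rich_club_coefficient(net, k, survivor_rule)
        for k in range(k_min, k_max + 1)
    }


def rewire_preserving_degree(
    net: BinaryNetwork, n_swap_per_edge: int = 10, seed: int = 0
) -> BinaryNetwork:
    """Maslov-Sneppen degree-preserving randomization.

    Attempts ``n_swap_per_edge * E`` pairwise edge swaps (a,b)+(c,d) ->
    (a,d)+(c,b); a swap is rejected if it would create a self-loop or a
    multi-edge. The degree sequence, node count, and edge count are conserved
    exactly. Deterministic given ``seed``.
    """
    edges = np.argwhere(np.triu(net.adjacency, 1) > 0)
    n_edges = len(edges)
    if n_edges < 2:
        logger.warning("network has %d edge(s); returning it unchanged", n_edges)
        return net
    rng = np.random.default_rng(seed)
    edge_set = {tuple(e) for e in edges}
    edges = [tuple(e) for e in edges]
    n_attempts = n_swap_per_edge * n_edges
    pairs = rng.integers(0, n_edges, size=(n_attempts, 2))
    sides = rng.integers(0, 2, size=n_attempts)
    for (ei, ej), flip in zip(pairs, sides):
        if ei == ej:
            continue
        a, b = edges[ei]
        c, d = edges[ej]
        if flip:  # swap one endpoint orientation for mixing over both pairings
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[ei] = new1
        edges[ej] = new2
    adj = np.zeros_like(net.adjacency)
    if edge_set:
        idx = np.array(sorted(edge_set))
        adj[idx[:, 0], idx[:, 1]] = 1
        adj[idx[:, 1], idx[:, 0]] = 1
    return BinaryNetwork(net.node_labels, adj)


def normalized_rich_club(
    net: BinaryNetwork,
    n_random: int = 1000,
    n_swap_per_edge: int = 10,
    seed: int = 0,
    survivor_rule: str = "ge",
) -> RichClubProfile:
    """Phi_norm(k) = Phi(k) / mean Phi(k) over ``n_random`` degree-preserving nulls.

    The null average at each k is taken over nulls where Phi(k) is defined;
    Phi_norm is NaN where Phi itself is undefined, where no null defines
    Phi(k), or where the null average is zero. Per-null seeds are derived
    from ``seed`` by counter so runs are reproducible.
    """
    if n_random < 1:
        raise ValueError(f"n_random must be >= 1, got {n_random}")
    curve = rich_club_curve(net, survivor_rule)
    k_values = np.array(sorted(curve), dtype=np.int64)
    phi = np.array([curve[k] for k in k_values], dtype=float)

    null_sum = np.zeros(len(k_values))
    null_count = np.zeros(len(k_values), dtype=np.int64)
    ss = np.random.SeedSequence(seed)
    null_seeds = [int(s) for s in ss.generate_state(n_random)]
    for null_seed in null_seeds:
        null = rewire_preserving_degree(net, n_swap_per_edge, seed=null_seed)
        # identical degree sequence -> identical k sweep
        for i, k in enumerate(k_values):
            val = rich_club_coefficient(null, int(k), survivor_rule)
            if not math.isnan(val):
                null_sum[i] += val
                null_count[i] += 1
    phi_random = np.where(null_count > 0, null_sum / np.maximum(null_count, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(
            np.isnan(phi) | np.isnan(phi_random) | (phi_random == 0),
            np.nan,
            phi / phi_random,
        )
    return RichClubProfile(k_values, phi, phi_random, phi_norm, n_random, seed)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def identify_rich_club_nodes(
    group_net: GroupAverageNetwork | BinaryNetwork, hub_fraction: float = 0.12
) -> tuple[str, ...]:
    """Top ``round(hub_fraction * N)`` nodes by binary degree (round half up).

    Ties at the cut degree are broken by ascending label order, which is
    logged; the result is deterministic and invariant to node permutation up
    to that tie-break. With 90 nodes and the default fraction 0.12 this
    yields exactly 11 hub regions.
    """
    if not 0 < hub_fraction < 1:
        raise ValueError(f"hub_fraction must be in (0, 1), got {hub_fraction}")
    n = group_net.n_nodes
    n_hubs = _round_half_up(hub_fraction * n)
    if n_hubs == 0:
        raise ValueError(f"hub_fraction {hub_fraction} yields 0 hubs on {n} nodes")
    deg = node_degree(group_net)
    order = sorted(range(n), key=lambda i: (-deg[i], group_net.node_labels[i]))
    cut_degree = deg[order[n_hubs - 1]]
    if n_hubs < n and deg[order[n_hubs]] == cut_degree:
        logger.info("degree tie at the hub cut (degree %d); broken by label order", cut_degree)
    return tuple(group_net.node_labels[i] for i in order[:n_hubs])


def classify_edges(
    net: ConnectivityMatrix | BinaryNetwork, hubs: set[str] | tuple[str, ...]
) -> HubPartition:
    """Assign every existing edge to rich (hub-hub), feeder (hub-nonhub) or
    local (nonhub-nonhub) by endpoint hub membership."""
    hubs = frozenset(hubs)
    unknown = hubs - set(net.node_labels)
    if unknown:
        raise ValueError(f"hub labels not in network: {sorted(unknown)}")
    mat = net.weights if isinstance(net, ConnectivityMatrix) else net.adjacency
    labels = net.node_labels
    is_hub = np.array([lab in hubs for lab in labels])
    edge_class: dict[tuple[str, str], str] = {}
    ii, jj = np.nonzero(np.triu(mat, 1))
    for i, j in zip(ii, jj):
        n_hub_ends = int(is_hub[i]) + int(is_hub[j])
        edge_class[(labels[i], labels[j])] = EDGE_CLASSES[2 - n_hub_ends]
    return HubPartition(hub_nodes=hubs, edge_class=edge_class, hub_fraction=len(hubs) / len(labels))


def class_metrics(net: ConnectivityMatrix, partition: HubPartition) -> ClassMetrics:
    """Class-wise connectivity strength and density for one subject.

    Strength is the sum of the subject's edge weights within a class (each
    undirected edge counted once); density normalizes by whole-network
    strength. Class membership follows the partition's hub set re-applied to
    this subject's own edges, so subjects may have edges absent from the
    group network.
    """
    label_index = {lab: i for i, lab in enumerate(net.node_labels)}
    for hub in partition.hub_nodes:
        if hub not in label_index:
            raise ValueError(f"partition hub {hub!r} not among network labels")
    is_hub = np.array([lab in partition.hub_nodes for lab in net.node_labels])
    w = np.triu(net.weights, 1)
    hub_outer = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    strengths = {
        "rich": float(w[hub_outer == 2].sum()),
        "feeder": float(w[hub_outer == 1].sum()),
        "local": float(w[hub_outer == 0].sum()),
    }
    total = sum(strengths.values())
    if total > 0:
        densities = {c: strengths[c] / total for c in EDGE_CLASSES}
    else:
        densities = {c: UNDEFINED for c in EDGE_CLASSES}
    return ClassMetrics(
        strength_rich=strengths["rich"],
        strength_feeder=strengths["feeder"],
        strength_local=strengths["local"],
        density_rich=densities["rich"],
        density_feeder=densities["feeder"],
        density_local=densities["local"],
        subject_id=net.subject_id,
    )
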