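"""Connectivity-matrix data model, thresholding, degree, and group-averaged networks.

A structural connectome is represented as a symmetric, zero-diagonal matrix of
nonnegative streamline counts over an ordered list of parcellation labels
(e.g. the 90 cortical/subcortical regions of AAL-90). Degree is always the
*binary* degree — the number of nonzero off-diagonal entries in a row — never
the weighted strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NetworkValidationError(ValueError):
    """Raised when a connectivity matrix violates a structural invariant."""


def _validate_square_symmetric(weights: np.ndarray, labels: tuple[str, ...]) -> None:
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise NetworkValidationError(f"matrix must be square, got shape {weights.shape}")
    if len(labels) != weights.shape[0]:
        raise NetworkValidationError(
            f"{len(labels)} labels for a {weights.shape[0]}x{weights.shape[1]} matrix"
        )
    neg = np.argwhere(weights < 0)
    if neg.size:
        i, j = neg[0]
        raise NetworkValidationError(f"negative weight {weights[i, j]} at cell ({i}, {j})")
    asym = np.argwhere(weights != weights.T)
    if asym.size:
        i, j = asym[0]
        raise NetworkValidationError(
            f"asymmetric at cell ({i}, {j}): w[{i},{j}]={weights[i, j]} != w[{j},{i}]={weights[j, i]}"
        )
    diag = np.flatnonzero(np.diag(weights))
    if diag.size:
        i = diag[0]
        raise NetworkValidationError(f"nonzero diagonal at cell ({i}, {i})")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric weighted adjacency over labeled nodes.

    Parameters
    ----------
    node_labels
        Ordered region identifiers; node identity is carried by these strings,
        internal indexing is 0-based positional.
    weights
        N x N nonnegative streamline counts; symmetric with a zero diagonal.
    subject_id
        Opaque subject identifier.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))
        w = np.asarray(self.weights)
        _validate_square_symmetric(w, self.node_labels)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def binarize(self) -> "BinaryNetwork":
        """0/1 adjacency: an edge exists wherever the weight is nonzero."""
        return BinaryNetwork(self.node_labels, (self.weights > 0).astype(np.int8))


@dataclass(frozen=True)
class BinaryNetwork:
    """Unweighted undirected network over labeled nodes (0/1 adjacency)."""

    node_labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_labels", tuple(str(x) for x in self.node_labels))
        a = np.asarray(self.adjacency)
        _validate_square_symmetric(a, self.node_labels)
        if not np.isin(a, (0, 1)).all():
            raise NetworkValidationError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class GroupAverageNetwork(BinaryNetwork):
    """Group-level binary network keeping edges present in at least a
    ``prevalence_threshold`` fraction of the group's subjects."""

    prevalence_threshold: float = 1.0
    group_id: str = ""


def threshold_matrix(raw: ConnectivityMatrix, min_streamlines: int) -> ConnectivityMatrix:
    """Zero out edges supported by fewer than ``min_streamlines`` streamlines.

    Edges with count >= ``min_streamlines`` are retained with their raw count
    unchanged (the comparison is inclusive: a count exactly at the floor
    survives). Idempotent, symmetry-preserving.
    """
    if min_streamlines < 1:
        raise ValueError(f"min_streamlines must be >= 1, got {min_streamlines}")
    w = raw.weights.copy()
    w[w < min_streamlines] = 0
    return ConnectivityMatrix(raw.node_labels, w, raw.subject_id)


def node_degree(net: ConnectivityMatrix | BinaryNetwork) -> np.ndarray:
    """Binary degree per node: number of nonzero off-diagonal entries in its row."""
    mat = net.weights if isinstance(net, ConnectivityMatrix) else net.adjacency
    return (mat > 0).sum(axis=1).astype(np.int64)


def group_average_network(
    mats: list[ConnectivityMatrix],
    prevalence: float,
    group_id: str = "",
) -> GroupAverageNetwork:
    """Binary group network: edge kept iff present in >= ``prevalence`` of subjects.

    The boundary is inclusive (3 of 5 subjects passes prevalence 0.60). All
    matrices must share identical node labels.
    """
    if not mats:
        raise ValueError("need at least one matrix")
    if not 0 < prevalence <= 1:
        raise ValueError(f"prevalence must be in (0, 1], got {prevalence}")
    labels = mats[0].node_labels
    for m in mats[1:]:
        if m.node_labels != labels:
            bad = next(
                (a, b) for a, b in zip(labels, m.node_labels) if a != b
            ) if len(labels) == len(m.node_labels) else (len(labels), len(m.node_labels))
            raise ValueError(
                f"node label mismatch for subject {m.subject_id!r}: first mismatch {bad}"
            )
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for m in mats:
        counts += m.weights > 0
    adj = (counts / len(mats) >= prevalence).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return GroupAverageNetwork(labels, adj, prevalence_threshold=prevalence, group_id=group_id)
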