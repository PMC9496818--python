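"""Network information measures: Shannon entropy, Fisher information, and the
Shannon-Fisher plane.

A connectome is binarized at a threshold (default 0.5, strict ``>``) into an
adjacency matrix. For each node i the one-step random-walk distribution is
p_{i->j} = a_ij / k_i over the other nodes j (ascending node order, skipping
i), where k_i is the degree. The node's normalized Shannon entropy is
S[P(i)] / ln(N-1) and its normalized Fisher information is
(1/2) * sum over consecutive entries (sqrt(p_next) - sqrt(p))^2. Averaging
over nodes gives the network measures H and F, each in [0, 1]; a subject's
connectome becomes the point (H, F) on the Shannon-Fisher plane. Dense,
homogeneous graphs sit near the disordered corner (H ~ 1, F ~ 0); sparse,
locally concentrated graphs near the ordered corner (H ~ 0, F ~ 1).

Isolated nodes (k_i = 0) leave the walk distribution undefined; they are
assigned H(i) = 0 and F(i) = 1 — the maximally ordered convention — and
flagged in the returned distribution / the module log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .core import ConnectivityMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal."""

    a: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise ValidationError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValidationError("adjacency diagonal must be zero")
        self.a = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(int)


@dataclass
class NodeDistribution:
    """Random-walk distribution of one node over the other N-1 nodes."""

    node: int
    probs: np.ndarray
    degree: int

    @property
    def isolated(self) -> bool:
        return self.degree == 0


@dataclass
class PlanePoint:
    """A subject's coordinates on the Shannon-Fisher plane."""

    subject_id: str
    H: float
    F: float
    site: str = ""

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.H <= 1 + 1e-12 and -1e-12 <= self.F <= 1 + 1e-12):
            raise ValidationError(f"(H, F) = ({self.H}, {self.F}) outside the unit square")
        self.H = float(min(max(self.H, 0.0), 1.0))
        self.F = float(min(max(self.F, 0.0), 1.0))


def binarize(m: ConnectivityMatrix, threshold: float = 0.5) -> AdjacencyMatrix:
    """Edge present iff weight strictly exceeds the threshold; diagonal zeroed."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    a = (m.weights > threshold).astype(np.uint8)
    np.fill_diagonal(a, 0)
    a &= a.T  # weights are symmetric, but guard against tolerance-level asymmetry
    return AdjacencyMatrix(a=a, threshold_used=float(threshold))


def walk_distribution(a: AdjacencyMatrix, i: int) -> NodeDistribution:
    """One-step random-walk probabilities from node i, ascending j, j != i."""
    n = a.n_nodes
    if not (0 <= i < n):
        raise ValidationError(f"node index {i} out of range for N = {n}")
    row = a.a[i].astype(float)
    k = int(row.sum())
    probs = np.delete(row, i)
    if k > 0:
        probs = probs / k
    return NodeDistribution(node=i, probs=probs, degree=k)


def nodal_entropy(d: NodeDistribution, n: int) -> float:
    """Normalized nodal Shannon entropy S[P(i)] / ln(N-1), in [0, 1]."""
    if n < 3:
        raise ValidationError("entropy normalization needs N >= 3")
    if d.isolated:
        return 0.0
    s = float(-np.sum(xlogy(d.probs, d.probs)))
    return s / np.log(n - 1)


def nodal_fisher(d: NodeDistribution) -> float:
    """Normalized nodal Fisher information: half the summed squared jumps of
    sqrt(p) along the ordered distribution. Isolated nodes score 1."""
    if d.isolated:
        return 1.0
    root = np.sqrt(d.probs)
    return float(0.5 * np.sum(np.diff(root) ** 2))


def network_entropy(a: AdjacencyMatrix) -> float:
    """Normalized network Shannon entropy: mean of nodal entropies.

    1 for the complete graph, -> 0 for sparse graphs.
    """
    n = a.n_nodes
    if n < 3:
        raise ValidationError("network entropy needs N >= 3")
    k = a.degrees
    if (k == 0).any():
        logger.info("graph has %d isolated node(s); assigning H(i) = 0", int((k == 0).sum()))
    # each walk distribution is uniform over k neighbors, so S[P(i)] = ln k
    with np.errstate(divide="ignore"):
        nodal = np.where(k > 0, np.log(np.maximum(k, 1)) / np.log(n - 1), 0.0)
    return float(nodal.mean())


def network_fisher(a: AdjacencyMatrix) -> float:
    """Normalized network Fisher information: mean of nodal Fisher values.

    0 for the complete graph; isolated nodes contribute 1.
    """
    n = a.n_nodes
    if n < 3:
        raise ValidationError("network Fisher needs N >= 3")
    vals = [nodal_fisher(walk_distribution(a, i)) for i in range(n)]
    return float(np.mean(vals))


def shannon_fisher_point(
    m: ConnectivityMatrix, threshold: float = 0.5, site: str = ""
) -> PlanePoint:
    """Binarize a connectome and place it on the Shannon-Fisher plane."""
    a = binarize(m, threshold)
    return PlanePoint(
        subject_id=m.subject_id,
        H=network_entropy(a),
        F=network_fisher(a),
        site=site,
    )
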