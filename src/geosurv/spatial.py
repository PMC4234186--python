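"""Region adjacency and the intrinsic-CAR (ICAR) prior structure.

The structured spatial effect f_str carries an improper Gaussian Markov
random field prior with precision tau^-2 K_s, where K_s is the graph
Laplacian of the province adjacency (degree on the diagonal, -1 between
neighbours).  Each region is conditionally Normal around the mean of its
neighbours with variance tau^2 / degree.  The unstructured effect is iid
Normal per region; both are kept mean-zero for identifiability and their sum
is the total residual spatial effect reported on maps.
"""

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


class GraphParseError(ValueError):
    pass


@dataclass(frozen=True)
class RegionGraph:
    """Ordered region labels with a validated symmetric adjacency."""

    labels: tuple
    neighbors: dict

    def __post_init__(self):
        index = {lab: i for i, lab in enumerate(self.labels)}
        if len(index) != len(self.labels):
            raise GraphParseError("duplicate region label")
        for lab, nbrs in self.neighbors.items():
            if lab in nbrs:
                raise GraphParseError(f"region {lab!r} listed as its own neighbour")
            for nb in nbrs:
                if nb not in index:
                    raise GraphParseError(f"unknown neighbour label {nb!r} for region {lab!r}")
                if lab not in self.neighbors[nb]:
                    raise GraphParseError(
                        f"asymmetric adjacency: {nb!r} is a neighbour of {lab!r} "
                        f"but not conversely"
                    )

    @property
    def n_regions(self):
        return len(self.labels)

    @property
    def index(self):
        return {lab: i for i, lab in enumerate(self.labels)}

    def degree(self, label):
        return len(self.neighbors[label])

    def adjacency(self):
        a = np.zeros((self.n_regions, self.n_regions))
        idx = self.index
        for lab, nbrs in self.neighbors.items():
            for nb in nbrs:
                a[idx[lab], idx[nb]] = 1.0
        return a

    def precision(self):
        """ICAR precision K_s: the graph Laplacian (degree minus adjacency)."""
        a = self.adjacency()
        return np.diag(a.sum(axis=1)) - a

    def n_components(self):
        n, _ = connected_components(csr_matrix(self.adjacency()), directed=False)
        return int(n)

    def is_connected(self):
        return self.n_components() == 1


def load_graph(path):
    """Parse a plain-text adjacency file.

    Format (BayesX-graph-like): first non-empty line is the number of
    regions; then, per region, three lines: label, neighbour count, and a
    whitespace-separated list of neighbour labels (an empty line when the
    count is zero is not allowed — every region line triple must be present).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise GraphParseError(f"{path}: empty graph file")
    try:
        n = int(lines[0])
    except ValueError:
        raise GraphParseError(f"{path}: line 1: expected a region count, got {lines[0]!r}")
    if len(lines) != 1 + 3 * n:
        raise GraphParseError(
            f"{path}: expected {1 + 3 * n} non-empty lines for {n} regions, found {len(lines)}"
        )
    labels, neighbors = [], {}
    for r in range(n):
        lab = lines[1 + 3 * r]
        try:
            k = int(lines[2 + 3 * r])
        except ValueError:
            raise GraphParseError(
                f"{path}: line {3 + 3 * r}: expected neighbour count for {lab!r}"
            )
        nbrs = tuple(lines[3 + 3 * r].split())
        if len(nbrs) != k:
            raise GraphParseError(
                f"{path}: region {lab!r} declares {k} neighbours but lists {len(nbrs)}"
            )
        if lab in neighbors:
            raise GraphParseError(f"{path}: duplicate region {lab!r}")
        labels.append(lab)
        neighbors[lab] = nbrs
    return RegionGraph(labels=tuple(labels), neighbors=neighbors)


def drc_provinces():
    """The shipped 11-province (pre-2015) DRC adjacency."""
    with resources.as_file(resources.files("geosurv.data") / "drc_provinces.graph") as p:
        return load_graph(p)


def icar_logdensity(f, tau2, graph):
    """ICAR log-density of a centered region vector, up to a constant.

    Equals -f' K_s f / (2 tau^2), i.e. minus the sum of squared neighbour
    differences over unordered pairs, scaled by 2 tau^2.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    f = np.asarray(f, dtype=float)
    if f.shape[0] != graph.n_regions:
        raise ValueError("effect vector length does not match the graph")
    return float(-f @ graph.precision() @ f / (2.0 * tau2))


def conditional_moments(region, f, tau2, graph):
    """Full-conditional (mean, variance) of one region's structured effect.

    mean = average of the neighbouring values, variance = tau^2 / degree.
    Isolated regions have no ICAR conditional; model them through the
    unstructured term instead.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    nbrs = graph.neighbors[region]
    if not nbrs:
        raise ValueError(
            f"region {region!r} has no neighbours; an ICAR effect is undefined — "
            f"use the unstructured (iid) term only"
        )
    f = np.asarray(f, dtype=float)
    idx = graph.index
    vals = np.array([f[idx[nb]] for nb in nbrs])
    return float(vals.mean()), float(tau2 / len(nbrs))
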