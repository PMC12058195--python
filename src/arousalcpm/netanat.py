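"""Signed network construction and anatomy statistics.

The consensus feature mask splits into positive (high-arousal) and negative
(low-arousal) edge sets. Overlap between two datasets' sets is tested with
the right-tail hypergeometric probability — implemented literally as the
survival formulation p = P(X > x) = 1 - hygecdf(x, M, K, n), with a flag for
the inclusive P(X >= x) convention — and with the Jaccard index against a
position-shuffle null. Network-pair enrichment compares the proportion of
selected edges between each pair of the 8 canonical functional networks
(VIS, SOM, DAN, VAN, LIM, FPN, DMN, SUB; 8 within + 28 between = 36 cells)
against a null in which the same number of edges is re-placed uniformly over
the whole edge index, with BH-FDR across the 36 cells per sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dynfc import EdgeIndex
from .permstats import bh_fdr, permutation_pvalue

__all__ = [
    "CANONICAL_NETWORKS",
    "NetworkAssignment",
    "SignedEdgeSet",
    "intersect_networks",
    "hypergeometric_overlap_test",
    "jaccard_overlap_test",
    "pair_possible_edges",
    "networkpair_enrichment",
    "overlap_fraction",
    "load_assignment",
    "default_assignment_122",
    "mask_to_signed_edge_set",
]

CANONICAL_NETWORKS = ("VIS", "SOM", "DAN", "VAN", "LIM", "FPN", "DMN", "SUB")


@dataclass(frozen=True)
class NetworkAssignment:
    """ROI id -> one of the 8 canonical functional network labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(CANONICAL_NETWORKS)
        if bad:
            raise ValueError(f"unknown network label(s): {sorted(bad)}")

    @property
    def n_roi(self) -> int:
        return len(self.labels)

    def members(self, network: str) -> np.ndarray:
        if network not in CANONICAL_NETWORKS:
            raise ValueError(f"unknown network label: {network}")
        return np.flatnonzero(np.asarray(self.labels) == network)


@dataclass(frozen=True)
class SignedEdgeSet:
    """Disjoint positive/negative edge-id sets under one edge index."""

    positive: frozenset[int]
    negative: frozenset[int]
    edge_hash: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative edge sets must be disjoint")


def mask_to_signed_edge_set(mask, edge_hash: str | None = None,
                            source: str = "") -> SignedEdgeSet:
    """Build a signed edge set from a CPM feature mask."""
    return SignedEdgeSet(positive=frozenset(int(e) for e in mask.positive()),
                         negative=frozenset(int(e) for e in mask.negative()),
                         edge_hash=edge_hash, source=source)


def load_assignment(path) -> NetworkAssignment:
    """Read a two-column (roi_index, label) TSV into a NetworkAssignment."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values(df.columns[0])
    return NetworkAssignment(labels=tuple(df[df.columns[1]].astype(str)))


def default_assignment_122() -> NetworkAssignment:
    """The bundled 122-ROI assignment (synthetic stand-in).

    The cortical block sizes are a plausible synthetic stand-in, not the
    atlas table used on real data; the final 8 ROIs are subcortical (SUB).
    Replace the bundled TSV with a real atlas table for real analyses.
    """
    with resources.files("arousalcpm").joinpath(
        "data/roi122_networks_synthetic.tsv"
    ).open() as fh:
        return load_assignment(fh)


def intersect_networks(a: SignedEdgeSet, b: SignedEdgeSet) -> SignedEdgeSet:
    """Sign-wise intersection: the overlap network of two datasets."""
    if a.edge_hash is not None and b.edge_hash is not None and a.edge_hash != b.edge_hash:
        raise ValueError("edge index mismatch between edge sets")
    return SignedEdgeSet(positive=a.positive & b.positive,
                         negative=a.negative & b.negative,
                         edge_hash=a.edge_hash or b.edge_hash,
                         source=f"intersect({a.source},{b.source})")


def hypergeometric_overlap_test(x: int, M: int, K: int, n: int,
                                inclusive: bool = False) -> float:
    """Right-tail probability of drawing an overlap of ``x`` by chance.

    Two sets of sizes K and n are placed at random in a population of M
    items. Default is the strict survival formulation P(X > x) =
    1 - hygecdf(x, M, K, n); ``inclusive=True`` gives the conventional
    P(X >= x). The two differ negligibly at realistic scales but matter on
    toy instances.
    """
    if not (0 <= x <= min(K, n) <= M):
        raise ValueError("need 0 <= x <= min(K, n) <= M")
    return float(hypergeom.sf(x - 1 if inclusive else x, M, K, n))


def jaccard_overlap_test(a, b, M: int, n_perm: int = 10000,
                         seed: int = 0) -> tuple[float, float]:
    """Jaccard index |a&b|/|a|b| with a position-shuffle permutation p.

    Null: both sets' positions are re-drawn uniformly at random over the M
    edges with their sizes fixed; p is one-tailed greater.
    """
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    j_emp = len(a & b) / len(a | b)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for it in range(n_perm):
        ra = rng.choice(M, size=len(a), replace=False)
        rb = rng.choice(M, size=len(b), replace=False)
        inter = len(np.intersect1d(ra, rb, assume_unique=True))
        nulls[it] = inter / (len(a) + len(b) - inter)
    return j_emp, permutation_pvalue(j_emp, nulls, tail="greater")


def pair_possible_edges(assignment: NetworkAssignment, net_a: str, net_b: str) -> int:
    """Number of distinct edges between (or within) two networks."""
    na = len(assignment.members(net_a))
    if net_a == net_b:
        return na * (na - 1) // 2
    nb = len(assignment.members(net_b))
    return na * nb


def _edge_pair_labels(edges: EdgeIndex, assignment: NetworkAssignment) -> np.ndarray:
    """Map every edge to its (unordered) network-pair cell id, 0..35."""
    if assignment.n_roi != edges.n_roi:
        raise ValueError("assignment does not cover the edge index's ROIs")
    order = {name: k for k, name in enumerate(CANONICAL_NETWORKS)}
    roi_net = np.array([order[l] for l in assignment.labels])
    a = roi_net[edges.pairs[:, 0]]
    b = roi_net[edges.pairs[:, 1]]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return lo * len(CANONICAL_NETWORKS) + hi  # unique cell per unordered pair


def _pair_cells() -> list[tuple[str, str]]:
    k = len(CANONICAL_NETWORKS)
    return [(CANONICAL_NETWORKS[i], CANONICAL_NETWORKS[j])
            for i in range(k) for j in range(i, k)]


def networkpair_enrichment(edge_ids, assignment: NetworkAssignment, edges: EdgeIndex,
                           n_perm: int = 10000, seed: int = 0, q: float = 0.05) -> pd.DataFrame:
    """Per network pair: proportion of selected edges, permutation p, FDR flag.

    ``edge_ids`` is one sign's edge set. The null re-places the same number
    of edges uniformly over the whole index and recomputes all 36 cell
    proportions; each cell's p is one-tailed greater, BH-FDR corrected
    across the 36 cells.
    """
    sel = np.asarray(sorted(set(map(int, edge_ids))), dtype=np.int64)
    labels = _edge_pair_labels(edges, assignment)
    k = len(CANONICAL_NETWORKS)
    cells = _pair_cells()
    cell_ids = np.array([CANONICAL_NETWORKS.index(a) * k + CANONICAL_NETWORKS.index(b)
                         for a, b in cells])
    possible = np.bincount(labels, minlength=k * k)[cell_ids].astype(float)
    selected = (np.bincount(labels[sel], minlength=k * k)[cell_ids]
                if sel.size else np.zeros(len(cells)))
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(possible > 0, selected / possible, 0.0)
    if sel.size:
        rng = np.random.default_rng(seed)
        null_counts = np.empty((n_perm, len(cells)))
        for it in range(n_perm):
            draw = rng.choice(edges.n_edges, size=sel.size, replace=False)
            null_counts[it] = np.bincount(labels[draw], minlength=k * k)[cell_ids]
        with np.errstate(invalid="ignore", divide="ignore"):
            null_prop = np.where(possible > 0, null_counts / possible, 0.0)
        pvals = np.array([permutation_pvalue(prop[c], null_prop[:, c], "greater")
                          for c in range(len(cells))])
        reject, p_adj = bh_fdr(pvals, q=q)
    else:
        pvals = np.ones(len(cells))
        p_adj = np.ones(len(cells))
        reject = np.zeros(len(cells), dtype=bool)
    return pd.DataFrame({
        "net_a": [c[0] for c in cells],
        "net_b": [c[1] for c in cells],
        "possible": possible.astype(int),
        "selected": selected.astype(int),
        "proportion": prop,
        "p": pvals,
        "p_fdr": p_adj,
        "significant": reject,
    })


def overlap_fraction(shared: int, total: int) -> float:
    """Percentage of a network's edges that are shared, to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= shared <= total:
        raise ValueError("need 0 <= shared <= total")
    return round(100.0 * shared / total, 2)
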