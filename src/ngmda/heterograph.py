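"""Microbe-drug heterogeneous graph and raw node-feature construction.

Drugs and microbes form a two-type graph: within-type edges carry
similarity values at or above a threshold ``beta``, and cross-type edges
carry the known binary associations.  Node ordering is fixed globally:
drugs occupy indices ``0 .. N_d-1``, microbe ``m_j`` maps to global index
``N_d + j``.  Four raw feature families are derived for every node:

* similarity features  -- block-diagonal of the two (unthresholded)
  similarity matrices;
* multi-modal features -- similarities plus association profile;
* position features    -- the node's row of the heterogeneous adjacency;
* multi-scale topology -- return probabilities of 1..t step random walks
  on the column-normalized adjacency.

Thresholded within-type edges keep their similarity VALUE (weighted
graph); ``binarize`` switches to 0/1 edges.  The unit diagonal of a
similarity matrix always survives thresholding, so every node has a
self-loop and positive degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "HeteroGraphData",
    "microbe_cosine_similarity",
    "threshold_similarity",
    "build_hetero_adjacency",
    "build_similarity_features",
    "build_multimodal_features",
    "random_walk_topology",
    "build_hetero_graph_data",
]

DRUG, MICROBE = 0, 1

_SYM_TOL = 1e-8


@dataclass
class AssociationMatrix:
    """Binary drug x microbe association matrix with identifiers."""

    values: np.ndarray
    drug_ids: list[str]
    microbe_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        n_d, n_m = self.values.shape
        if n_d < 1 or n_m < 1:
            raise ValueError("association matrix must be non-empty")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self.drug_ids = [str(x) for x in self.drug_ids]
        self.microbe_ids = [str(x) for x in self.microbe_ids]
        if len(self.drug_ids) != n_d or len(self.microbe_ids) != n_m:
            raise ValueError("identifier lists do not match matrix shape")
        for name, ids in (("drug", self.drug_ids), ("microbe", self.microbe_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.values.shape[1]

    def positive_pairs(self) -> np.ndarray:
        """(n_pos, 2) array of (drug_index, microbe_index) known associations."""
        return np.argwhere(self.values == 1)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity in [0, 1] with unit diagonal for one node type."""

    values: np.ndarray
    node_type: str  # "drug" | "microbe"
    ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.node_type not in ("drug", "microbe"):
            raise ValueError(f"unknown node type {self.node_type!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -_SYM_TOL or v.max() > 1.0 + _SYM_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        np.clip(v, 0.0, 1.0, out=v)
        np.fill_diagonal(v, 1.0)
        if self.ids is not None:
            self.ids = [str(x) for x in self.ids]
            if len(self.ids) != v.shape[0]:
                raise ValueError("identifier list does not match matrix shape")


@dataclass
class HeteroGraphData:
    """Adjacency, node types and raw feature families for one training graph."""

    adjacency: np.ndarray          # (N, N), weighted, symmetric, self-loops
    node_types: np.ndarray         # (N,), 0 = drug (first), 1 = microbe
    h_simi: np.ndarray             # (N, N) block-diagonal similarities
    h_moda: np.ndarray             # (N, N) similarities + associations
    h_posi: np.ndarray             # (N, N) = adjacency
    h_topo: np.ndarray             # (N, t) random-walk return probabilities
    n_drugs: int = field(default=0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def microbe_cosine_similarity(attributes: np.ndarray,
                              microbe_ids: list[str] | None = None) -> SimilarityMatrix:
    """Pairwise cosine similarity of attribute rows rescaled to [0, 1].

    ``K_ij = (cos(X_i, X_j) + 1) / 2`` so orthogonal profiles score 0.5 and
    anti-parallel ones score 0.  A zero-norm attribute row is rejected with
    the offending microbe named.
    """
    x = np.asarray(attributes, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("attribute matrix must be 2-D")
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        ident = microbe_ids[bad[0]] if microbe_ids is not None else f"row {bad[0]}"
        raise ValueError(f"zero-norm attribute vector for microbe {ident!r}")
    unit = x / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    k = 0.5 * (cos + 1.0)
    k = 0.5 * (k + k.T)
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(k, "microbe", ids=microbe_ids)


def threshold_similarity(sim: SimilarityMatrix | np.ndarray, beta: float) -> np.ndarray:
    """Zero out similarities below ``beta``; kept entries retain their value.

    "Not less than" is inclusive: values exactly equal to ``beta`` survive,
    and the unit diagonal always does.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    return np.where(values >= beta, values, 0.0)


def build_hetero_adjacency(k_drug_t: np.ndarray, k_micr_t: np.ndarray,
                           b: AssociationMatrix) -> np.ndarray:
    """Block adjacency [[K~drug, B], [B^T, K~micr]] of the two-type graph."""
    k_drug_t = np.asarray(k_drug_t, dtype=np.float64)
    k_micr_t = np.asarray(k_micr_t, dtype=np.float64)
    bv = b.values.astype(np.float64)
    if k_drug_t.shape != (b.n_drugs, b.n_drugs):
        raise ValueError("drug similarity block does not match association matrix")
    if k_micr_t.shape != (b.n_microbes, b.n_microbes):
        raise ValueError("microbe similarity block does not match association matrix")
    top = np.hstack([k_drug_t, bv])
    bottom = np.hstack([bv.T, k_micr_t])
    return np.vstack([top, bottom])


def build_similarity_features(k_drug: np.ndarray, k_micr: np.ndarray) -> np.ndarray:
    """Block-diagonal [[Kdrug, 0], [0, Kmicr]] of UN-thresholded similarities."""
    k_drug = np.asarray(k_drug, dtype=np.float64)
    k_micr = np.asarray(k_micr, dtype=np.float64)
    for blk in (k_drug, k_micr):
        if blk.ndim != 2 or blk.shape[0] != blk.shape[1]:
            raise ValueError("similarity blocks must be square")
    n_d, n_m = k_drug.shape[0], k_micr.shape[0]
    out = np.zeros((n_d + n_m, n_d + n_m))
    out[:n_d, :n_d] = k_drug
    out[n_d:, n_d:] = k_micr
    return out


def build_multimodal_features(k_drug: np.ndarray, k_micr: np.ndarray,
                              b: AssociationMatrix) -> np.ndarray:
    """[[Kdrug, B], [B^T, Kmicr]] with UN-thresholded similarities.

    Drug row i holds its similarities to all drugs followed by its
    association profile over microbes; microbe rows mirror this.
    """
    k_drug = np.asarray(k_drug, dtype=np.float64)
    k_micr = np.asarray(k_micr, dtype=np.float64)
    if k_drug.shape != (b.n_drugs, b.n_drugs) or k_micr.shape != (b.n_microbes, b.n_microbes):
        raise ValueError("similarity blocks do not match association matrix")
    bv = b.values.astype(np.float64)
    return np.vstack([np.hstack([k_drug, bv]), np.hstack([bv.T, k_micr])])


def random_walk_topology(adjacency: np.ndarray, t: int) -> np.ndarray:
    """Return probabilities of 1..t step walks: row i is [RW^1_ii .. RW^t_ii].

    The transition operator is ``A D^-1`` with D the diagonal of column
    sums, hence column-stochastic; diagonals of its powers are the
    multi-scale return probabilities.
    """
    if t < 1:
        raise ValueError("walk step count t must be >= 1")
    a = np.asarray(adjacency, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if (a < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    degrees = a.sum(axis=0)
    if (degrees == 0).any():
        raise ValueError("every node needs positive degree (self-loops expected)")
    transition = a / degrees[np.newaxis, :]
    n = a.shape[0]
    out = np.empty((n, t))
    power = np.eye(n)
    for step in range(t):
        power = transition @ power
        out[:, step] = np.diag(power)
    return np.clip(out, 0.0, 1.0)


def build_hetero_graph_data(b: AssociationMatrix, k_drug: SimilarityMatrix,
                            k_micr: SimilarityMatrix, beta: float = 0.9,
                            walk_steps: int = 2,
                            binarize: bool = False) -> HeteroGraphData:
    """Assemble adjacency and all four raw feature families for one graph."""
    kd_t = threshold_similarity(k_drug, beta)
    km_t = threshold_similarity(k_micr, beta)
    if binarize:
        kd_t = (kd_t > 0).astype(np.float64)
        km_t = (km_t > 0).astype(np.float64)
    adjacency = build_hetero_adjacency(kd_t, km_t, b)
    node_types = np.concatenate([
        np.full(b.n_drugs, DRUG, dtype=np.int8),
        np.full(b.n_microbes, MICROBE, dtype=np.int8),
    ])
    return HeteroGraphData(
        adjacency=adjacency,
        node_types=node_types,
        h_simi=build_similarity_features(k_drug.values, k_micr.values),
        h_moda=build_multimodal_features(k_drug.values, k_micr.values, b),
        h_posi=adjacency.copy(),
        h_topo=random_walk_topology(adjacency, walk_steps),
        n_drugs=b.n_drugs,
    )
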