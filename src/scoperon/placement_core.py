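"""Reference-constrained alignment and distance-based phylogenetic placement.

Queries are projected into a fixed reference alignment by global affine-gap
alignment against the column profile, keeping the reference coordinate
system (query-specific insertions are discarded, so every aligned query has
exactly the reference width W). Placement attaches a query to the
reference-tree edge minimising the least-squares mismatch between observed
query-to-leaf p-distances and path lengths through a free attachment point
(pendant length and position along the edge, both constrained
non-negative). Placement stability is quantified by non-parametric
bootstrap over alignment columns.

This is a deliberate distance-based stand-in for full maximum-likelihood
re-inference: it is deterministic, fast, and exhaustively verifiable (every
edge is scored, so the reported optimum is the global optimum of the
criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from numba import njit

from .seqio import OperonRecord, Region, TaxonomyRow

# nucleotide encoding: A=0 C=1 G=2 T=3, anything else (gap, N, ambiguity) = 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i

GAP_OPEN = 2.0
GAP_EXTEND = 0.5
MIN_QUERY_LEN = 50
DEFAULT_MIN_OVERLAP = 100
SATURATION_CAP = 0.75


class InsufficientOverlap(ValueError):
    """Too few shared ungapped columns to compute a distance."""


class PlacementFailed(RuntimeError):
    """Query could not be attached to the reference tree."""


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReferenceDB:
    """Fixed reference alignment + tree + taxonomy.

    The alignment defines the coordinate system all queries are projected
    into; ``trim_mask`` marks the columns retained for distance computation
    (columns with < 50% non-gap occupancy are dropped, standing in for
    automated alignment trimming).
    """

    alignment: dict[str, str]
    tree: dendropy.Tree
    taxonomy: list[TaxonomyRow] = field(default_factory=list)
    trim_mask: np.ndarray | None = None
    region_spans: dict[Region, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.alignment.values()}
        if len(widths) > 1:
            raise ValueError(f"reference rows have unequal widths {sorted(widths)}")
        leaf_labels = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if leaf_labels != set(self.alignment):
            raise ValueError(
                "tree leaf set and alignment key set differ: "
                f"{sorted(leaf_labels ^ set(self.alignment))[:5]} ..."
            )
        # stable node labels: leaves keep taxon labels, internal nodes get
        # postorder names once; edge ids are child-node labels
        for i, node in enumerate(self.tree.postorder_node_iter()):
            if node.is_leaf():
                node.label = node.taxon.label
            elif not node.label:
                node.label = f"n{i}"
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        if self.trim_mask is None:
            self.trim_mask = compute_trim_mask(self.alignment)
        self.trim_mask = np.asarray(self.trim_mask, dtype=bool)
        if self.trim_mask.shape[0] != self.width:
            raise ValueError("trim_mask length differs from alignment width")

    @property
    def width(self) -> int:
        return len(next(iter(self.alignment.values())))

    @property
    def leaf_ids(self) -> list[str]:
        return sorted(self.alignment)

    def taxonomy_for(self, leaf_id: str) -> TaxonomyRow | None:
        for row in self.taxonomy:
            if row.leaf_id == leaf_id:
                return row
        return None

    def restrict_to_regions(self, regions: list[Region]) -> "ReferenceDB":
        """A new ReferenceDB keeping only the columns of the named regions."""
        if not self.region_spans:
            raise ValueError("reference has no region span annotations")
        cols: list[np.ndarray] = []
        spans: dict[Region, tuple[int, int]] = {}
        pos = 0
        for reg in regions:
            s, e = self.region_spans[reg]
            cols.append(np.arange(s, e))
            spans[reg] = (pos, pos + (e - s))
            pos += e - s
        idx = np.concatenate(cols)
        aln = {
            k: "".join(np.frombuffer(v.encode(), dtype="S1")[idx].astype(str))
            for k, v in self.alignment.items()
        }
        return ReferenceDB(
            alignment=aln,
            tree=self.tree.clone(depth=1),
            taxonomy=self.taxonomy,
            trim_mask=self.trim_mask[idx],
            region_spans=spans,
        )

    def drop_leaf(self, leaf_id: str) -> "ReferenceDB":
        """Reference with one leaf removed (for leave-one-out checks)."""
        tree = self.tree.clone(depth=1)
        taxon = tree.taxon_namespace.get_taxon(leaf_id)
        tree.prune_taxa([taxon], suppress_unifurcations=True)
        aln = {k: v for k, v in self.alignment.items() if k != leaf_id}
        return ReferenceDB(
            alignment=aln,
            tree=tree,
            taxonomy=[t for t in self.taxonomy if t.leaf_id != leaf_id],
            trim_mask=None,
            region_spans=self.region_spans,
        )


def compute_trim_mask(alignment: dict[str, str], min_occupancy: float = 0.5) -> np.ndarray:
    """Mask of columns with at least ``min_occupancy`` non-gap residues."""
    rows = np.stack([encode(s) for s in alignment.values()])
    occ = (rows != 4).mean(axis=0)
    return occ >= min_occupancy


@dataclass(frozen=True)
class AlignedQuery:
    """A query projected into reference coordinates (length exactly W)."""

    query_id: str
    states: str

    def encoded(self) -> np.ndarray:
        return encode(self.states)


@dataclass(frozen=True)
class Placement:
    """Attachment of a query to one reference-tree edge.

    ``edge_id`` names the edge by its child node; ``pendant_length`` is the
    length of the branch from the attachment point to the query;
    ``distal_fraction`` locates the attachment point along the edge as the
    distance to the child node over the edge length (0 = at the child, 1 =
    at the parent); ``score`` is the residual sum of squares of
    the distance fit (lower is better); ``support`` is the bootstrap
    fraction of replicates recovering the same edge, when computed.
    """

    query_id: str
    edge_id: str
    pendant_length: float
    distal_fraction: float
    score: float
    support: float | None = None


# ---------------------------------------------------------------------------
# profile alignment (keeplength projection)
# ---------------------------------------------------------------------------

_NEG = -1.0e30


@njit(cache=True)
def _align_kernel(q, freqs, occ, go, ge):  # pragma: no cover - numba
    L = q.shape[0]
    W = occ.shape[0]
    M = np.full((L + 1, W + 1), _NEG, dtype=np.float64)
    Ix = np.full((L + 1, W + 1), _NEG, dtype=np.float64)  # query insertion
    Iy = np.full((L + 1, W + 1), _NEG, dtype=np.float64)  # column skipped
    ptr_m = np.zeros((L + 1, W + 1), dtype=np.int8)
    ptr_x = np.zeros((L + 1, W + 1), dtype=np.int8)
    ptr_y = np.zeros((L + 1, W + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, W + 1):
        Iy[0, j] = 0.0  # free leading deletions (semi-global)
        ptr_y[0, j] = 2
    for i in range(1, L + 1):
        Ix[i, 0] = -go - ge * i
        ptr_x[i, 0] = 1
    for i in range(1, L + 1):
        qb = q[i - 1]
        for j in range(1, W + 1):
            if qb < 4:
                sc = occ[j - 1] * (2.0 * freqs[qb, j - 1] - 1.0)
            else:
                sc = 0.0
            # match state
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + sc
            ptr_m[i, j] = p
            # insertion in query (consume query base, no column)
            a = M[i - 1, j] - go - ge
            b = Ix[i - 1, j] - ge
            if a >= b:
                Ix[i, j] = a
                ptr_x[i, j] = 0
            else:
                Ix[i, j] = b
                ptr_x[i, j] = 1
            # deletion (skip reference column); cheap for gappy columns
            dcost = ge * occ[j - 1]
            a = M[i, j - 1] - go * occ[j - 1] - dcost
            b = Iy[i, j - 1] - dcost
            if a >= b:
                Iy[i, j] = a
                ptr_y[i, j] = 0
            else:
                Iy[i, j] = b
                ptr_y[i, j] = 2
    # free trailing deletions: end at (L, j) in M or Ix, columns j..W unmatched
    best_score = _NEG
    best_j = W
    best_state = 0
    for j in range(W + 1):
        if M[L, j] > best_score:
            best_score = M[L, j]
            best_j = j
            best_state = 0
        if Ix[L, j] > best_score:
            best_score = Ix[L, j]
            best_j = j
            best_state = 1
    states = np.full(W, 4, dtype=np.uint8)
    i, j, st = L, best_j, best_state
    while i > 0 or j > 0:
        if st == 0:  # match
            if i == 0 and j == 0:
                break
            states[j - 1] = q[i - 1]
            st = ptr_m[i, j]
            i -= 1
            j -= 1
        elif st == 1:  # query insertion: discard base
            st = ptr_x[i, j]
            i -= 1
        else:  # deletion: column stays gap
            st = ptr_y[i, j]
            j -= 1
    return states, best_score


class _Profile:
    def __init__(self, refdb: ReferenceDB) -> None:
        rows = np.stack([encode(refdb.alignment[k]) for k in refdb.leaf_ids])
        self.rows = rows
        W = rows.shape[1]
        counts = np.zeros((4, W), dtype=np.float64)
        for b in range(4):
            counts[b] = (rows == b).sum(axis=0)
        nongap = counts.sum(axis=0)
        self.occ = nongap / rows.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(nongap > 0, counts / np.maximum(nongap, 1), 0.0)
        self.freqs = np.ascontiguousarray(freqs)


def _workspace(refdb: ReferenceDB) -> "_Workspace":
    ws = getattr(refdb, "_ws", None)
    if ws is None:
        ws = _Workspace(refdb)
        object.__setattr__(refdb, "_ws", ws)
    return ws


def align_to_reference(query: OperonRecord, refdb: ReferenceDB) -> AlignedQuery:
    """Project an ungapped query into the reference alignment.

    Global affine-gap alignment against the column-wise profile (match
    reward from column base frequencies, scaled by column occupancy so that
    gap-riddled columns are nearly free to skip); end deletions are free so
    partial-operon amplicons align to their region. Query-specific
    insertions are discarded: the output always has the reference width.
    """
    if len(query.sequence) < MIN_QUERY_LEN:
        raise ValueError(
            f"query {query.id}: length {len(query.sequence)} < {MIN_QUERY_LEN}, "
            "too short to place"
        )
    if "-" in query.sequence:
        raise ValueError(f"query {query.id}: must be ungapped")
    prof = _workspace(refdb).profile
    q = encode(query.sequence)
    states, _ = _align_kernel(q, prof.freqs, prof.occ, GAP_OPEN, GAP_EXTEND)
    chars = np.array(list("ACGT-"), dtype="U1")
    return AlignedQuery(query_id=query.id, states="".join(chars[np.minimum(states, 4)]))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def pairwise_distance(
    a: str,
    b: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    mask: np.ndarray | None = None,
) -> float:
    """p-distance with pairwise deletion over unambiguous columns."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    ea, eb = encode(a), encode(b)
    valid = (ea < 4) & (eb < 4)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n < min_overlap:
        raise InsufficientOverlap(f"only {n} comparable columns (< {min_overlap})")
    return float((ea[valid] != eb[valid]).sum() / n)


def distance_matrix(
    sequences: dict[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    mask: np.ndarray | None = None,
    cap: float | None = SATURATION_CAP,
) -> tuple[np.ndarray, list[str]]:
    """All-pairs p-distances from gapped rows, capped at the saturation guard."""
    labels = sorted(sequences)
    rows = np.stack([encode(sequences[k]) for k in labels])
    valid = rows < 4
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)[None, :]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        counts = both.sum(axis=1)
        if np.any(counts < min_overlap):
            j = int(np.argmin(counts)) + i + 1
            raise InsufficientOverlap(
                f"{labels[i]} vs {labels[j]}: only {counts.min()} comparable columns"
            )
        mism = ((rows[i] != rows[i + 1 :]) & both).sum(axis=1)
        D[i, i + 1 :] = D[i + 1 :, i] = mism / counts
    if cap is not None:
        D = np.minimum(D, cap)
    return D, labels


def nj_tree(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Labels are processed in lexicographic order so tie-breaking is
    deterministic; negative estimated branch lengths are clamped to zero.
    """
    import skbio

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix/label shape mismatch")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    if np.max(np.abs(np.diag(D))) > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")
    order = np.argsort(np.asarray(labels, dtype=object))
    D = D[np.ix_(order, order)]
    sorted_labels = [labels[i] for i in order]
    dm = skbio.DistanceMatrix(D, ids=sorted_labels)
    result = skbio.tree.nj(dm)
    newick = str(result).strip()
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


class _Workspace:
    """Cached per-reference arrays used by alignment and placement.

    Placement geometry uses branch lengths re-estimated from the reference
    alignment's own p-distances on the fixed topology (non-negative least
    squares over edge/path incidence), so observed query-to-leaf
    p-distances and reference path lengths live on one scale regardless of
    how the input tree's lengths were obtained.
    """

    def __init__(self, refdb: ReferenceDB) -> None:
        self.refdb = refdb
        self.profile = _Profile(refdb)
        self.leaf_ids = refdb.leaf_ids
        self.leaf_index = {k: i for i, k in enumerate(self.leaf_ids)}
        n = len(self.leaf_ids)
        tree = refdb.tree
        self.node_order = list(tree.postorder_node_iter())
        # leaf membership below each node
        inmask: dict = {}
        for node in self.node_order:
            m = np.zeros(n, dtype=bool)
            if node.is_leaf():
                m[self.leaf_index[node.taxon.label]] = True
            else:
                for ch in node.child_nodes():
                    m |= inmask[ch]
            inmask[node] = m
        self.inmask = inmask
        # placement edges in postorder (excluding the root's null edge)
        self.edges = [nd for nd in self.node_order if nd.parent_node is not None]
        self.edge_index = {nd.label: i for i, nd in enumerate(self.edges)}
        self.ref_rows = self.profile.rows  # leaf-order encoded alignment
        self.blen = self._fit_branch_lengths()
        # node -> distances to every leaf, in fitted p-distance units
        down: dict = {}
        for node in self.node_order:
            d = np.full(n, np.inf)
            if node.is_leaf():
                d[self.leaf_index[node.taxon.label]] = 0.0
            else:
                for ch in node.child_nodes():
                    cm = inmask[ch]
                    d[cm] = down[ch][cm] + self.blen[id(ch)]
            down[node] = d
        root = tree.seed_node
        self.full = {root: down[root].copy()}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            d = down[node].copy()
            out = ~inmask[node]
            d[out] = self.blen[id(node)] + self.full[node.parent_node][out]
            self.full[node] = d

    def _fit_branch_lengths(self) -> dict[int, float]:
        from scipy.optimize import nnls

        rows = self.ref_rows
        mask = self.refdb.trim_mask
        valid = (rows < 4) & mask[None, :]
        n = rows.shape[0]
        pairs = []
        dvec = []
        for i in range(n):
            both = valid[i] & valid[i + 1 :]
            counts = np.maximum(both.sum(axis=1), 1)
            mism = ((rows[i] != rows[i + 1 :]) & both).sum(axis=1)
            for k, j in enumerate(range(i + 1, n)):
                pairs.append((i, j))
                dvec.append(min(mism[k] / counts[k], SATURATION_CAP))
        A = np.zeros((len(pairs), len(self.edges)))
        for e, node in enumerate(self.edges):
            m = self.inmask[node]
            for r, (i, j) in enumerate(pairs):
                if m[i] != m[j]:  # edge lies on the i-j path
                    A[r, e] = 1.0
        x, _ = nnls(A, np.asarray(dvec))
        return {id(node): float(x[e]) for e, node in enumerate(self.edges)}

    def branch_length(self, node) -> float:
        return self.blen.get(id(node), 0.0)

    def terminal_branch_lengths(self) -> np.ndarray:
        return np.array(
            [self.blen[id(nd)] for nd in self.edges if nd.is_leaf()]
        )

    def edge_by_id(self, edge_id: str):
        return self.edges[self.edge_index[edge_id]]


def _query_leaf_distances(
    qvec: np.ndarray,
    ws: _Workspace,
    mask: np.ndarray,
    weights: np.ndarray | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """(distances, usable) from a query to every reference leaf."""
    rows = ws.ref_rows
    valid = (rows < 4) & (qvec < 4)[None, :] & mask[None, :]
    mism = (rows != qvec[None, :]) & valid
    if weights is None:
        counts = valid.sum(axis=1).astype(float)
        bad = mism.sum(axis=1).astype(float)
    else:
        counts = valid @ weights
        bad = mism @ weights
    usable = counts >= min_overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(usable, bad / np.maximum(counts, 1e-12), np.nan)
    return d, usable


def _fit_edge(
    y: np.ndarray, s: np.ndarray, b: float, w: np.ndarray
) -> tuple[float, float, float]:
    """Min weighted RSS of y_i ≈ pendant + s_i * distal, pendant ≥ 0,
    distal ∈ [0, b]; weights follow Fitch-Margoliash (1/d²), so nearby
    leaves dominate the attachment."""
    wsum = float(w.sum())
    wssum = float((w * s).sum())
    wysum = float((w * y).sum())
    wsy = float((w * s) @ y)
    candidates: list[tuple[float, float]] = []
    det = wsum * wsum - wssum * wssum
    if det > 1e-12:
        p = (wsum * wysum - wssum * wsy) / det
        x = (wsum * wsy - wssum * wysum) / det
        if p >= 0 and 0 <= x <= b:
            candidates.append((p, x))
    # boundary solutions
    candidates.append((max(0.0, wysum / wsum), 0.0))
    if b > 0:
        candidates.append((max(0.0, (wysum - wssum * b) / wsum), b))
        candidates.append((0.0, min(b, max(0.0, wsy / wsum))))
    candidates.append((0.0, 0.0))
    best = (np.inf, 0.0, 0.0)
    for p, x in candidates:
        rss = float((w * (y - p - s * x) ** 2).sum())
        if rss < best[0] - 1e-15:
            best = (rss, p, x)
    return best


def _place(
    qvec: np.ndarray,
    query_id: str,
    ws: _Workspace,
    weights: np.ndarray | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Placement:
    mask = ws.refdb.trim_mask
    d, usable = _query_leaf_distances(qvec, ws, mask, weights, min_overlap)
    n_leaves = len(ws.leaf_ids)
    if usable.sum() <= n_leaves * 0.5:
        raise PlacementFailed(
            f"query {query_id}: insufficient overlap to "
            f"{n_leaves - int(usable.sum())} of {n_leaves} reference leaves"
        )
    obs = d[usable]
    fm_w = 1.0 / np.maximum(obs, 1e-3) ** 2
    best = (np.inf, None, 0.0, 0.0)
    for node in ws.edges:
        b = ws.branch_length(node)
        inside = ws.inmask[node][usable]
        a = np.where(
            inside,
            ws.full[node][usable],
            ws.full[node.parent_node][usable] + b,
        )
        s = np.where(inside, 1.0, -1.0)
        y = obs - a
        rss, pendant, distal = _fit_edge(y, s, b, fm_w)
        if rss < best[0] - 1e-12:
            best = (rss, node, pendant, distal)
    rss, node, pendant, distal = best
    if node is None:
        raise PlacementFailed(f"query {query_id}: no edge could be fit")
    b = ws.branch_length(node)
    return Placement(
        query_id=query_id,
        edge_id=node.label,
        pendant_length=float(pendant),
        distal_fraction=float(distal / b) if b > 0 else 0.0,
        score=float(rss),
    )


def place_query(
    aq: AlignedQuery,
    refdb: ReferenceDB,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Placement:
    """Attach an aligned query to the best-fitting reference-tree edge.

    Every edge is scored by constrained least squares between the query's
    observed p-distances to the reference leaves and the tree path lengths
    through a candidate attachment point; the returned edge is the global
    optimum, with ties broken by postorder edge index.
    """
    ws = _workspace(refdb)
    return _place(aq.encoded(), aq.query_id, ws, None, min_overlap)


def bootstrap_support(
    aq: AlignedQuery,
    refdb: ReferenceDB,
    n_reps: int = 100,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Fraction of column-bootstrap replicates recovering the original edge."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ws = _workspace(refdb)
    qvec = aq.encoded()
    original = _place(qvec, aq.query_id, ws, None, min_overlap)
    mask = ws.refdb.trim_mask
    cols = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        counts = rng.multinomial(cols.size, np.full(cols.size, 1.0 / cols.size))
        weights = np.zeros(mask.size)
        weights[cols] = counts
        try:
            rep = _place(qvec, aq.query_id, ws, weights, min_overlap)
        except PlacementFailed:
            continue
        if rep.edge_id == original.edge_id:
            hits += 1
    return hits / n_reps


def edge_path_distance(refdb: ReferenceDB, edge_a: str, edge_b: str) -> int:
    """Topological distance between two edges (line-graph shortest path).

    0 for the same edge, 1 for edges sharing a node, and so on. Used as the
    discordance measure between half-sequence placements.
    """
    if edge_a == edge_b:
        return 0
    ws = _workspace(refdb)
    na, nb = ws.edge_by_id(edge_a), ws.edge_by_id(edge_b)

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    def node_dist(x, y):
        anc_x, anc_y = ancestors(x), ancestors(y)
        idx = {id(n): i for i, n in enumerate(anc_x)}
        for j, n in enumerate(anc_y):
            if id(n) in idx:
                return idx[id(n)] + j
        raise ValueError("edges are not in the same tree")

    endpoints_a = (na, na.parent_node)
    endpoints_b = (nb, nb.parent_node)
    closest = min(node_dist(u, v) for u in endpoints_a for v in endpoints_b)
    return closest + 1


def write_placements_tsv(placements: list[Placement], path) -> None:
    import pandas as pd

    rows = [
        {
            "query_id": p.query_id,
            "edge_id": p.edge_id,
            "pendant_length": p.pendant_length,
            "distal_fraction": p.distal_fraction,
            "score": p.score,
            "support": "" if p.support is None else p.support,
        }
        for p in placements
    ]
    pd.DataFrame(
        rows,
        columns=["query_id", "edge_id", "pendant_length", "distal_fraction", "score", "support"],
    ).to_csv(path, sep="\t", index=False)


def write_jplace(placements: list[Placement], refdb: ReferenceDB, path) -> None:
    """Write placements as jplace-style JSON (edge-numbered tree + records)."""
    import json

    ws = _workspace(refdb)
    # edge numbers are indices into metadata.edge_ids (child-node labels)
    newick = refdb.tree.as_string(schema="newick", suppress_rooting=True).strip()
    doc = {
        "version": 3,
        "tree": newick,
        "fields": ["edge_id", "likelihood", "pendant_length", "distal_length"],
        "placements": [
            {
                "p": [
                    [
                        ws.edge_index[p.edge_id],
                        -p.score,
                        p.pendant_length,
                        p.distal_fraction * ws.edge_by_id(p.edge_id).edge.length,
                    ]
                ],
                "n": [p.query_id],
            }
            for p in placements
        ],
        "metadata": {"edge_ids": [nd.label for nd in ws.edges]},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
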