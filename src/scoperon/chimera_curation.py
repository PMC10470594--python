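"""Split-placement curation of long-read OTU sequences.

Each candidate OTU is placed on the reference tree three times: the full
sequence and its former/latter halves. A chimera joins two templates, so
its halves carry conflicting phylogenetic signal and attach to clearly
different parts of the tree; an artifactual consensus shows up instead as
an extremely long pendant branch. "Clearly different" is quantified two
ways, either sufficient: the topological edge distance between the half
placements reaches ``topo_threshold``, or the deepest taxonomic rank the
two placements share is shallower than ``taxo_rank_threshold`` (default:
the halves do not even share a family). "Extremely long branched" is a
robust z-score of the full-sequence pendant length against the reference
terminal branch lengths (median/MAD; IQR fallback when MAD is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import OperonRecord
from .rdna_regions import split_halves
from .placement_core import (
    AlignedQuery,
    Placement,
    PlacementFailed,
    ReferenceDB,
    align_to_reference,
    edge_path_distance,
    place_query,
    _workspace,
)

_RANK_DEPTH = {"phylum": 0, "order": 1, "family": 2, "genus": 3, "species": 4}


@dataclass(frozen=True)
class CurationParams:
    topo_threshold: int = 4
    taxo_rank_threshold: str = "family"
    pendant_k: float = 5.0
    min_half_overlap: int = 100
    rule_combination: str = "either"  # {"either", "both"}

    def __post_init__(self) -> None:
        if self.topo_threshold < 1:
            raise ValueError("topo_threshold must be >= 1")
        if self.pendant_k <= 0:
            raise ValueError("pendant_k must be > 0")
        if self.taxo_rank_threshold not in _RANK_DEPTH:
            raise ValueError(f"unknown rank {self.taxo_rank_threshold!r}")
        if self.rule_combination not in ("either", "both"):
            raise ValueError("rule_combination must be 'either' or 'both'")


@dataclass
class ChimeraVerdict:
    query_id: str
    placement_full: Placement | None
    placement_left: Placement | None
    placement_right: Placement | None
    topo_discordance: int = 0
    patristic_discordance: float = 0.0
    lca_rank: str | None = None
    pendant_z: float = 0.0
    flag_chimera: bool = False
    flag_long_branch: bool = False
    decision: str = "keep"  # {"keep", "exclude", "failed"}
    reason: str = ""


@dataclass
class CurationReport:
    """Conservation-checked accounting of one curation pass."""

    n_input: int = 0
    n_kept: int = 0
    n_excluded_chimera: int = 0
    n_excluded_long_branch: int = 0
    n_excluded_both: int = 0
    n_failed: int = 0
    verdicts: list[ChimeraVerdict] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_chimera + self.n_excluded_long_branch + self.n_excluded_both

    def check_conservation(self) -> None:
        total = self.n_kept + self.n_excluded + self.n_failed
        if total != self.n_input:
            raise AssertionError(
                f"conservation violated: {self.n_input} input != "
                f"{self.n_kept} kept + {self.n_excluded} excluded + "
                f"{self.n_failed} failed"
            )

    def to_json_dict(self, params: CurationParams | None = None) -> dict:
        d = {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_excluded_chimera": self.n_excluded_chimera,
            "n_excluded_long_branch": self.n_excluded_long_branch,
            "n_excluded_both": self.n_excluded_both,
            "n_excluded_total": self.n_excluded,
            "n_failed": self.n_failed,
        }
        if params is not None:
            d["params"] = {
                "topo_threshold": params.topo_threshold,
                "taxo_rank_threshold": params.taxo_rank_threshold,
                "pendant_k": params.pendant_k,
                "min_half_overlap": params.min_half_overlap,
                "rule_combination": params.rule_combination,
            }
        return d


def _terminal_branch_stats(refdb: ReferenceDB) -> tuple[float, float]:
    """(median, robust scale) of reference terminal branch lengths.

    Uses the p-distance-refit branch lengths of the placement workspace so
    the pendant z-score compares like with like."""
    lengths = _workspace(refdb).terminal_branch_lengths()
    med = float(np.median(lengths))
    mad = float(np.median(np.abs(lengths - med)))
    if mad > 0:
        return med, 1.4826 * mad
    q75, q25 = np.percentile(lengths, [75, 25])
    iqr = float(q75 - q25)
    if iqr > 0:
        return med, iqr / 1.349
    return med, max(med, 1e-9)


def _edge_clade_taxonomy(refdb: ReferenceDB, edge_id: str) -> dict[str, str]:
    """Shared rank->name map over the leaves below an attachment edge."""
    ws = _workspace(refdb)
    node = ws.edge_by_id(edge_id)
    leaves = [lf.taxon.label for lf in node.leaf_iter()]
    rows = [refdb.taxonomy_for(l) for l in leaves]
    rows = [r for r in rows if r is not None]
    if not rows:
        return {}
    shared: dict[str, str] = {}
    for rank in _RANK_DEPTH:
        names = {r.name_at(rank) for r in rows}
        if len(names) == 1 and None not in names:
            shared[rank] = names.pop()
        else:
            break
    return shared


def _lca_rank(refdb: ReferenceDB, edge_a: str, edge_b: str) -> str | None:
    """Deepest taxonomic rank shared by the clades of two placements.

    Nested placements (one attachment clade containing the other) are
    lower resolution, not conflict: they count as agreeing at the deeper
    clade's deepest labeled rank."""
    ws = _workspace(refdb)
    na, nb = ws.edge_by_id(edge_a), ws.edge_by_id(edge_b)
    leaves_a = {lf.taxon.label for lf in na.leaf_iter()}
    leaves_b = {lf.taxon.label for lf in nb.leaf_iter()}
    ta, tb = _edge_clade_taxonomy(refdb, edge_a), _edge_clade_taxonomy(refdb, edge_b)
    if leaves_a <= leaves_b or leaves_b <= leaves_a:
        deeper = ta if len(ta) >= len(tb) else tb
        last = None
        for rank in _RANK_DEPTH:
            if rank in deeper:
                last = rank
        return last
    deepest = None
    for rank in _RANK_DEPTH:  # phylum -> species
        if rank in ta and rank in tb and ta[rank] == tb[rank]:
            deepest = rank
        else:
            break
    return deepest


def _patristic(refdb: ReferenceDB, pa: Placement, pb: Placement) -> float:
    """Branch-length path distance between the two attachment points."""
    ws = _workspace(refdb)
    na, nb = ws.edge_by_id(pa.edge_id), ws.edge_by_id(pb.edge_id)
    ba = na.edge.length or 0.0
    bb = nb.edge.length or 0.0
    if na is nb:
        return abs(pa.distal_fraction - pb.distal_fraction) * ba

    def node_dist(x, y):
        anc = {}
        d, n = 0.0, x
        while n is not None:
            anc[id(n)] = d
            d += n.edge.length or 0.0
            n = n.parent_node
        d, n = 0.0, y
        while id(n) not in anc:
            d += n.edge.length or 0.0
            n = n.parent_node
        return d + anc[id(n)]

    # attachment sits distal_fraction * b away from the child node; the path
    # to the other point enters the edge via one of its two endpoints
    off_a = (pa.distal_fraction * ba, (1 - pa.distal_fraction) * ba)
    off_b = (pb.distal_fraction * bb, (1 - pb.distal_fraction) * bb)
    ends_a = (na, na.parent_node)
    ends_b = (nb, nb.parent_node)
    return min(
        off_a[i] + node_dist(ends_a[i], ends_b[j]) + off_b[j]
        for i in range(2)
        for j in range(2)
    )


def assess_query(
    query: OperonRecord, refdb: ReferenceDB, params: CurationParams = CurationParams()
) -> ChimeraVerdict:
    """Place a query and its halves; flag split-placement discordance and
    extreme pendant length.

    The halves are re-aligned to the reference independently (not sliced
    from the full-query alignment), matching how original and divided
    sequences are added to the reference alignment separately.
    """
    if len(query.sequence) < 2 * params.min_half_overlap:
        raise ValueError(
            f"query {query.id}: length {len(query.sequence)} too short for "
            f"split assessment (need >= {2 * params.min_half_overlap})"
        )
    verdict = ChimeraVerdict(query.id, None, None, None)
    left_seq, right_seq = split_halves(query.sequence)
    try:
        aq_full = align_to_reference(query, refdb)
        p_full = place_query(aq_full, refdb, min_overlap=params.min_half_overlap)
        verdict.placement_full = p_full
        for tag, seq in (("left", left_seq), ("right", right_seq)):
            half = OperonRecord(
                id=f"{query.id}|{tag}", sequence=seq, source=query.source
            )
            aq = align_to_reference(half, refdb)
            p = place_query(aq, refdb, min_overlap=params.min_half_overlap)
            setattr(verdict, f"placement_{tag}", p)
    except (PlacementFailed, ValueError) as exc:
        verdict.decision = "failed"
        verdict.reason = f"unplaceable: {exc}"
        return verdict
    p_left, p_right = verdict.placement_left, verdict.placement_right
    verdict.topo_discordance = edge_path_distance(
        refdb, p_left.edge_id, p_right.edge_id
    )
    verdict.patristic_discordance = _patristic(refdb, p_left, p_right)
    verdict.lca_rank = _lca_rank(refdb, p_left.edge_id, p_right.edge_id)
    med, scale = _terminal_branch_stats(refdb)
    verdict.pendant_z = float((p_full.pendant_length - med) / scale)
    lca_depth = _RANK_DEPTH.get(verdict.lca_rank, -1) if verdict.lca_rank else -1
    # the edge-count rule only fires when the halves are also separated by
    # more branch length than the robust terminal-branch outlier scale —
    # a few near-zero-length edges apart is placement jitter, not conflict
    patristic_gate = med + params.pendant_k * scale
    verdict.flag_chimera = (
        verdict.topo_discordance >= params.topo_threshold
        and verdict.patristic_discordance > patristic_gate
    ) or lca_depth < _RANK_DEPTH[params.taxo_rank_threshold]
    verdict.flag_long_branch = verdict.pendant_z > params.pendant_k
    if params.rule_combination == "either":
        exclude = verdict.flag_chimera or verdict.flag_long_branch
    else:
        exclude = verdict.flag_chimera and verdict.flag_long_branch
    verdict.decision = "exclude" if exclude else "keep"
    reasons = []
    if verdict.flag_chimera:
        reasons.append("split_placement_discordant")
    if verdict.flag_long_branch:
        reasons.append("long_branch")
    verdict.reason = "+".join(reasons) if exclude else ""
    return verdict


def curate_set(
    queries: list[OperonRecord],
    refdb: ReferenceDB,
    params: CurationParams = CurationParams(),
) -> tuple[list[OperonRecord], CurationReport]:
    """Assess every query; return kept records and the accounting report."""
    report = CurationReport(n_input=len(queries))
    kept: list[OperonRecord] = []
    by_id = {q.id: q for q in queries}
    for query in queries:
        verdict = assess_query(query, refdb, params)
        report.verdicts.append(verdict)
        if verdict.decision == "failed":
            report.n_failed += 1
        elif verdict.decision == "keep":
            report.n_kept += 1
        elif verdict.flag_chimera and verdict.flag_long_branch:
            report.n_excluded_both += 1
        elif verdict.flag_chimera:
            report.n_excluded_chimera += 1
        else:
            report.n_excluded_long_branch += 1
    report.verdicts.sort(key=lambda v: v.query_id)
    kept = [by_id[v.query_id] for v in report.verdicts if v.decision == "keep"]
    report.check_conservation()
    return kept, report


def select_candidates(
    otus: list[OperonRecord], refdb: ReferenceDB, target_clade: str
) -> list[OperonRecord]:
    """Keep OTUs whose placement edge lies inside the named clade's subtree.

    The taxonomy-based pre-filter applied before curation (e.g. keep only
    the OTUs putatively identified as the target phylum).
    """
    clade_leaves = {
        t.leaf_id
        for t in refdb.taxonomy
        if any(name == target_clade for _, name in t.rank_path)
    }
    if not clade_leaves:
        names = sorted(
            {name for t in refdb.taxonomy for _, name in t.rank_path[:-1]}
        )
        raise ValueError(
            f"unknown clade {target_clade!r}; available: {', '.join(names)}"
        )
    ws = _workspace(refdb)
    selected: list[OperonRecord] = []
    for otu in otus:
        try:
            aq = align_to_reference(otu, refdb)
            placement = place_query(aq, refdb)
        except (PlacementFailed, ValueError) as exc:
            warnings.warn(f"{otu.id}: not placeable ({exc}); dropped", stacklevel=2)
            continue
        node = ws.edge_by_id(placement.edge_id)
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below <= clade_leaves:
            selected.append(otu)
    return selected


def verdicts_to_frame(report: CurationReport):
    import pandas as pd

    rows = []
    for v in report.verdicts:
        rows.append(
            {
                "query_id": v.query_id,
                "edge_full": v.placement_full.edge_id if v.placement_full else "",
                "edge_left": v.placement_left.edge_id if v.placement_left else "",
                "edge_right": v.placement_right.edge_id if v.placement_right else "",
                "topo_discordance": v.topo_discordance,
                "patristic_discordance": round(v.patristic_discordance, 6),
                "lca_rank": v.lca_rank or "",
                "pendant_z": round(v.pendant_z, 4),
                "flag_chimera": v.flag_chimera,
                "flag_long_branch": v.flag_long_branch,
                "decision": v.decision,
                "reason": v.reason,
            }
        )
    return pd.DataFrame(rows)
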