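"""Lineage delimitation and ecology for single-cell operon sequences.

Single-cell records are clustered into species-like "lineages" by
single-linkage at high pairwise identity (pairwise deletion over
trim-masked columns), with a placement-coherence check so that records
that happen to be similar but attach to distant parts of the reference
tree are kept apart. Lineages are then assigned a taxonomy from their
representative's placement, screened for ecology conflicts (a lineage
placed in a fungus-parasite clade but observed growing on an alga is a
putative hyper-parasite), and compared with curated metabarcoding OTUs to
measure the overlap between the two culture-independent methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import OperonRecord
from .synthetic_data import FUNGAL_HOSTS
from .placement_core import (
    AlignedQuery,
    InsufficientOverlap,
    Placement,
    PlacementFailed,
    ReferenceDB,
    align_to_reference,
    edge_path_distance,
    place_query,
    _workspace,
    encode,
)

_RANKS = ("phylum", "order", "family", "genus", "species")

DEFAULT_IDENTITY = 0.99
COHERENCE_EDGES = 2  # members farther apart than this many edges are split


@dataclass
class Lineage:
    lineage_id: str
    member_record_ids: set[str]
    member_cell_ids: set[str]
    representative_id: str
    placement: Placement | None = None
    assigned_clade: tuple[tuple[str, str], ...] = ()
    novelty_rank: str | None = None
    ecology_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ConcordanceRow:
    lineage_id: str
    nearest_otu_id: str | None
    identity: float
    match_level: str  # {"species_level", "same_genus_clade", "same_family_clade", "unmatched"}


class _AlignmentCache:
    def __init__(self, refdb: ReferenceDB) -> None:
        self.refdb = refdb
        self.aligned: dict[str, AlignedQuery] = {}
        self.placed: dict[str, Placement] = {}

    def align(self, record: OperonRecord) -> AlignedQuery:
        if record.id not in self.aligned:
            self.aligned[record.id] = align_to_reference(record, self.refdb)
        return self.aligned[record.id]

    def place(self, record: OperonRecord) -> Placement:
        if record.id not in self.placed:
            self.placed[record.id] = place_query(self.align(record), self.refdb)
        return self.placed[record.id]


def _edge_shared_ranks(refdb: ReferenceDB, edge_id: str) -> dict[str, str]:
    ws = _workspace(refdb)
    node = ws.edge_by_id(edge_id)
    rows = [refdb.taxonomy_for(lf.taxon.label) for lf in node.leaf_iter()]
    rows = [r for r in rows if r is not None]
    shared: dict[str, str] = {}
    for rank in _RANKS:
        names = {r.name_at(rank) for r in rows}
        if len(names) == 1 and None not in names:
            shared[rank] = names.pop()
        else:
            break
    return shared


def exclude_offtarget(
    records: list[OperonRecord],
    refdb: ReferenceDB,
    excluded_clades: list[str],
    cache: _AlignmentCache | None = None,
) -> tuple[list[OperonRecord], list[tuple[OperonRecord, str]]]:
    """Remove records placing inside any excluded clade (e.g. non-target
    phyla), reporting each with the clade it fell into."""
    known = {name for t in refdb.taxonomy for _, name in t.rank_path}
    for clade in excluded_clades:
        if clade not in known:
            raise ValueError(f"unknown clade {clade!r}")
    clade_leafsets = {
        clade: {
            t.leaf_id
            for t in refdb.taxonomy
            if any(n == clade for _, n in t.rank_path)
        }
        for clade in excluded_clades
    }
    cache = cache or _AlignmentCache(refdb)
    ws = _workspace(refdb)
    kept: list[OperonRecord] = []
    excluded: list[tuple[OperonRecord, str]] = []
    for rec in records:
        placement = cache.place(rec)
        below = {
            lf.taxon.label for lf in ws.edge_by_id(placement.edge_id).leaf_iter()
        }
        hit = next(
            (c for c, leaves in clade_leafsets.items() if below <= leaves), None
        )
        if hit is None:
            kept.append(rec)
        else:
            excluded.append((rec, hit))
    return kept, excluded


def _identity_matrix(
    records: list[OperonRecord],
    cache: _AlignmentCache,
    min_overlap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(identity, comparable) matrices over trim-masked columns."""
    refdb = cache.refdb
    mask = refdb.trim_mask
    rows = np.stack([cache.align(r).encoded() for r in records])
    valid = (rows < 4) & mask[None, :]
    n = len(records)
    ident = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        counts = both.sum(axis=1)
        match = ((rows[i] == rows[i + 1 :]) & both).sum(axis=1)
        ok = counts >= min_overlap
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ok, match / np.maximum(counts, 1), 0.0)
        ident[i, i + 1 :] = ident[i + 1 :, i] = vals
        comparable[i, i + 1 :] = comparable[i + 1 :, i] = ok
        ident[i, i] = 1.0
        comparable[i, i] = True
    return ident, comparable


def cluster_lineages(
    records: list[OperonRecord],
    refdb: ReferenceDB,
    identity_threshold: float = DEFAULT_IDENTITY,
    min_overlap: int = 100,
    coherence_edges: int = COHERENCE_EDGES,
    cache: _AlignmentCache | None = None,
) -> list[Lineage]:
    """Single-linkage clustering at ``identity_threshold`` with a
    placement-coherence split.

    Two records join the same lineage if a chain of pairs at or above the
    identity threshold connects them AND their placements stay within
    ``coherence_edges`` of each other along the chain. Records with no
    comparable overlap to anything become singletons with a warning.
    Lineage ids are assigned in input order of each lineage's first member.
    """
    if not records:
        return []
    cache = cache or _AlignmentCache(refdb)
    ident, comparable = _identity_matrix(records, cache, min_overlap)
    n = len(records)
    isolated = ~(comparable & ~np.eye(n, dtype=bool)).any(axis=1)
    for i in np.flatnonzero(isolated):
        warnings.warn(
            f"record {records[i].id}: no comparable overlap to any other "
            "record; kept as singleton lineage",
            stacklevel=2,
        )
    placements = [cache.place(r) for r in records]
    # union-find over pairs passing both identity and coherence
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if not comparable[i, j] or ident[i, j] < identity_threshold:
                continue
            if (
                edge_path_distance(refdb, placements[i].edge_id, placements[j].edge_id)
                > coherence_edges
            ):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    lineages: list[Lineage] = []
    for k, root in enumerate(sorted(groups)):
        members = groups[root]
        rep = max(members, key=lambda i: (len(records[i].sequence), records[i].id))
        lineages.append(
            Lineage(
                lineage_id=f"L{k + 1}",
                member_record_ids={records[i].id for i in members},
                member_cell_ids={records[i].sample_id for i in members},
                representative_id=records[rep].id,
                placement=placements[rep],
            )
        )
    return lineages


def detect_multi_lineage_cells(lineages: list[Lineage]) -> dict[str, set[str]]:
    """Cells whose records fall in two or more lineages.

    These are samples where two independent parasites infected one host
    (or a parasite plus its hyper-parasite were co-isolated)."""
    by_cell: dict[str, set[str]] = {}
    for lin in lineages:
        for cell in lin.member_cell_ids:
            by_cell.setdefault(cell, set()).add(lin.lineage_id)
    return {c: ls for c, ls in by_cell.items() if len(ls) >= 2}


def assign_taxonomy(lineage: Lineage, refdb: ReferenceDB) -> Lineage:
    """Assign the taxonomy of the smallest labeled clade containing the
    placement edge, and the rank at which the lineage is novel.

    A representative identical to a reference leaf is assigned that leaf's
    full rank path. A placement on the stem edge of, say, a family clade is
    contained only by the parent order, so the lineage is assigned the
    order and reported as novel at family rank. Novelty is a report, not a
    taxonomic assertion.
    """
    if lineage.placement is None:
        raise PlacementFailed(f"lineage {lineage.lineage_id}: no placement")
    ws = _workspace(refdb)
    node = ws.edge_by_id(lineage.placement.edge_id)
    if node.is_leaf():
        row = refdb.taxonomy_for(node.taxon.label)
        lineage.assigned_clade = row.rank_path if row else ()
        lineage.novelty_rank = None
        return lineage
    parent_shared = _edge_shared_ranks_for_node(refdb, node.parent_node)
    lineage.assigned_clade = tuple(
        (r, parent_shared[r]) for r in _RANKS if r in parent_shared
    )
    deepest = None
    for r in _RANKS:
        if r in parent_shared:
            deepest = r
    idx = _RANKS.index(deepest) if deepest else -1
    lineage.novelty_rank = _RANKS[idx + 1] if idx + 1 < len(_RANKS) else None
    return lineage


def _edge_shared_ranks_for_node(refdb: ReferenceDB, node) -> dict[str, str]:
    rows = [refdb.taxonomy_for(lf.taxon.label) for lf in node.leaf_iter()]
    rows = [r for r in rows if r is not None]
    shared: dict[str, str] = {}
    for rank in _RANKS:
        names = {r.name_at(rank) for r in rows}
        if len(names) == 1 and None not in names:
            shared[rank] = names.pop()
        else:
            break
    return shared


def flag_ecology_conflict(
    lineage: Lineage,
    metadata: dict[str, dict[str, str]],
    refdb: ReferenceDB,
    fungal_hosts: frozenset[str] = FUNGAL_HOSTS,
) -> set[str]:
    """Flag conflicts between observed ecology and placement.

    A lineage placed in a clade of fungus parasites whose members were
    observed as epibiotic/endobiotic parasites of a non-fungal host is a
    putative hyper-parasite (the sequenced fungus was likely infecting the
    chytrid rather than the alga). A lineage in a saprotroph-containing
    clade whose host cells were dead or moribund is a putative saprotroph.
    """
    if lineage.placement is None:
        lineage.ecology_flags = {"none"}
        return lineage.ecology_flags
    ws = _workspace(refdb)
    node = ws.edge_by_id(lineage.placement.edge_id)
    modes = [
        refdb.taxonomy_for(lf.taxon.label).trophic_mode
        for lf in node.leaf_iter()
        if refdb.taxonomy_for(lf.taxon.label) is not None
    ]
    flags: set[str] = set()
    metas = []
    for rid in sorted(lineage.member_record_ids):
        m = metadata.get(rid)
        if m is None:
            continue
        metas.append(m)
    if not metas:
        warnings.warn(
            f"lineage {lineage.lineage_id}: no member metadata; ecology not assessed",
            stacklevel=2,
        )
        lineage.ecology_flags = {"none"}
        return lineage.ecology_flags
    clade_parasitises_fungi = modes and all(m == "parasite_of_fungi" for m in modes)
    clade_has_saprotrophs = any(m == "saprotroph" for m in modes)
    for m in metas:
        habit = m.get("habit", "unknown")
        host = m.get("host_taxon", "")
        if (
            clade_parasitises_fungi
            and habit in ("epibiotic", "endobiotic")
            and host
            and host not in fungal_hosts
        ):
            flags.add("putative_hyperparasite")
        if clade_has_saprotrophs and m.get("host_status") in ("dead", "moribund"):
            flags.add("putative_saprotroph")
    lineage.ecology_flags = flags or {"none"}
    return lineage.ecology_flags


def concordance(
    lineages: list[Lineage],
    otus: list[OperonRecord],
    refdb: ReferenceDB,
    species_threshold: float = 0.995,
    min_overlap: int = 100,
    cache: _AlignmentCache | None = None,
) -> list[ConcordanceRow]:
    """Nearest curated OTU for each single-cell lineage.

    Identity is computed over shared trim-masked columns (so a partial 18S
    OTU is compared to a full operon representative on the columns both
    cover). ``species_level`` needs identity at or above the threshold;
    otherwise the match level reports whether the nearest OTU's placement
    shares the lineage's genus or family clade.
    """
    cache = cache or _AlignmentCache(refdb)
    if not otus:
        return [
            ConcordanceRow(l.lineage_id, None, 0.0, "unmatched") for l in lineages
        ]
    mask = refdb.trim_mask
    otu_rows = np.stack([cache.align(o).encoded() for o in otus])
    otu_valid = (otu_rows < 4) & mask[None, :]
    rows: list[ConcordanceRow] = []
    by_id = {r.id: r for r in otus}
    for lin in lineages:
        rep_aq = cache.aligned.get(lin.representative_id)
        if rep_aq is None:
            raise KeyError(
                f"representative {lin.representative_id} not in alignment cache; "
                "pass the cache used for clustering"
            )
        rep = rep_aq.encoded()
        both = otu_valid & (rep < 4)[None, :]
        counts = both.sum(axis=1)
        match = ((otu_rows == rep[None, :]) & both).sum(axis=1)
        ok = counts >= min_overlap
        if not ok.any():
            rows.append(ConcordanceRow(lin.lineage_id, None, 0.0, "unmatched"))
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            idents = np.where(ok, match / np.maximum(counts, 1), -1.0)
        best = int(np.argmax(idents))
        best_id = otus[best].id
        ident = float(idents[best])
        if ident >= species_threshold:
            level = "species_level"
        else:
            otu_clade = _edge_shared_ranks(refdb, cache.place(by_id[best_id]).edge_id)
            lin_clade = dict(lin.assigned_clade)
            if (
                "genus" in otu_clade
                and otu_clade.get("genus") == lin_clade.get("genus")
            ):
                level = "same_genus_clade"
            elif (
                "family" in otu_clade
                and otu_clade.get("family") == lin_clade.get("family")
            ):
                level = "same_family_clade"
            else:
                level = "unmatched"
        rows.append(ConcordanceRow(lin.lineage_id, best_id, ident, level))
    return rows


def lineages_to_frame(lineages: list[Lineage]):
    import pandas as pd

    rows = []
    for lin in lineages:
        rows.append(
            {
                "lineage_id": lin.lineage_id,
                "n_records": len(lin.member_record_ids),
                "members": ",".join(sorted(lin.member_record_ids)),
                "cells": ",".join(sorted(lin.member_cell_ids)),
                "representative": lin.representative_id,
                "edge_id": lin.placement.edge_id if lin.placement else "",
                "assigned_clade": ";".join(n for _, n in lin.assigned_clade),
                "novelty_rank": lin.novelty_rank or "",
                "ecology_flags": ",".join(sorted(lin.ecology_flags)) or "none",
            }
        )
    return pd.DataFrame(rows)
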