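"""Synthetic reference databases, query sets and single-cell samples.

The generator emulates the statistical structure the analysis assumes: a
Yule reference phylogeny with gamma rate heterogeneity across sites,
gap-free operon alignments whose columns are the true homology, a query
set of clean descendants / two-parent mid-breakpoint chimeras / long-branch
artifacts, and "cells" that yield one or two independent parasite lineages
with host metadata — including hyper-parasitic lineages whose placement
(a fungus-parasite clade) conflicts with their observed ecology (epibiotic
on an alga). Every generated id is recorded in a ground-truth ledger so the
downstream filters can be scored exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
from scipy import stats

from .seqio import (
    OperonRecord,
    Region,
    REGION_ORDER,
    RegionAnnotation,
    Source,
    TaxonomyRow,
)
from .placement_core import ReferenceDB

_BASES = np.array(list("ACGT"), dtype="U1")

# hosts by trophic guild of the parasite clade; fungal hosts matter for the
# hyper-parasite conflict rule (a fungus-parasite on a fungal host is fine)
_HOSTS = {
    "parasite_of_algae": ["Mougeotia", "Spirogyra", "Aulacoseira", "Desmidium"],
    "parasite_of_fungi": ["Chytridium", "Rhizophydium"],
    "parasite_of_animals": ["Keratella", "Daphnia"],
    "parasite_of_protists": ["Arcella", "Euglypha"],
    "saprotroph": ["pollen", "detritus"],
    "unknown": ["unknown"],
}

FUNGAL_HOSTS = frozenset(_HOSTS["parasite_of_fungi"])

_ALGAL_HOSTS = _HOSTS["parasite_of_algae"]

_TROPHIC_CYCLE = (
    "parasite_of_algae",
    "parasite_of_fungi",
    "saprotroph",
    "parasite_of_protists",
    "parasite_of_animals",
)

_DEFAULT_REGION_LENGTHS = {
    Region.SSU18S: 1300,
    Region.ITS1: 150,
    Region.R5_8S: 160,
    Region.ITS2: 180,
    Region.LSU28S: 900,
}

# relative substitution rates per region (ITS evolves fastest, 5.8S slowest);
# normalised at run time so the length-weighted mean rate is 1
_DEFAULT_REGION_RATES = {
    Region.SSU18S: 0.7,
    Region.ITS1: 2.5,
    Region.R5_8S: 0.5,
    Region.ITS2: 2.5,
    Region.LSU28S: 1.0,
}


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions.

    Divergences are expected substitutions per site. ``birth_rate`` is the
    Yule speciation rate per lineage per unit time; with the default the
    50-leaf reference has terminal branches of a few hundredths of a
    substitution per site, i.e. species-level 18S divergence.
    """

    n_ref_taxa: int = 50
    birth_rate: float = 25.0
    region_lengths: dict[Region, int] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_LENGTHS)
    )
    region_rates: dict[Region, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_RATES)
    )
    subst_model: str = "JC"  # {"JC", "GTR"}
    gamma_shape: float | None = 0.5  # None = homogeneous rates
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # query set
    n_queries: int = 200
    query_divergence: float = 0.02
    chimera_fraction: float = 0.2
    chimera_jitter: float = 0.0  # breakpoint jitter, fraction of L (e.g. 0.1)
    longbranch_fraction: float = 0.05
    longbranch_rate_multiplier: float = 20.0
    insertion_rate: float = 0.002  # per site, exercises keeplength projection
    # single cells
    n_cells: int = 60
    n_lineages: int = 30
    p_two_lineages_per_cell: float = 0.1
    p_hyperparasite: float = 0.1
    p_seq_success: float = 1.0
    n_offtarget_cells: int = 2
    intra_lineage_divergence: float = 0.002
    inter_lineage_divergence: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_ref_taxa < 4:
            bad.append("n_ref_taxa (need >= 4)")
        if self.birth_rate <= 0:
            bad.append("birth_rate")
        for reg, ln in self.region_lengths.items():
            if ln <= 0:
                bad.append(f"region_lengths[{reg.value}]")
        for name in (
            "chimera_fraction",
            "longbranch_fraction",
            "p_two_lineages_per_cell",
            "p_hyperparasite",
            "p_seq_success",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        if self.longbranch_rate_multiplier <= 1:
            bad.append("longbranch_rate_multiplier (need > 1)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            bad.append("base_freqs (must sum to 1)")
        if self.subst_model not in ("JC", "GTR"):
            bad.append("subst_model")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            bad.append("gamma_shape")
        if bad:
            raise ValueError(f"invalid SimParams field(s): {', '.join(bad)}")

    @property
    def total_length(self) -> int:
        return sum(self.region_lengths.values())

    def region_spans(self) -> dict[Region, tuple[int, int]]:
        spans = {}
        pos = 0
        for reg in REGION_ORDER:
            ln = self.region_lengths[reg]
            spans[reg] = (pos, pos + ln)
            pos += ln
        return spans

    def region_annotations(self) -> list[RegionAnnotation]:
        return [
            RegionAnnotation(reg, s, e) for reg, (s, e) in self.region_spans().items()
        ]


@dataclass
class SimTruth:
    """Ground-truth ledger for one generator run."""

    true_tree: dendropy.Tree | None = None
    chimera_parents: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    longbranch_ids: set[str] = field(default_factory=set)
    clean_parent: dict[str, str] = field(default_factory=dict)
    cell_lineage_map: dict[str, set[str]] = field(default_factory=dict)
    record_lineage: dict[str, str] = field(default_factory=dict)
    lineage_source_leaf: dict[str, str] = field(default_factory=dict)
    hyperparasite_ids: set[str] = field(default_factory=set)
    hyperparasite_lineages: set[str] = field(default_factory=set)
    offtarget_ids: set[str] = field(default_factory=set)
    offtarget_clade: str = ""
    failed_cells: set[str] = field(default_factory=set)
    site_rates: np.ndarray | None = None
    seed: int = 0

    def query_category(self, query_id: str) -> str:
        cats = []
        if query_id in self.chimera_parents:
            cats.append("chimera")
        if query_id in self.longbranch_ids:
            cats.append("longbranch")
        if query_id in self.clean_parent:
            cats.append("clean")
        if len(cats) != 1:
            raise ValueError(f"{query_id}: truth categories {cats}")
        return cats[0]

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chimera_parents": {
                k: list(v) for k, v in sorted(self.chimera_parents.items())
            },
            "longbranch_ids": sorted(self.longbranch_ids),
            "clean_parent": dict(sorted(self.clean_parent.items())),
            "cell_lineage_map": {
                k: sorted(v) for k, v in sorted(self.cell_lineage_map.items())
            },
            "record_lineage": dict(sorted(self.record_lineage.items())),
            "hyperparasite_ids": sorted(self.hyperparasite_ids),
            "offtarget_ids": sorted(self.offtarget_ids),
            "offtarget_clade": self.offtarget_clade,
            "failed_cells": sorted(self.failed_cells),
        }


# ---------------------------------------------------------------------------
# substitution machinery
# ---------------------------------------------------------------------------


def _rate_matrix(params: SimParams) -> np.ndarray:
    pi = np.asarray(params.base_freqs, dtype=float)
    if params.subst_model == "JC":
        R = np.ones((4, 4))
        pi = np.full(4, 0.25)
    else:  # GTR with transition-weighted exchangeabilities
        ex = {"AC": 1.0, "AG": 4.0, "AT": 1.0, "CG": 1.0, "CT": 4.0, "GT": 1.0}
        R = np.zeros((4, 4))
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pair, v in ex.items():
            i, j = idx[pair[0]], idx[pair[1]]
            R[i, j] = R[j, i] = v
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    return Q / mean_rate


class _Evolver:
    """Samples sequence evolution along branches under Q with site rates."""

    def __init__(self, params: SimParams) -> None:
        Q = _rate_matrix(params)
        w, U = np.linalg.eig(Q)
        self._w, self._U, self._Uinv = w, U, np.linalg.inv(U)
        self.pi = (
            np.full(4, 0.25)
            if params.subst_model == "JC"
            else np.asarray(params.base_freqs)
        )

    def transition(self, t: float) -> np.ndarray:
        P = (self._U * np.exp(self._w * t)) @ self._Uinv
        P = np.clip(P.real, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def root_sequence(self, L: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(4, size=L, p=self.pi)

    def evolve(
        self,
        parent: np.ndarray,
        t: float,
        site_rates: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        if t == 0:
            return parent.copy()
        child = parent.copy()
        # sites share a small set of distinct rates (gamma categories)
        for r in np.unique(site_rates):
            P = self.transition(t * r)
            sel = site_rates == r
            for s in range(4):
                idx = np.flatnonzero(sel & (parent == s))
                if idx.size:
                    child[idx] = rng.choice(4, size=idx.size, p=P[s])
        return child


def _site_rates(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-site rates: 4 gamma categories (mean 1) times region rates."""
    L = params.total_length
    if params.gamma_shape is None or math.isinf(params.gamma_shape):
        cat_rates = np.ones(1)
        cats = np.zeros(L, dtype=int)
    else:
        a = params.gamma_shape
        quantiles = (np.arange(4) + 0.5) / 4
        cat_rates = stats.gamma.ppf(quantiles, a, scale=1.0 / a)
        cat_rates = cat_rates / cat_rates.mean()
        cats = rng.integers(0, 4, size=L)
    rates = cat_rates[cats].astype(float)
    region_mult = np.ones(L)
    for reg, (s, e) in params.region_spans().items():
        region_mult[s:e] = params.region_rates.get(reg, 1.0)
    region_mult /= region_mult.mean()
    return rates * region_mult


def decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------


def _yule_tree(params: SimParams) -> dendropy.Tree:
    from dendropy.simulate import treesim

    pyrng = random.Random(params.seed + 1)
    tree = treesim.birth_death_tree(
        birth_rate=params.birth_rate,
        death_rate=0.0,
        num_extant_tips=params.n_ref_taxa,
        rng=pyrng,
    )
    width = len(str(params.n_ref_taxa))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"REF{i + 1:0{width}d}"
    return tree


def _assign_taxonomy(tree: dendropy.Tree) -> list[TaxonomyRow]:
    """Rank paths by clade depth: root children are phyla, then order,
    family, genus; species is the leaf itself. Trophic modes cycle over
    family clades so every guild is represented."""
    clade_id: dict[int, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        clade_id[id(node)] = i
    prefixes = ["phy", "ord", "fam", "gen"]
    rows: list[TaxonomyRow] = []
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        path_nodes = []
        node = leaf.parent_node
        while node is not None and node.parent_node is not None:
            path_nodes.append(node)
            node = node.parent_node
        path_nodes.reverse()  # root-side first, excluding the root itself
        names: list[str] = []
        for depth, prefix in enumerate(prefixes):
            if depth < len(path_nodes):
                names.append(f"{prefix}{clade_id[id(path_nodes[depth])]}")
            elif names:
                names.append(f"{prefix}.{names[-1]}")
            else:
                names.append(f"{prefix}.leaf{clade_id[id(leaf)]}")
        rank_path = tuple(
            zip(("phylum", "order", "family", "genus"), names)
        ) + (("species", leaf.taxon.label),)
        rows.append(TaxonomyRow(leaf_id=leaf.taxon.label, rank_path=rank_path))
    families = sorted({r.name_at("family") for r in rows})
    mode_of = {
        fam: _TROPHIC_CYCLE[i % len(_TROPHIC_CYCLE)] for i, fam in enumerate(families)
    }
    return [
        TaxonomyRow(
            leaf_id=r.leaf_id,
            rank_path=r.rank_path,
            trophic_mode=mode_of[r.name_at("family")],
        )
        for r in rows
    ]


def simulate_reference(
    params: SimParams, tree: dendropy.Tree | None = None
) -> tuple[ReferenceDB, SimTruth]:
    """Simulate a reference database with known tree and true homology.

    The alignment is gap-free (columns are sites), so the trim mask keeps
    every column; taxonomy ranks follow clade depth and trophic modes are
    assigned per family clade. Deterministic for a fixed seed.
    """
    params.validate()
    rng_rates, rng_seq = _rng_children(params.seed, 2)
    if tree is None:
        tree = _yule_tree(params)
    evolver = _Evolver(params)
    site_rates = _site_rates(params, rng_rates)
    L = params.total_length
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = evolver.root_sequence(L, rng_seq)
    alignment: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        seqs[id(node)] = evolver.evolve(seqs[id(node.parent_node)], t, site_rates, rng_seq)
        if node.is_leaf():
            alignment[node.taxon.label] = decode(seqs[id(node)])
    taxonomy = _assign_taxonomy(tree)
    refdb = ReferenceDB(
        alignment=alignment,
        tree=tree,
        taxonomy=taxonomy,
        region_spans=params.region_spans(),
    )
    truth = SimTruth(true_tree=tree, site_rates=site_rates, seed=params.seed)
    return refdb, truth


# ---------------------------------------------------------------------------
# query artifacts
# ---------------------------------------------------------------------------


def make_chimera(
    parent_a: OperonRecord, parent_b: OperonRecord, breakpoint: int
) -> OperonRecord:
    """Join the 5' part of one parent to the 3' part of another.

    Parents must be in the same coordinate system (equal length); this is
    the artifact the split-placement filter is built to catch.
    """
    if len(parent_a.sequence) != len(parent_b.sequence):
        raise ValueError("chimera parents must share a coordinate system")
    L = len(parent_a.sequence)
    if not (0 < breakpoint < L):
        raise ValueError(f"breakpoint {breakpoint} out of range (0, {L})")
    seq = parent_a.sequence[:breakpoint] + parent_b.sequence[breakpoint:]
    return OperonRecord(
        id=f"chim_{parent_a.id}_{parent_b.id}",
        sequence=seq,
        source=Source.OTU,
        regions=list(parent_a.regions),
    )


def make_long_branch(
    parent: OperonRecord,
    rate_multiplier: float,
    seed: int,
    base_divergence: float = 0.02,
    params: SimParams | None = None,
) -> OperonRecord:
    """Re-evolve a parent at an inflated substitution rate.

    The result sits on an artificially long pendant branch
    (``rate_multiplier`` times the clean query divergence), emulating the
    degraded/misassembled OTU consensus sequences the curation step flags.
    """
    if rate_multiplier < 1:
        raise ValueError("rate_multiplier must be >= 1")
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    evolver = _Evolver(params)
    arr = np.frombuffer(parent.sequence.encode(), dtype="S1").astype("U1")
    enc = np.searchsorted(_BASES, arr)
    rates = np.ones(len(parent.sequence))
    child = evolver.evolve(enc, base_divergence * rate_multiplier, rates, rng)
    return OperonRecord(
        id=f"lb_{parent.id}_{seed}",
        sequence=decode(child),
        source=Source.OTU,
        regions=list(parent.regions),
    )


def _with_insertions(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Insert geometric-length runs of random bases at random positions."""
    if rate <= 0:
        return seq
    n_events = rng.binomial(len(seq), rate)
    if n_events == 0:
        return seq
    out = seq
    for _ in range(n_events):
        pos = int(rng.integers(0, len(out) + 1))
        ln = int(rng.geometric(0.5))
        ins = rng.choice(4, size=ln)
        out = np.concatenate([out[:pos], ins, out[pos:]])
    return out


def _leaf_pair_interfamily(
    refdb: ReferenceDB, rng: np.random.Generator, min_edges: int = 6
) -> tuple[str, str]:
    """Two reference leaves in different family clades, well separated."""
    from .placement_core import edge_path_distance

    fam = {t.leaf_id: t.name_at("family") for t in refdb.taxonomy}
    leaves = refdb.leaf_ids
    # small references may not offer the requested separation; relax the
    # edge requirement (never the inter-family one) until a pair exists
    for need in range(min_edges, 1, -1):
        for _ in range(200):
            a, b = rng.choice(len(leaves), size=2, replace=False)
            la, lb = leaves[int(a)], leaves[int(b)]
            if fam[la] != fam[lb] and edge_path_distance(refdb, la, lb) >= need:
                return la, lb
    raise RuntimeError("could not find inter-family leaf pair")


def simulate_queries(
    refdb: ReferenceDB, truth: SimTruth, params: SimParams
) -> tuple[list[OperonRecord], SimTruth]:
    """Generate an 18S OTU-like query set with known ground truth.

    The set mixes clean descendants of reference leaves, two-parent
    chimeras with a (near-)mid-sequence breakpoint joining inter-family
    parents, and long-branch artifacts; the truth ledger partitions the
    ids over the three categories. Short insertions exercise the
    keeplength projection.
    """
    params.validate()
    (rng,) = _rng_children(params.seed + 101, 1)
    evolver = _Evolver(params)
    s18, e18 = refdb.region_spans[Region.SSU18S]
    rates18 = (
        truth.site_rates[s18:e18]
        if truth.site_rates is not None
        else np.ones(e18 - s18)
    )
    leaf_enc = {
        k: np.searchsorted(
            _BASES, np.frombuffer(v.encode(), dtype="S1").astype("U1")
        )[s18:e18]
        for k, v in refdb.alignment.items()
    }
    n = params.n_queries
    n_chim = int(round(n * params.chimera_fraction))
    n_lb = int(round(n * params.longbranch_fraction))
    n_clean = n - n_chim - n_lb
    records: list[OperonRecord] = []
    leaves = refdb.leaf_ids
    L18 = e18 - s18

    def clean_descendant(leaf: str, divergence: float) -> np.ndarray:
        return evolver.evolve(leaf_enc[leaf], divergence, rates18, rng)

    for i in range(n_clean):
        leaf = leaves[int(rng.integers(0, len(leaves)))]
        seq = clean_descendant(leaf, params.query_divergence)
        qid = f"OTU{i + 1:04d}"
        seq = _with_insertions(seq, params.insertion_rate, rng)
        records.append(OperonRecord(id=qid, sequence=decode(seq), source=Source.OTU))
        truth.clean_parent[qid] = leaf
    for i in range(n_chim):
        la, lb = _leaf_pair_interfamily(refdb, rng)
        pa = clean_descendant(la, params.query_divergence)
        pb = clean_descendant(lb, params.query_divergence)
        bp = L18 // 2
        if params.chimera_jitter > 0:
            span = int(L18 * params.chimera_jitter)
            bp += int(rng.integers(-span, span + 1))
        seq = np.concatenate([pa[:bp], pb[bp:]])
        qid = f"OTU{n_clean + i + 1:04d}"
        seq = _with_insertions(seq, params.insertion_rate, rng)
        records.append(OperonRecord(id=qid, sequence=decode(seq), source=Source.OTU))
        truth.chimera_parents[qid] = (la, lb, bp)
    for i in range(n_lb):
        leaf = leaves[int(rng.integers(0, len(leaves)))]
        seq = clean_descendant(
            leaf, params.query_divergence * params.longbranch_rate_multiplier
        )
        qid = f"OTU{n_clean + n_chim + i + 1:04d}"
        seq = _with_insertions(seq, params.insertion_rate, rng)
        records.append(OperonRecord(id=qid, sequence=decode(seq), source=Source.OTU))
        truth.longbranch_ids.add(qid)
    return records, truth


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------


def simulate_cells(
    refdb: ReferenceDB, params: SimParams, truth: SimTruth | None = None
) -> tuple[list[OperonRecord], SimTruth]:
    """Simulate single-cell operon records with host metadata and truth.

    Hidden lineage founders diverge from reference leaves by half the
    inter-lineage divergence; each cell yields records from one lineage or
    (with probability ``p_two_lineages_per_cell``) two. Hyper-parasitic
    lineages descend from a fungus-parasite clade while their metadata says
    epibiotic on an alga — the conflict the ecology flag must catch.
    Off-target cells (non-target phylum, mirroring zygomycete by-catch) and
    sequencing failures are also planted so pipeline accounting can be
    exercised.
    """
    params.validate()
    truth = truth or SimTruth(true_tree=refdb.tree, seed=params.seed)
    (rng,) = _rng_children(params.seed + 202, 1)
    evolver = _Evolver(params)
    L = refdb.width
    rates = truth.site_rates if truth.site_rates is not None else np.ones(L)
    enc = {
        k: np.searchsorted(_BASES, np.frombuffer(v.encode(), dtype="S1").astype("U1"))
        for k, v in refdb.alignment.items()
    }
    tax_by_leaf = {t.leaf_id: t for t in refdb.taxonomy}
    phyla: dict[str, list[str]] = {}
    for t in refdb.taxonomy:
        phyla.setdefault(t.name_at("phylum"), []).append(t.leaf_id)
    # smallest phylum is reserved as the off-target (zygomycete-like) clade
    offtarget_phylum = min(phyla, key=lambda p: (len(phyla[p]), p))
    truth.offtarget_clade = offtarget_phylum
    target_leaves = [l for p, ls in phyla.items() if p != offtarget_phylum for l in ls]
    fungi_parasite_leaves = [
        l
        for l in target_leaves
        if tax_by_leaf[l].trophic_mode == "parasite_of_fungi"
    ]
    other_leaves = [
        l
        for l in target_leaves
        if tax_by_leaf[l].trophic_mode != "parasite_of_fungi"
    ]

    # lineage founders
    founders: dict[str, np.ndarray] = {}
    lineage_leaf: dict[str, str] = {}
    lineage_hyper: dict[str, bool] = {}
    half_inter = params.inter_lineage_divergence / 2.0
    for i in range(params.n_lineages):
        lid = f"TL{i + 1:02d}"
        hyper = bool(rng.random() < params.p_hyperparasite) and fungi_parasite_leaves
        pool = fungi_parasite_leaves if hyper else other_leaves
        leaf = pool[int(rng.integers(0, len(pool)))]
        founders[lid] = evolver.evolve(enc[leaf], half_inter, rates, rng)
        lineage_leaf[lid] = leaf
        lineage_hyper[lid] = bool(hyper)
        truth.lineage_source_leaf[lid] = leaf
    if lineage_hyper:
        truth.hyperparasite_lineages = {l for l, h in lineage_hyper.items() if h}

    offtarget_founders: dict[str, np.ndarray] = {}
    for i in range(params.n_offtarget_cells):
        leaf = phyla[offtarget_phylum][int(rng.integers(0, len(phyla[offtarget_phylum])))]
        offtarget_founders[f"OT{i + 1}"] = evolver.evolve(
            enc[leaf], half_inter, rates, rng
        )

    lineage_ids = sorted(founders)
    width = len(str(params.n_cells))
    records: list[OperonRecord] = []
    half_intra = params.intra_lineage_divergence / 2.0
    annotations = [
        RegionAnnotation(reg, s, e) for reg, (s, e) in refdb.region_spans.items()
    ] if refdb.region_spans else []

    def metadata_for(lid: str) -> dict[str, str]:
        if lineage_hyper[lid]:
            host = _ALGAL_HOSTS[int(rng.integers(0, len(_ALGAL_HOSTS)))]
            return {
                "host_taxon": host,
                "habit": "epibiotic",
                "site": f"site{int(rng.integers(1, 4))}",
                "observed_role": "parasite",
                "host_status": "alive",
            }
        mode = tax_by_leaf[lineage_leaf[lid]].trophic_mode
        hosts = _HOSTS.get(mode, ["unknown"])
        return {
            "host_taxon": hosts[int(rng.integers(0, len(hosts)))],
            "habit": ["epibiotic", "endobiotic"][int(rng.integers(0, 2))],
            "site": f"site{int(rng.integers(1, 4))}",
            "observed_role": "parasite" if mode.startswith("parasite") else "saprotroph",
            "host_status": "alive",
        }

    n_target_cells = params.n_cells - params.n_offtarget_cells
    for c in range(params.n_cells):
        cell_id = f"PSC{c + 1:0{width}d}"
        sequenced = bool(rng.random() < params.p_seq_success)
        if not sequenced:
            truth.failed_cells.add(cell_id)
            truth.cell_lineage_map[cell_id] = set()
            continue
        if c >= n_target_cells:  # off-target cells planted last
            fid = f"OT{c - n_target_cells + 1}"
            seq = evolver.evolve(offtarget_founders[fid], half_intra, rates, rng)
            rid = f"{cell_id}.1"
            records.append(
                OperonRecord(
                    id=rid,
                    sample_id=cell_id,
                    sequence=decode(seq),
                    source=Source.SINGLE_CELL,
                    regions=list(annotations),
                    metadata={
                        "host_taxon": "detritus",
                        "habit": "unknown",
                        "site": "site1",
                        "observed_role": "unknown",
                        "host_status": "alive",
                    },
                )
            )
            truth.offtarget_ids.add(rid)
            truth.cell_lineage_map[cell_id] = set()
            continue
        # every lineage is guaranteed at least one cell, then random reuse
        primary = (
            lineage_ids[c % len(lineage_ids)]
            if c < len(lineage_ids)
            else lineage_ids[int(rng.integers(0, len(lineage_ids)))]
        )
        cell_lineages = [primary]
        if len(lineage_ids) > 1 and rng.random() < params.p_two_lineages_per_cell:
            other = primary
            while other == primary:
                other = lineage_ids[int(rng.integers(0, len(lineage_ids)))]
            cell_lineages.append(other)
        truth.cell_lineage_map[cell_id] = set(cell_lineages)
        for k, lid in enumerate(cell_lineages):
            seq = evolver.evolve(founders[lid], half_intra, rates, rng)
            rid = f"{cell_id}.{k + 1}"
            records.append(
                OperonRecord(
                    id=rid,
                    sample_id=cell_id,
                    sequence=decode(seq),
                    source=Source.SINGLE_CELL,
                    regions=list(annotations),
                    metadata=metadata_for(lid),
                )
            )
            truth.record_lineage[rid] = lid
            if lineage_hyper[lid]:
                truth.hyperparasite_ids.add(rid)
    return records, truth


def params_to_dict(params: SimParams) -> dict:
    d = asdict(params)
    d["region_lengths"] = {k.value: v for k, v in params.region_lengths.items()}
    d["region_rates"] = {k.value: v for k, v in params.region_rates.items()}
    return d
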