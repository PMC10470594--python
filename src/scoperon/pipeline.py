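"""End-to-end orchestration: simulate → place → curate → lineages → concord.

Every run is driven by one config and one seed, writes its artifacts under
a single output directory, and finishes with a manifest (parameters, seed,
per-stage counts) plus a conservation-checked accounting report in the
style of a single-cell study's bookkeeping: cells processed → cells with a
sequence → on-target (fungal) cells → cells retained for phylogeny, with
integer percentages of the processed total.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .seqio import (
    Region,
    Source,
    write_fasta,
    write_metadata,
    write_newick,
    write_taxonomy,
)
from .synthetic_data import (
    SimParams,
    params_to_dict,
    simulate_cells,
    simulate_queries,
    simulate_reference,
)
from .placement_core import write_jplace, write_placements_tsv
from .chimera_curation import CurationParams, curate_set, verdicts_to_frame
from .lineage_analysis import (
    _AlignmentCache,
    assign_taxonomy,
    cluster_lineages,
    concordance,
    detect_multi_lineage_cells,
    exclude_offtarget,
    flag_ecology_conflict,
    lineages_to_frame,
)

log = logging.getLogger("scoperon")

_STAGES = ("processed", "with_sequence", "fungal", "retained")


@dataclass(frozen=True)
class AccountingReport:
    """Stage tallies with integer percentages of the processed total."""

    n_processed_cells: int
    n_with_sequence: int
    n_fungal: int
    n_retained_for_phylogeny: int
    pct_with_sequence: int
    pct_fungal: int
    pct_retained: int

    def to_json_dict(self) -> dict:
        return dict(self.__dict__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def accounting(counts: tuple[int, int, int, int]) -> AccountingReport:
    """Bookkeeping report from the four stage tallies.

    Percentages are of the processed total, rounded half-up to integers
    (e.g. 139 of 259 cells with sequence prints as 54%). Counts must be
    non-negative and non-increasing through the stages.
    """
    if len(counts) != 4:
        raise ValueError("expected (processed, with_sequence, fungal, retained)")
    if any(c < 0 for c in counts):
        raise ValueError("stage counts must be non-negative")
    for i in range(3):
        if counts[i + 1] > counts[i]:
            raise ValueError(
                f"stage counts must be non-increasing: "
                f"{_STAGES[i + 1]} ({counts[i + 1]}) > {_STAGES[i]} ({counts[i]})"
            )
    total = counts[0]
    pct = [
        _round_half_up(100.0 * c / total) if total else 0 for c in counts[1:]
    ]
    return AccountingReport(
        n_processed_cells=counts[0],
        n_with_sequence=counts[1],
        n_fungal=counts[2],
        n_retained_for_phylogeny=counts[3],
        pct_with_sequence=pct[0],
        pct_fungal=pct[1],
        pct_retained=pct[2],
    )


@dataclass
class PipelineConfig:
    out_dir: Path = Path("scoperon_run")
    sim: SimParams = field(default_factory=SimParams)
    curation: CurationParams = field(default_factory=CurationParams)
    identity_threshold: float = 0.99
    species_threshold: float = 0.995
    skip_curate: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.sim.seed = self.seed


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts, and return the manifest.

    Deterministic for a fixed config: two runs produce byte-identical
    tabular outputs. On stage failure the manifest written so far is kept
    with a ``.partial`` suffix and the exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    params_doc = params_to_dict(config.sim)
    params_hash = hashlib.sha256(
        json.dumps(params_doc, sort_keys=True).encode()
    ).hexdigest()[:12]
    manifest: dict = {
        "tool": "scoperon",
        "version": __version__,
        "seed": config.seed,
        "params": params_doc,
        "params_hash": params_hash,
        "stages": {},
    }
    t0 = time.time()
    stage = "simulate"
    try:
        log.info("stage=simulate seed=%d", config.seed)
        refdb, truth = simulate_reference(config.sim)
        queries, truth = simulate_queries(refdb, truth, config.sim)
        cells, truth = simulate_cells(refdb, config.sim, truth)
        write_fasta(
            [_as_record(k, v) for k, v in sorted(refdb.alignment.items())],
            out / "reference.fasta",
        )
        write_newick(refdb.tree, out / "reference.nwk")
        write_taxonomy(refdb.taxonomy, out / "taxonomy.tsv")
        write_fasta(queries, out / "queries.fasta")
        write_fasta(cells, out / "cells.fasta")
        write_metadata({r.id: r.metadata for r in cells}, out / "metadata.tsv")
        (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
        manifest["stages"]["simulate"] = {
            "n_ref_taxa": len(refdb.leaf_ids),
            "n_queries": len(queries),
            "n_cell_records": len(cells),
            "n_cells": config.sim.n_cells,
        }

        stage = "place"
        cache = _AlignmentCache(refdb)
        placements = [cache.place(r) for r in cells]
        write_placements_tsv(placements, out / "cell_placements.tsv")
        write_jplace(placements, refdb, out / "cell_placements.jplace")
        manifest["stages"]["place"] = {"n_placed": len(placements)}

        stage = "curate"
        refdb18 = refdb.restrict_to_regions([Region.SSU18S])
        if config.skip_curate:
            kept_otus = queries
            manifest["stages"]["curate"] = "skipped"
        else:
            kept_otus, report = curate_set(queries, refdb18, config.curation)
            write_fasta(kept_otus, out / "kept.fasta")
            verdicts_to_frame(report).to_csv(
                out / "verdicts.tsv", sep="\t", index=False
            )
            report_doc = report.to_json_dict(config.curation)
            report_doc["seed"] = config.seed
            report_doc["tool_version"] = __version__
            (out / "curation_report.json").write_text(json.dumps(report_doc, indent=1))
            manifest["stages"]["curate"] = report.to_json_dict()

        stage = "lineages"
        on_target, offtarget = exclude_offtarget(
            cells, refdb, [truth.offtarget_clade] if truth.offtarget_clade else [], cache
        )
        lineages = cluster_lineages(
            on_target, refdb, config.identity_threshold, cache=cache
        )
        meta_by_record = {r.id: r.metadata for r in cells}
        for lin in lineages:
            assign_taxonomy(lin, refdb)
            flag_ecology_conflict(lin, meta_by_record, refdb)
        lineages_to_frame(lineages).to_csv(out / "lineages.tsv", sep="\t", index=False)
        multi = detect_multi_lineage_cells(lineages)
        with open(out / "multi_lineage_cells.tsv", "w") as fh:
            fh.write("cell_id\tlineage_ids\n")
            for cell in sorted(multi):
                fh.write(f"{cell}\t{','.join(sorted(multi[cell]))}\n")
        cells_with_seq = {r.sample_id for r in cells}
        fungal_cells = {r.sample_id for r in on_target}
        retained_cells = {
            c for lin in lineages for c in lin.member_cell_ids
        }
        acct = accounting(
            (
                config.sim.n_cells,
                len(cells_with_seq),
                len(fungal_cells),
                len(retained_cells),
            )
        )
        manifest["stages"]["lineages"] = {
            "n_lineages": len(lineages),
            "n_multi_lineage_cells": len(multi),
            "n_offtarget_records": len(offtarget),
            "n_hyperparasite_lineages": sum(
                1 for l in lineages if "putative_hyperparasite" in l.ecology_flags
            ),
            "accounting": acct.to_json_dict(),
        }

        stage = "concord"
        rows = concordance(
            lineages, kept_otus, refdb, config.species_threshold, cache=cache
        )
        with open(out / "concordance.tsv", "w") as fh:
            fh.write("lineage_id\tnearest_otu_id\tidentity\tmatch_level\n")
            for row in rows:
                fh.write(
                    f"{row.lineage_id}\t{row.nearest_otu_id or ''}\t"
                    f"{row.identity:.4f}\t{row.match_level}\n"
                )
        levels: dict[str, int] = {}
        for row in rows:
            levels[row.match_level] = levels.get(row.match_level, 0) + 1
        manifest["stages"]["concord"] = {"match_levels": levels}
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json.partial").write_text(json.dumps(manifest, indent=1))
        log.error("stage=%s failed", stage)
        raise
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete in %.1fs", manifest["runtime_s"])
    return manifest


def _as_record(name: str, seq: str):
    from .seqio import OperonRecord

    return OperonRecord(id=name, sequence=seq, source=Source.REFERENCE)
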