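"""Readers and writers for the formats the pipeline touches.

Sequences are rDNA operons (18S-ITS1-5.8S-ITS2-28S) or fragments thereof,
carried as :class:`OperonRecord`. Coordinates are 0-based, half-open
everywhere. RNA input (U) is normalised to T; raw query sequences are
de-gapped on read (gaps are only meaningful inside a reference alignment).
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

_RANKS = ("phylum", "order", "family", "genus", "species")

TROPHIC_MODES = frozenset(
    {
        "saprotroph",
        "parasite_of_algae",
        "parasite_of_fungi",
        "parasite_of_animals",
        "parasite_of_protists",
        "unknown",
    }
)

HABITS = frozenset({"epibiotic", "endobiotic", "unknown"})


class Source(str, enum.Enum):
    """Provenance of a sequence record."""

    SINGLE_CELL = "single_cell"
    OTU = "otu"
    REFERENCE = "reference"


class Region(str, enum.Enum):
    """Named regions of the rDNA operon, 5' to 3'."""

    SSU18S = "SSU18S"
    ITS1 = "ITS1"
    R5_8S = "R5_8S"
    ITS2 = "ITS2"
    LSU28S = "LSU28S"


REGION_ORDER = (Region.SSU18S, Region.ITS1, Region.R5_8S, Region.ITS2, Region.LSU28S)


@dataclass(frozen=True)
class RegionAnnotation:
    """A half-open [start, end) interval naming one operon region."""

    name: Region
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region interval {self.name}: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OperonRecord:
    """One rDNA operon (or fragment) with region annotations and metadata.

    ``sample_id`` names the physical sample (cell or OTU); several records may
    share it, e.g. a cell yielding two independent parasite sequences.
    """

    id: str
    sequence: str
    source: Source = Source.SINGLE_CELL
    sample_id: str = ""
    regions: list[RegionAnnotation] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            self.sample_id = self.id
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - IUPAC_CHARS
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"record {self.id}: non-IUPAC character {self.sequence[pos]!r} "
                f"at position {pos}"
            )
        prev_end = -1
        prev_start = -1
        for ann in self.regions:
            if ann.start < prev_start:
                raise ValueError(f"record {self.id}: regions not sorted by start")
            if ann.start < prev_end:
                raise ValueError(f"record {self.id}: overlapping regions")
            if ann.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id}: region {ann.name} end {ann.end} exceeds "
                    f"sequence length {len(self.sequence)}"
                )
            prev_start, prev_end = ann.start, ann.end

    def region(self, name: Region) -> RegionAnnotation | None:
        for ann in self.regions:
            if ann.name == name:
                return ann
        return None


@dataclass(frozen=True)
class TaxonomyRow:
    """Taxonomic rank path and trophic annotation for one reference leaf."""

    leaf_id: str
    rank_path: tuple[tuple[str, str], ...]  # ((rank, name), ...) phylum -> species
    trophic_mode: str = "unknown"

    def __post_init__(self) -> None:
        if not self.rank_path:
            raise ValueError(f"{self.leaf_id}: empty rank path")
        ranks = [r for r, _ in self.rank_path]
        order = [r for r in _RANKS if r in ranks]
        if ranks != order:
            raise ValueError(
                f"{self.leaf_id}: ranks {ranks} not strictly ordered phylum→species"
            )

    def name_at(self, rank: str) -> str | None:
        for r, n in self.rank_path:
            if r == rank:
                return n
        return None


def _normalise(seq: str, rec_id: str, source: Source) -> str:
    seq = seq.upper().replace("U", "T")
    if "-" in seq and source is not Source.REFERENCE:
        warnings.warn(
            f"record {rec_id}: stripping {seq.count('-')} gap characters from "
            f"raw {source.value} sequence",
            stacklevel=3,
        )
        seq = seq.replace("-", "")
    return seq


def read_fasta(path: str | Path, source: Source = Source.SINGLE_CELL) -> list[OperonRecord]:
    """Read a FASTA file into :class:`OperonRecord` objects.

    The header token before the first whitespace is the record id. Sequences
    are uppercased and U→T normalised; gaps are kept only for
    ``Source.REFERENCE`` input.
    """
    path = Path(path)
    records: list[OperonRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _normalise(str(entry.seq), entry.id, source)
        records.append(OperonRecord(id=entry.id, sequence=seq, source=source))
    if not records:
        warnings.warn(f"{path}: no FASTA entries found", stacklevel=2)
    return records


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a single Newick tree.

    Missing branch lengths default to 0.0. Unbalanced parentheses are
    reported with a character offset; duplicate leaf labels are an error.
    """
    if isinstance(path_or_string, Path) or (
        "(" not in str(path_or_string) and Path(str(path_or_string)).exists()
    ):
        text = Path(path_or_string).read_text()
    else:
        text = str(path_or_string)
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses: {depth} '(' left open at end of input "
            f"(offset {len(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


_META_REQUIRED = ("sample_id", "host_taxon", "habit")
_TAXO_REQUIRED = ("leaf_id", "trophic_mode")


def read_annotations(path: str | Path) -> tuple[dict[str, dict[str, str]], list[TaxonomyRow]]:
    """Read a tab-separated annotation table (header-keyed, any column order).

    Two dialects are recognised by their headers: per-sample metadata
    (``sample_id``, ``host_taxon``, ``habit``, optionally ``site``,
    ``observed_role``, ``host_status``) and reference taxonomy (``leaf_id``,
    rank columns, ``trophic_mode``). Returns ``(metadata_map, taxonomy_rows)``;
    the dialect not present in the file yields an empty container. Unknown
    enum values are mapped to ``"unknown"`` with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty and not df.columns.size:
        return {}, []
    cols = set(df.columns)
    metadata: dict[str, dict[str, str]] = {}
    taxonomy: list[TaxonomyRow] = []
    if "leaf_id" in cols:
        missing = [c for c in _TAXO_REQUIRED if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        rank_cols = [r for r in _RANKS if r in cols]
        if not rank_cols:
            raise ValueError(f"{path}: missing required column(s): one of {_RANKS}")
        for _, row in df.iterrows():
            mode = row["trophic_mode"]
            if mode not in TROPHIC_MODES:
                warnings.warn(
                    f"{path}: unknown trophic_mode {mode!r} for {row['leaf_id']}"
                    " mapped to 'unknown'",
                    stacklevel=2,
                )
                mode = "unknown"
            rank_path = tuple((r, row[r]) for r in rank_cols if row[r])
            taxonomy.append(
                TaxonomyRow(leaf_id=row["leaf_id"], rank_path=rank_path, trophic_mode=mode)
            )
    elif "sample_id" in cols:
        missing = [c for c in _META_REQUIRED if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for _, row in df.iterrows():
            meta = {c: row[c] for c in df.columns if c != "sample_id"}
            if meta.get("habit", "unknown") not in HABITS:
                warnings.warn(
                    f"{path}: unknown habit {meta['habit']!r} for "
                    f"{row['sample_id']} mapped to 'unknown'",
                    stacklevel=2,
                )
                meta["habit"] = "unknown"
            metadata[row["sample_id"]] = meta
    elif len(df) == 0:
        return {}, []
    else:
        raise ValueError(
            f"{path}: missing required column 'sample_id' (metadata) or 'leaf_id' (taxonomy)"
        )
    return metadata, taxonomy


def write_taxonomy(taxonomy: list[TaxonomyRow], path: str | Path) -> None:
    rows = []
    for t in taxonomy:
        row = {"leaf_id": t.leaf_id, **{r: n for r, n in t.rank_path}}
        row["trophic_mode"] = t.trophic_mode
        rows.append(row)
    cols = ["leaf_id", *(r for r in _RANKS), "trophic_mode"]
    pd.DataFrame(rows).reindex(columns=cols).fillna("").to_csv(path, sep="\t", index=False)


def write_metadata(metadata: dict[str, dict[str, str]], path: str | Path) -> None:
    rows = [{"sample_id": k, **v} for k, v in metadata.items()]
    df = pd.DataFrame(rows)
    if "sample_id" not in df.columns:
        df = pd.DataFrame(columns=["sample_id", "host_taxon", "habit"])
    df.fillna("").to_csv(path, sep="\t", index=False)
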