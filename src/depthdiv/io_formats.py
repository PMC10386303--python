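"""Readers and writers for the tables the pipeline consumes and produces.

The classification dialect is the one printed by Kaiju: one row per read,
tab-separated, with a single-character status flag (``C``/``U``), the read
identifier and the NCBI taxon id; when ``kaiju-addTaxonNames`` has been run a
fourth column carries the semicolon-delimited named lineage (superkingdom,
phylum, class, order, family, genus, species). Only those columns are
interpreted; anything beyond them (e.g. score columns) is ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical clade levels, outermost first.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Closed vocabulary of depth layers: surface, deep chlorophyll maximum, mesopelagic.
LAYERS = ("SRF", "DCM", "MES")

#: Reserved token for a missing value in every TSV this package writes.
NA_TOKEN = "NA"

_GO_PATTERN = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """A malformed row or value in an input table."""


@dataclass(frozen=True)
class ClassifiedRead:
    """One row of a Kaiju-style classification table."""

    classified: bool
    read_id: str
    taxon_id: int
    # lineage[i] corresponds to RANKS[i]; None where the rank is unresolved
    lineage: tuple[str | None, ...] = ()

    def name_at(self, rank: str) -> str | None:
        """Taxon name at ``rank``, or None if absent/unresolved."""
        idx = RANKS.index(rank)
        if idx >= len(self.lineage):
            return None
        return self.lineage[idx]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    station: str
    layer: str
    ocean: str


@dataclass
class TaxonomicProfile:
    """Read counts per taxon for one sample at a fixed aggregation rank.

    ``unassigned_at_rank`` counts classified reads whose lineage does not
    resolve the rank (reads attributed to higher taxonomic nodes).
    """

    sample_id: str
    rank: str
    counts: dict[str, int] = field(default_factory=dict)
    unassigned_at_rank: int = 0

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values()) + self.unassigned_at_rank


@dataclass(frozen=True)
class GOAnnotation:
    read_id: str
    term_id: str


def _parse_lineage(names_field: str) -> tuple[str | None, ...]:
    # Kaiju prints "Bacteria; Bacillota; ...; Staphylococcus aureus;" with a
    # trailing semicolon; strip whitespace, drop the trailing empty field.
    parts = [p.strip() for p in names_field.split(";")]
    if parts and parts[-1] == "":
        parts.pop()
    lineage = tuple(None if p in ("", NA_TOKEN) else p for p in parts)
    if len(lineage) > len(RANKS):
        lineage = lineage[: len(RANKS)]
    return lineage


def read_kaiju_table(path: str | Path) -> list[ClassifiedRead]:
    """Parse a Kaiju(-addTaxonNames) classification TSV.

    Accepts both the bare 3-column output (status, read id, taxon id) and the
    >=4-column output with the named-lineage column. Row order is preserved.

    Raises
    ------
    FormatError
        On a row with fewer than 3 columns, an unknown status flag, or a
        non-integer taxon id; the message names the 1-based line number.
    """
    path = Path(path)
    reads: list[ClassifiedRead] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            status, read_id, taxid_s = fields[0], fields[1], fields[2]
            if status not in ("C", "U"):
                raise FormatError(f"{path}:{lineno}: unknown status flag {status!r}")
            try:
                taxon_id = int(taxid_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer taxon id {taxid_s!r}"
                ) from None
            if taxon_id < 0:
                raise FormatError(f"{path}:{lineno}: negative taxon id {taxon_id}")
            classified = status == "C"
            if classified and taxon_id == 0:
                # defensive: flagged classified but with the null taxon
                logger.warning(
                    "%s:%d: read %s flagged classified with taxon id 0; treating as unclassified",
                    path, lineno, read_id,
                )
                classified = False
            lineage: tuple[str | None, ...] = ()
            if classified and len(fields) >= 4:
                lineage = _parse_lineage(fields[3])
            reads.append(ClassifiedRead(classified, read_id, taxon_id, lineage))
    if not reads:
        logger.warning("%s: classification table contains no data rows", path)
    return reads


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (columns sample_id, station, layer, ocean)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "station", "layer", "ocean"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    records: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        if row["layer"] not in LAYERS:
            raise FormatError(
                f"{path}: row {i + 2}: unknown layer {row['layer']!r} "
                f"(expected one of {LAYERS})"
            )
        if row["sample_id"] in seen:
            raise FormatError(f"{path}: duplicate sample_id {row['sample_id']!r}")
        seen.add(row["sample_id"])
        records.append(
            SampleMetadata(row["sample_id"], row["station"], row["layer"], row["ocean"])
        )
    return records


def aggregate_profile(
    reads: Iterable[ClassifiedRead], rank: str, sample_id: str = ""
) -> TaxonomicProfile:
    """Tally classified reads by taxon name at ``rank``.

    Unclassified reads are excluded entirely; classified reads whose lineage
    does not resolve ``rank`` are counted in ``unassigned_at_rank``, so that
    counts + unassigned always conserve the classified-read total.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    counts: dict[str, int] = {}
    unassigned = 0
    for read in reads:
        if not read.classified:
            continue
        name = read.name_at(rank)
        if name is None:
            unassigned += 1
        else:
            counts[name] = counts.get(name, 0) + 1
    return TaxonomicProfile(sample_id=sample_id, rank=rank, counts=counts,
                            unassigned_at_rank=unassigned)


def read_go_annotations(path: str | Path) -> list[GOAnnotation]:
    """Read a two-column read_id -> GO term TSV; a read may recur."""
    path = Path(path)
    annotations: list[GOAnnotation] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            read_id, term_id = fields[0], fields[1]
            if not _GO_PATTERN.match(term_id):
                raise FormatError(
                    f"{path}:{lineno}: malformed GO identifier {term_id!r}"
                )
            annotations.append(GOAnnotation(read_id, term_id))
    return annotations


def write_table(
    rows: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
    allow_empty: bool = False,
) -> None:
    """Write any tabular product as a UTF-8 TSV with a trailing newline.

    Floats are rendered with 6 significant digits; missing values as ``NA``.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path} (allow_empty=False)")
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
              float_format="%.6g", encoding="utf-8")


def write_classification_table(reads: Iterable[ClassifiedRead], path: str | Path) -> None:
    """Emit reads back in the Kaiju dialect (inverse of read_kaiju_table)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for read in reads:
            if read.classified:
                names = "; ".join(NA_TOKEN if n is None else n for n in read.lineage)
                fh.write(f"C\t{read.read_id}\t{read.taxon_id}\t{names};\n")
            else:
                fh.write(f"U\t{read.read_id}\t0\n")
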