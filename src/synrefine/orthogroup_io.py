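"""Reader for hierarchical-orthogroup tables and the gene↔HOG join.

The refinement consumes an initial homology clustering in the hierarchical
orthogroup (HOG) table dialect: tab-delimited, three fixed leading columns
(HOG, OG, Gene Tree Parent Clade) followed by one column per genome whose
cells hold ", "-separated protein accessions.  The older orthogroup-table
shape (a single fixed leading column) is accepted via ``n_fixed_columns=1``.

Genome columns are matched to manifest entries positionally — the manifest
is the user's statement of column order — with an optional explicit mapping
to guard against misordered manifests.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import TextIO

from .annotation_io import Gene, GenomeAnnotation, Manifest

__all__ = [
    "HogTable",
    "AnnotatedDataset",
    "HogTableError",
    "parse_hog_table",
    "link_genes",
]

logger = logging.getLogger(__name__)


class HogTableError(ValueError):
    """Raised for malformed orthogroup tables."""


@dataclass
class HogTable:
    """Mapping hog_id → per-genome member identifier lists.

    ``genome_order`` mirrors the table's genome columns (equal to the
    manifest order after the positional join).  ``fixed_columns`` keeps the
    leading non-genome cells per row so output tables can echo them.
    """

    hogs: dict[str, dict[str, list[str]]]
    genome_order: list[str]
    fixed_columns: dict[str, list[str]] = field(default_factory=dict)
    fixed_header: list[str] = field(
        default_factory=lambda: ["HOG", "OG", "Gene Tree Parent Clade"]
    )

    def member_counts(self, hog_id: str) -> dict[str, int]:
        return {g: len(m) for g, m in self.hogs[hog_id].items()}


@dataclass
class AnnotatedDataset:
    """Parsed annotations joined to the orthogroup table.

    ``hog_of`` / ``members_of`` are mutually consistent inverses over the
    resolved genes; identifiers that matched no annotated gene are listed in
    ``unmatched`` and take no part in the analysis.
    """

    annotations: dict[str, GenomeAnnotation]
    table: HogTable
    hog_of: dict[Gene, str]
    members_of: dict[str, list[Gene]]
    unmatched: list[tuple[str, str]]
    #: genomes in manifest order; fixes iteration and SOG tie-break order
    genome_order: list[str]
    #: hog_id → set of genomes contributing ≥1 resolved gene (window filter)
    genomes_with_hog: dict[str, set[str]] = field(default_factory=dict)

    def hog_in_genome(self, hog_id: str, genome_id: str) -> bool:
        return genome_id in self.genomes_with_hog.get(hog_id, ())

    def genome_rank(self, genome_id: str) -> int:
        return self.genome_order.index(genome_id)


def _split_cell(cell: str) -> list[str]:
    return [tok for tok in (t.strip() for t in cell.split(",")) if tok]


def parse_hog_table(
    stream: TextIO | str,
    manifest: Manifest,
    n_fixed_columns: int = 3,
) -> HogTable:
    """Parse a hierarchical-orthogroup table against a manifest.

    Genome columns are paired with manifest entries positionally; the column
    count must therefore equal ``n_fixed_columns + len(manifest.entries)``.

    Raises
    ------
    HogTableError
        On a column-count mismatch, a duplicated hog_id, or an identifier
        appearing in more than one HOG.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise HogTableError("orthogroup table is empty") from None
    expected = n_fixed_columns + len(manifest.entries)
    if len(header) != expected:
        raise HogTableError(
            f"orthogroup table has {len(header)} columns but manifest lists "
            f"{len(manifest.entries)} genomes (expected {expected} = "
            f"{n_fixed_columns} fixed + genomes); check manifest order/contents"
        )
    genome_ids = manifest.genome_ids
    hogs: dict[str, dict[str, list[str]]] = {}
    fixed_columns: dict[str, list[str]] = {}
    claimed: dict[str, str] = {}  # identifier → hog, cross-HOG uniqueness
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != expected:
            raise HogTableError(f"row {lineno}: expected {expected} columns, got {len(row)}")
        hog_id = row[0].strip()
        if hog_id in hogs:
            raise HogTableError(f"duplicate hog_id {hog_id!r} (row {lineno})")
        members = {
            genome_ids[i]: _split_cell(row[n_fixed_columns + i])
            for i in range(len(genome_ids))
        }
        for genome_id, idents in members.items():
            for ident in idents:
                prev = claimed.setdefault(ident, hog_id)
                if prev != hog_id:
                    raise HogTableError(
                        f"identifier {ident!r} ({genome_id}) appears in both "
                        f"{prev} and {hog_id}"
                    )
        hogs[hog_id] = members
        fixed_columns[hog_id] = [c.strip() for c in row[:n_fixed_columns]]
    return HogTable(
        hogs=hogs,
        genome_order=list(genome_ids),
        fixed_columns=fixed_columns,
        fixed_header=list(header[:n_fixed_columns]),
    )


def link_genes(
    table: HogTable, annotations: dict[str, GenomeAnnotation]
) -> AnnotatedDataset:
    """Resolve table identifiers to annotated genes.

    Identifiers are matched by product accession first, then locus_tag.  An
    accession recorded at several loci (identical-protein records) labels
    *every* such locus with the HOG — the synteny test discriminates among
    them downstream.  Unresolved identifiers are collected and excluded; a
    genome with >10% unresolved identifiers triggers a loud warning since it
    usually indicates a manifest/column misorder.
    """
    by_accession: dict[str, dict[str, list[Gene]]] = {}
    by_locus: dict[str, dict[str, Gene]] = {}
    for genome_id, ann in annotations.items():
        acc_index: dict[str, list[Gene]] = {}
        locus_index: dict[str, Gene] = {}
        for gene in ann.genes():
            if gene.product_accession:
                acc_index.setdefault(gene.product_accession, []).append(gene)
            locus_index[gene.locus_tag] = gene
        by_accession[genome_id] = acc_index
        by_locus[genome_id] = locus_index

    hog_of: dict[Gene, str] = {}
    members_of: dict[str, list[Gene]] = {}
    unmatched: list[tuple[str, str]] = []
    totals: dict[str, int] = {g: 0 for g in table.genome_order}
    misses: dict[str, int] = {g: 0 for g in table.genome_order}

    for hog_id, per_genome in table.hogs.items():
        resolved: list[Gene] = []
        for genome_id in table.genome_order:
            for ident in per_genome.get(genome_id, []):
                totals[genome_id] += 1
                hits = by_accession.get(genome_id, {}).get(ident)
                if not hits:
                    locus_hit = by_locus.get(genome_id, {}).get(ident)
                    hits = [locus_hit] if locus_hit is not None else []
                if not hits:
                    misses[genome_id] += 1
                    unmatched.append((genome_id, ident))
                    continue
                for gene in hits:
                    if gene in hog_of:
                        continue  # same accession listed twice in one cell
                    hog_of[gene] = hog_id
                    resolved.append(gene)
        members_of[hog_id] = resolved

    for genome_id in table.genome_order:
        if totals[genome_id] and misses[genome_id] / totals[genome_id] > 0.10:
            logger.warning(
                "genome %s: %d/%d orthogroup identifiers matched no annotated "
                "gene — manifest order and table columns may disagree",
                genome_id,
                misses[genome_id],
                totals[genome_id],
            )
        elif misses[genome_id]:
            logger.info(
                "genome %s: %d unresolved orthogroup identifier(s)",
                genome_id,
                misses[genome_id],
            )

    genomes_with_hog = {
        hog_id: {g.genome_id for g in genes} for hog_id, genes in members_of.items()
    }
    return AnnotatedDataset(
        annotations=annotations,
        table=table,
        hog_of=hog_of,
        members_of=members_of,
        unmatched=unmatched,
        genome_order=list(table.genome_order),
        genomes_with_hog=genomes_with_hog,
    )
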