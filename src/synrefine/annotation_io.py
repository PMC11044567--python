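"""Readers for NCBI RefSeq feature tables and the run manifest.

The synteny test operates on gene *order*, so the only annotation substrate
we keep is the ordered list of protein-coding loci per replicon.  RNA genes
and pseudogenes without a product are invisible to the window: the homology
input is a proteome clustering, and a locus that can never carry a homology
label would only dilute the window.

Coordinates stay 1-based inclusive as in the feature-table dialect; ordinals
are 0-based ranks along each replicon.  Circular replicons are treated as
linear — windows truncate at replicon boundaries and never wrap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "Manifest",
    "ManifestError",
    "FeatureTableError",
    "parse_manifest",
    "parse_feature_table",
    "write_feature_table",
]

#: columns a feature table must provide (after stripping the leading "# ").
REQUIRED_COLUMNS = (
    "feature",
    "genomic_accession",
    "start",
    "end",
    "strand",
    "product_accession",
    "locus_tag",
)


class ManifestError(ValueError):
    """Raised for malformed or inconsistent run manifests."""


class FeatureTableError(ValueError):
    """Raised for malformed feature tables."""


@dataclass(frozen=True, slots=True)
class Gene:
    """One protein-coding locus placed on a replicon.

    ``ordinal`` is the 0-based rank of the gene along its replicon when all
    protein-coding loci are sorted by start coordinate; it is the coordinate
    system the look-around window walks in.
    """

    genome_id: str
    replicon_id: str
    ordinal: int
    locus_tag: str
    product_accession: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """(genome_id, locus_tag) — unique within a dataset."""
        return (self.genome_id, self.locus_tag)

    def __repr__(self) -> str:  # compact; genes appear in bulk in diagnostics
        return f"Gene({self.genome_id}:{self.locus_tag}@{self.replicon_id}[{self.ordinal}])"


@dataclass
class GenomeAnnotation:
    """Ordered per-replicon gene lists for one genome."""

    genome_id: str
    replicons: dict[str, list[Gene]] = field(default_factory=dict)

    def genes(self) -> Iterable[Gene]:
        for replicon in self.replicons.values():
            yield from replicon

    @property
    def n_genes(self) -> int:
        return sum(len(r) for r in self.replicons.values())


@dataclass
class Manifest:
    """Ordered genome list pairing feature tables with orthogroup-table columns.

    The order of entries must match the genome column order of the
    orthogroup table; the positional join happens downstream.
    """

    entries: list[tuple[str, str]]

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.entries]


def parse_manifest(stream: TextIO | str) -> Manifest:
    """Parse the run manifest: one genome per line, ``#`` comments allowed.

    Each non-blank line holds a genome identifier optionally followed by
    whitespace and the path of its feature table; when the path is omitted
    the identifier itself is used (e.g. an accession that doubles as a file
    stem).

    Raises
    ------
    ManifestError
        On an empty manifest or a duplicated genome identifier.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        genome_id = parts[0]
        path = parts[1].strip() if len(parts) > 1 else genome_id
        if genome_id in seen:
            raise ManifestError(
                f"duplicate genome identifier {genome_id!r} (line {lineno})"
            )
        seen.add(genome_id)
        entries.append((genome_id, path))
    if not entries:
        raise ManifestError("manifest contains no genome entries")
    return Manifest(entries=entries)


def _read_table(stream: TextIO | str) -> pd.DataFrame:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    # NCBI prefixes the header with "# "; normalise the first column name.
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(
            f"feature table missing required column(s): {', '.join(missing)}"
        )
    return df


def parse_feature_table(stream: TextIO | str, genome_id: str) -> GenomeAnnotation:
    """Parse an NCBI RefSeq ``*_feature_table.txt`` into ordered gene models.

    One :class:`Gene` is produced per distinct protein-coding locus: rows
    with ``feature == "CDS"`` and a non-empty ``locus_tag``.  Multiple CDS
    rows sharing a locus_tag (joined intervals) collapse to a single gene
    spanning ``min(start)..max(end)`` — one locus occupies one window slot.
    Genes are grouped by ``genomic_accession``, sorted ascending by start,
    and given contiguous 0-based ordinals per replicon.

    Raises
    ------
    FeatureTableError
        If required columns are absent or no CDS rows are present.
    """
    df = _read_table(stream)
    cds = df[(df["feature"] == "CDS") & (df["locus_tag"] != "")]
    if cds.empty:
        raise FeatureTableError(
            f"feature table for {genome_id!r} contains no CDS rows with a locus_tag"
        )
    cds = cds.assign(
        start=cds["start"].astype(int),
        end=cds["end"].astype(int),
    )

    annotation = GenomeAnnotation(genome_id=genome_id)
    for replicon_id, group in cds.groupby("genomic_accession", sort=True):
        loci = group.groupby("locus_tag", sort=False).agg(
            start=("start", "min"),
            end=("end", "max"),
            strand=("strand", "first"),
            product_accession=(
                "product_accession",
                lambda s: next((v for v in s if v), ""),
            ),
        )
        loci = loci.sort_values(["start", "end"])
        genes = [
            Gene(
                genome_id=genome_id,
                replicon_id=str(replicon_id),
                ordinal=i,
                locus_tag=str(tag),
                product_accession=str(row.product_accession),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand) or "+",
            )
            for i, (tag, row) in enumerate(loci.iterrows())
        ]
        seen_tags = {g.locus_tag for g in genes}
        if len(seen_tags) != len(genes):  # cannot happen after groupby; guard
            raise FeatureTableError(f"duplicate locus_tag within {replicon_id}")
        annotation.replicons[str(replicon_id)] = genes

    tags = [g.locus_tag for g in annotation.genes()]
    if len(tags) != len(set(tags)):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise FeatureTableError(
            f"locus_tag(s) appear on multiple replicons of {genome_id!r}: "
            + ", ".join(dup[:5])
        )
    return annotation


_HEADER = (
    "# feature\tclass\tassembly\tassembly_unit\tseq_type\tchromosome\t"
    "genomic_accession\tstart\tend\tstrand\tproduct_accession\t"
    "non-redundant_refseq\trelated_accession\tname\tsymbol\tGeneID\t"
    "locus_tag\tfeature_interval_length\tproduct_length\tattributes"
)


def write_feature_table(annotation: GenomeAnnotation, stream: TextIO) -> None:
    """Serialise an annotation to a minimal feature table (round-trip safe).

    Only the columns the reader consumes are filled; the rest are left
    empty so the output stays a valid instance of the dialect.
    """
    stream.write(_HEADER + "\n")
    for replicon_id in sorted(annotation.replicons):
        for g in annotation.replicons[replicon_id]:
            row = [""] * 20
            row[0] = "CDS"
            row[1] = "with_protein"
            row[6] = g.replicon_id
            row[7] = str(g.start)
            row[8] = str(g.end)
            row[9] = g.strand
            row[10] = g.product_accession
            row[16] = g.locus_tag
            row[17] = str(g.end - g.start + 1)
            stream.write("\t".join(row) + "\n")
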