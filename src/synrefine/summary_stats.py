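"""HOG classification, outcome aggregation, AMNOG, and output writers.

HOG classes follow the standard taxonomy for orthogroup shape:

* ``one_to_one`` — exactly one gene from every genome;
* ``zero_or_one`` — at least one genome missing, none contributing more
  than one, at least two genomes present;
* ``paralogous`` — some genome contributed two or more genes;
* ``single_genome`` — only one genome contributed (not analyzable by a
  cross-genome synteny test).

AMNOG — the average maximum number of orthologs in paralog-free SOGs — is
the sensitivity proxy at (near-)fixed specificity: per HOG, take the
largest number of genomes represented in any of its SOGs that contain no
within-genome paralogs, then average over HOGs.  Which HOGs enter the
average is ambiguous in common usage, so both conventions are computed:
``all`` averages over every analyzed multi-genome HOG (a HOG with no
paralog-free SOG contributes 0), ``qualifying`` restricts the average to
HOGs possessing at least one paralog-free SOG.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .annotation_io import Gene
from .orthogroup_io import AnnotatedDataset, HogTable
from .synteny_core import HogRefinement, Outcome, SyntenyParams

__all__ = [
    "HogClass",
    "RunSummary",
    "classify_hog",
    "amnog",
    "summarize",
    "write_outputs",
]


class HogClass(str, enum.Enum):
    ONE_TO_ONE = "one_to_one"
    ZERO_OR_ONE = "zero_or_one"
    PARALOGOUS = "paralogous"
    SINGLE_GENOME = "single_genome"


def classify_hog(member_counts: dict[str, int]) -> HogClass:
    """Classify a HOG from its per-genome member counts (table row).

    Classes are exhaustive and mutually exclusive; an empty row (no members
    anywhere) is an error.
    """
    counts = [c for c in member_counts.values() if c > 0]
    if not counts:
        raise ValueError("HOG row has no members in any genome")
    if any(c >= 2 for c in counts):
        return HogClass.PARALOGOUS
    if len(counts) == 1:
        return HogClass.SINGLE_GENOME
    if len(counts) == len(member_counts):
        return HogClass.ONE_TO_ONE
    return HogClass.ZERO_OR_ONE


def _best_paralog_free(refinement: HogRefinement) -> int:
    sizes = [s.n_genomes for s in refinement.sogs if not s.has_paralogs]
    return max(sizes, default=0)


def amnog(refinements: list[HogRefinement], mode: str = "all") -> float:
    """Average maximum number of orthologs in paralog-free SOGs.

    Requires refinements computed with ``run_all_hogs`` so that every
    multi-genome HOG carries scores.  ``mode="all"`` (default) averages over
    all analyzed HOGs with non-qualifying HOGs contributing 0;
    ``mode="qualifying"`` averages only over HOGs with at least one
    paralog-free SOG.
    """
    if mode not in ("all", "qualifying"):
        raise ValueError(f"unknown AMNOG mode {mode!r}")
    analyzed = [r for r in refinements if r.outcome is not Outcome.NOT_ANALYZED]
    if not analyzed:
        raise ValueError("AMNOG undefined: no analyzed HOGs")
    best = [_best_paralog_free(r) for r in analyzed]
    if mode == "qualifying":
        best = [b for b in best if b > 0]
        if not best:
            raise ValueError("AMNOG undefined: no HOG has a paralog-free SOG")
    return sum(best) / len(best)


@dataclass
class RunSummary:
    """Dataset-level counts, percentages and AMNOG for one refinement run."""

    class_counts: dict[HogClass, int]
    #: HogClass → Outcome → count, for analyzed (multi-genome) classes
    outcome_counts: dict[HogClass, dict[Outcome, int]]
    n_hogs: int
    n_genomes: int
    amnog_all: float | None
    amnog_qualifying: float | None
    params: SyntenyParams

    def class_percent(self, cls: HogClass) -> float:
        return 100.0 * self.class_counts.get(cls, 0) / self.n_hogs if self.n_hogs else 0.0

    def outcome_percent(self, cls: HogClass, outcome: Outcome) -> float:
        per_class = self.outcome_counts.get(cls, {})
        total = sum(per_class.values())
        return 100.0 * per_class.get(outcome, 0) / total if total else 0.0


def summarize(
    refinements: list[HogRefinement],
    table: HogTable,
    params: SyntenyParams,
) -> RunSummary:
    """Aggregate refinement outcomes by HOG class.

    Single-genome HOGs are counted in the class breakdown but excluded from
    outcome percentages (they cannot be analyzed).  AMNOG is reported when
    every multi-genome HOG was scored (``run_all_hogs``); otherwise the
    1-per-genome HOGs carry no scores and the statistic is left unset.
    """
    by_hog = {r.hog_id: r for r in refinements}
    class_counts: Counter = Counter()
    outcome_counts: dict[HogClass, dict[Outcome, int]] = {}
    for hog_id in table.hogs:
        cls = classify_hog(table.member_counts(hog_id))
        class_counts[cls] += 1
        if cls is HogClass.SINGLE_GENOME:
            continue
        refinement = by_hog.get(hog_id)
        outcome = refinement.outcome if refinement else Outcome.NOT_ANALYZED
        outcome_counts.setdefault(cls, {}).setdefault(outcome, 0)
        outcome_counts[cls][outcome] += 1

    amnog_all = amnog_qual = None
    analyzed = [r for r in refinements if r.outcome is not Outcome.NOT_ANALYZED]
    multi_genome = sum(
        1
        for hog_id in table.hogs
        if classify_hog(table.member_counts(hog_id)) is not HogClass.SINGLE_GENOME
    )
    if analyzed and len(analyzed) == multi_genome:
        amnog_all = amnog(refinements, mode="all")
        try:
            amnog_qual = amnog(refinements, mode="qualifying")
        except ValueError:
            amnog_qual = None

    return RunSummary(
        class_counts=dict(class_counts),
        outcome_counts=outcome_counts,
        n_hogs=sum(class_counts.values()),
        n_genomes=len(table.genome_order),
        amnog_all=amnog_all,
        amnog_qualifying=amnog_qual,
        params=params,
    )


def _gene_identifier(gene: Gene) -> str:
    return gene.product_accession or gene.locus_tag


def _gene_label(gene: Gene) -> str:
    return f"{gene.genome_id}:{gene.locus_tag}"


def write_outputs(
    summary: RunSummary,
    refinements: list[HogRefinement],
    dataset: AnnotatedDataset,
    out_prefix: str | Path,
) -> list[Path]:
    """Write the three result tables; returns their paths.

    * ``<prefix>.sogs.tsv`` — refined orthogroup table in the input table's
      dialect, one row per SOG labelled ``SOG<hog>.<k>``, excluded genes
      omitted;
    * ``<prefix>.scores.tsv`` — every evaluated pair with match count,
      denominator, ratio and the syntenic call;
    * ``<prefix>.summary.tsv`` — the run summary as key/value rows.

    Row order is deterministic; reruns on identical inputs are
    byte-identical.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    table = dataset.table
    paths = []

    sog_path = out_prefix.with_suffix(".sogs.tsv")
    with open(sog_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(table.fixed_header + table.genome_order) + "\n")
        for refinement in refinements:
            fixed = table.fixed_columns.get(
                refinement.hog_id, [""] * len(table.fixed_header)
            )
            for sog in refinement.sogs:
                per_genome: dict[str, list[str]] = {g: [] for g in table.genome_order}
                for gene in sog.members:
                    per_genome[gene.genome_id].append(_gene_identifier(gene))
                row = [sog.label] + fixed[1:]
                row += [", ".join(per_genome[g]) for g in table.genome_order]
                fh.write("\t".join(row) + "\n")
    paths.append(sog_path)

    score_path = out_prefix.with_suffix(".scores.tsv")
    with open(score_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("hog\tgene_a\tgene_b\tmatches\tdenominator\tsr\tsyntenic\n")
        for refinement in refinements:
            for s in refinement.scores:
                fh.write(
                    f"{refinement.hog_id}\t{_gene_label(s.gene_a)}\t"
                    f"{_gene_label(s.gene_b)}\t{s.matches}\t{s.denominator}\t"
                    f"{s.ratio:.6g}\t{int(s.is_syntenic)}\n"
                )
    paths.append(score_path)

    summary_path = out_prefix.with_suffix(".summary.tsv")
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("key\tvalue\n")
        p = summary.params
        rows: list[tuple[str, object]] = [
            ("window_size", p.window_size),
            ("synteny_ratio_cutoff", p.synteny_ratio_cutoff),
            ("cutoff_cmp", p.cutoff_cmp),
            ("run_all_hogs", p.run_all_hogs),
            ("truncation_mode", p.truncation_mode),
            ("n_genomes", summary.n_genomes),
            ("n_hogs", summary.n_hogs),
        ]
        for cls in HogClass:
            rows.append((f"n_{cls.value}", summary.class_counts.get(cls, 0)))
            rows.append((f"pct_{cls.value}", f"{summary.class_percent(cls):.1f}"))
        for cls in (HogClass.ONE_TO_ONE, HogClass.ZERO_OR_ONE, HogClass.PARALOGOUS):
            per_class = summary.outcome_counts.get(cls, {})
            for outcome in Outcome:
                n = per_class.get(outcome, 0)
                rows.append((f"n_{cls.value}_{outcome.value}", n))
                rows.append(
                    (
                        f"pct_{cls.value}_{outcome.value}",
                        f"{summary.outcome_percent(cls, outcome):.1f}",
                    )
                )
        rows.append(
            ("amnog_all", f"{summary.amnog_all:.6g}" if summary.amnog_all is not None else "NA")
        )
        rows.append(
            (
                "amnog_qualifying",
                f"{summary.amnog_qualifying:.6g}"
                if summary.amnog_qualifying is not None
                else "NA",
            )
        )
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")
    paths.append(summary_path)
    return paths
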