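"""Synthetic genome/orthogroup generator with known truth, plus brute-force oracles.

The generator emulates exactly the inputs the synteny test consumes: per
genome an *ordered* list of genes labelled by homology family, produced by
descending every genome from a common ancestral gene order through a small
set of rearrangement events.  No sequences are simulated — the algorithm
never looks at them — so an event model over order and labels is the whole
of the relevant biology:

* inversion — a contiguous span is reversed in place;
* translocation — a contiguous span is cut out and reinserted elsewhere;
* tandem duplication — a gene gains an adjacent copy;
* dispersed duplication — a gene gains a copy at a random distant position;
* loss — a gene is deleted.

Every simulated gene carries its ancestral family index and a flag marking
duplication-derived lineages, so the true ortholog/paralog status of every
cross-genome pair is known.  Families play the role of orthogroups: the
emitted HOG table groups *all* descendants of one ancestral gene, duplicates
included, mimicking an initial homology clustering that has not yet
discriminated paralogs.

The brute-force routines at the bottom re-implement the scoring and
partition contracts by exhaustive scanning with no shared code; they exist
only as independent test oracles and refuse instances above 50 genes per
genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import Gene, GenomeAnnotation, write_feature_table
from .orthogroup_io import AnnotatedDataset, HogTable, link_genes
from .synteny_core import HogRefinement, SyntenyParams, SyntenyScore

__all__ = [
    "SimParams",
    "TruthSet",
    "SimulatedDataset",
    "simulate_dataset",
    "write_dataset",
    "brute_force_sr",
    "brute_force_partition",
    "score_against_truth",
    "score_groups",
]

_ORACLE_MAX_GENES = 50


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator.

    Defaults emulate a handful of closely related bacterial genomes — high
    gene-order conservation perturbed by a few large-scale rearrangements
    and a modest number of duplications and losses per genome.  ``seed`` is
    mandatory: every run is reproducible by construction.
    """

    seed: int
    n_genomes: int = 4
    genes_per_genome: int = 100
    n_inversions: int = 2
    inversion_span: int = 6
    n_translocations: int = 1
    n_tandem_dups: int = 3
    n_dispersed_dups: int = 2
    n_losses: int = 3
    n_replicons: int = 1

    def __post_init__(self) -> None:
        counts = {
            "n_genomes": self.n_genomes,
            "genes_per_genome": self.genes_per_genome,
            "n_inversions": self.n_inversions,
            "inversion_span": self.inversion_span,
            "n_translocations": self.n_translocations,
            "n_tandem_dups": self.n_tandem_dups,
            "n_dispersed_dups": self.n_dispersed_dups,
            "n_losses": self.n_losses,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_genomes < 1 or self.genes_per_genome < 1 or self.n_replicons < 1:
            raise ValueError("n_genomes, genes_per_genome and n_replicons must be >= 1")
        if self.inversion_span > self.genes_per_genome:
            raise ValueError(
                f"inversion_span {self.inversion_span} exceeds genome length "
                f"{self.genes_per_genome}"
            )


@dataclass
class TruthSet:
    """Known ortholog/paralog status of every cross-genome same-family pair.

    Pairs are frozensets of ``(genome_id, locus_tag)`` keys.  A pair is a
    true ortholog when both genes descend from the same ancestral gene with
    no duplication on either lineage; any same-family cross-genome pair
    touching a duplication-derived copy is a paralog pair.  The two sets are
    disjoint.
    """

    true_ortholog_pairs: set[frozenset]
    paralog_pairs: set[frozenset]


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    params: SimParams
    annotations: dict[str, GenomeAnnotation]
    hog_table: HogTable
    truth: TruthSet
    #: per genome, the final (family, is_duplicate) lineage sequence
    lineages: dict[str, list[tuple[int, bool]]]

    def link(self) -> AnnotatedDataset:
        return link_genes(self.hog_table, self.annotations)


# instance in flight during simulation: (family index, duplication-derived?)
_Instance = tuple[int, bool]


def _apply_events(
    genes: list[_Instance], params: SimParams, rng: np.random.Generator
) -> list[_Instance]:
    span = params.inversion_span
    for _ in range(params.n_inversions):
        if len(genes) < span:
            break
        i = int(rng.integers(0, len(genes) - span + 1))
        genes[i : i + span] = genes[i : i + span][::-1]
    for _ in range(params.n_translocations):
        if len(genes) < span + 1:
            break
        i = int(rng.integers(0, len(genes) - span + 1))
        block = genes[i : i + span]
        rest = genes[:i] + genes[i + span :]
        j = int(rng.integers(0, len(rest) + 1))
        genes = rest[:j] + block + rest[j:]
    for _ in range(params.n_tandem_dups):
        i = int(rng.integers(0, len(genes)))
        genes.insert(i + 1, (genes[i][0], True))
    for _ in range(params.n_dispersed_dups):
        i = int(rng.integers(0, len(genes)))
        j = int(rng.integers(0, len(genes) + 1))
        genes.insert(j, (genes[i][0], True))
    for _ in range(params.n_losses):
        if len(genes) <= 1:
            break
        i = int(rng.integers(0, len(genes)))
        del genes[i]
    return genes


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Derive ``n_genomes`` genomes from a common ancestor and emit inputs.

    Coordinates are synthetic: the k-th gene of a replicon starts at
    ``1000*k + 1`` and is 900 bp long on the forward strand.  The emitted
    orthogroup table groups all descendants of each ancestral family;
    families losing every member are dropped.  Deterministic: a fixed seed
    regenerates the dataset byte-for-byte.
    """
    rng = np.random.default_rng(params.seed)
    genome_ids = [f"G{i}" for i in range(params.n_genomes)]
    annotations: dict[str, GenomeAnnotation] = {}
    lineages: dict[str, list[_Instance]] = {}
    # family → genome → list of (locus_tag, product_accession, is_dup)
    family_members: dict[int, dict[str, list[tuple[str, str, bool]]]] = {}

    for genome_id in genome_ids:
        genes: list[_Instance] = [(k, False) for k in range(params.genes_per_genome)]
        genes = _apply_events(genes, params, rng)
        lineages[genome_id] = list(genes)

        annotation = GenomeAnnotation(genome_id=genome_id)
        n = len(genes)
        chunk = -(-n // params.n_replicons)  # ceil division; contiguous chunks
        serial = 0
        for r in range(params.n_replicons):
            block = genes[r * chunk : (r + 1) * chunk]
            if not block:
                continue
            replicon_id = f"{genome_id}_rep{r}"
            gene_objs = []
            for k, (family, is_dup) in enumerate(block):
                locus_tag = f"{genome_id}_{serial:05d}"
                accession = f"P_{genome_id}_{serial:05d}"
                serial += 1
                gene_objs.append(
                    Gene(
                        genome_id=genome_id,
                        replicon_id=replicon_id,
                        ordinal=k,
                        locus_tag=locus_tag,
                        product_accession=accession,
                        start=1000 * k + 1,
                        end=1000 * k + 900,
                        strand="+",
                    )
                )
                family_members.setdefault(family, {}).setdefault(genome_id, []).append(
                    (locus_tag, accession, is_dup)
                )
            annotation.replicons[replicon_id] = gene_objs
        annotations[genome_id] = annotation

    hogs: dict[str, dict[str, list[str]]] = {}
    fixed_columns: dict[str, list[str]] = {}
    for family in sorted(family_members):
        hog_id = f"N0.HOG{family:07d}"
        hogs[hog_id] = {
            g: [acc for _, acc, _ in family_members[family].get(g, [])]
            for g in genome_ids
        }
        fixed_columns[hog_id] = [hog_id, f"OG{family:07d}", "n0"]
    hog_table = HogTable(
        hogs=hogs, genome_order=list(genome_ids), fixed_columns=fixed_columns
    )

    true_pairs: set[frozenset] = set()
    paralog_pairs: set[frozenset] = set()
    for family, per_genome in family_members.items():
        flat = [
            (g, locus, dup)
            for g, members in per_genome.items()
            for locus, _, dup in members
        ]
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                ga, la, da = flat[i]
                gb, lb, db = flat[j]
                if ga == gb:
                    continue
                pair = frozenset({(ga, la), (gb, lb)})
                if da or db:
                    paralog_pairs.add(pair)
                else:
                    true_pairs.add(pair)
    return SimulatedDataset(
        params=params,
        annotations=annotations,
        hog_table=hog_table,
        truth=TruthSet(true_ortholog_pairs=true_pairs, paralog_pairs=paralog_pairs),
        lineages=lineages,
    )


def write_dataset(sim: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset in the dialects the readers consume.

    Produces one ``<genome>_feature_table.txt`` per genome, ``N0.tsv`` and
    ``manifest.txt``; returns the paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest_lines = []
    for genome_id, annotation in sim.annotations.items():
        ft_path = out_dir / f"{genome_id}_feature_table.txt"
        with open(ft_path, "w", encoding="utf-8", newline="\n") as fh:
            write_feature_table(annotation, fh)
        paths[genome_id] = ft_path
        manifest_lines.append(f"{genome_id}\t{ft_path.name}")

    hog_path = out_dir / "N0.tsv"
    table = sim.hog_table
    with open(hog_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(table.fixed_header + table.genome_order) + "\n")
        for hog_id in table.hogs:
            fixed = table.fixed_columns[hog_id]
            cells = [", ".join(table.hogs[hog_id][g]) for g in table.genome_order]
            fh.write("\t".join(fixed + cells) + "\n")
    paths["hogs"] = hog_path

    manifest_path = out_dir / "manifest.txt"
    manifest_path.write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")
    paths["manifest"] = manifest_path
    return paths


# --------------------------------------------------------------------------
# Brute-force oracles (test-only; no code shared with synteny_core)
# --------------------------------------------------------------------------


def _check_oracle_size(annotations: dict[str, GenomeAnnotation]) -> None:
    for genome_id, ann in annotations.items():
        if ann.n_genes > _ORACLE_MAX_GENES:
            raise ValueError(
                f"brute-force oracle limited to {_ORACLE_MAX_GENES} genes/genome; "
                f"{genome_id} has {ann.n_genes}"
            )


def _oracle_window(
    annotations: dict[str, GenomeAnnotation],
    hog_of: dict[Gene, str],
    center: Gene,
    other_genome: str,
    w: int,
) -> list[Gene]:
    # HOGs present in the other genome, recomputed from hog_of every call.
    present = {
        hog_of[g] for g in annotations[other_genome].genes() if g in hog_of
    }
    row = sorted(
        annotations[center.genome_id].replicons[center.replicon_id],
        key=lambda g: g.start,
    )
    pos = row.index(center)
    lefts = [
        g for g in row[:pos][::-1] if g in hog_of and hog_of[g] in present
    ]
    rights = [g for g in row[pos + 1 :] if g in hog_of and hog_of[g] in present]
    take_left = min(w // 2, len(lefts))
    take_right = min(w // 2, len(rights))
    while take_left + take_right < w and (
        take_left < len(lefts) or take_right < len(rights)
    ):
        if take_right < len(rights):
            take_right += 1
        else:
            take_left += 1
    return lefts[:take_left] + rights[:take_right]


def brute_force_sr(
    annotations: dict[str, GenomeAnnotation],
    hog_of: dict[Gene, str],
    gene_a: Gene,
    gene_b: Gene,
    params: SyntenyParams,
) -> SyntenyScore:
    """Exhaustive-scan synteny ratio with greedy pair matching (oracle)."""
    _check_oracle_size(annotations)
    w = params.window_size
    win_a = _oracle_window(annotations, hog_of, gene_a, gene_b.genome_id, w)
    win_b = _oracle_window(annotations, hog_of, gene_b, gene_a.genome_id, w)
    used = [False] * len(win_b)
    matches = 0
    for ga in win_a:
        for i, gb in enumerate(win_b):
            if not used[i] and hog_of[ga] == hog_of[gb]:
                used[i] = True
                matches += 1
                break
    if params.truncation_mode == "fixed_denominator":
        denominator = w
    else:
        denominator = max(len(win_a), len(win_b))
        denominator = w if denominator > w else denominator
    ratio = matches / denominator if denominator else 0.0
    syntenic = (
        (ratio >= params.synteny_ratio_cutoff)
        if params.cutoff_cmp == "ge"
        else (ratio > params.synteny_ratio_cutoff)
    ) if denominator else False
    return SyntenyScore(
        gene_a=gene_a,
        gene_b=gene_b,
        matches=matches,
        denominator=denominator or w,
        ratio=ratio,
        is_syntenic=syntenic,
    )


def brute_force_partition(
    annotations: dict[str, GenomeAnnotation],
    hog_of: dict[Gene, str],
    members: Sequence[Gene],
    params: SyntenyParams,
) -> tuple[list[frozenset], set]:
    """Union-find SOG partition oracle over one HOG's members.

    Returns (list of SOG member-key frozensets, set of excluded member
    keys); keys are ``(genome_id, locus_tag)``.  Components confined to a
    single genome are excluded, matching the SOG definition.
    """
    _check_oracle_size(annotations)
    parent = {g.key: g.key for g in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(members):
        for b in list(members)[i + 1 :]:
            if a.genome_id == b.genome_id:
                continue
            if brute_force_sr(annotations, hog_of, a, b, params).is_syntenic:
                parent[find(a.key)] = find(b.key)

    components: dict = {}
    for g in members:
        components.setdefault(find(g.key), []).append(g)
    sogs: list[frozenset] = []
    excluded: set = set()
    for genes in components.values():
        if len({g.genome_id for g in genes}) >= 2:
            sogs.append(frozenset(g.key for g in genes))
        else:
            excluded.update(g.key for g in genes)
    return sogs, excluded


# --------------------------------------------------------------------------
# Scoring against truth
# --------------------------------------------------------------------------


def score_groups(
    groups: Iterable[Sequence[Gene]], truth: TruthSet
) -> dict[str, float]:
    """Precision/recall of an arbitrary grouping against the truth set.

    Precision: fraction of within-group cross-genome pairs that are true
    ortholog pairs.  Recall: fraction of true ortholog pairs co-grouped.
    A grouping proposing no cross-genome pairs has precision 1 by
    convention (it asserts nothing false).
    """
    proposed: set[frozenset] = set()
    for genes in groups:
        keys = [g.key for g in genes]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if keys[i][0] != keys[j][0]:
                    proposed.add(frozenset({keys[i], keys[j]}))
    n_true = len(proposed & truth.true_ortholog_pairs)
    precision = n_true / len(proposed) if proposed else 1.0
    recall = (
        n_true / len(truth.true_ortholog_pairs)
        if truth.true_ortholog_pairs
        else 1.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "n_pairs_proposed": float(len(proposed)),
        "n_pairs_true": float(len(truth.true_ortholog_pairs)),
    }


def score_against_truth(
    refinements: Sequence[HogRefinement], truth: TruthSet
) -> dict[str, float]:
    """Precision/recall of the refined SOG partition against the truth set."""
    return score_groups(
        (sog.members for r in refinements for sog in r.sogs), truth
    )
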