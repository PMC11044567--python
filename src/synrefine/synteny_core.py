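"""Look-around window synteny scoring and syntenic ortholog group construction.

The method: for every pair of same-HOG genes drawn from two different
genomes, build a window of up to ``w`` neighbor genes around each gene
(``w/2`` per side), count the neighbor HOGs the two windows share, and call
the pair syntenic when the matched fraction (the synteny ratio) passes a
cutoff.  Within each HOG, genes linked pairwise-or-transitively by syntenic
edges form a syntenic ortholog group (SOG); members with no syntenic link to
any cross-genome partner are excluded as presumed paralogs.

Window semantics
----------------
The window is homolog-filtered per genome pair: when walking outward from
the center gene, a neighbor only occupies a window slot if its HOG has at
least one member in the *other* genome of the comparison — a gene with no
counterpart there carries no signal and is skipped, letting the window reach
further.  The center gene itself never occupies a slot.  When one side of
the window hits a replicon end, the other side is extended so the total
number of slots still approaches ``w``; windows never wrap around circular
replicons.

Matching is a matched-pairs count: each window gene can be used at most
once, so a HOG present twice in one window and once in the other contributes
one match (min-multiplicity).  Gene order and strand within the window are
deliberately ignored — neighborhood content, not collinearity, is the
criterion.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import networkx as nx

from .annotation_io import Gene
from .orthogroup_io import AnnotatedDataset

__all__ = [
    "SyntenyParams",
    "WindowGenes",
    "SyntenyScore",
    "Sog",
    "Outcome",
    "HogRefinement",
    "homolog_filtered_window",
    "synteny_ratio",
    "evaluate_hog",
    "refine_all",
]


@dataclass(frozen=True)
class SyntenyParams:
    """Tunable parameters of the synteny test.

    window_size:
        Total neighbor slots inspected, ``w/2`` per side of the center gene;
        must be even and ≥ 2.  Default 8 — suited to closely related
        genomes; 30 with a 0.2 cutoff is the recommended regime for distant
        genomes.
    synteny_ratio_cutoff:
        Fraction of the window that must match for a pair to count as
        syntenic; in (0, 1], default 0.5.
    cutoff_cmp:
        ``"ge"`` (default) treats a ratio exactly at the cutoff as syntenic;
        ``"gt"`` requires strictly more.
    run_all_hogs:
        Also score HOGs with a single gene per genome (no within-genome
        paralogs).  Default False: only HOGs where some genome contributed
        at least two genes are refined.
    truncation_mode:
        Denominator at replicon boundaries where fewer than ``w`` qualifying
        neighbors exist.  ``"effective_denominator"`` (default) divides by
        the larger of the two realised window sizes, so edge genes can still
        reach ratio 1; ``"fixed_denominator"`` always divides by ``w``.
    """

    window_size: int = 8
    synteny_ratio_cutoff: float = 0.5
    cutoff_cmp: Literal["ge", "gt"] = "ge"
    run_all_hogs: bool = False
    truncation_mode: Literal[
        "effective_denominator", "fixed_denominator"
    ] = "effective_denominator"

    def __post_init__(self) -> None:
        w = self.window_size
        if w < 2 or w % 2 != 0:
            raise ValueError(f"window_size must be even and >= 2, got {w}")
        if not (0.0 < self.synteny_ratio_cutoff <= 1.0):
            raise ValueError(
                f"synteny_ratio_cutoff must be in (0, 1], got {self.synteny_ratio_cutoff}"
            )
        if self.cutoff_cmp not in ("ge", "gt"):
            raise ValueError(f"cutoff_cmp must be 'ge' or 'gt', got {self.cutoff_cmp!r}")
        if self.truncation_mode not in ("effective_denominator", "fixed_denominator"):
            raise ValueError(f"unknown truncation_mode {self.truncation_mode!r}")

    def passes(self, ratio: float) -> bool:
        if self.cutoff_cmp == "ge":
            return ratio >= self.synteny_ratio_cutoff
        return ratio > self.synteny_ratio_cutoff


@dataclass
class WindowGenes:
    """The qualifying neighbors around ``center`` for one genome pair."""

    center: Gene
    other_genome: str
    members: list[Gene]


class Outcome(str, Enum):
    """Refinement outcome of one HOG."""

    CONFIRMED = "confirmed"      # a single SOG holds every analyzed member
    MODIFIED = "modified"        # ≥1 paralog removed and/or HOG split
    UNCONFIRMED = "unconfirmed"  # no synteny support for any subgroup
    NOT_ANALYZED = "not_analyzed"


@dataclass(frozen=True)
class SyntenyScore:
    """Synteny evaluation of one cross-genome gene pair (symmetric)."""

    gene_a: Gene
    gene_b: Gene
    matches: int
    denominator: int
    ratio: float
    is_syntenic: bool


@dataclass
class Sog:
    """A syntenic ortholog group: a synteny-connected subset of one HOG."""

    hog_id: str
    sog_index: int
    members: list[Gene]
    has_paralogs: bool

    @property
    def label(self) -> str:
        return f"SOG{_short_hog(self.hog_id)}.{self.sog_index}"

    @property
    def n_genomes(self) -> int:
        return len({g.genome_id for g in self.members})


def _short_hog(hog_id: str) -> str:
    """'N0.HOG0000019' → '19'; anything else is used verbatim."""
    tail = hog_id.rsplit("HOG", 1)
    if len(tail) == 2 and tail[1].isdigit():
        return str(int(tail[1]))
    return hog_id


@dataclass
class HogRefinement:
    """Complete refinement record for one HOG."""

    hog_id: str
    scores: list[SyntenyScore]
    sogs: list[Sog]
    excluded: list[Gene]
    outcome: Outcome

    @property
    def analyzed_members(self) -> list[Gene]:
        return [g for s in self.sogs for g in s.members] + list(self.excluded)


def homolog_filtered_window(
    dataset: AnnotatedDataset, center: Gene, other_genome: str, w: int
) -> WindowGenes:
    """Collect up to ``w`` qualifying neighbors around ``center``.

    Walks outward along the center's replicon, skipping genes whose HOG is
    unassigned or has no member in ``other_genome``; up to ``w/2`` slots are
    drawn from each side, and a boundary shortfall on one side is made up
    from the other.  The center gene is never included.
    """
    replicon = dataset.annotations[center.genome_id].replicons.get(center.replicon_id)
    if replicon is None or center.ordinal >= len(replicon) or replicon[center.ordinal] != center:
        raise RuntimeError(f"center gene {center!r} not placed on its replicon")

    def qualifies(g: Gene) -> bool:
        hog = dataset.hog_of.get(g)
        return hog is not None and dataset.hog_in_genome(hog, other_genome)

    # Nearest-first qualifying genes on each side; collect up to w per side
    # because a boundary on the opposite side may push the quota over w/2.
    left: list[Gene] = []
    for i in range(center.ordinal - 1, -1, -1):
        if len(left) == w:
            break
        if qualifies(replicon[i]):
            left.append(replicon[i])
    right: list[Gene] = []
    for i in range(center.ordinal + 1, len(replicon)):
        if len(right) == w:
            break
        if qualifies(replicon[i]):
            right.append(replicon[i])

    half = w // 2
    n_left = min(half, len(left))
    n_right = min(half, len(right))
    shortfall = w - (n_left + n_right)
    if shortfall > 0:  # extend whichever side still has genes
        extra_right = min(shortfall, len(right) - n_right)
        n_right += extra_right
        shortfall -= extra_right
        n_left += min(shortfall, len(left) - n_left)

    members = list(reversed(left[:n_left])) + right[:n_right]
    return WindowGenes(center=center, other_genome=other_genome, members=members)


def synteny_ratio(
    dataset: AnnotatedDataset, gene_a: Gene, gene_b: Gene, params: SyntenyParams
) -> SyntenyScore:
    """Score one cross-genome gene pair.

    A window is built around each gene against the other gene's genome; the
    match count is the multiset intersection of the two windows' HOG labels
    (each window gene usable at most once).  The result is symmetric in the
    pair by construction.
    """
    if gene_a.genome_id == gene_b.genome_id:
        raise ValueError(
            f"synteny is defined across genomes; both genes are from {gene_a.genome_id}"
        )
    w = params.window_size
    win_a = homolog_filtered_window(dataset, gene_a, gene_b.genome_id, w)
    win_b = homolog_filtered_window(dataset, gene_b, gene_a.genome_id, w)
    counts_a = Counter(dataset.hog_of[g] for g in win_a.members)
    counts_b = Counter(dataset.hog_of[g] for g in win_b.members)
    matches = sum((counts_a & counts_b).values())
    if params.truncation_mode == "fixed_denominator":
        denominator = w
    else:
        denominator = min(w, max(len(win_a.members), len(win_b.members)))
    ratio = matches / denominator if denominator else 0.0
    return SyntenyScore(
        gene_a=gene_a,
        gene_b=gene_b,
        matches=matches,
        denominator=denominator if denominator else w,
        ratio=ratio,
        is_syntenic=params.passes(ratio) if denominator else False,
    )


def _is_analyzable(dataset: AnnotatedDataset, hog_id: str, params: SyntenyParams) -> bool:
    members = dataset.members_of.get(hog_id, [])
    genome_counts = Counter(g.genome_id for g in members)
    if len(genome_counts) < 2:
        return False
    if params.run_all_hogs:
        return True
    return any(c >= 2 for c in genome_counts.values())


def _member_sort_key(dataset: AnnotatedDataset, g: Gene) -> tuple:
    return (dataset.genome_rank(g.genome_id), g.replicon_id, g.ordinal)


def evaluate_hog(
    dataset: AnnotatedDataset, hog_id: str, params: SyntenyParams
) -> HogRefinement:
    """Refine one HOG into SOGs.

    Every cross-genome member pair is scored; syntenic pairs become edges of
    a graph on the HOG members, and connected components spanning at least
    two genomes become SOGs (a component confined to one genome has no
    cross-genome support and its members are excluded).  Same-genome
    paralogs can co-cluster only transitively, via a shared cross-genome
    partner — the tandem-duplicate case.

    HOGs failing the analyzability pre-filter (single genome, or no paralogs
    without ``run_all_hogs``) are returned untouched as ``not_analyzed``.
    """
    members = dataset.members_of.get(hog_id, [])
    if not _is_analyzable(dataset, hog_id, params):
        return HogRefinement(
            hog_id=hog_id, scores=[], sogs=[], excluded=[], outcome=Outcome.NOT_ANALYZED
        )

    members = sorted(members, key=lambda g: _member_sort_key(dataset, g))
    graph = nx.Graph()
    graph.add_nodes_from(members)
    scores: list[SyntenyScore] = []
    for a, b in itertools.combinations(members, 2):
        if a.genome_id == b.genome_id:
            continue
        score = synteny_ratio(dataset, a, b, params)
        scores.append(score)
        if score.is_syntenic:
            graph.add_edge(a, b)

    sog_components: list[list[Gene]] = []
    excluded: list[Gene] = []
    for component in nx.connected_components(graph):
        genes = sorted(component, key=lambda g: _member_sort_key(dataset, g))
        if len({g.genome_id for g in genes}) >= 2:
            sog_components.append(genes)
        else:
            excluded.extend(genes)
    sog_components.sort(key=lambda genes: _member_sort_key(dataset, genes[0]))
    excluded.sort(key=lambda g: _member_sort_key(dataset, g))

    sogs = [
        Sog(
            hog_id=hog_id,
            sog_index=i,
            members=genes,
            has_paralogs=len({g.genome_id for g in genes}) < len(genes),
        )
        for i, genes in enumerate(sog_components)
    ]

    if not sogs:
        outcome = Outcome.UNCONFIRMED
    elif len(sogs) == 1 and not excluded:
        outcome = Outcome.CONFIRMED
    else:
        outcome = Outcome.MODIFIED
    return HogRefinement(
        hog_id=hog_id, scores=scores, sogs=sogs, excluded=excluded, outcome=outcome
    )


def refine_all(
    dataset: AnnotatedDataset, params: SyntenyParams
) -> list[HogRefinement]:
    """Refine every HOG in table order.

    Per-HOG results are independent, so the output is identical regardless
    of evaluation order; table order keeps the run deterministic.
    """
    return [
        evaluate_hog(dataset, hog_id, params) for hog_id in dataset.table.hogs
    ]
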