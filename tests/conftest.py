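"""Shared builders: programmatic datasets with hand-specified gene orders."""

from __future__ import annotations

import pytest

from synrefine.annotation_io import Gene, GenomeAnnotation
from synrefine.orthogroup_io import AnnotatedDataset, HogTable, link_genes

Label = "str | int | tuple | None"


def hog_id_for(label) -> str:
    """'19' / 19 → 'N0.HOG0000019'; non-numeric labels pass through."""
    s = str(label)
    return f"N0.HOG{int(s):07d}" if s.isdigit() else s


def make_dataset(orders: dict) -> AnnotatedDataset:
    """Build a linked dataset from per-genome gene-order specs.

    ``orders`` maps genome_id → gene order, where the order is either a
    flat list (one replicon) or a dict replicon_id → list.  Each entry is a
    homology label (int/str), ``None`` for an unassigned gene, or a tuple
    ``(label, locus_tag)`` to pin the locus tag.  Genome column order of
    the resulting table follows dict insertion order.
    """
    annotations: dict[str, GenomeAnnotation] = {}
    members: dict[str, dict[str, list[str]]] = {}
    genome_order = list(orders)
    for genome_id, spec in orders.items():
        replicons = spec if isinstance(spec, dict) else {"chr": spec}
        ann = GenomeAnnotation(genome_id=genome_id)
        serial = 0
        for replicon_id, labels in replicons.items():
            genes = []
            for k, entry in enumerate(labels):
                if isinstance(entry, tuple):
                    label, locus_tag = entry
                else:
                    label, locus_tag = entry, f"{genome_id}_{serial:04d}"
                serial += 1
                accession = f"{locus_tag}_p"
                genes.append(
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
                if label is not None:
                    members.setdefault(hog_id_for(label), {}).setdefault(
                        genome_id, []
                    ).append(accession)
            ann.replicons[replicon_id] = genes
        annotations[genome_id] = ann

    hogs = {
        hog: {g: m.get(g, []) for g in genome_order}
        for hog, m in sorted(members.items())
    }
    table = HogTable(
        hogs=hogs,
        genome_order=genome_order,
        fixed_columns={h: [h, h.replace("HOG", "OG"), "n0"] for h in hogs},
    )
    return link_genes(table, annotations)


def _ctx(base: int, n: int = 8) -> list[int]:
    return list(range(base, base + n))


def _block(ctx: list[int], member=None) -> list:
    """A context block: 4 context genes, optional member, 4 context genes."""
    if member is None:
        return list(ctx)
    return list(ctx[:4]) + [member] + list(ctx[4:])


@pytest.fixture(scope="session")
def escherichia_like():
    """Synthetic reconstruction of the four-genome case-study neighborhoods.

    This is *not* the real Escherichia data: it is a programmatically built
    stand-in encoding the neighborhood structure of the scenario — two
    conserved contexts carrying the two syntenic subgroups of an
    ABC-transporter-like orthogroup (HOG 19), the rpn-like orthogroup
    (HOG 21) whose window must skip three homology families absent from one
    genome, and isolated contexts for every member excluded as a paralog.
    Locus tags use real Escherichia conventions so assertions read
    naturally.
    """
    ctxA = _ctx(100)       # SOG19.0 neighborhood, conserved in all 4 genomes
    ctxB = _ctx(200)       # SOG19.1 neighborhood
    ctxC = _ctx(400)       # SOG21.1 neighborhood
    ctxE = {i: _ctx(300 + 10 * i) for i in range(1, 7)}  # isolation contexts

    # HOG21 neighborhood: families 3433-3435 are absent from E. fergusonii,
    # so its windows skip them and reach 1862-1864 (+1865) instead.
    left21 = [1855, 1856, 1857, 1858]
    right21_full = [3433, 3434, 3435, 1862, 1863, 1864, 1865]
    right21_ferg = [1862, 1863, 1864, 1865]

    def hog21_block(member, ferg: bool) -> list:
        return left21 + [member] + (right21_ferg if ferg else right21_full)

    orders = {
        "ecoli": (
            _block(ctxA, (19, "b0652"))
            + _block(ctxB, (19, "b3271"))
            + _block(ctxE[1], (19, "b4106"))
            + _block(ctxE[2], (19, "b4096"))
            + hog21_block((21, "b2244"), ferg=False)
            + _block(ctxC, (21, "b3411"))
            + _block(ctxE[3]) + _block(ctxE[4]) + _block(ctxE[5]) + _block(ctxE[6])
        ),
        "fergusonii": (
            _block(ctxA, (19, "HVX45_RS07420"))
            + _block(ctxB, (19, "HVX45_RS11505"))
            + _block(ctxE[3], (19, "HVX45_RS02390"))
            + _block(ctxE[4], (19, "HVX45_RS04025"))
            + _block(ctxE[5], (19, "HVX45_RS09410"))
            + hog21_block((21, "HVX45_RS21485"), ferg=True)
            + _block(ctxC, (21, "HVX45_RS12120"))
            + _block(ctxE[6], (21, "HVX45_RS22925"))
            + _block(ctxE[1]) + _block(ctxE[2])
        ),
        "albertii": (
            _block(ctxA, (19, "JRC41_RS15115"))
            + hog21_block((21, "JRC41_RS07400"), ferg=False)
            + _block(ctxB) + _block(ctxC)
            + _block(ctxE[1]) + _block(ctxE[2]) + _block(ctxE[3])
            + _block(ctxE[4]) + _block(ctxE[5]) + _block(ctxE[6])
        ),
        "marmotae": (
            _block(ctxA, (19, "GV529_RS05870"))
            + _block(ctxB, (19, "GV529_RS14465"))
            + hog21_block((21, "GV529_RS12150"), ferg=False)
            + _block(ctxC, (21, "GV529_RS10930"))
            + _block(ctxE[1]) + _block(ctxE[2]) + _block(ctxE[3])
            + _block(ctxE[4]) + _block(ctxE[5]) + _block(ctxE[6])
        ),
    }
    return make_dataset(orders)


def gene_by_tag(dataset: AnnotatedDataset, locus_tag: str) -> Gene:
    for ann in dataset.annotations.values():
        for gene in ann.genes():
            if gene.locus_tag == locus_tag:
                return gene
    raise KeyError(locus_tag)
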