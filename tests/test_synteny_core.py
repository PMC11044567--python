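"""Look-around window, synteny ratio, and SOG construction."""

import pytest

from conftest import gene_by_tag, hog_id_for, make_dataset
from synrefine.synteny_core import (
    Outcome,
    SyntenyParams,
    evaluate_hog,
    homolog_filtered_window,
    refine_all,
    synteny_ratio,
)


def identical_pair(n=20):
    """Two genomes with identical content and order, singleton HOGs."""
    return make_dataset({"gA": list(range(n)), "gB": list(range(n))})


class TestWindow:
    def test_four_genes_each_side(self):
        ds = identical_pair()
        center = ds.annotations["gA"].replicons["chr"][10]
        win = homolog_filtered_window(ds, center, "gB", w=8)
        assert [g.ordinal for g in win.members] == [6, 7, 8, 9, 11, 12, 13, 14]
        assert center not in win.members

    def test_boundary_extends_other_side(self):
        ds = identical_pair()
        center = ds.annotations["gA"].replicons["chr"][1]
        win = homolog_filtered_window(ds, center, "gB", w=8)
        assert [g.ordinal for g in win.members] == [0, 2, 3, 4, 5, 6, 7, 8]

    def test_short_replicon_truncates(self):
        ds = make_dataset({"gA": [0, 1, 2, 3, 4], "gB": [0, 1, 2, 3, 4]})
        center = ds.annotations["gA"].replicons["chr"][2]
        win = homolog_filtered_window(ds, center, "gB", w=8)
        assert [g.ordinal for g in win.members] == [0, 1, 3, 4]

    def test_skips_hogs_absent_from_other_genome(self, escherichia_like):
        ds = escherichia_like
        b2244 = gene_by_tag(ds, "b2244")
        skipped = {hog_id_for(h) for h in (3433, 3434, 3435)}
        gained = {hog_id_for(h) for h in (1862, 1863, 1864)}

        vs_ferg = homolog_filtered_window(ds, b2244, "fergusonii", w=8)
        hogs_ferg = {ds.hog_of[g] for g in vs_ferg.members}
        assert len(vs_ferg.members) == 8
        assert hogs_ferg.isdisjoint(skipped)
        assert gained <= hogs_ferg

        vs_marm = homolog_filtered_window(ds, b2244, "marmotae", w=8)
        hogs_marm = {ds.hog_of[g] for g in vs_marm.members}
        assert skipped <= hogs_marm

    def test_unassigned_genes_skipped(self):
        ds = make_dataset(
            {"gA": [0, None, 1, None, 2, 3, 4], "gB": [0, 1, 2, 3, 4]}
        )
        center = ds.annotations["gA"].replicons["chr"][4]  # hog 2
        win = homolog_filtered_window(ds, center, "gB", w=4)
        assert [ds.hog_of[g] for g in win.members] == [
            hog_id_for(h) for h in (0, 1, 3, 4)
        ]


class TestSyntenyRatio:
    def test_perfect_collinearity_scores_one(self):
        ds = identical_pair()
        a = ds.annotations["gA"].replicons["chr"][10]
        b = ds.annotations["gB"].replicons["chr"][10]
        score = synteny_ratio(ds, a, b, SyntenyParams())
        assert score.matches == 8
        assert score.ratio == 1.0
        assert score.is_syntenic

    def test_min_multiplicity_matching(self):
        # hog 1 occurs twice in window A but once in window B → one match
        ds = make_dataset(
            {
                "gA": [5, 1, ("C", "a_center"), 1, 8, 9],
                "gB": [5, 1, ("C", "b_center"), 8, 9],
            }
        )
        score = synteny_ratio(
            ds,
            gene_by_tag(ds, "a_center"),
            gene_by_tag(ds, "b_center"),
            SyntenyParams(window_size=4),
        )
        assert score.matches == 3  # hogs 5, 1, 8 — not 1 twice
        assert score.ratio == pytest.approx(0.75)

    def test_symmetry(self):
        ds = make_dataset(
            {
                "gA": [0, 1, ("C", "ca"), 2, 3, 9, 9],
                "gB": [3, 1, ("C", "cb"), 0, 9, 2, 9],
            }
        )
        params = SyntenyParams(window_size=4)
        ab = synteny_ratio(ds, gene_by_tag(ds, "ca"), gene_by_tag(ds, "cb"), params)
        ba = synteny_ratio(ds, gene_by_tag(ds, "cb"), gene_by_tag(ds, "ca"), params)
        assert (ab.matches, ab.denominator, ab.ratio) == (
            ba.matches,
            ba.denominator,
            ba.ratio,
        )

    def test_cutoff_comparison_modes_at_boundary(self):
        # 2 of 4 window genes match; 7,8 present in gA but far from ca
        ds = make_dataset(
            {
                "gA": [0, 1, ("C", "ca"), 2, 3, 7, 8],
                "gB": [0, 1, ("C", "cb"), 7, 8, 2, 3],
            }
        )
        a, b = gene_by_tag(ds, "ca"), gene_by_tag(ds, "cb")
        ge = synteny_ratio(ds, a, b, SyntenyParams(window_size=4, cutoff_cmp="ge"))
        gt = synteny_ratio(ds, a, b, SyntenyParams(window_size=4, cutoff_cmp="gt"))
        assert ge.ratio == pytest.approx(0.5)
        assert ge.is_syntenic and not gt.is_syntenic

    def test_truncation_modes_at_replicon_edge(self):
        # only 4 neighbors exist; effective mode divides by 4, fixed by w=8
        ds = make_dataset({"gA": [0, 1, ("C", "ca"), 2, 3], "gB": [0, 1, ("C", "cb"), 2, 3]})
        a, b = gene_by_tag(ds, "ca"), gene_by_tag(ds, "cb")
        eff = synteny_ratio(ds, a, b, SyntenyParams(window_size=8))
        fixed = synteny_ratio(
            ds, a, b, SyntenyParams(window_size=8, truncation_mode="fixed_denominator")
        )
        assert (eff.matches, eff.denominator, eff.ratio) == (4, 4, 1.0)
        assert (fixed.matches, fixed.denominator, fixed.ratio) == (4, 8, 0.5)
        # fixed mode leaves the edge pair exactly at the cutoff: the strict
        # comparison rejects it, the inclusive default keeps it
        strict = synteny_ratio(
            ds,
            a,
            b,
            SyntenyParams(
                window_size=8, truncation_mode="fixed_denominator", cutoff_cmp="gt"
            ),
        )
        assert eff.is_syntenic and fixed.is_syntenic and not strict.is_syntenic

    def test_same_genome_pair_rejected(self):
        ds = identical_pair()
        a, b = ds.annotations["gA"].replicons["chr"][:2]
        with pytest.raises(ValueError, match="across genomes"):
            synteny_ratio(ds, a, b, SyntenyParams())


class TestParams:
    @pytest.mark.parametrize("w", [0, 1, 3, 7, -2])
    def test_odd_or_nonpositive_window_rejected(self, w):
        with pytest.raises(ValueError):
            SyntenyParams(window_size=w)

    @pytest.mark.parametrize("cutoff", [0.0, -0.1, 1.2])
    def test_cutoff_out_of_range_rejected(self, cutoff):
        with pytest.raises(ValueError):
            SyntenyParams(synteny_ratio_cutoff=cutoff)

    def test_distant_genome_regime_accepted(self):
        p = SyntenyParams(window_size=30, synteny_ratio_cutoff=0.2)
        assert p.window_size == 30


class TestEvaluateHog:
    def test_single_copy_hogs_gated_by_run_all(self):
        ds = make_dataset(
            {"gA": list(range(9)), "gB": list(range(9)), "gC": list(range(9))}
        )
        hog = hog_id_for(4)
        default = evaluate_hog(ds, hog, SyntenyParams())
        assert default.outcome is Outcome.NOT_ANALYZED
        all_hogs = evaluate_hog(ds, hog, SyntenyParams(run_all_hogs=True))
        assert all_hogs.outcome is Outcome.CONFIRMED
        assert len(all_hogs.sogs) == 1
        assert all_hogs.sogs[0].n_genomes == 3

    def test_single_genome_hog_not_analyzed(self):
        ds = make_dataset({"gA": [0, 1, 7, 2, 3], "gB": [0, 1, 2, 3]})
        result = evaluate_hog(ds, hog_id_for(7), SyntenyParams(run_all_hogs=True))
        assert result.outcome is Outcome.NOT_ANALYZED

    def test_tandem_duplicates_join_one_sog_transitively(self):
        # two adjacent same-HOG copies in gA both syntenic to the one gB gene
        ds = make_dataset(
            {
                "gA": [1, 2, ("T", "a_t1"), ("T", "a_t2"), 3, 4],
                "gB": [1, 2, ("T", "b_t"), 3, 4],
            }
        )
        result = evaluate_hog(ds, "T", SyntenyParams(window_size=4))
        assert result.outcome is Outcome.CONFIRMED
        assert len(result.sogs) == 1
        sog = result.sogs[0]
        assert {g.locus_tag for g in sog.members} == {"a_t1", "a_t2", "b_t"}
        assert sog.has_paralogs

    def test_paralog_in_foreign_context_excluded(self):
        # gA's second copy sits in a neighborhood gB also has — but far from
        # gB's copy, so it gains no syntenic partner and is excluded.
        ds = make_dataset(
            {
                "gA": [1, 2, ("T", "a_true"), 3, 4, 5, 6, 7, 8, ("T", "a_par"), 9, 10],
                "gB": [1, 2, ("T", "b_t"), 3, 4, 5, 6, 7, 8, 9, 10],
            }
        )
        result = evaluate_hog(ds, "T", SyntenyParams(window_size=4))
        assert result.outcome is Outcome.MODIFIED
        assert [g.locus_tag for g in result.excluded] == ["a_par"]
        assert {g.locus_tag for g in result.sogs[0].members} == {"a_true", "b_t"}

    def test_partition_law(self, escherichia_like):
        for hog in ("N0.HOG0000019", "N0.HOG0000021"):
            result = evaluate_hog(escherichia_like, hog, SyntenyParams())
            in_sogs = [g for s in result.sogs for g in s.members]
            assert len(in_sogs) + len(result.excluded) == len(
                escherichia_like.members_of[hog]
            )
            assert set(in_sogs).isdisjoint(result.excluded)
            assert set(in_sogs) | set(result.excluded) == set(
                escherichia_like.members_of[hog]
            )

    def test_cutoff_monotonicity(self, escherichia_like):
        # lowering the cutoff can only add edges: SOGs merge or grow
        hogs = ("N0.HOG0000019", "N0.HOG0000021")
        for hog in hogs:
            prev_excluded = None
            for cutoff in (1.0, 0.75, 0.5, 0.25):
                r = evaluate_hog(
                    escherichia_like, hog, SyntenyParams(synteny_ratio_cutoff=cutoff)
                )
                excluded = {g.key for g in r.excluded}
                if prev_excluded is not None:
                    assert excluded <= prev_excluded
                prev_excluded = excluded


class TestRefineAll:
    def test_empty_table(self):
        ds = make_dataset({"gA": [None], "gB": [None]})
        assert refine_all(ds, SyntenyParams()) == []

    def test_identical_genomes_all_confirmed(self):
        ds = identical_pair()
        results = refine_all(ds, SyntenyParams(run_all_hogs=True))
        assert len(results) == 20
        assert all(r.outcome is Outcome.CONFIRMED for r in results)

    def test_results_independent_of_order(self, escherichia_like):
        params = SyntenyParams()
        twice = [refine_all(escherichia_like, params) for _ in range(2)]
        for r1, r2 in zip(*twice):
            assert r1.outcome == r2.outcome
            assert [s.members for s in r1.sogs] == [s.members for s in r2.sogs]
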