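"""Copy-number matrices, the conservation filter and enrichment testing."""
import math
from fractions import Fraction

import numpy as np
import pytest

from avinc.conservation import (
    absence_report,
    build_matrix,
    conservation_cutoff,
    export_heatmap,
    filter_conserved,
    fisher_exact_2x2,
    flag_missing,
    microchromosome_enrichment,
    read_heatmap_tsv,
)
from avinc.model import Annotation, ConservationConfig


def make_ann(genome, family, rna_class="microRNA", scaffold="s1", start=0, end=100):
    return Annotation(genome, scaffold, family, start, end, "+", 50.0, 1e-6, rna_class)


def hypergeom_fisher(a, b, c, d, sidedness="greater"):
    """Exact-rational oracle by enumeration of the hypergeometric support."""
    row1, row2, col1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = math.comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return Fraction(0)
        return Fraction(math.comb(row1, x) * math.comb(row2, col1 - x), denom)

    support = range(max(0, col1 - row2), min(row1, col1) + 1)
    p_obs = prob(a)
    if sidedness == "greater":
        return sum(prob(x) for x in support if x >= a)
    if sidedness == "less":
        return sum(prob(x) for x in support if x <= a)
    return sum(p for p in (prob(x) for x in support) if p <= p_obs)


class TestBuildMatrix:
    def test_zero_matrix_over_declared_families(self):
        mat = build_matrix({"gA": [], "gB": []}, families={"RF1": "rRNA"})
        assert mat.counts.shape == (1, 2)
        assert int(mat.counts.values.sum()) == 0
        assert mat.classes["RF1"] == "rRNA"

    def test_counts_per_genome(self):
        anns = {"gA": [make_ann("gA", "RF1")] * 3, "gB": []}
        mat = build_matrix(anns)
        assert list(mat.counts.loc["RF1"]) == [3, 0]

    def test_column_sums_equal_annotation_counts(self):
        rng = np.random.default_rng(2)
        anns = {
            f"g{i}": [make_ann(f"g{i}", f"RF{int(rng.integers(0, 5))}")
                      for _ in range(int(rng.integers(0, 10)))]
            for i in range(4)
        }
        mat = build_matrix(anns)
        for g, a in anns.items():
            assert int(mat.counts[g].sum()) == len(a)

    def test_planted_counts_recovered(self):
        planted = {("RF1", "gA"): 3, ("RF1", "gB"): 1, ("RF2", "gA"): 2}
        anns = {"gA": [], "gB": []}
        for (fam, g), k in planted.items():
            anns[g].extend(make_ann(g, fam, start=i * 200, end=i * 200 + 100)
                           for i in range(k))
        mat = build_matrix(anns)
        for (fam, g), k in planted.items():
            assert mat.counts.at[fam, g] == k


class TestFilterConserved:
    def _matrix(self, presence, n_genomes=48):
        """presence: family -> number of genomes with one copy."""
        genomes = [f"g{i}" for i in range(n_genomes)]
        anns = {g: [] for g in genomes}
        for fam, k in presence.items():
            for g in genomes[:k]:
                anns[g].append(make_ann(g, fam))
        return build_matrix(anns, families={f: "microRNA" for f in presence})

    def test_ten_percent_of_48_needs_5_genomes(self):
        mat = self._matrix({"low": 4, "high": 5})
        kept, removed = filter_conserved(mat)
        assert kept.families == ["high"]
        assert removed == ["low"]

    def test_fraction_one_keeps_only_universal(self):
        mat = self._matrix({"every": 48, "almost": 47})
        kept, _ = filter_conserved(mat, ConservationConfig(min_genome_fraction=1.0))
        assert kept.families == ["every"]

    def test_ubiquitous_family_always_retained(self):
        mat = self._matrix({"every": 48})
        for frac in (0.01, 0.1, 0.5, 1.0):
            kept, _ = filter_conserved(mat, ConservationConfig(min_genome_fraction=frac))
            assert kept.families == ["every"]

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(3)
        mat = self._matrix({f"F{i}": int(rng.integers(0, 49)) for i in range(20)})
        previous = None
        for frac in (0.05, 0.1, 0.25, 0.5, 1.0):
            kept, _ = filter_conserved(mat, ConservationConfig(min_genome_fraction=frac))
            families = set(kept.families)
            if previous is not None:
                assert families <= previous
            previous = families

    def test_cutoff_float_artefacts(self):
        # 0.1 * 30 is 3.0000000000000004 in binary floating point
        assert conservation_cutoff(30, 0.1) == 3
        assert conservation_cutoff(48, 0.1) == 5
        assert conservation_cutoff(10, 0.1) == 1

    def test_total_conserved_under_family_filter(self):
        mat = self._matrix({"low": 4, "high": 20})
        kept, _ = filter_conserved(mat)
        assert int(kept.counts.values.sum()) == 20


class TestAbsenceReport:
    def test_avian_absent_flag(self):
        mat = build_matrix({"gA": [], "gB": []}, families={"RF1": "rRNA"})
        report = absence_report(mat, outgroup_presence={"RF1": {"alligator"}})
        assert bool(report.loc["RF1", "avian_absent"])
        assert not bool(report.loc["RF1", "patchy"])

    def test_patchy_flag(self):
        mat = build_matrix({"gA": [make_ann("gA", "RF1")], "gB": []})
        report = absence_report(mat)
        assert bool(report.loc["RF1", "patchy"])
        assert not bool(report.loc["RF1", "avian_absent"])

    def test_ubiquitous_family_unflagged(self):
        mat = build_matrix(
            {"gA": [make_ann("gA", "RF1")], "gB": [make_ann("gB", "RF1")]}
        )
        report = absence_report(mat)
        assert not bool(report.loc["RF1", "avian_absent"])
        assert not bool(report.loc["RF1", "patchy"])


class TestFisherExact:
    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(0, 0, 3, 7).p_value == pytest.approx(1.0)

    def test_known_table_17_over_70(self):
        t = fisher_exact_2x2(3, 1, 1, 3, sidedness="greater")
        assert t.p_value == pytest.approx(17 / 70, rel=1e-9)

    def test_endpoint_table(self):
        t = fisher_exact_2x2(10, 0, 0, 10, sidedness="greater")
        assert t.p_value == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert t.odds_ratio == math.inf

    def test_all_zero_table_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_odds_ratio_sample_estimate(self):
        assert fisher_exact_2x2(6, 2, 3, 4).odds_ratio == pytest.approx(4.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            cells = [int(x) for x in rng.integers(0, 11, size=4)]
            if sum(cells) == 0:
                continue
            for side in ("greater", "two-sided"):
                got = fisher_exact_2x2(*cells, sidedness=side).p_value
                want = float(hypergeom_fisher(*cells, sidedness=side))
                assert got == pytest.approx(want, rel=1e-7, abs=1e-12), (cells, side)

    def test_one_sided_p_non_increasing_in_enrichment_cell(self):
        # shift mass onto the diagonal at fixed margins
        ps = []
        for a in range(0, 6):
            b, c, d = 5 - a, 5 - a, a
            ps.append(fisher_exact_2x2(a + 5, b, c, d + 5, "greater").p_value)
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


class TestMicrochromosomeEnrichment:
    def test_paper_like_pattern_cell_a(self):
        chrom = {f"mi{i}": "micro" for i in range(10)}
        chrom.update({f"ma{i}": "macro" for i in range(10)})
        missing = {f"M{i}": f"mi{i}" for i in range(6)}
        missing["M6"] = "ma0"  # the one missing family on a macrochromosome
        everything = dict(missing)
        for i in range(20):
            everything[f"P{i}"] = f"ma{i % 10}" if i < 16 else f"mi{i % 10}"
        t = microchromosome_enrichment(missing, everything, chrom)
        assert (t.a, t.b) == (6, 1)

    def test_balanced_background_not_significant(self):
        chrom = {"mi": "micro", "ma": "macro"}
        missing = {"M1": "mi", "M2": "ma"}
        everything = dict(missing)
        everything.update({"P1": "mi", "P2": "ma"})
        t = microchromosome_enrichment(missing, everything, chrom)
        assert t.p_value > 0.5

    def test_unassigned_scaffolds_excluded_and_empty_is_error(self):
        with pytest.raises(ValueError):
            microchromosome_enrichment({"M1": "sX"}, {"M1": "sX"}, {})

    def test_planted_effect_rejects(self):
        from avinc.conservation import ConservationConfig  # noqa: F401
        from avinc.simulate import SimConfig, simulate

        sim = simulate(SimConfig(n_genomes=24, seed=12))
        truth = sim.truth
        missing = {f: truth.reference_scaffold[f] for f in truth.missing_families
                   if f in truth.reference_scaffold}
        everything = dict(truth.reference_scaffold)
        t = microchromosome_enrichment(missing, everything, sim.chrom_classes)
        assert t.p_value < 0.01

    def test_type_one_error_controlled_under_null(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            chrom = {"mi": "micro", "ma": "macro"}
            fams = [f"F{i}" for i in range(30)]
            loci = {f: ("mi" if rng.random() < 0.4 else "ma") for f in fams}
            missing = {f: loci[f] for f in fams[:7]}  # placement independent of class
            t = microchromosome_enrichment(missing, loci, chrom)
            rejections += t.p_value <= 0.05
        # Fisher's exact test is conservative; allow binomial slack above alpha
        assert rejections / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestHeatmapExport:
    def test_zero_matrix_round_trip(self):
        mat = build_matrix({"gA": [], "gB": []}, families={"RF1": "rRNA"})
        back = read_heatmap_tsv(export_heatmap(mat))
        assert back.counts.equals(mat.counts)
        assert back.classes == mat.classes

    def test_grouping_preserves_within_class_order(self):
        fams = {"A1": "x", "B1": "y", "A2": "x", "B2": "y"}
        mat = build_matrix({"g": []}, families=fams)
        lines = export_heatmap(mat, group_by_class=True).splitlines()[1:]
        assert [l.split("\t")[0] for l in lines] == ["A1", "A2", "B1", "B2"]

    def test_round_trip_nontrivial(self):
        anns = {"gA": [make_ann("gA", "RF1")] * 2, "gB": [make_ann("gB", "RF2", "rRNA")]}
        mat = build_matrix(anns)
        back = read_heatmap_tsv(export_heatmap(mat))
        assert back.counts.loc["RF1", "gA"] == 2
        assert int(back.counts.values.sum()) == int(mat.counts.values.sum())
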