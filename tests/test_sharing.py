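import numpy as np
import pytest

from tcrnet import (
    CategoryScheme,
    Clonotype,
    Cohort,
    Repertoire,
    build_network,
    cross_species_sharing,
    cs_public,
    cumulative_frequency,
    degree_sharing_correlation,
    abundance_degree_r2,
    frequency_by_sharing_profile,
    sharing_levels,
    top_n,
)
from tcrnet.sharing import SharingTable, mean_degree_by_sharing, write_sharing_table

from oracles import brute_force_sharing, pearson_correlation, rank_based_correlation


def _cohort(members, name="c", species="x"):
    reps = [Repertoire(f"i{k}", [Clonotype(aa, 1) for aa in seqs])
            for k, seqs in enumerate(members)]
    return Cohort(name=name, repertoires=reps, species=species)


class TestSharingLevels:
    def test_public_and_private(self):
        cohort = _cohort([{"CASSF", "CAAAF"}, {"CASSF"}, {"CASSF"}])
        table = sharing_levels(cohort)
        assert table.level("CASSF") == 3
        assert table.level("CAAAF") == 1
        assert table.level("CWWWF") == 0

    def test_matches_brute_force_scan(self, small_cohort, rng):
        universe = sorted(small_cohort.universe)
        probes = list(rng.choice(universe, size=100, replace=False))
        table = sharing_levels(small_cohort, seqs=probes)
        for aa in probes:
            assert table.level(aa) == brute_force_sharing(small_cohort, aa)

    def test_bounded_by_cohort_size(self, small_cohort):
        table = sharing_levels(small_cohort)
        assert all(1 <= s <= len(small_cohort) for s in table.levels.values())

    def test_abundance_rescaling_invariance(self, small_cohort):
        scaled = Cohort(
            "scaled",
            [Repertoire(r.individual_id,
                        [Clonotype(c.cdr3_aa, c.total_count * 7) for c in r])
             for r in small_cohort],
            species=small_cohort.species,
        )
        assert sharing_levels(small_cohort).levels == sharing_levels(scaled).levels

    def test_leave_self_out(self):
        cohort = _cohort([{"CASSF"}, {"CASSF"}, {"CAAAF"}])
        table = sharing_levels(cohort, leave_out="i0")
        assert table.cohort_size == 2
        assert table.level("CASSF") == 1

    def test_min_count_floor(self):
        rep1 = Repertoire("a", [Clonotype("CASSF", 1)])
        rep2 = Repertoire("b", [Clonotype("CASSF", 10)])
        cohort = Cohort("c", [rep1, rep2])
        assert sharing_levels(cohort, min_count=2).level("CASSF") == 1

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            sharing_levels(Cohort("empty", []))


class TestCrossSpecies:
    def test_disjoint_cohorts(self):
        a = _cohort([{"CAAAF"}, {"CAADF"}])
        b = _cohort([{"CWWWF"}])
        res = cross_species_sharing(a, b)
        assert res.intersection == set()
        assert all(f == 0.0 for f in res.fraction_by_level.values())

    def test_superset_cohort(self):
        a = _cohort([{"CAAAF", "CAADF"}, {"CAAAF"}])
        b = _cohort([{"CAAAF", "CAADF", "CWWWF"}])
        res = cross_species_sharing(a, b)
        assert all(f == 1.0 for f in res.fraction_by_level.values())
        assert res.intersection == {"CAAAF", "CAADF"}

    def test_fraction_increases_with_sharing_on_synthetic_cohorts(
            self, small_cohort, small_human_cohort):
        res = cross_species_sharing(small_cohort, small_human_cohort)
        levels = sorted(res.fraction_by_level)
        fractions = [res.fraction_by_level[s] for s in levels]
        assert rank_based_correlation(levels, fractions) > 0


class TestCsPublic:
    def test_meets_both_thresholds(self):
        ta = SharingTable({"CASSF": 26, "CAAAF": 28}, cohort_size=28)
        tb = SharingTable({"CASSF": 11, "CAAAF": 10}, cohort_size=11)
        assert cs_public(ta, tb) == {"CASSF"}

    def test_threshold_exceeding_cohort_errors(self):
        ta = SharingTable({}, cohort_size=10)
        tb = SharingTable({}, cohort_size=11)
        with pytest.raises(ValueError):
            cs_public(ta, tb, CategoryScheme(public_min_a=25, public_min_b=11))

    def test_monotone_in_thresholds(self, small_cohort, small_human_cohort):
        ta = sharing_levels(small_cohort)
        tb = sharing_levels(small_human_cohort)
        loose = cs_public(ta, tb, CategoryScheme(public_min_a=3, public_min_b=2))
        tight = cs_public(ta, tb, CategoryScheme(public_min_a=5, public_min_b=4))
        assert tight <= loose

    def test_subset_of_single_species_public_sets(self):
        ta = SharingTable({"CAAAF": 28, "CAADF": 25}, cohort_size=28)
        tb = SharingTable({"CAAAF": 11, "CWWWF": 11}, cohort_size=11)
        scheme = CategoryScheme()
        cs = cs_public(ta, tb, scheme)
        assert cs <= ta.sequences_at_least(25) & tb.sequences_at_least(11)

    def test_category_partition(self):
        scheme = CategoryScheme()
        assert scheme.category(26, 11) == "cs_public"
        assert scheme.category(28, 10) == "public_a_only"
        assert scheme.category(2, 11) == "public_b_only"
        assert scheme.category(24, 10) == "not_public"


class TestFrequencies:
    def test_all_sequences_sum_to_one(self, toy_repertoire):
        assert cumulative_frequency(toy_repertoire, toy_repertoire.sequences) == \
            pytest.approx(1.0)

    def test_disjoint_is_zero(self, toy_repertoire):
        assert cumulative_frequency(toy_repertoire, {"CWWWF"}) == 0.0

    def test_arithmetic(self):
        rep = Repertoire("r", [Clonotype("CA", 6), Clonotype("CD", 3), Clonotype("CC", 1)])
        assert cumulative_frequency(rep, {"CA", "CC"}) == pytest.approx(0.7)

    def test_profile_all_private(self):
        rep = Repertoire("r", [Clonotype("CAAAF", 2), Clonotype("CAADF", 3)])
        table = SharingTable({"CAAAF": 1, "CAADF": 1}, cohort_size=3)
        profile = frequency_by_sharing_profile(rep, table)
        assert profile[1] == pytest.approx(1.0)
        assert sum(profile.values()) == pytest.approx(1.0)

    def test_profile_mass_conservation(self, small_repertoire, small_cohort):
        table = sharing_levels(small_cohort)
        sub = top_n(small_repertoire, 300)
        profile = frequency_by_sharing_profile(sub, table)
        assert sum(profile.values()) == pytest.approx(sub.accumulated_frequency())


class TestCorrelations:
    def _net_with_sharing(self, degrees_equal_sharing=True):
        # path of 4 nodes: degrees 1,2,2,1
        seqs = ["CAAAA", "CAAAD", "CAADD", "CADDD"]
        net = build_network(set(seqs))
        deg = {s: net.degree(s) for s in seqs}
        levels = deg if degrees_equal_sharing else {s: 1 for s in seqs}
        return net, SharingTable(dict(levels), cohort_size=28)

    def test_perfect_correlation(self):
        net, table = self._net_with_sharing()
        res = degree_sharing_correlation(net, table)
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        net, table = self._net_with_sharing(degrees_equal_sharing=False)
        res = degree_sharing_correlation(net, table)
        assert not res.defined

    def test_permuted_sharing_uncorrelated(self, small_repertoire, rng):
        sub = top_n(small_repertoire, 1000)
        net = build_network(sub.sequences)
        nodes = sorted(net.nodes)
        rs = []
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(len(nodes))
            table = SharingTable(
                {n: int(1 + perm[i] % 28) for i, n in enumerate(nodes)}, 28)
            rs.append(degree_sharing_correlation(net, table).r)
        assert all(abs(r) < 0.1 for r in rs)

    def test_agrees_with_independent_formulas(self, rng):
        seqs = ["CAAAA", "CAAAD", "CAADD", "CADDD", "CWWWW", "CWWWY"]
        net = build_network(set(seqs))
        levels = {s: int(v) for s, v in zip(seqs, rng.integers(1, 29, len(seqs)))}
        table = SharingTable(levels, cohort_size=28)
        nodes = sorted(net.nodes)
        deg = [net.degree(n) for n in nodes]
        sh = [table.level(n) for n in nodes]
        r_p = degree_sharing_correlation(net, table, "pearson").r
        r_s = degree_sharing_correlation(net, table, "spearman").r
        assert r_p == pytest.approx(pearson_correlation(deg, sh), abs=1e-12)
        assert r_s == pytest.approx(rank_based_correlation(deg, sh), abs=1e-12)

    def test_abundance_degree_r2_range(self, small_repertoire):
        sub = top_n(small_repertoire, 800)
        from tcrnet import network_from_repertoire

        net = network_from_repertoire(sub)
        r2 = abundance_degree_r2(net)
        assert 0.0 <= r2 <= 1.0


class TestExports:
    def test_sharing_table_tsv(self, tmp_path):
        ta = SharingTable({"CASSF": 26}, cohort_size=28)
        tb = SharingTable({"CASSF": 11}, cohort_size=11)
        path = tmp_path / "sharing.tsv"
        write_sharing_table(path, {"CASSF"}, ta, tb)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["cdr3_aa", "s_a", "N_a", "s_b", "N_b", "category"]
        assert lines[1].split("\t") == ["CASSF", "26", "28", "11", "11", "cs_public"]

    def test_mean_degree_by_sharing_shape(self, small_repertoire, small_cohort):
        table = sharing_levels(small_cohort)
        net = build_network(top_n(small_repertoire, 300).sequences)
        md = mean_degree_by_sharing(net, table)
        assert set(md) <= set(range(0, len(small_cohort) + 1))
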