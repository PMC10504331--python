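"""SNV calling, matrix construction, clustering and substitution estimates."""

import math

import numpy as np
import pytest

import pelagiscope as pg
from pelagiscope import popgen, synthetic as syn
from pelagiscope.coverage_hvr import CoverageProfile
from pelagiscope.popgen import SNVRecord


def make_pileup(length, depth, ref_codes, variant_sites=None):
    """Monomorphic pileup at the reference base, with optional variants.

    ``variant_sites`` maps position -> (alt_code, alt_count).
    """
    counts = np.zeros((length, 4), dtype=int)
    counts[np.arange(length), ref_codes] = depth
    for pos, (alt, n_alt) in (variant_sites or {}).items():
        counts[pos, ref_codes[pos]] -= n_alt
        counts[pos, alt] += n_alt
    return counts


@pytest.fixture(scope="module")
def ref100():
    return pg.simulate_genome(100, 0.5, seed=81, genome_id="R")


class TestCallSnvs:
    def test_departure_above_threshold_is_called(self, ref100):
        codes = syn.encode_sequence(ref100.sequence)
        alt = (codes[7] + 1) % 4
        pileup = make_pileup(100, 10, codes, {7: (alt, 2)})
        snvs = pg.call_snvs(pileup, ref100, sample_id="s")
        assert [(s.position, s.coverage, s.departure) for s in snvs] == \
            [(7, 10, pytest.approx(0.2))]

    def test_low_coverage_position_filtered(self, ref100):
        codes = syn.encode_sequence(ref100.sequence)
        pileup = make_pileup(100, 0, codes)
        pileup[3] = [1, 2, 0, 0]  # coverage 3 < 10
        assert pg.call_snvs(pileup, ref100) == []

    def test_departure_below_threshold_filtered(self, ref100):
        codes = syn.encode_sequence(ref100.sequence)
        alt = (codes[5] + 1) % 4
        pileup = make_pileup(100, 100, codes, {5: (alt, 5)})  # departure 0.05
        assert pg.call_snvs(pileup, ref100) == []

    def test_departure_bounded_by_three_quarters(self, ref100):
        codes = syn.encode_sequence(ref100.sequence)
        pileup = make_pileup(100, 0, codes)
        pileup[0] = [25, 25, 25, 25]
        snvs = pg.call_snvs(pileup, ref100)
        assert snvs[0].departure == pytest.approx(0.75)

    def test_downsampling_preserves_departure_in_expectation(self, ref100):
        """Binomially thinning a pileup leaves departure unchanged on average."""
        rng = np.random.default_rng(82)
        codes = syn.encode_sequence(ref100.sequence)
        alt = (codes[11] + 1) % 4
        pileup = make_pileup(100, 1000, codes, {11: (alt, 300)})
        downs = []
        for _ in range(200):
            thin = rng.binomial(pileup, 0.1)
            cov = thin[11].sum()
            downs.append(1 - thin[11].max() / cov)
        se = math.sqrt(0.3 * 0.7 / 100) / math.sqrt(200)
        assert abs(np.mean(downs) - 0.30) < 4 * se

    def test_planted_divergent_sites_recovered(self, ref100):
        """A 50/50 two-strain mixture flags exactly the planted sites."""
        ref = pg.simulate_genome(2000, 0.4, seed=83, genome_id="A")
        rng = np.random.default_rng(84)
        planted = np.sort(rng.choice(2000, size=20, replace=False))
        codes = syn.encode_sequence(ref.sequence)
        strain_codes = codes.copy()
        strain_codes[planted] = (strain_codes[planted] + 1) % 4
        strain = pg.Genome(id="A|s2",
                           sequence=syn.decode_sequence(strain_codes))
        hits = 0
        for rep in range(10):
            comm = pg.CommunityDesign("S", {}, {"A": 1.0})
            reads, _ = syn.simulate_reads(
                comm, {"A": ref}, {"A": [ref, strain]}, 2000, 100, 0.0,
                seed=850 + rep)  # ~100x mean coverage
            pileup = np.zeros((2000, 4), dtype=int)
            for r in reads:
                rc = syn.encode_sequence(r.sequence)
                for off, c in enumerate(rc):
                    pileup[r.start + off, c] += 1
            snvs = pg.call_snvs(pileup, ref, min_position_coverage=50)
            called = {s.position for s in snvs}
            if set(planted) <= called:
                hits += 1
            assert called <= set(planted)  # no false positives possible
        assert hits >= 9


class TestBuildSnvMatrix:
    @staticmethod
    def flat_profile(sample, length=1000, depth=50, covered=1.0):
        d = np.full(length, depth)
        n_zero = int(round((1 - covered) * length))
        if n_zero:
            d[-n_zero:] = 0
        return CoverageProfile(genome_id="A", sample_id=sample, depth=d)

    @staticmethod
    def snv(sample, pos, departure=0.2, coverage=50):
        counts = [0, 0, 0, 0]
        counts[0] = int(coverage * (1 - departure))
        counts[1] = coverage - counts[0]
        return SNVRecord(sample_id=sample, position=pos, coverage=coverage,
                         base_counts=tuple(counts), departure=departure)

    def test_bookkeeping_22_samples_461_positions(self):
        """22 retained metagenomes x 461 SNV positions = 10,142 entries."""
        samples = [f"m{i:02d}" for i in range(22)]
        profiles = {s: self.flat_profile(s) for s in samples}
        snvs = {s: [self.snv(s, p) for p in range(461)] for s in samples}
        matrix = pg.build_snv_matrix(snvs, profiles)
        assert matrix.values.shape == (22, 461)
        assert matrix.n_entries == 10_142

    def test_sample_below_breadth_cutoff_excluded(self):
        profiles = {"good": self.flat_profile("good", covered=0.71),
                    "bad": self.flat_profile("bad", covered=0.69)}
        snvs = {"good": [self.snv("good", 5)], "bad": [self.snv("bad", 5)]}
        matrix = pg.build_snv_matrix(snvs, profiles)
        assert matrix.samples == ("good",)

    def test_no_snvs_gives_zero_columns(self):
        profiles = {"s": self.flat_profile("s")}
        matrix = pg.build_snv_matrix({"s": []}, profiles)
        assert matrix.values.shape == (1, 0)

    def test_covered_invariant_position_is_zero_undercovered_is_nan(self):
        p1 = self.flat_profile("s1")
        d2 = np.full(1000, 50)
        d2[7] = 3  # below the per-position floor in s2
        p2 = CoverageProfile(genome_id="A", sample_id="s2", depth=d2)
        snvs = {"s1": [self.snv("s1", 7)], "s2": []}
        matrix = pg.build_snv_matrix(snvs, {"s1": p1, "s2": p2})
        assert matrix.positions == (7,)
        assert matrix.values[0, 0] == pytest.approx(0.2)
        assert np.isnan(matrix.values[1, 0])

    def test_entry_count_is_samples_times_positions(self):
        samples = [f"s{i}" for i in range(5)]
        profiles = {s: self.flat_profile(s) for s in samples}
        snvs = {s: [self.snv(s, p) for p in range(i + 1)]
                for i, s in enumerate(samples)}
        matrix = pg.build_snv_matrix(snvs, profiles)
        assert matrix.n_entries == len(matrix.samples) * len(matrix.positions)
        assert matrix.values.size == matrix.n_entries


class TestClusterSnvProfiles:
    def test_identical_rows_cluster_together(self):
        matrix = pg.SNVMatrix(samples=("a", "b"), positions=(0, 1),
                              values=np.array([[0.2, 0.3], [0.2, 0.3]]))
        Z, labels = pg.cluster_snv_profiles(matrix, k=1)
        assert Z[0, 2] == 0.0  # merge distance zero
        assert labels == {"a": 1, "b": 1}

    def test_outlier_row_separates(self):
        matrix = pg.SNVMatrix(samples=("a", "b", "c"), positions=(0,),
                              values=np.array([[0.0], [0.0], [10.0]]))
        _, labels = pg.cluster_snv_profiles(matrix, k=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_planted_populations_recovered(self):
        """Polar-like vs tropical-like allele frequencies split at k=2."""
        rng = np.random.default_rng(86)
        n_pos = 40
        polar_freq = rng.uniform(0.3, 0.6, size=n_pos)
        tropical_freq = np.zeros(n_pos)
        rows, names = [], []
        for i in range(6):
            base = polar_freq if i < 3 else tropical_freq
            noisy = np.clip(base + rng.normal(0, 0.03, size=n_pos), 0, 0.75)
            rows.append(noisy)
            names.append(("polar" if i < 3 else "trop") + str(i))
        matrix = pg.SNVMatrix(samples=tuple(names),
                              positions=tuple(range(n_pos)),
                              values=np.array(rows))
        _, labels = pg.cluster_snv_profiles(matrix, k=2)
        polar_labels = {labels[s] for s in names[:3]}
        trop_labels = {labels[s] for s in names[3:]}
        assert len(polar_labels) == len(trop_labels) == 1
        assert polar_labels != trop_labels

    def test_single_sample_rejected(self):
        matrix = pg.SNVMatrix(samples=("a",), positions=(0,),
                              values=np.array([[0.1]]))
        with pytest.raises(ValueError):
            pg.cluster_snv_profiles(matrix, k=2)

    def test_isolate_pseudo_profiles_join_the_clustering(self, ref100):
        codes = syn.encode_sequence(ref100.sequence)
        mutated = codes.copy()
        mutated[[3, 8]] = (mutated[[3, 8]] + 1) % 4
        isolate = pg.Genome(id="iso", sequence=syn.decode_sequence(mutated))
        prof = popgen.isolate_pseudo_profile(isolate, ref100,
                                             positions=[3, 5, 8])
        assert prof.tolist() == [1.0, 0.0, 1.0]

    def test_newick_serialisation_round_trips_leaf_names(self):
        matrix = pg.SNVMatrix(samples=("a", "b", "c"), positions=(0,),
                              values=np.array([[0.0], [0.1], [5.0]]))
        Z, _ = pg.cluster_snv_profiles(matrix)
        nwk = popgen.dendrogram_to_newick(Z, list(matrix.samples))
        assert nwk.endswith(";")
        for name in ("a", "b", "c"):
            assert name in nwk


class TestMixtureRecovery:
    def test_mixing_fraction_from_mean_departure(self):
        """A 30/70 strain mixture is read back from departure at planted sites."""
        ref = pg.simulate_genome(2000, 0.4, seed=87, genome_id="A")
        codes = syn.encode_sequence(ref.sequence)
        planted = np.arange(100, 2000, 100)
        minor_codes = codes.copy()
        minor_codes[planted] = (minor_codes[planted] + 1) % 4
        minor = pg.Genome(id="A|minor",
                          sequence=syn.decode_sequence(minor_codes))
        comm = pg.CommunityDesign("S", {}, {"A": 1.0})
        # 3:7 strain list → minor fraction 0.3 at ~100x coverage
        strains = [minor] * 3 + [ref] * 7
        reads, _ = syn.simulate_reads(comm, {"A": ref}, {"A": strains},
                                      2000, 100, 0.0, seed=88)
        pileup = np.zeros((2000, 4), dtype=int)
        for r in reads:
            rc = syn.encode_sequence(r.sequence)
            pileup[r.start:r.start + 100][np.arange(100), rc] += 1
        snvs = pg.call_snvs(pileup, ref, min_position_coverage=50)
        by_pos = {s.position: s.departure for s in snvs}
        mean_dep = np.mean([by_pos.get(p, 0.0) for p in planted])
        assert abs(mean_dep - 0.30) < 0.05


class TestSubstitutionAccumulation:
    def test_per_year_bounds_match_reported_estimate(self):
        est = pg.substitution_accumulation(1e-6, 1e-4, 35392)
        assert round(est.subs_low, 2) == 0.04
        assert round(est.subs_high, 1) == 3.5

    def test_thousand_year_bounds(self):
        est = pg.substitution_accumulation(1e-6, 1e-4, 35392, years=1000)
        assert est.subs_low == pytest.approx(35.392)
        assert est.subs_high == pytest.approx(3539.2)

    def test_zero_years(self):
        est = pg.substitution_accumulation(1e-6, 1e-4, 35392, years=0)
        assert est.subs_low == est.subs_high == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pg.substitution_accumulation(-1e-6, 1e-4, 35392)
        with pytest.raises(ValueError):
            pg.substitution_accumulation(1e-4, 1e-6, 35392)
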