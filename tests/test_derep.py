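"""Quality filtering, sketch ANI and greedy species clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panprop import synthetic as syn
from panprop.derep import (
    AniEstimate,
    GenomeRecord,
    cluster_genomes,
    estimate_ani,
    estimate_ani_matrix,
    quality_filter,
    select_representative,
)


def _g(gid, comp=1.0, cont=0.0):
    return GenomeRecord(genome_id=gid, completeness=comp, contamination=cont)


class TestQualityFilter:
    def test_strict_boundaries(self):
        # exactly at the thresholds means excluded ("higher than" / "lower than")
        genomes = [_g("at_comp", 0.50, 0.01), _g("at_cont", 0.9, 0.10),
                   _g("interior", 0.51, 0.09)]
        kept = quality_filter(genomes)
        assert [g.genome_id for g in kept] == ["interior"]

    def test_empty_input(self):
        assert quality_filter([]) == []

    def test_missing_metric_names_genome(self):
        with pytest.raises(ValueError, match="gX.*completeness"):
            quality_filter([GenomeRecord(genome_id="gX", contamination=0.0)])


class TestEstimateAni:
    def test_identical_sequences(self):
        seq = syn.random_sequence(20_000, 1)
        est = estimate_ani(seq, seq)
        assert est.ani == 1.0
        assert est.aligned_fraction == 1.0
        assert not est.below_detection

    def test_strand_invariance(self):
        seq = syn.random_sequence(10_000, 2)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[b] for b in reversed(seq))
        est = estimate_ani(seq, rc)
        assert est.ani > 0.999

    def test_unrelated_sequences_flagged_not_raised(self):
        a = syn.random_sequence(5_000, 3)
        b = syn.random_sequence(5_000, 4)
        est = estimate_ani(a, b)
        assert est.below_detection
        assert est.ani == 0.0

    def test_short_sequence_raises(self):
        with pytest.raises(ValueError):
            estimate_ani("ACGTACGTACGT", "ACGT" * 100)  # first shorter than k

    def test_divergence_window_at_3_percent(self):
        anis = []
        for seed in range(50):
            pair = syn.simulate_sequence_pair(500_000, 0.03, seed=seed)
            anis.append(estimate_ani(pair.seq_a, pair.seq_b, sketch_size=1000).ani)
        assert all(0.955 <= a <= 0.985 for a in anis)

    def test_mean_ani_tracks_divergence(self):
        # estimator expectation is 1 + ln(1-d); within 0.5 pp of 1-d at low d,
        # and within 0.2 pp of the analytic value up to d = 0.10
        for d in (0.02, 0.05, 0.10):
            anis = []
            for s in range(50):
                pair = syn.simulate_sequence_pair(500_000, d, seed=s)
                anis.append(
                    estimate_ani(pair.seq_a, pair.seq_b, sketch_size=5000).ani
                )
            mean = np.mean(anis)
            assert abs(mean - (1 + math.log(1 - d))) < 0.002
            if d <= 0.05:
                assert abs(mean - (1 - d)) < 0.005


def brute_force_greedy(pairs, genomes, thr, min_af):
    """Independent re-enumeration of the greedy quality-ranked assignment."""
    lookup = {frozenset((a, b)): (ani, af) for a, b, ani, af in pairs}
    order = sorted(
        genomes,
        key=lambda g: (-(g.completeness - 5 * g.contamination), g.genome_id),
    )
    clusters = []
    for g in order:
        for cl in clusters:
            rep = cl[0]
            ani, af = lookup.get(frozenset((g.genome_id, rep)), (0.0, 0.0))
            if ani >= thr and af >= min_af:
                cl.append(g.genome_id)
                break
        else:
            clusters.append([g.genome_id])
    return [tuple(c) for c in clusters]


def _estimates(pairs):
    return [AniEstimate(a, b, ani, af) for a, b, ani, af in pairs]


class TestClustering:
    def test_all_identical_single_cluster(self):
        genomes = [_g(f"g{i}") for i in range(4)]
        pairs = [(a.genome_id, b.genome_id, 1.0, 1.0)
                 for a, b in itertools.combinations(genomes, 2)]
        clusters = cluster_genomes(_estimates(pairs), genomes)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == [g.genome_id for g in genomes]

    def test_all_below_threshold_all_singletons(self):
        genomes = [_g(f"g{i}") for i in range(5)]
        pairs = [(a.genome_id, b.genome_id, 0.90, 1.0)
                 for a, b in itertools.combinations(genomes, 2)]
        clusters = cluster_genomes(_estimates(pairs), genomes)
        assert len(clusters) == 5

    def test_toy_matrix_matches_brute_force_oracle(self):
        genomes = [_g("g1", 0.99), _g("g2", 0.95), _g("g3", 0.90),
                   _g("g4", 0.85), _g("g5", 0.80)]
        clique = {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        pairs = []
        for a, b in itertools.combinations([g.genome_id for g in genomes], 2):
            ani = 0.99 if (a, b) in clique else 0.70
            pairs.append((a, b, ani, 0.9))
        clusters = cluster_genomes(_estimates(pairs), genomes)
        got = [c.member_ids for c in clusters]
        assert got == brute_force_greedy(pairs, genomes, 0.965, 0.60)
        assert len(clusters) == 3  # one 3-clique + two singletons

    def test_aligned_fraction_gate(self):
        genomes = [_g("a"), _g("b")]
        est = [AniEstimate("a", "b", 0.99, 0.5)]  # high ANI, low coverage
        assert len(cluster_genomes(est, genomes)) == 2

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            cluster_genomes([], [_g("a")], ani_threshold=1.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_clustering_is_a_partition(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(8)]
        genomes = [_g(i, comp=float(rng.uniform(0.5, 1.0))) for i in ids]
        pairs = [(a, b, float(rng.uniform(0.9, 1.0)), float(rng.uniform(0.4, 1.0)))
                 for a, b in itertools.combinations(ids, 2)]
        clusters = cluster_genomes(_estimates(pairs), genomes)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(ids)
        for c in clusters:
            assert c.representative_id in c.member_ids
        # matches the independent oracle too
        assert [c.member_ids for c in clusters] == brute_force_greedy(
            pairs, genomes, 0.965, 0.60
        )

    def test_threshold_monotonicity_on_separated_tables(self):
        # For well-separated (block-structured) similarity tables the cluster
        # count is non-decreasing in the ANI threshold. (This is not a theorem
        # for arbitrary tables: a stricter threshold can promote a hub genome
        # to representative and absorb would-be singletons.)
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(12)]
        genomes = [_g(i, comp=float(rng.uniform(0.6, 1.0))) for i in ids]
        block = {i: idx // 3 for idx, i in enumerate(ids)}
        pairs = []
        for a, b in itertools.combinations(ids, 2):
            ani = rng.uniform(0.97, 1.0) if block[a] == block[b] else rng.uniform(0.7, 0.9)
            pairs.append((a, b, float(ani), 0.9))
        est = _estimates(pairs)
        counts = [len(cluster_genomes(est, genomes, ani_threshold=t))
                  for t in (0.92, 0.95, 0.965, 0.975, 0.999)]
        assert counts == sorted(counts)

    def test_synthetic_species_recovered(self):
        # two planted species, divergent enough to split, cohesive enough to merge
        root = syn.random_sequence(20_000, 7)
        rng = np.random.default_rng(np.random.SeedSequence([7, 99]))
        genomes = []
        for s in range(2):
            anc, _ = syn.mutate_sequence(root, 0.04, rng)
            for m in range(3):
                seq, _ = syn.mutate_sequence(anc, 0.0025, rng)
                genomes.append(GenomeRecord(genome_id=f"sp{s}_m{m}", sequence=seq,
                                            completeness=1.0, contamination=0.0))
        ani = estimate_ani_matrix(genomes)
        clusters = cluster_genomes(ani, genomes)
        assert len(clusters) == 2
        for c in clusters:
            species = {m.split("_")[0] for m in c.member_ids}
            assert len(species) == 1


class TestSelectRepresentative:
    def test_score_arithmetic(self):
        # A: 0.95 - 5*0.01 = 0.90 beats B: 0.99 - 5*0.02 = 0.89
        meta = {"A": (0.95, 0.01), "B": (0.99, 0.02)}
        assert select_representative(["A", "B"], meta) == "A"

    def test_single_member(self):
        assert select_representative(["only"], {"only": (0.7, 0.0)}) == "only"

    def test_tie_breaks_lexicographically(self):
        meta = {"g2": (0.9, 0.01), "g1": (0.9, 0.01)}
        assert select_representative(["g2", "g1"], meta) == "g1"

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            select_representative([], {})
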