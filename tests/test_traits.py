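"""KO matrix construction, prevalence, marker rule and habitat enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panprop import synthetic as syn
from panprop.traits import (
    KoMatrix,
    MarkerCriteria,
    build_ko_matrix,
    enrichment_frame,
    habitat_enrichment,
    phylum_markers,
    prevalence,
)


def _meta(ids, habitat=None, focal=None):
    return pd.DataFrame(
        {
            "habitat": habitat or ["AD"] * len(ids),
            "focal": focal if focal is not None else [True] * len(ids),
        },
        index=pd.Index(ids, name="genome_id"),
    )


def _matrix(values, ids=None, kos=None, **meta_kw):
    values = np.asarray(values)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    kos = kos or [f"K{j:05d}" for j in range(values.shape[1])]
    counts = pd.DataFrame(values, index=pd.Index(ids, name="genome_id"), columns=kos)
    return KoMatrix(counts=counts, meta=_meta(ids, **meta_kw))


class TestBuildKoMatrix:
    def test_sparse_long_to_dense(self):
        ann = pd.DataFrame(
            {"genome_id": ["g1", "g1", "g2"], "ko_id": ["K1", "K2", "K1"],
             "count": [1, 1, 2]}
        )
        m = build_ko_matrix(ann, _meta(["g1", "g2"]))
        assert m.counts.shape == (2, 2)
        assert m.counts.loc["g2", "K2"] == 0
        assert m.counts.loc["g2", "K1"] == 2

    def test_duplicate_rows_are_summed(self):
        ann = pd.DataFrame(
            {"genome_id": ["g1", "g1"], "ko_id": ["K00001", "K00001"], "count": [1, 2]}
        )
        m = build_ko_matrix(ann, _meta(["g1"]))
        assert m.counts.loc["g1", "K00001"] == 3

    def test_empty_annotations_warn_and_zero_fill(self):
        ann = pd.DataFrame(columns=["genome_id", "ko_id"])
        with pytest.warns(UserWarning, match="empty annotation"):
            m = build_ko_matrix(ann, _meta(["g1", "g2"]))
        assert m.counts.shape == (2, 0)

    def test_unknown_genome_listed(self):
        ann = pd.DataFrame({"genome_id": ["ghost"], "ko_id": ["K1"]})
        with pytest.raises(ValueError, match="ghost"):
            build_ko_matrix(ann, _meta(["g1"]))


class TestPrevalence:
    def test_simple_fractions(self):
        m = _matrix([[1], [1], [5], [0]])
        assert prevalence(m, "AD").iloc[0] == 0.75

    def test_absent_ko_is_zero(self):
        m = _matrix([[0], [0]])
        assert prevalence(m, "AD").iloc[0] == 0.0

    def test_matches_brute_force_column_means(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(10, 6))
        habitat = ["AD"] * 6 + ["aquatic"] * 4
        m = _matrix(vals, habitat=habitat)
        got = prevalence(m, "AD").to_numpy()
        expected = (vals[:6] > 0).mean(axis=0)
        np.testing.assert_allclose(got, expected)

    def test_unknown_group_raises(self):
        with pytest.raises(ValueError):
            prevalence(_matrix([[1]]), "landfill")


class TestPhylumMarkers:
    def test_perfect_marker(self):
        m = _matrix([[1], [1], [0], [0]], focal=[True, True, False, False])
        hits = phylum_markers(m)
        assert list(hits.index) == ["K00000"]
        assert hits.loc["K00000", "prev_focal"] == 1.0

    def test_inclusive_boundaries_qualify(self):
        # exactly 75% focal and exactly 25% background prevalence is a marker
        focal_col = [1, 1, 1, 0]
        bg_col = [1, 0, 0, 0]
        m = _matrix(
            [[v] for v in focal_col + bg_col],
            focal=[True] * 4 + [False] * 4,
        )
        assert list(phylum_markers(m).index) == ["K00000"]

    def test_just_outside_boundaries_fail(self):
        m = _matrix(
            [[1], [1], [0], [0]] + [[1], [1], [0], [0]],
            focal=[True] * 4 + [False] * 4,
        )  # 50% focal, 50% background
        assert phylum_markers(m).empty

    def test_planted_markers_recovered_exactly(self):
        rng = np.random.default_rng(1)
        focal = [True] * 10 + [False] * 10
        vals = rng.integers(0, 2, size=(20, 50))
        planted = [3, 17, 25, 31, 49]
        for j in planted:
            vals[:10, j] = 1
            vals[10:, j] = 0
        m = _matrix(vals, focal=focal)
        hits = set(phylum_markers(m).index)
        # exhaustive check of the rule
        expected = set()
        inc = vals > 0
        for j in range(50):
            if inc[:10, j].mean() >= 0.75 and inc[10:, j].mean() <= 0.25:
                expected.add(f"K{j:05d}")
        assert hits == expected
        assert {f"K{j:05d}" for j in planted} <= hits

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tightening_criteria_never_grows_marker_set(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 2, size=(12, 20))
        m = _matrix(vals, focal=[True] * 7 + [False] * 5)
        loose = set(phylum_markers(m, criteria=MarkerCriteria(0.6, 0.6)).index)
        tight = set(phylum_markers(m, criteria=MarkerCriteria(0.8, 0.8)).index)
        assert tight <= loose

    def test_empty_focal_raises(self):
        m = _matrix([[1], [1]], focal=[False, False])
        with pytest.raises(ValueError):
            phylum_markers(m)


def bh_oracle(p):
    """Hand-coded Benjamini-Hochberg step-up (independent of statsmodels)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


class TestHabitatEnrichment:
    def _matrix_two_groups(self, x0, x1):
        vals = np.vstack([x0, x1])
        habitat = ["AD"] * len(x0) + ["aquatic"] * len(x1)
        ids = [f"g{i}" for i in range(len(vals))]
        counts = pd.DataFrame(vals, index=pd.Index(ids, name="genome_id"),
                              columns=[f"K{j:05d}" for j in range(vals.shape[1])])
        return KoMatrix(counts=counts, meta=_meta(ids, habitat=habitat))

    def test_identical_groups_yield_no_hits(self):
        block = np.tile([[1, 2, 3]], (4, 1))
        m = self._matrix_two_groups(block, block)
        fr = enrichment_frame(habitat_enrichment(m))
        assert (fr.coef == 0).all()
        assert (fr.q_value == 1.0).all()

    def test_planted_difference_detected_with_documented_sign(self):
        rng = np.random.default_rng(0)
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x0 = rng.poisson(5.0, size=(20, 10))  # AD group, KO 0 enriched
            x1 = rng.poisson(5.0, size=(20, 10))
            x0[:, 0] = rng.poisson(5.0, 20)
            x1[:, 0] = 0
            m = self._matrix_two_groups(x0, x1)
            fr = enrichment_frame(habitat_enrichment(m))
            row = fr[fr.ko_id == "K00000"].iloc[0]
            if row.q_value < 0.05:
                detected += 1
                assert row.coef < 0  # enriched in AD => negative coefficient
                assert row.enriched_in == "AD"
        assert detected >= 19

    def test_q_values_match_hand_coded_bh(self):
        rng = np.random.default_rng(3)
        m = self._matrix_two_groups(rng.poisson(2, (6, 15)), rng.poisson(3, (6, 15)))
        fr = enrichment_frame(habitat_enrichment(m))
        np.testing.assert_allclose(fr.q_value, bh_oracle(fr.p_value), atol=1e-12)

    def test_bh_oracle_agrees_with_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_oracle([0.001, 0.01, 0.02, 0.8]),
            [0.004, 0.02, 0.02666667, 0.8],
            atol=1e-8,
        )

    def test_label_swap_flips_coefficients_only(self):
        rng = np.random.default_rng(4)
        m = self._matrix_two_groups(rng.poisson(2, (5, 8)), rng.poisson(4, (5, 8)))
        a = enrichment_frame(habitat_enrichment(m, habitats=("AD", "aquatic")))
        b = enrichment_frame(habitat_enrichment(m, habitats=("aquatic", "AD")))
        np.testing.assert_allclose(a.coef, -b.coef)
        np.testing.assert_allclose(a.p_value, b.p_value)
        np.testing.assert_allclose(a.q_value, b.q_value)

    def test_zero_variance_ko_reported_inert(self):
        x = np.ones((4, 2), dtype=int)
        m = self._matrix_two_groups(x, np.ones((4, 2), dtype=int))
        fr = enrichment_frame(habitat_enrichment(m))
        assert (fr.p_value == 1.0).all()
        assert (fr.coef == 0.0).all()

    def test_small_group_raises(self):
        m = self._matrix_two_groups(np.ones((2, 3)), np.ones((5, 3)))
        with pytest.raises(ValueError, match="need >= 3"):
            habitat_enrichment(m)

    def test_null_fdr_is_controlled(self, quiet):
        # global null: no group structure; average discovery fraction <= alpha
        fracs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            m = self._matrix_two_groups(rng.poisson(3, (10, 50)),
                                        rng.poisson(3, (10, 50)))
            fr = enrichment_frame(habitat_enrichment(m))
            fracs.append((fr.q_value < 0.05).mean())
        assert np.mean(fracs) <= 0.05


class TestPlantedMarkerRecovery:
    def test_recovery_on_simulated_pangenome(self, small_pangenome):
        t = small_pangenome
        m = KoMatrix(counts=t.observed_matrix.astype(int), meta=t.genome_meta)
        hits = set(phylum_markers(m, "focal").index)
        assert len(hits & t.marker_kos) == len(t.marker_kos)
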