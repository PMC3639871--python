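"""Synthetic cohort generator: exact censuses, determinism, score model."""

import numpy as np
import pytest

from clgfnet.cohort import (CohortSpec, MotifAbundance,
                            TopologyInfeasibleError, build_topology,
                            count_distribution_moments, draw_scores,
                            make_cohort, make_topology, synthesize_signals)
from clgfnet.motifs import make_default_region_map
from clgfnet.stats import pearson_r


def small_spec(**kw):
    defaults = dict(
        n_subjects_per_group=(3, 3), n_channels=20, duration=2.0,
        archetypes={"control": MotifAbundance(4, 3, 2, n_negative=1),
                    "patient": MotifAbundance(2, 2, 0.5, n_negative=1)},
        seed=5)
    defaults.update(kw)
    return CohortSpec(**defaults)


def full_names(n=102):
    return [f"ch{i:03d}" for i in range(n)]


class TestBuildTopology:
    def test_empty_request_gives_empty_network(self, rng):
        names = full_names()
        topo = build_topology(names, make_default_region_map(names),
                              0, 0, 0, rng)
        assert topo.edges == []
        assert topo.census().n_clgf == 0

    def test_census_matches_request_exactly(self, rng):
        names = full_names()
        rmap = make_default_region_map(names)
        for _ in range(40):
            L = int(rng.integers(0, 12))
            C = int(rng.integers(0, L + 1)) if L else 0
            G = int(rng.integers(max(1 if C else 0, 0), 10))
            try:
                topo = build_topology(names, rmap, L, G, C, rng, n_negative=2)
            except TopologyInfeasibleError:
                continue
            census = topo.census()
            assert (census.n_pos_fb_local, census.n_pos_fb_global,
                    census.n_clgf) == (L, G, C)
            assert census.n_neg_fb == 2

    def test_lags_follow_scope_ranges(self, rng):
        names = full_names()
        topo = build_topology(names, make_default_region_map(names),
                              6, 5, 4, rng)
        for e in topo.edges:
            lo, hi = (6.0, 10.0) if e.scope == "local" else (15.0, 25.0)
            assert lo <= e.causal_lag_ms <= hi

    def test_infeasible_request_names_constraint(self, rng):
        names = full_names(8)  # 4 regions of 2: one local partner per hub
        rmap = make_default_region_map(names)
        with pytest.raises(TopologyInfeasibleError, match="n_clgf"):
            build_topology(names, rmap, 3, 5, 5, rng)

    def test_same_seed_same_topology(self):
        spec = small_spec()
        t1 = make_topology(spec, "control", 123)
        t2 = make_topology(spec, "control", 123)
        assert [e.pair + (e.sign, e.causal_lag_ms) for e in t1.edges] \
            == [e.pair + (e.sign, e.causal_lag_ms) for e in t2.edges]


class TestSynthesizeSignals:
    def test_same_seed_bit_identical(self):
        spec = small_spec()
        topo = make_topology(spec, "patient", 9)
        s1 = synthesize_signals(topo, spec, np.random.default_rng(77))
        s2 = synthesize_signals(topo, spec, np.random.default_rng(77))
        assert np.array_equal(s1.data, s2.data)
        assert s1.n_samples == spec.n_samples

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            small_spec(duration=-1.0)


class TestScoreModel:
    def test_count_moments_match_monte_carlo(self, rng):
        mu, sd = count_distribution_moments(2.0, 1.0)
        draws = np.maximum(0, np.round(rng.normal(2.0, 1.0, 200_000)))
        assert mu == pytest.approx(draws.mean(), abs=0.01)
        assert sd == pytest.approx(draws.std(), abs=0.01)

    def test_noiseless_model_is_a_perfect_line(self, rng):
        counts = rng.integers(0, 8, 15).astype(float)
        scores = draw_scores(counts, rng, r=-1.0, count_mean=3.0, count_sd=2.0)
        assert pearson_r(counts, scores).estimate == pytest.approx(-1.0)

    def test_generating_r_recovered_in_expectation(self, rng):
        # true r = -0.5, n = 15: E[sample r] ~ r(1-(1-r^2)/(2n)) ~ -0.4875
        mu, sd = count_distribution_moments(2.0, 1.0)
        rs = []
        for _ in range(200):
            counts = np.maximum(0, np.round(rng.normal(2.0, 1.0, 15)))
            while np.ptp(counts) == 0:
                counts = np.maximum(0, np.round(rng.normal(2.0, 1.0, 15)))
            scores = draw_scores(counts, rng, -0.5, mu, sd)
            rs.append(pearson_r(counts, scores).estimate)
        assert np.mean(rs) == pytest.approx(-0.5, abs=0.06)


class TestMakeCohort:
    def test_default_group_sizes_give_32_rows(self):
        spec = small_spec()
        assert spec.__class__().n_subjects_per_group == (17, 15)
        cohort = make_cohort(small_spec(n_subjects_per_group=(17, 15)),
                             with_signals=False)
        assert len(cohort.table) == 32

    def test_patient_archetype_contract_enforced(self):
        with pytest.raises(ValueError, match="strictly fewer"):
            small_spec(archetypes={
                "control": MotifAbundance(4, 3, 2),
                "patient": MotifAbundance(5, 3, 3)})

    def test_cohort_determinism(self):
        c1 = make_cohort(small_spec(), with_signals=False)
        c2 = make_cohort(small_spec(), with_signals=False)
        assert c1.table.equals(c2.table)

    def test_scores_only_for_patients(self):
        cohort = make_cohort(small_spec(), with_signals=False)
        assert cohort.table.loc[cohort.table.group == "control",
                                "panss_negative"].isna().all()
        assert cohort.table.loc[cohort.table.group == "patient",
                                "panss_negative"].notna().all()

    def test_group_contrast_in_every_cohort(self):
        # ground-truth CLGF abundance: patient mean < control mean in all
        # of 20 independently seeded cohorts
        for seed in range(20):
            cohort = make_cohort(small_spec(n_subjects_per_group=(6, 6),
                                            n_channels=102, seed=seed),
                                 with_signals=False)
            g = cohort.table.groupby("group")["truth_n_clgf"].mean()
            assert g["patient"] < g["control"]

    def test_score_model_metadata_recorded(self):
        cohort = make_cohort(small_spec(), with_signals=False)
        assert cohort.score_model["r"] == -0.5
        assert cohort.score_model["slope"] < 0
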