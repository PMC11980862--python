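"""z-scores, Youden decomposition, detection thresholds, anomaly diagnosis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diatomring import (
    detection_threshold,
    diagnose,
    fit_mixture,
    match_composition,
    proficiency_verdict,
    youden_circle,
    youden_classify,
    z_scores,
)
from diatomring.proficiency import ProficiencyError


class TestZScores:
    def test_centred_value_is_zero(self):
        res = z_scores({"A": 10.0, "B": 12.0, "C": 14.0})
        assert {r.participant: r.z for r in res}["B"] == pytest.approx(0.0)

    def test_two_sigma_boundary_in_control(self):
        # construct x = mu + 2*sigma exactly by solving on a 3-lab group
        vals = {"A": 1.0, "B": 1.0, "C": 1.0 + 3.0}
        res = {r.participant: r for r in z_scores(vals)}
        x, mu, s = res["C"].x, res["C"].mu, res["C"].sigma
        assert res["C"].z == pytest.approx((x - mu) / s)
        assert abs(res["C"].z) <= 2 and res["C"].zone == "in_control"

    def test_warning_zone(self):
        # 10 labs with spread, one moderately outlying -> 2 < |z| <= 3
        vals = {f"P{i}": float(i % 2) for i in range(10)}
        vals["X"] = 4.0
        res = {r.participant: r for r in z_scores(vals)}
        assert 2 < abs(res["X"].z) <= 3
        assert res["X"].zone == "warning"

    def test_degenerate_dispersion_all_zero(self):
        res = z_scores({"A": 20.0, "B": 20.0, "C": 20.0})
        assert all(r.z == 0.0 and r.degenerate for r in res)
        assert proficiency_verdict(res) == ("pass", [])

    def test_verdict_fail_lists_offender(self):
        # 20 labs tight, one far out -> |z| > 3
        vals = {f"P{i:02d}": 0.0 for i in range(20)}
        vals["P05"] = 0.01
        vals["BAD"] = 10.0
        res = z_scores(vals)
        verdict, offenders = proficiency_verdict(res)
        assert verdict == "fail" and offenders == ["BAD"]

    def test_empty_verdict_rejected(self):
        with pytest.raises(ProficiencyError):
            proficiency_verdict([])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ProficiencyError):
            z_scores({"A": 1.0, "B": 2.0})

    def test_robust_variant_resists_outlier(self):
        vals = {f"P{i}": float(i % 3) for i in range(9)}
        vals["OUT"] = 1e6
        plain = {r.participant: r.z for r in z_scores(vals)}
        robust = {r.participant: r.z for r in z_scores(vals, robust=True)}
        assert abs(robust["OUT"]) > abs(plain["OUT"])

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    def test_affine_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        vals = {f"P{i}": float(v) for i, v in enumerate(rng.normal(10, 2, 6))}
        base = {r.participant: r.z for r in z_scores(vals)}
        moved = {k: scale * v + shift for k, v in vals.items()}
        trans = {r.participant: r.z for r in z_scores(moved)}
        for k in vals:
            assert trans[k] == pytest.approx(base[k], abs=1e-9)


class TestYouden:
    def test_systematic_error_near_diagonal(self):
        res = youden_classify({"A": (3.5, 3.4)})
        assert res[0].label == "systematic_error"

    def test_total_error_off_diagonal(self):
        res = youden_classify({"A": (3.5, -3.5)})
        assert res[0].label == "total_error"

    def test_random_error_inside_box(self):
        res = youden_classify({"A": (1.5, -1.6)})  # |v| = 3.1/sqrt(2) > 2
        assert res[0].label == "random_error"

    def test_in_control_geometry(self):
        res = youden_classify({"A": (1.0, 1.0)})
        assert res[0].label == "in_control"
        assert res[0].u == pytest.approx(np.sqrt(2))
        assert res[0].v == pytest.approx(0.0)

    def test_missing_pair_skipped(self):
        res = youden_classify({"A": (1.0, np.nan), "B": (0.5, 0.5)})
        assert [r.participant for r in res] == ["B"]

    def test_probability_circle_radius(self):
        # chi-square(2) 95% quantile is 5.991...
        assert youden_circle(0.95) == pytest.approx(np.sqrt(5.991464547), abs=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(-6, 6), st.floats(-6, 6))
    def test_rotation_is_isometry(self, za, zb):
        r = youden_classify({"A": (za, zb)})[0]
        assert r.u**2 + r.v**2 == pytest.approx(za**2 + zb**2, abs=1e-9)


class TestDetectionThreshold:
    def test_all_detected_threshold_zero(self):
        df = pd.DataFrame(np.full((3, 4), 0.25))
        assert detection_threshold(df) == 0.0

    def test_toy_configuration(self):
        # 5% seen by all; 0.8% missed by one; 0.2% missed by two
        df = pd.DataFrame(
            {
                "p1": [0.05, 0.008, 0.002],
                "p2": [0.05, 0.0, 0.002],
                "p3": [0.05, 0.008, 0.0],
                "p4": [0.05, 0.008, 0.0],
            },
            index=["abundant", "mid", "rare"],
        )
        assert detection_threshold(df) == pytest.approx(0.008)
        assert detection_threshold(df, representative="mean") == pytest.approx(0.008)

    def test_taxon_absent_everywhere_ignored(self):
        df = pd.DataFrame({"p1": [0.5, 0.0], "p2": [0.5, 0.0]})
        assert detection_threshold(df) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_guarantee_property_brute_force(self, seed):
        # every taxon with representative abundance strictly above the
        # threshold must be detected by all participants
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 0.1, size=(8, 4))
        vals[rng.random(vals.shape) < 0.3] = 0.0
        df = pd.DataFrame(vals)
        thr = detection_threshold(df)
        for _, row in df.iterrows():
            detected = row > 0
            if not detected.any():
                continue
            rep = row[detected].max()
            if rep > thr:
                assert detected.all()

    def test_needs_two_participants(self):
        with pytest.raises(ProficiencyError):
            detection_threshold(pd.DataFrame({"p1": [0.5]}))


class TestMatchComposition:
    def test_exact_identity(self, communities):
        refs = {k: v for k, v in communities.items() if len(v)}
        for name in ("L", "R", "M"):
            best, d = match_composition(communities[name], refs)
            assert best == name and d == pytest.approx(0.0)

    def test_tie_broken_lexicographically(self):
        p = pd.Series([1.0], index=["x"])
        best, d = match_composition(p, {"b": p.copy(), "a": p.copy()})
        assert best == "a" and d == 0.0

    def test_empty_query_vs_empty_reference(self):
        best, d = match_composition(
            pd.Series(dtype=float), {"W": pd.Series(dtype=float)}
        )
        assert best is None and np.isnan(d)

    def test_no_references_rejected(self):
        with pytest.raises(ProficiencyError):
            match_composition(pd.Series([1.0], index=["x"]), {})


class TestFitMixture:
    def test_exact_half_mixture(self, communities):
        taxa = communities["L"].index.union(communities["M"].index)
        q = 0.5 * communities["L"].reindex(taxa).fillna(0) + 0.5 * communities[
            "M"
        ].reindex(taxa).fillna(0)
        alpha, res = fit_mixture(q, communities["L"], communities["M"])
        assert alpha == pytest.approx(0.5, abs=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_endpoint(self, communities):
        alpha, res = fit_mixture(communities["L"], communities["L"], communities["M"])
        assert alpha == pytest.approx(1.0) and res == pytest.approx(0.0, abs=1e-12)

    def test_identical_references_rejected(self, communities):
        with pytest.raises(ProficiencyError):
            fit_mixture(communities["L"], communities["M"], communities["M"])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_closed_form_matches_grid_search(self, communities, seed):
        # brute-force oracle: densely scan alpha, compare argmin
        rng = np.random.default_rng(seed)
        taxa = communities["L"].index.union(communities["M"].index)
        L = communities["L"].reindex(taxa).fillna(0).to_numpy()
        M = communities["M"].reindex(taxa).fillna(0).to_numpy()
        true_alpha = rng.uniform(0.1, 0.9)
        q = true_alpha * L + (1 - true_alpha) * M + rng.normal(0, 0.002, len(taxa))
        q = np.clip(q, 0, None)
        query = pd.Series(q, index=taxa)
        alpha, _ = fit_mixture(query, communities["L"], communities["M"])
        grid = np.linspace(0, 1, 101)
        sse = [np.sum((q - (a * L + (1 - a) * M)) ** 2) for a in grid]
        assert abs(alpha - grid[int(np.argmin(sse))]) <= 0.01


class TestDiagnose:
    def test_clean_sample(self, communities):
        refs = {k: v for k, v in communities.items() if len(v)}
        rep = diagnose(communities["R"], "R", refs)
        assert rep.verdict == "clean"

    def test_swap_into_blank(self, communities):
        refs = {k: v for k, v in communities.items() if len(v)}
        rep = diagnose(communities["L"], None, refs, sample="E1/E/W/1")
        assert rep.verdict == "swap_suspect" and rep.best_match == "L"

    def test_mixture_detected(self, communities):
        refs = {k: v for k, v in communities.items() if len(v)}
        taxa = communities["L"].index.union(communities["M"].index)
        q = 0.5 * communities["L"].reindex(taxa).fillna(0) + 0.5 * communities[
            "M"
        ].reindex(taxa).fillna(0)
        rep = diagnose(q, "L", refs)
        assert rep.verdict == "mixture_suspect"
        assert set(rep.mixture_sources) == {"L", "M"}
        assert rep.alpha == pytest.approx(0.5, abs=1e-9)

    def test_empty_blank(self, communities):
        refs = {k: v for k, v in communities.items() if len(v)}
        rep = diagnose(pd.Series(dtype=float), None, refs, sample="E1/A/W/1")
        assert rep.verdict == "empty"
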