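"""Filtering standards: boundary fidelity, oracle equivalence, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncomodules.filtering import (FilterThresholds, apply_filters,
                                   call_significant_drivers,
                                   call_significant_relationships,
                                   call_tumour_drivers, filter_valid,
                                   project_to_significant,
                                   validate_assignments)

from _oracles import brute_filter, random_assignment_instance


def frame(rows):
    return pd.DataFrame(rows, columns=["tumour_id", "sga", "deg", "posterior"])


class TestPosteriorFloor:
    def test_strictly_above_kept(self):
        out = filter_valid(frame([("t1", "s", "d", 0.9)]), 0.5)
        assert len(out) == 1

    def test_boundary_removed(self):
        out = filter_valid(frame([("t1", "s", "d", 0.5)]), 0.5)
        assert len(out) == 0

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        rows = [(f"t{i % 7}", f"s{i % 5}", f"d{i}", float(rng.random()))
                for i in range(100)]
        out = filter_valid(frame(rows), 0.3)
        expected = [r for r in rows if r[3] > 0.3]
        assert list(map(tuple, out.itertuples(index=False))) == expected

    def test_empty_input(self):
        assert len(filter_valid(frame([]), 0.5)) == 0


class TestDriverCalls:
    def test_five_degs_is_driver(self):
        rows = [("t", "s", f"d{i}", 0.9) for i in range(5)]
        assert call_tumour_drivers(frame(rows)) == {("t", "s")}

    def test_four_degs_is_not(self):
        rows = [("t", "s", f"d{i}", 0.9) for i in range(4)]
        assert call_tumour_drivers(frame(rows)) == set()


class TestSignificantDrivers:
    def obs(self, sga, n):
        return pd.DataFrame({"tumour_id": [f"o{i}" for i in range(n)],
                             "sga": sga})

    def calls(self, sga, n):
        return {(f"t{i}", sga) for i in range(n)}

    def test_30_of_120_significant(self):
        out = call_significant_drivers(self.calls("s", 30), self.obs("s", 120))
        assert out == {"s"}

    def test_29_tumours_fails_count(self):
        out = call_significant_drivers(self.calls("s", 29), self.obs("s", 40))
        assert out == set()

    def test_30_of_121_fails_fraction(self):
        out = call_significant_drivers(self.calls("s", 30), self.obs("s", 121))
        assert out == set()

    def test_unobserved_driver_rejected(self):
        with pytest.raises(ValueError, match="never observed"):
            call_significant_drivers(self.calls("s", 30), self.obs("x", 40))


class TestSignificantRelationships:
    def test_50_tumours_branch(self):
        rows = [(f"t{i}", "s", "d", 0.9) for i in range(50)]
        calls = {(f"t{i}", "s") for i in range(250)}
        out = call_significant_relationships(frame(rows), {"s"}, calls)
        assert out == [("s", "d")]

    def test_20_percent_branch(self):
        rows = [(f"t{i}", "s", "d", 0.9) for i in range(10)]
        calls = {(f"t{i}", "s") for i in range(50)}
        out = call_significant_relationships(frame(rows), {"s"}, calls)
        assert out == [("s", "d")]

    def test_18_percent_and_9_tumours_fails(self):
        rows = [(f"t{i}", "s", "d", 0.9) for i in range(9)]
        calls = {(f"t{i}", "s") for i in range(50)}
        out = call_significant_relationships(frame(rows), {"s"}, calls)
        assert out == []


class TestProjection:
    def test_empty_significant_set(self):
        rows = frame([("t", "s", "d", 0.9)])
        assert len(project_to_significant(rows, [])) == 0

    def test_all_significant_is_identity(self):
        rows = frame([("t", "s", "d", 0.9), ("t", "s", "e", 0.8)])
        out = project_to_significant(rows, [("s", "d"), ("s", "e")])
        pd.testing.assert_frame_equal(out, rows)

    def test_membership_filter_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        rows, _ = random_assignment_instance(rng)
        keep = [(r[1], r[2]) for r in rows if rng.random() < 0.3]
        out = project_to_significant(frame(rows), keep)
        expected = [r for r in rows if (r[1], r[2]) in set(keep)]
        assert list(map(tuple, out.itertuples(index=False))) == expected


@pytest.mark.parametrize("seed", range(6))
def test_pipeline_matches_bruteforce_oracle(seed):
    """Standards 1-4 agree exactly with an independent exhaustive scan."""
    rng = np.random.default_rng(seed)
    rows, obs = random_assignment_instance(
        rng, n_tumours=int(rng.integers(10, 50)),
        n_sgas=int(rng.integers(3, 12)), n_degs=int(rng.integers(10, 30)))
    thresholds = FilterThresholds(
        posterior_floor=0.3, min_degs_per_driver=3, min_driver_tumours=4,
        min_driver_fraction=0.3, min_relationship_tumours=5,
        min_relationship_fraction=0.5)
    result = apply_filters(
        frame(rows), pd.DataFrame(obs, columns=["tumour_id", "sga"]),
        thresholds)
    _valid, b_drivers, b_sig, b_rel = brute_filter(
        rows, obs, floor=0.3, min_degs=3, min_tumours=4, min_frac=0.3,
        rel_tumours=5, rel_frac=0.5)
    assert result.driver_calls == b_drivers
    assert result.significant_drivers == b_sig
    assert set(result.significant_relationships) == b_rel


def test_row_order_invariance():
    rng = np.random.default_rng(11)
    rows, obs = random_assignment_instance(rng)
    thresholds = FilterThresholds(posterior_floor=0.4, min_degs_per_driver=3,
                                  min_driver_tumours=3,
                                  min_driver_fraction=0.2,
                                  min_relationship_tumours=4,
                                  min_relationship_fraction=0.4)
    obs_df = pd.DataFrame(obs, columns=["tumour_id", "sga"])
    a = apply_filters(frame(rows), obs_df, thresholds)
    shuffled = frame(rows).sample(frac=1.0, random_state=5)
    b = apply_filters(shuffled, obs_df, thresholds)
    assert a.significant_drivers == b.significant_drivers
    assert a.significant_relationships == b.significant_relationships


@settings(max_examples=25, deadline=None, derandomize=True)
@given(floor=st.floats(0.0, 1.0),
       min_degs=st.integers(1, 6),
       min_tumours=st.integers(1, 8),
       bump=st.integers(0, 3))
def test_driver_calls_monotone_in_thresholds(floor, min_degs, min_tumours, bump):
    """Raising the floor or driver thresholds never adds a driver.

    Note the *relationship* set is deliberately not asserted here: raising
    the posterior floor or the per-tumour DEG count shrinks the
    driver-tumour denominator of the relationship-fraction rule, which can
    legitimately make a surviving pair's fraction larger.
    """
    rng = np.random.default_rng(99)
    rows, obs = random_assignment_instance(rng, n_tumours=15, n_sgas=6,
                                           n_degs=12, density=0.5)
    obs_df = pd.DataFrame(obs, columns=["tumour_id", "sga"])
    lo = FilterThresholds(posterior_floor=floor, min_degs_per_driver=min_degs,
                          min_driver_tumours=min_tumours,
                          min_driver_fraction=0.2,
                          min_relationship_tumours=3,
                          min_relationship_fraction=0.3)
    hi = FilterThresholds(posterior_floor=min(1.0, floor + 0.1 * bump),
                          min_degs_per_driver=min_degs + bump,
                          min_driver_tumours=min_tumours + bump,
                          min_driver_fraction=0.2,
                          min_relationship_tumours=3,
                          min_relationship_fraction=0.3)
    a = apply_filters(frame(rows), obs_df, lo)
    b = apply_filters(frame(rows), obs_df, hi)
    assert b.driver_calls <= a.driver_calls
    assert b.significant_drivers <= a.significant_drivers


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rel_tumours=st.integers(1, 8), rel_frac=st.floats(0.05, 0.9),
       bump_t=st.integers(0, 4), bump_f=st.floats(0.0, 0.1))
def test_relationships_monotone_in_relationship_thresholds(
        rel_tumours, rel_frac, bump_t, bump_f):
    """Raising only the relationship thresholds never adds a relationship."""
    rng = np.random.default_rng(98)
    rows, obs = random_assignment_instance(rng, n_tumours=15, n_sgas=6,
                                           n_degs=12, density=0.5)
    obs_df = pd.DataFrame(obs, columns=["tumour_id", "sga"])
    common = dict(posterior_floor=0.3, min_degs_per_driver=2,
                  min_driver_tumours=2, min_driver_fraction=0.2)
    lo = FilterThresholds(**common, min_relationship_tumours=rel_tumours,
                          min_relationship_fraction=rel_frac)
    hi = FilterThresholds(**common,
                          min_relationship_tumours=rel_tumours + bump_t,
                          min_relationship_fraction=min(1.0, rel_frac + bump_f))
    a = apply_filters(frame(rows), obs_df, lo)
    b = apply_filters(frame(rows), obs_df, hi)
    assert set(b.significant_relationships) <= set(a.significant_relationships)


def test_duplicate_rows_collapse_to_max_posterior(caplog):
    rows = frame([("t", "s", "d", 0.4), ("t", "s", "d", 0.9)])
    out = validate_assignments(rows)
    assert len(out) == 1
    assert out["posterior"].iloc[0] == 0.9


def test_one_cause_violation_rejected():
    rows = frame([("t", "s1", "d", 0.9), ("t", "s2", "d", 0.8)])
    with pytest.raises(ValueError, match="one-cause"):
        validate_assignments(rows)
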