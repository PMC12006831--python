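"""Closed-form TBI mathematics: examples, inverses and flag behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from teabag import (
    AsymptoteReachedError,
    Flag,
    HarvestRecord,
    PairingError,
    TBIConstants,
    decomposable_fraction_rooibos,
    k_from_asymptote,
    mass_margin,
    remaining_fraction,
    stabilisation_factor,
    tbi_from_pair,
)

CONSTANTS = TBIConstants()


def make_pair(green_remaining, rooibos_remaining, days=90.0, pair_id="p"):
    g = HarvestRecord("g", "green", 2.0, 2.0 * green_remaining, days, pair_id)
    r = HarvestRecord("r", "rooibos", 2.0, 2.0 * rooibos_remaining, days, pair_id)
    return g, r


class TestRemainingFraction:
    @pytest.mark.parametrize(
        "a,k,t,expected,tol",
        [
            (0.4416, 0.009279, 0.0, 1.0, 0.0),  # no mass lost at t=0
            (0.4416, 0.009279, 1e9, 0.5584, 1e-12),  # the asymptote 1 - a
            (0.4416, 0.009279, 90.0, 0.7500, 1e-4),  # inverse of the k example
        ],
    )
    def test_examples(self, a, k, t, expected, tol):
        assert remaining_fraction(a, k, t) == pytest.approx(expected, abs=max(tol, 1e-15))

    def test_domain_violations(self):
        for bad in [(-0.1, 0.01, 1.0), (1.1, 0.01, 1.0), (0.5, -0.01, 1.0), (0.5, 0.01, -1.0)]:
            with pytest.raises(ValueError):
                remaining_fraction(*bad)

    @given(
        a=st.floats(0.0, 1.0),
        k=st.floats(0.0, 1.0),
        t=st.floats(0.0, 1000.0),
    )
    def test_bounded_between_asymptote_and_one(self, a, k, t):
        m = remaining_fraction(a, k, t)
        assert 1.0 - a - 1e-12 <= m <= 1.0 + 1e-12


class TestStabilisationFactor:
    @pytest.mark.parametrize(
        "loss,expected",
        [
            (CONSTANTS.h_green, 0.0),  # entire hydrolysable pool decomposed
            (0.0, 1.0),  # full stabilisation
            (0.6, 1.0 - 0.6 / 0.842),  # hand evaluation: 0.28741...
        ],
    )
    def test_examples(self, loss, expected):
        assert stabilisation_factor(loss, CONSTANTS) == pytest.approx(expected, abs=1e-5)

    def test_hand_value(self):
        assert stabilisation_factor(0.6, CONSTANTS) == pytest.approx(0.28741, abs=1e-5)

    def test_out_of_range_loss_raises(self):
        with pytest.raises(ValueError):
            stabilisation_factor(-0.01)
        with pytest.raises(ValueError):
            stabilisation_factor(1.01)

    @given(s=st.floats(-0.5, 1.0))
    def test_inverse_recovers_loss(self, s):
        """loss = H_green * (1 - S) recovers the input loss for any S <= 1."""
        loss = CONSTANTS.h_green * (1.0 - s)
        if 0.0 <= loss <= 1.0:
            assert stabilisation_factor(loss, CONSTANTS) == pytest.approx(s, abs=1e-12)

    def test_strictly_decreasing_in_loss(self):
        losses = np.linspace(0, 1, 50)
        s = [stabilisation_factor(x, CONSTANTS) for x in losses]
        assert all(b < a for a, b in zip(s, s[1:]))


class TestDecomposableFractionRooibos:
    @pytest.mark.parametrize(
        "s,expected",
        [(0.2, 0.4416), (1.0, 0.0), (0.0, CONSTANTS.h_rooibos)],
    )
    def test_examples(self, s, expected):
        assert decomposable_fraction_rooibos(s, CONSTANTS) == pytest.approx(expected, abs=1e-12)

    def test_negative_s_exceeds_hydrolysable_fraction(self):
        assert decomposable_fraction_rooibos(-0.1, CONSTANTS) > CONSTANTS.h_rooibos

    def test_s_above_one_raises(self):
        with pytest.raises(ValueError):
            decomposable_fraction_rooibos(1.5)


class TestKFromAsymptote:
    def test_worked_example(self):
        assert k_from_asymptote(0.75, 0.5584, 90.0) == pytest.approx(0.009279, abs=1e-5)

    def test_no_mass_loss_boundary(self):
        assert k_from_asymptote(1.0, 0.5584, 90.0) == 0.0

    def test_asymptote_reached_raises_with_margin(self):
        with pytest.raises(AsymptoteReachedError) as exc:
            k_from_asymptote(0.5584, 0.5584, 90.0)
        assert exc.value.margin_pct == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(AsymptoteReachedError):
            k_from_asymptote(0.50, 0.5584, 90.0)

    def test_diverges_approaching_asymptote(self):
        ks = [k_from_asymptote(0.5584 + eps, 0.5584, 90.0) for eps in (1e-2, 1e-4, 1e-8)]
        assert ks[0] < ks[1] < ks[2]

    def test_monotone_in_remaining_and_asymptote(self):
        remainings = np.linspace(0.60, 0.99, 25)
        ks = [k_from_asymptote(m, 0.5584, 90.0) for m in remainings]
        assert all(b < a for a, b in zip(ks, ks[1:]))
        asymptotes = np.linspace(0.30, 0.70, 25)
        ks2 = [k_from_asymptote(0.75, A, 90.0) for A in asymptotes]
        assert all(b > a for a, b in zip(ks2, ks2[1:]))

    @given(
        a=st.floats(0.2, 0.95),
        k=st.floats(1e-3, 0.05),
        t=st.floats(5.0, 100.0),
    )
    def test_round_trip(self, a, k, t):
        """Exact inverse of remaining_fraction to 1e-10 relative."""
        m = remaining_fraction(a, k, t)
        assert k_from_asymptote(m, 1.0 - a, t) == pytest.approx(k, rel=1e-10)


class TestMassMargin:
    @pytest.mark.parametrize(
        "remaining,asymptote,expected",
        [(0.75, 0.5584, 19.16), (0.33, 0.33, 0.0), (0.54, 0.5584, -1.84)],
    )
    def test_examples(self, remaining, asymptote, expected):
        assert mass_margin(remaining, asymptote) == pytest.approx(expected, abs=1e-10)

    def test_implausible_fraction_raises(self):
        with pytest.raises(ValueError):
            mass_margin(1.3, 0.5)

    def test_decreasing_in_time_towards_zero(self):
        a, k = 0.4416, 0.0093
        t = np.linspace(1, 2000, 200)
        mm = [mass_margin(remaining_fraction(a, k, ti), 1 - a) for ti in t]
        assert all(b < x for x, b in zip(mm, mm[1:]))
        assert mm[-1] == pytest.approx(0.0, abs=1e-4)


class TestTbiFromPair:
    def test_worked_chain(self):
        g, r = make_pair(1.0 - 0.6736, 0.75)
        res = tbi_from_pair(g, r)
        assert res.s_tbi == pytest.approx(0.2, abs=1e-12)
        assert res.a_rooibos == pytest.approx(0.4416, abs=1e-12)
        assert res.k_tbi == pytest.approx(0.009279, abs=1e-5)
        assert res.mm_rooibos_pct == pytest.approx(19.16, abs=1e-9)
        assert res.flags == frozenset()

    def test_negative_s_flagged_not_clamped(self):
        g, r = make_pair(0.10, 0.75)  # green lost 90% > hydrolysable pool
        res = tbi_from_pair(g, r)
        assert res.s_tbi == pytest.approx(1.0 - 0.9 / 0.842, abs=1e-4)
        assert res.s_tbi == pytest.approx(-0.0689, abs=1e-4)
        assert Flag.NEGATIVE_S in res.flags

    def test_asymptote_reached_gives_undefined_k(self):
        g, r = make_pair(1.0 - 0.6736, 0.5584)  # rooibos exactly at 1 - a_r
        res = tbi_from_pair(g, r)
        assert Flag.ASYMPTOTE_REACHED in res.flags
        assert res.k_tbi is None
        assert res.mm_rooibos_pct == pytest.approx(0.0, abs=1e-12)

    def test_low_mass_margin_and_window_flags(self):
        g, r = make_pair(1.0 - 0.6736, 0.60)  # MM = 4.16%
        res = tbi_from_pair(g, r)
        assert Flag.LOW_MASS_MARGIN in res.flags
        g2, r2 = make_pair(1.0 - 0.6736, 0.75, days=140.0)
        assert Flag.OUT_OF_WINDOW in tbi_from_pair(g2, r2).flags

    def test_rooibos_mass_gain_flagged_with_zero_k(self):
        g, r = make_pair(1.0 - 0.6736, 1.02)
        res = tbi_from_pair(g, r)
        assert Flag.MASS_GAIN in res.flags
        assert res.k_tbi == 0.0

    def test_green_mass_gain_treated_as_zero_loss(self):
        g, r = make_pair(1.05, 0.75)
        res = tbi_from_pair(g, r)
        assert Flag.MASS_GAIN in res.flags
        assert res.s_tbi == 1.0  # zero loss => full stabilisation, invariant S <= 1

    def test_pairing_errors(self):
        g, r = make_pair(0.33, 0.75)
        with pytest.raises(PairingError):
            tbi_from_pair(r, g)  # swapped tea types
        g2 = HarvestRecord("g", "green", 2.0, 0.66, 89.0, "p")
        with pytest.raises(PairingError):
            tbi_from_pair(g2, r)  # days differ beyond tolerance 0
        assert tbi_from_pair(g2, r, day_tolerance=1.0).incubation_days == 90.0

    def test_matches_manual_composition_on_random_inputs(self, rng):
        """The aggregate op equals the chained elementary ops, 1000 draws."""
        n = 1000
        green_rem = rng.uniform(0.158, 0.999, n)  # loss within [0, h_green]... wide
        rooibos_rem = rng.uniform(0.30, 0.999, n)
        for gr, rr in zip(green_rem, rooibos_rem):
            g, r = make_pair(gr, rr)
            res = tbi_from_pair(g, r)
            s = stabilisation_factor(1.0 - gr, CONSTANTS)
            a_r = decomposable_fraction_rooibos(s, CONSTANTS)
            assert res.s_tbi == s
            assert res.a_rooibos == a_r
            if not 0.0 < 1.0 - a_r < 1.0:
                assert res.k_tbi is None
                continue
            mm = mass_margin(rr, 1.0 - a_r)
            assert res.mm_rooibos_pct == mm
            if mm > 0:
                assert res.k_tbi == k_from_asymptote(rr, 1.0 - a_r, 90.0)
            else:
                assert res.k_tbi is None
                assert Flag.ASYMPTOTE_REACHED in res.flags


class TestRecordsAndConstants:
    def test_harvest_record_validation(self):
        with pytest.raises(ValueError):
            HarvestRecord("x", "green", 0.0, 1.0, 90.0)
        with pytest.raises(ValueError):
            HarvestRecord("x", "green", 2.0, -0.1, 90.0)
        with pytest.raises(ValueError):
            HarvestRecord("x", "green", 2.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            HarvestRecord("x", "oolong", 2.0, 1.0, 90.0)

    def test_mass_gain_permitted_but_flagged(self):
        rec = HarvestRecord("x", "green", 2.0, 2.2, 90.0)
        assert rec.has_mass_gain
        assert rec.remaining_fraction == pytest.approx(1.1)

    def test_tea_type_normalisation(self):
        assert HarvestRecord("x", " Green ", 2.0, 1.0, 90.0).tea_type.value == "green"

    def test_constants_validated(self):
        with pytest.raises(ValueError):
            TBIConstants(h_green=0.0)
        with pytest.raises(ValueError):
            TBIConstants(h_rooibos=1.2)
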