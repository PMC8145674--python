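import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adhesim.engine import EventSeries
from adhesim.observables import (
    binding_window_fraction,
    complex_concentration,
    fit_lifetime_prefactor,
    segment_contact_events,
    segregation_threshold,
    two_dimensional_binding_constant,
    zone_area,
    zone_lifetime,
    zone_probability,
)
from adhesim.params import ModelParameters

INTERVAL = 200_000


def make_series(contact, tcr, n_window=None, interval=INTERVAL, equilibration=0):
    """EventSeries from boolean/int lists (contact counts and TCR bond counts)."""
    n = len(contact)
    contact = np.asarray(contact, dtype=int)
    tcr = np.asarray(tcr, dtype=int)
    if n_window is None:
        n_window = np.zeros(n, dtype=int)
    data = pd.DataFrame(
        {
            "step": equilibration + interval * np.arange(1, n + 1),
            "n_tcr_self": tcr,
            "n_tcr_foreign": np.zeros(n, dtype=int),
            "n_lfa_icam": np.zeros(n, dtype=int),
            "n_contact": contact,
            "n_window": np.asarray(n_window, dtype=int),
            "min_separation": np.where(contact > 0, 15.0, 40.0),
            "e_bend": np.zeros(n),
            "e_bind": np.zeros(n),
        }
    )
    return EventSeries(data=data, sampling_interval=interval,
                       equilibration_steps=equilibration)


def brute_segment(contact, tcr):
    """Reference segmentation: maximal runs of contact samples; qualifying iff
    any sample in the run has a TCR bond."""
    events = []
    run = []
    for idx, c in enumerate(contact):
        if c:
            run.append(idx)
        elif run:
            events.append((run[0], run[-1], any(tcr[i] for i in run)))
            run = []
    if run:
        events.append((run[0], run[-1], any(tcr[i] for i in run)))
    return events


class TestSegmentation:
    def test_continuous_contact_with_bonds_is_one_full_event(self):
        series = make_series([3] * 10, [1] * 10)
        events = segment_contact_events(series)
        assert len(events) == 1
        e = events[0]
        assert (e.start_index, e.end_index, e.had_tcr_bond) == (0, 9, True)
        assert zone_probability(series, events) == 1.0

    def test_no_contact_means_no_events(self):
        series = make_series([0] * 8, [0] * 8)
        assert segment_contact_events(series) == []
        assert zone_probability(series) == 0.0

    def test_single_bonded_sample_qualifies_the_whole_run(self):
        # contact run of 5 samples with a TCR bond only in the middle one
        series = make_series([0, 1, 1, 1, 1, 1, 0], [0, 0, 0, 1, 0, 0, 0])
        events = [e for e in segment_contact_events(series) if e.had_tcr_bond]
        assert len(events) == 1 and events[0].n_samples == 5

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            segment_contact_events(make_series([], []))

    @given(
        contact=st.lists(st.booleans(), min_size=1, max_size=60),
        bond_at=st.data(),
    )
    def test_matches_brute_force_reference(self, contact, bond_at):
        tcr = [c and bond_at.draw(st.booleans()) for c in contact]
        series = make_series([int(c) for c in contact], [int(t) for t in tcr])
        got = [
            (e.start_index, e.end_index, e.had_tcr_bond)
            for e in segment_contact_events(series)
        ]
        assert got == brute_segment(contact, tcr)

    @given(contact=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_probability_equals_qualifying_sample_fraction(self, contact):
        tcr = [int(c) for c in contact]  # every contact sample carries a bond
        series = make_series([int(c) for c in contact], tcr)
        events = segment_contact_events(series)
        inside = sum(e.n_samples for e in events if e.had_tcr_bond)
        assert zone_probability(series, events) * len(contact) == pytest.approx(inside)


class TestZoneLifetime:
    def test_full_window_event_reports_To(self):
        n = 20
        series = make_series([1] * n, [1] * n)
        events = segment_contact_events(series)
        To = series.measurement_length()
        life = zone_lifetime(events, To)
        assert life.mean_t0 == To == n * INTERVAL
        assert life.fraction_of_To == 1.0

    def test_mean_of_two_events(self):
        # events of 10 and 30 samples at 2e5 t0 sampling -> mean 4e6 t0
        contact = [1] * 10 + [0] + [1] * 30 + [0]
        tcr = [1] * 10 + [0] + [1] * 30 + [0]
        series = make_series(contact, tcr)
        life = zone_lifetime(segment_contact_events(series), To=len(contact) * INTERVAL)
        assert life.mean_t0 == pytest.approx(20 * INTERVAL)
        assert life.n_events == 2

    def test_no_events_is_flagged_empty(self):
        life = zone_lifetime([], To=100)
        assert life.empty and life.mean_t0 == 0.0


class TestZoneAreaAndConcentration:
    PARAMS = ModelParameters()

    def test_area_counts_subthreshold_patches(self):
        series = make_series([37] * 5, [1] * 5)
        assert zone_area(series, self.PARAMS) == pytest.approx(37 * 225.0)

    def test_full_and_empty_membrane_limits(self):
        full = 100 * 100
        series = make_series([full] * 4, [1] * 4)
        assert zone_area(series, self.PARAMS) == pytest.approx(2.25e6)  # 2.25 um^2
        assert zone_area(make_series([0] * 4, [0] * 4), self.PARAMS) == 0.0

    def test_concentration_of_225_bonds_on_default_membrane(self):
        n = 6
        data_series = make_series([0] * n, [0] * n)
        data_series.data["n_lfa_icam"] = 225
        assert complex_concentration(data_series, 2, self.PARAMS) == pytest.approx(100.0)

    def test_concentration_scales_with_area(self):
        small = ModelParameters(lattice_nx=30, lattice_ny=30, n_tcr=24, n_lfa=24,
                                n_self_pmhc=24, n_foreign_pmhc=0, n_icam=24)
        series = make_series([0] * 4, [0] * 4)
        series.data["n_lfa_icam"] = 20.25
        assert complex_concentration(series, 2, small) == pytest.approx(100.0)

    def test_zero_bonds_zero_concentration(self):
        series = make_series([0] * 4, [0] * 4)
        assert complex_concentration(series, 0, self.PARAMS) == 0.0


class TestBindingWindowFraction:
    PARAMS = ModelParameters()

    def test_counts_window_patches_within_zone(self):
        series = make_series([100] * 5, [1] * 5, n_window=[20] * 5)
        assert binding_window_fraction(series, self.PARAMS) == pytest.approx(0.2)

    def test_whole_membrane_reference(self):
        series = make_series([100] * 5, [1] * 5, n_window=[20] * 5)
        frac = binding_window_fraction(series, self.PARAMS, within_zone=False)
        assert frac == pytest.approx(20 / 10_000)

    def test_requires_in_event_samples(self):
        series = make_series([0] * 5, [0] * 5)
        with pytest.raises(ValueError):
            binding_window_fraction(series, self.PARAMS)


class TestLifetimeRegression:
    def test_exact_recovery(self):
        pts = [(u, math.exp(-0.9 + u)) for u in (4.0, 5.5, 7.0)]
        c, err = fit_lifetime_prefactor(pts)
        assert c == pytest.approx(-0.9, abs=1e-12)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_single_point_slope_fixed(self):
        c, err = fit_lifetime_prefactor([(5.0, math.exp(4.1))])
        assert c == pytest.approx(-0.9)
        assert math.isnan(err)

    def test_noisy_points_recovered_within_ci(self, rng):
        true_c = -0.95
        us = np.repeat(np.arange(4.0, 9.0), 8)
        taus = np.exp(true_c + us + rng.normal(0, 0.1, us.size))
        c, err = fit_lifetime_prefactor(list(zip(us, taus)))
        assert c == pytest.approx(true_c, abs=4 * err)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime_prefactor([(5.0, 0.0)])


class TestAnalyticFormulas:
    def test_segregation_threshold_default_parameters(self):
        # 0.65/(20*625) nm^-2 = 52/um^2, which the threshold estimate rounds
        # to about 50/um^2
        assert segregation_threshold(20.0, 25.0, 0.65) == pytest.approx(52.0)
        assert segregation_threshold(20.0, 25.0, 0.5) == pytest.approx(40.0)

    def test_threshold_scaling_in_mismatch(self):
        assert segregation_threshold(20.0, 50.0) == pytest.approx(
            segregation_threshold(20.0, 25.0) / 4
        )

    def test_threshold_rejects_nonpositive_arguments(self):
        with pytest.raises(ValueError):
            segregation_threshold(-1.0, 25.0)

    def test_k2d_all_mass_in_window_at_zero_energy(self):
        params = ModelParameters()
        seps = np.array([14.6, 15.0, 15.4])
        w = np.array([0.3, 0.4, 0.3])
        k2d = two_dimensional_binding_constant(seps, w, 0.0, params)
        assert k2d == pytest.approx(225.0 / 1e6)  # a^2 in um^2

    def test_k2d_partial_window_mass(self):
        # 20% of the mass in the window at U = 12.5 gives ~12.1 um^2
        params = ModelParameters()
        seps = np.array([15.0, 30.0])
        w = np.array([0.2, 0.8])
        k2d = two_dimensional_binding_constant(seps, w, 12.5, params)
        assert k2d == pytest.approx(0.2 * 225 * math.exp(12.5) / 1e6, rel=1e-12)
        assert 10 < k2d < 13

    def test_k2d_no_mass_in_window_is_zero(self):
        params = ModelParameters()
        seps = np.array([39.8, 40.0, 40.2])
        w = np.array([0.3, 0.4, 0.3])
        assert two_dimensional_binding_constant(seps, w, 12.5, params) == 0.0

    def test_k2d_requires_normalized_distribution(self):
        params = ModelParameters()
        with pytest.raises(ValueError):
            two_dimensional_binding_constant(
                np.array([15.0]), np.array([0.5]), 5.0, params
            )
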