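"""Equilibrium analysis of sampled trajectories.

Close-contact events are segmented from the sampled-conformation table: an
event is a maximal contiguous run of samples that each contain at least one
apposing patch pair with separation below the contact threshold (20 nm), and
it qualifies as a close-contact zone if at least one sample in the run holds
at least one TCR/pMHC complex. The second condition absorbs fluctuations in
which the instantaneous complex number of a small zone briefly drops to zero.

The module also provides the analytic companions of the simulation: the
curvature-mediated segregation threshold for the LFA-1/ICAM-1 concentration,
c * kBT / (kappa * dl^2) with prefactor c = 0.65 +- 0.15 and rest-length
mismatch dl, and the two-dimensional binding constant
K2D = integral k2D(l) P(l) dl with k2D(l) = a^2 exp(U) inside the TCR/pMHC
binding window and 0 outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import DwellRecord, EventSeries
from .params import ModelParameters

__all__ = [
    "ContactEvent",
    "ZoneLifetime",
    "AnalysisResults",
    "segment_contact_events",
    "zone_probability",
    "zone_lifetime",
    "zone_area",
    "complex_concentration",
    "binding_window_fraction",
    "fit_lifetime_prefactor",
    "segregation_threshold",
    "two_dimensional_binding_constant",
    "analyze_series",
    "aggregate_means",
]

SEGREGATION_PREFACTOR = 0.65  # dimensionless, +- 0.15


@dataclass(frozen=True)
class ContactEvent:
    """One maximal contiguous run of contact-containing samples."""

    start_index: int  # sample index of the first conformation in the run
    end_index: int  # sample index of the last conformation (inclusive)
    sampling_interval: int
    had_tcr_bond: bool
    censored_start: bool = False  # run touches the first sample of the window
    censored_end: bool = False  # run touches the last sample of the window

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def duration(self) -> int:
        """Event duration in t0 (number of samples times the sampling interval)."""
        return self.n_samples * self.sampling_interval


@dataclass(frozen=True)
class ZoneLifetime:
    mean_t0: float
    fraction_of_To: float
    n_events: int
    empty: bool


def segment_contact_events(
    series: EventSeries, params: Optional[ModelParameters] = None, equilibrated: bool = True
) -> list[ContactEvent]:
    """Segment the sampled series into maximal contact events.

    Only qualifying events (>= 1 TCR/pMHC complex in >= 1 conformation of the
    run) count as close-contact zones; non-qualifying runs are returned too,
    flagged via ``had_tcr_bond``.
    """
    if equilibrated:
        series = series.equilibrated()
    if series.n_samples == 0:
        raise ValueError("cannot segment an empty sample series")
    contact = series.data["n_contact"].to_numpy() > 0
    tcr = series.tcr_bond_counts() > 0
    events: list[ContactEvent] = []
    n = contact.size
    i = 0
    while i < n:
        if not contact[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and contact[j + 1]:
            j += 1
        events.append(
            ContactEvent(
                start_index=i,
                end_index=j,
                sampling_interval=series.sampling_interval,
                had_tcr_bond=bool(tcr[i : j + 1].any()),
                censored_start=i == 0,
                censored_end=j == n - 1,
            )
        )
        i = j + 1
    return events


def _qualifying(events: Iterable[ContactEvent]) -> list[ContactEvent]:
    return [e for e in events if e.had_tcr_bond]


def zone_probability(series: EventSeries, events: Optional[list[ContactEvent]] = None) -> float:
    """Fraction of equilibrated samples that are part of qualifying events."""
    eq = series.equilibrated()
    if events is None:
        events = segment_contact_events(series)
    total = eq.n_samples
    if total == 0:
        raise ValueError("no equilibrated samples")
    inside = sum(e.n_samples for e in _qualifying(events))
    return inside / total


def zone_lifetime(
    events: Sequence[ContactEvent],
    To: int,
    include_censored: bool = True,
) -> ZoneLifetime:
    """Mean duration of qualifying close-contact events.

    A single event spanning the whole measurement window reports lifetime To.
    Boundary-censored events are included by default (their true duration is
    at least the observed one; the full-window case makes exclusion
    degenerate) but can be dropped.
    """
    qual = _qualifying(events)
    if not include_censored:
        qual = [e for e in qual if not (e.censored_start or e.censored_end)]
    if not qual:
        return ZoneLifetime(mean_t0=0.0, fraction_of_To=0.0, n_events=0, empty=True)
    mean = float(np.mean([e.duration for e in qual]))
    return ZoneLifetime(
        mean_t0=mean,
        fraction_of_To=mean / To if To > 0 else float("nan"),
        n_events=len(qual),
        empty=False,
    )


def _in_event_mask(series_eq: EventSeries, events: Sequence[ContactEvent]) -> np.ndarray:
    mask = np.zeros(series_eq.n_samples, dtype=bool)
    for e in _qualifying(events):
        mask[e.start_index : e.end_index + 1] = True
    return mask


def zone_area(
    series: EventSeries,
    params: ModelParameters,
    events: Optional[list[ContactEvent]] = None,
) -> float:
    """Mean close-contact area in nm^2, averaged over in-event samples.

    The area of a conformation is the number of apposing patch pairs with
    separation below the contact threshold times the patch area a^2; all
    sub-threshold patches count (no connected-component labelling).
    """
    eq = series.equilibrated()
    if events is None:
        events = segment_contact_events(series)
    mask = _in_event_mask(eq, events)
    if not mask.any():
        return 0.0
    counts = eq.data["n_contact"].to_numpy()[mask]
    return float(counts.mean() * params.patch_size**2)


def complex_concentration(series: EventSeries, kind: int, params: ModelParameters) -> float:
    """Mean areal concentration of complexes of one kind, in 1/um^2.

    Kind 0 = TCR/self-pMHC, 1 = TCR/foreign-pMHC, 2 = LFA-1/ICAM-1.
    """
    col = ("n_tcr_self", "n_tcr_foreign", "n_lfa_icam")[kind]
    eq = series.equilibrated()
    if eq.n_samples == 0:
        raise ValueError("no equilibrated samples")
    return float(eq.data[col].mean() / params.membrane_area_um2)


def binding_window_fraction(
    series: EventSeries,
    params: ModelParameters,
    events: Optional[list[ContactEvent]] = None,
    within_zone: bool = True,
) -> float:
    """Fraction of patch pairs inside the TCR/pMHC binding window, averaged
    over in-event conformations.

    With ``within_zone`` (default) the fraction is taken relative to the
    patches of the close-contact zone itself (separation below the contact
    threshold); otherwise relative to the whole membrane.
    """
    eq = series.equilibrated()
    if events is None:
        events = segment_contact_events(series)
    mask = _in_event_mask(eq, events)
    if not mask.any():
        raise ValueError("no in-event samples to average over")
    n_window = eq.data["n_window"].to_numpy()[mask].astype(float)
    if within_zone:
        n_ref = eq.data["n_contact"].to_numpy()[mask].astype(float)
    else:
        n_ref = np.full(n_window.shape, float(params.lattice_nx * params.lattice_ny))
    valid = n_ref > 0
    return float(np.mean(n_window[valid] / n_ref[valid]))


def fit_lifetime_prefactor(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Fit ln(tau) = c + U with the slope fixed at 1.

    ``points`` are (U in kBT, mean dwell time in t0) pairs. Returns
    ``(c, stderr)``; with a single point the standard error is NaN.
    """
    if len(points) < 1:
        raise ValueError("need at least one (U, tau) point")
    us = np.array([p[0] for p in points], dtype=float)
    taus = np.array([p[1] for p in points], dtype=float)
    if np.any(taus <= 0):
        raise ValueError("dwell times must be positive")
    resid = np.log(taus) - us
    c = float(resid.mean())
    n = resid.size
    stderr = float(resid.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return c, stderr


def segregation_threshold(
    kappa: float, delta_l: float, prefactor: float = SEGREGATION_PREFACTOR
) -> float:
    """Critical LFA-1/ICAM-1 concentration for curvature-mediated segregation.

    Evaluates prefactor * kBT / (kappa * delta_l^2) with kappa in kBT and
    delta_l in nm, returned in complexes per um^2. At kappa = 20 kBT and
    delta_l = 25 nm the default prefactor gives 52/um^2.
    """
    if kappa <= 0 or delta_l <= 0 or prefactor <= 0:
        raise ValueError("all arguments must be positive")
    per_nm2 = prefactor / (kappa * delta_l**2)
    return per_nm2 * 1e6


def two_dimensional_binding_constant(
    separations: np.ndarray,
    weights: np.ndarray,
    U: float,
    params: ModelParameters,
) -> float:
    """Two-dimensional binding constant K2D = integral k2D(l) P(l) dl, in um^2.

    ``separations``/``weights`` describe the (normalized) distribution P(l) of
    local membrane separations; k2D(l) equals a^2 exp(U) inside the TCR/pMHC
    binding window and 0 outside, so K2D reduces to the probability mass
    inside the window times a^2 exp(U).
    """
    separations = np.asarray(separations, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if separations.shape != weights.shape:
        raise ValueError("separations and weights must have the same shape")
    total = weights.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-6, abs_tol=1e-9):
        raise ValueError(f"P(l) must be normalized (sum = {total})")
    lo = params.tcr_pmhc_rest_length - params.tcr_pmhc_half_width
    hi = params.tcr_pmhc_rest_length + params.tcr_pmhc_half_width
    mass = float(weights[(separations >= lo) & (separations <= hi)].sum())
    return mass * params.patch_size**2 * math.exp(U) / 1e6


@dataclass
class AnalysisResults:
    """Derived equilibrium quantities of one or more trajectories."""

    zone_probability: float
    zone_lifetime: ZoneLifetime
    zone_area_nm2: float
    concentrations_per_um2: dict[str, float]
    To: int
    binding_window_fraction: Optional[float] = None
    c_regression: Optional[tuple[float, float]] = None
    k2d_um2: Optional[float] = None
    segregation_threshold_per_um2: float = field(
        default_factory=lambda: segregation_threshold(20.0, 25.0)
    )


def analyze_series(
    series: EventSeries,
    params: ModelParameters,
    dwell: Optional[DwellRecord] = None,
) -> AnalysisResults:
    """Standard analysis bundle for one trajectory."""
    events = segment_contact_events(series)
    To = series.measurement_length()
    prob = zone_probability(series, events)
    life = zone_lifetime(events, To)
    area = zone_area(series, params, events)
    conc = {
        name: complex_concentration(series, kind, params)
        for kind, name in ((0, "TCR/self-pMHC"), (1, "TCR/foreign-pMHC"), (2, "LFA-1/ICAM-1"))
    }
    try:
        frac = binding_window_fraction(series, params, events)
    except ValueError:
        frac = None
    c_reg = None
    if dwell is not None and dwell.n_events() > 0:
        u_by_kind = {0: params.u_self, 1: params.u_foreign}
        pts = [
            (u_by_kind[k], float(dwell.lifetimes[k].mean()))
            for k in (0, 1)
            if dwell.lifetimes[k].size > 0
        ]
        if pts:
            c_reg = fit_lifetime_prefactor(pts)
    return AnalysisResults(
        zone_probability=prob,
        zone_lifetime=life,
        zone_area_nm2=area,
        concentrations_per_um2=conc,
        To=To,
        binding_window_fraction=frac,
        c_regression=c_reg,
        segregation_threshold_per_um2=segregation_threshold(
            params.kappa, params.length_mismatch
        ),
    )


def aggregate_means(values: Sequence[float]) -> tuple[float, float]:
    """Mean and error of the mean over independent trajectories."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sem
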