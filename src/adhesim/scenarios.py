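"""Adhesion scenario presets, the six-run protocol and deterministic test fixtures.

Three scenario presets mirror the standard study conditions on a 100x100
lattice (1.5x1.5 um^2 membrane, 120/um^2 per protein species):

* ``single_pmhc``:   270 TCR + 270 LFA-1 apposing 270 self-pMHC + 270 ICAM-1
  (one peptide-MHC type; its TCR binding energy is scanned),
* ``three_foreign``: 3 foreign-pMHC + 267 self-pMHC,
* ``one_foreign``:   1 foreign-pMHC + 269 self-pMHC.

Scaled-down presets shrink the lattice while preserving all areal densities
and energies, which keeps local kinetics and areal equilibria comparable at a
fraction of the cost (collective observables acquire finite-size shifts that
callers should report alongside the scale factor).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .engine import make_initial_state
from .lattice import MembraneState
from .params import ModelParameters

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "SIX_RUN_INTERVALS",
    "build_scenario",
    "six_run_protocol",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    n_tcr: int
    n_lfa: int
    n_self_pmhc: int
    n_foreign_pmhc: int
    n_icam: int
    lattice: int = 100


PRESETS = {
    "single_pmhc": ScenarioPreset("single_pmhc", 270, 270, 270, 0, 270),
    "three_foreign": ScenarioPreset("three_foreign", 270, 270, 267, 3, 270),
    "one_foreign": ScenarioPreset("one_foreign", 270, 270, 269, 1, 270),
}

# initial separation intervals (nm) of the six independent runs; the first
# three seed both complex types, the last three start from LFA-1/ICAM-1-only
# adhesion near 40 nm
SIX_RUN_INTERVALS = (
    (14.5, 40.5),
    (13.5, 41.5),
    (12.5, 42.5),
    (39.5, 40.5),
    (38.5, 41.5),
    (37.5, 42.5),
)


def build_scenario(
    preset: str, scale: float = 1.0, **overrides
) -> ModelParameters:
    """Build fully populated parameters for a named scenario.

    ``scale`` shrinks the lattice linearly (dimensions rounded to the nearest
    integer) while preserving areal densities: species counts are rescaled by
    the area ratio and rounded to the nearest integer. ``overrides`` are
    applied last and must be valid ``ModelParameters`` fields.
    """
    try:
        p = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}") from None
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = max(1, round(p.lattice * scale))
    area_ratio = (n * n) / (p.lattice * p.lattice)

    def scaled(count: int) -> int:
        return round(count * area_ratio)

    kwargs = dict(
        lattice_nx=n,
        lattice_ny=n,
        n_tcr=scaled(p.n_tcr),
        n_lfa=scaled(p.n_lfa),
        n_self_pmhc=scaled(p.n_self_pmhc),
        n_foreign_pmhc=scaled(p.n_foreign_pmhc),
        n_icam=scaled(p.n_icam),
    )
    unknown = set(overrides) - {f.name for f in dataclasses.fields(ModelParameters)}
    if unknown:
        raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
    kwargs.update(overrides)
    return ModelParameters(**kwargs)


def six_run_protocol(master_seed: int) -> list[tuple[tuple[float, float], int]]:
    """The six-run protocol: initial separation interval + child seed per run.

    Child seeds are derived deterministically from the master seed and kept
    below 2^31. Both the separation field and the protein placements are
    re-randomized per child seed.
    """
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(SIX_RUN_INTERVALS))
    return [
        (interval, int(child.generate_state(1)[0] % (2**31)))
        for interval, child in zip(SIX_RUN_INTERVALS, children)
    ]


# -- deterministic small fixtures for tests ----------------------------------

FIXTURE_NAMES = ("flat15", "flat40", "single_bump", "tcr_pmhc_clamp")


def make_fixture(name: str, size: int = 8) -> MembraneState:
    """Deterministic small states for tests.

    * ``flat15``: flat field at 15 nm with one TCR/self-pMHC pair apposed at
      the centre (exactly one bond possible).
    * ``flat40``: flat field at 40 nm with two LFA-1/ICAM-1 pairs apposed
      (exactly two bonds).
    * ``single_bump``: flat field at 40 nm with the centre patch raised by
      1 nm (bending energy 20 * kappa/(2 a^2) for the default parameters).
    * ``tcr_pmhc_clamp``: flat field at 15 nm, one TCR/self-pMHC pair at the
      centre, no other proteins (single-complex dwell studies).
    """
    c = size // 2
    l40 = np.full((size, size), 40.0)
    l15 = np.full((size, size), 15.0)
    occ1 = np.zeros((size, size), dtype=np.int8)
    occ2 = np.zeros((size, size), dtype=np.int8)
    if name == "flat15":
        occ1[c, c] = K.M1_TCR
        occ2[c, c] = K.M2_SMHC
        return MembraneState(l15, occ1, occ2)
    if name == "flat40":
        occ1[c, c] = K.M1_LFA
        occ2[c, c] = K.M2_ICAM
        occ1[1, 1] = K.M1_LFA
        occ2[1, 1] = K.M2_ICAM
        return MembraneState(l40, occ1, occ2)
    if name == "single_bump":
        l = l40.copy()
        l[c, c] += 1.0
        return MembraneState(l, occ1, occ2)
    if name == "tcr_pmhc_clamp":
        occ1[c, c] = K.M1_TCR
        occ2[c, c] = K.M2_SMHC
        return MembraneState(l15, occ1, occ2)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def initial_state_for_run(
    params: ModelParameters, interval: tuple[float, float], seed: int
) -> MembraneState:
    """Initial state for one run of the protocol (separations and placements
    drawn from the child seed)."""
    return make_initial_state(params, interval, rng=np.random.default_rng(seed))
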