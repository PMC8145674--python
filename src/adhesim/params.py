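"""Model parameters: physical constants, species counts and the simulation schedule.

All energies are dimensionless in units of the thermal energy kBT, all lengths
are in nm, and all times are in units of t0, the duration of one Monte Carlo
step (one sweep of separation moves plus one diffusion attempt per protein and
per apposing partner pair).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = ["ModelParameters", "load_config", "save_config", "effective_rigidity"]


def effective_rigidity(kappa1: float, kappa2: float) -> float:
    """Effective bending rigidity of two apposed membranes, kappa1*kappa2/(kappa1+kappa2).

    The separation field of two fluctuating membranes behaves like a single
    elastic sheet with this reduced rigidity.
    """
    if kappa1 <= 0 or kappa2 <= 0:
        raise ValueError("membrane rigidities must be positive")
    return kappa1 * kappa2 / (kappa1 + kappa2)


@dataclass
class ModelParameters:
    """All physical and algorithmic constants of the adhesion model.

    Defaults reproduce the standard study conditions: a 100x100 lattice of
    15x15 nm^2 patches (1.5x1.5 um^2 membrane), effective rigidity 20 kBT,
    TCR/pMHC binding window 15+-0.5 nm, LFA-1/ICAM-1 window 40+-0.5 nm with
    binding energy 9.5 kBT, 270 proteins per species (120/um^2), trajectories
    of 2e8 steps with the first 4e7 discarded and conformations sampled every
    2e5 t0.
    """

    # geometry
    lattice_nx: int = 100
    lattice_ny: int = 100
    patch_size: float = 15.0  # nm, linear size a of a membrane patch

    # elasticity (kBT); if kappa1 and kappa2 are both given, kappa is derived
    kappa: float = 20.0
    kappa1: Optional[float] = None
    kappa2: Optional[float] = None

    # complex geometry (nm)
    tcr_pmhc_rest_length: float = 15.0
    tcr_pmhc_half_width: float = 0.5
    lfa_icam_rest_length: float = 40.0
    lfa_icam_half_width: float = 0.5

    # binding energies (kBT)
    u_self: float = 6.0
    u_foreign: float = 12.0
    u_lfa_icam: float = 9.5

    # species counts (membrane 1: TCR, LFA-1; membrane 2: pMHC, ICAM-1)
    n_tcr: int = 270
    n_lfa: int = 270
    n_self_pmhc: int = 270
    n_foreign_pmhc: int = 0
    n_icam: int = 270

    # Monte Carlo schedule
    separation_move_halfwidth: float = 0.5  # nm
    n_steps: int = 200_000_000
    equilibration_steps: int = 40_000_000
    sampling_interval: int = 200_000  # t0 between recorded conformations
    dwell_start_step: Optional[int] = None  # default: second half of the run

    # close-contact criterion
    contact_threshold: float = 20.0  # nm

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa1 is not None and self.kappa2 is not None:
            self.kappa = effective_rigidity(self.kappa1, self.kappa2)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def length_mismatch(self) -> float:
        """Rest-length difference Delta-l between the two complex types (nm)."""
        return self.lfa_icam_rest_length - self.tcr_pmhc_rest_length

    @property
    def membrane_area_nm2(self) -> float:
        return self.lattice_nx * self.lattice_ny * self.patch_size**2

    @property
    def membrane_area_um2(self) -> float:
        return self.membrane_area_nm2 / 1e6

    @property
    def n_proteins_membrane1(self) -> int:
        return self.n_tcr + self.n_lfa

    @property
    def n_proteins_membrane2(self) -> int:
        return self.n_self_pmhc + self.n_foreign_pmhc + self.n_icam

    @property
    def n_proteins_total(self) -> int:
        return self.n_proteins_membrane1 + self.n_proteins_membrane2

    @property
    def dwell_window(self) -> tuple[int, int]:
        """Step window [start, end] over which bond dwell statistics accumulate."""
        start = self.dwell_start_step
        if start is None:
            start = self.n_steps // 2
        return (start, self.n_steps)

    def binding_windows(self):
        """(rest, half_width, U) triples for the three complex kinds.

        Kind order: 0 = TCR/self-pMHC, 1 = TCR/foreign-pMHC, 2 = LFA-1/ICAM-1.
        """
        import numpy as np

        rest = np.array(
            [self.tcr_pmhc_rest_length, self.tcr_pmhc_rest_length, self.lfa_icam_rest_length]
        )
        halfw = np.array(
            [self.tcr_pmhc_half_width, self.tcr_pmhc_half_width, self.lfa_icam_half_width]
        )
        u = np.array([self.u_self, self.u_foreign, self.u_lfa_icam])
        return rest, halfw, u

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.lattice_nx < 1 or self.lattice_ny < 1:
            raise ValueError("lattice dimensions must be >= 1")
        for name in (
            "patch_size",
            "kappa",
            "tcr_pmhc_rest_length",
            "lfa_icam_rest_length",
            "contact_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.tcr_pmhc_half_width < self.tcr_pmhc_rest_length):
            raise ValueError("TCR/pMHC half-width must lie in (0, rest length)")
        if not (0 < self.lfa_icam_half_width < self.lfa_icam_rest_length):
            raise ValueError("LFA-1/ICAM-1 half-width must lie in (0, rest length)")
        # the two binding windows must not overlap, otherwise complex kinds
        # would be ambiguous at a shared separation
        lo_t = self.tcr_pmhc_rest_length - self.tcr_pmhc_half_width
        hi_t = self.tcr_pmhc_rest_length + self.tcr_pmhc_half_width
        lo_l = self.lfa_icam_rest_length - self.lfa_icam_half_width
        hi_l = self.lfa_icam_rest_length + self.lfa_icam_half_width
        if max(lo_t, lo_l) <= min(hi_t, hi_l):
            raise ValueError("TCR/pMHC and LFA-1/ICAM-1 binding windows overlap")
        if self.separation_move_halfwidth <= 0:
            raise ValueError("separation_move_halfwidth must be positive")
        for name in ("n_tcr", "n_lfa", "n_self_pmhc", "n_foreign_pmhc", "n_icam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_patches = self.lattice_nx * self.lattice_ny
        if self.n_proteins_membrane1 > n_patches:
            raise ValueError("membrane 1 holds more proteins than patches")
        if self.n_proteins_membrane2 > n_patches:
            raise ValueError("membrane 2 holds more proteins than patches")
        if self.n_steps < 0 or self.equilibration_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.equilibration_steps > self.n_steps:
            raise ValueError("equilibration_steps exceeds n_steps")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)


# -- flat key=value configuration files -------------------------------------

_SKIP_NONE = {"kappa1", "kappa2", "dwell_start_step"}


def save_config(params: ModelParameters, path) -> None:
    """Write parameters as a flat ``key = value`` text file (one key per line)."""
    lines = ["# adhesim configuration (lengths nm, energies kBT, times t0)"]
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if value is None and f.name in _SKIP_NONE:
            continue
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> ModelParameters:
    """Read a flat ``key = value`` configuration file; unknown keys are an error."""
    fields = {f.name: f for f in dataclasses.fields(ModelParameters)}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        typ = fields[key].type
        if value == "None":
            kwargs[key] = None
        elif "int" in str(typ):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return ModelParameters(**kwargs)
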