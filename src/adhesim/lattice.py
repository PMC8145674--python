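"""Membrane geometry and state.

Two apposing membranes are discretized into a periodic square lattice of patch
pairs. Each pair i shares one continuous separation value l_i (nm); each patch
holds at most one protein per membrane. Pairing of the two grids is by
identical (row, col) index -- projected geometry without lateral offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel as K
from .params import ModelParameters

__all__ = [
    "MembraneState",
    "BondView",
    "neighbors",
    "apposing_partner_pairs",
    "bonds",
    "write_snapshot",
    "read_snapshot",
    "SPECIES_M1",
    "SPECIES_M2",
    "COMPLEX_NAMES",
]

# species tags used in snapshots and reports
SPECIES_M1 = {K.M1_TCR: "TCR", K.M1_LFA: "LFA1"}
SPECIES_M2 = {K.M2_SMHC: "SMHC", K.M2_FMHC: "FMHC", K.M2_ICAM: "ICAM1"}
_TAG_TO_M1 = {v: k for k, v in SPECIES_M1.items()}
_TAG_TO_M2 = {v: k for k, v in SPECIES_M2.items()}

COMPLEX_NAMES = {
    K.KIND_TCR_SELF: "TCR/self-pMHC",
    K.KIND_TCR_FOREIGN: "TCR/foreign-pMHC",
    K.KIND_LFA_ICAM: "LFA-1/ICAM-1",
}


def neighbors(patch: tuple[int, int], geometry: tuple[int, int]) -> list[tuple[int, int]]:
    """The four nearest-neighbour patches of ``patch`` with periodic wrap.

    Order: up (row-1), down (row+1), left (col-1), right (col+1). On
    degenerate lattices (a dimension of 1 or 2) wrapped neighbours repeat.
    """
    i, j = patch
    nx, ny = geometry
    if not (0 <= i < nx and 0 <= j < ny):
        raise IndexError(f"patch {patch} outside {nx}x{ny} lattice")
    return [
        ((i - 1) % nx, j),
        ((i + 1) % nx, j),
        (i, (j - 1) % ny),
        (i, (j + 1) % ny),
    ]


class MembraneState:
    """Separation field plus per-membrane protein placements.

    Parameters
    ----------
    l : (nx, ny) array of separations in nm, periodic in both directions.
    occ1, occ2 : (nx, ny) int8 occupancy of membranes 1 and 2
        (``0`` empty; membrane 1: ``1`` TCR, ``2`` LFA-1; membrane 2:
        ``1`` self-pMHC, ``2`` foreign-pMHC, ``3`` ICAM-1).
    step_counter : Monte Carlo time of the state, in t0.
    """

    def __init__(self, l, occ1, occ2, step_counter: int = 0):
        self.l = np.ascontiguousarray(l, dtype=np.float64)
        self.occ1 = np.ascontiguousarray(occ1, dtype=np.int8)
        self.occ2 = np.ascontiguousarray(occ2, dtype=np.int8)
        if self.l.ndim != 2 or self.occ1.shape != self.l.shape or self.occ2.shape != self.l.shape:
            raise ValueError("l, occ1 and occ2 must share one 2-D shape")
        if np.any(self.l < 0):
            raise ValueError("separations must be non-negative")
        self.step_counter = int(step_counter)

    # -- basic geometry ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.l.shape

    @property
    def nx(self) -> int:
        return self.l.shape[0]

    @property
    def ny(self) -> int:
        return self.l.shape[1]

    def copy(self) -> "MembraneState":
        return MembraneState(self.l.copy(), self.occ1.copy(), self.occ2.copy(), self.step_counter)

    def species_counts(self) -> dict[str, int]:
        """Number of proteins per species, keyed by snapshot tag."""
        out = {}
        for code, tag in SPECIES_M1.items():
            out[tag] = int(np.count_nonzero(self.occ1 == code))
        for code, tag in SPECIES_M2.items():
            out[tag] = int(np.count_nonzero(self.occ2 == code))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, MembraneState):
            return NotImplemented
        return (
            self.step_counter == other.step_counter
            and np.array_equal(self.l, other.l)
            and np.array_equal(self.occ1, other.occ1)
            and np.array_equal(self.occ2, other.occ2)
        )


@dataclass
class BondView:
    """Derived view of all bound complexes in a state.

    A bond exists exactly where cognate species are apposed and the local
    separation lies inside the closed binding window of that complex kind.
    """

    patches: list[tuple[int, int]]
    kinds: list[int]

    def __len__(self) -> int:
        return len(self.patches)

    def count(self, kind: int | None = None) -> int:
        if kind is None:
            return len(self.patches)
        return sum(1 for k in self.kinds if k == kind)

    def counts_by_kind(self) -> np.ndarray:
        out = np.zeros(3, dtype=np.int64)
        for k in self.kinds:
            out[k] += 1
        return out


def apposing_partner_pairs(state: MembraneState) -> list[tuple[tuple[int, int], int]]:
    """All patches where cognate species sit apposed, regardless of separation.

    Returns ``[((row, col), kind), ...]``; its length is M, the number of
    apposing partner pairs eligible for pair moves.
    """
    out = []
    occ1, occ2 = state.occ1, state.occ2
    for i in range(state.nx):
        for j in range(state.ny):
            k = K.pair_kind(occ1[i, j], occ2[i, j])
            if k >= 0:
                out.append(((i, j), int(k)))
    return out


def bonds(state: MembraneState, params: ModelParameters) -> BondView:
    """Recompute the bound complexes of a state from scratch (source of truth)."""
    rest, halfw, _ = params.binding_windows()
    patches, kinds = [], []
    for (i, j), k in apposing_partner_pairs(state):
        if rest[k] - halfw[k] <= state.l[i, j] <= rest[k] + halfw[k]:
            patches.append((i, j))
            kinds.append(k)
    return BondView(patches=patches, kinds=kinds)


# -- snapshot files ----------------------------------------------------------
#
# Plain-text format:
#   header lines       key=value (nx, ny, patch_size, step_counter, seed_state)
#   separation field   nx rows of ny decimal values in nm
#   protein records    "<membrane> <row> <col> <tag>" with tag in
#                      {TCR, LFA1, SMHC, FMHC, ICAM1}


def write_snapshot(state: MembraneState, path, patch_size: float = 15.0,
                   seed_state: str = "none") -> None:
    """Write a state as a plain-text snapshot (lossless float round-trip)."""
    lines = [
        f"nx={state.nx}",
        f"ny={state.ny}",
        f"patch_size={patch_size!r}",
        f"step_counter={state.step_counter}",
        f"seed_state={seed_state}",
    ]
    for i in range(state.nx):
        lines.append(" ".join(repr(float(v)) for v in state.l[i]))
    for mem, occ, tags in ((1, state.occ1, SPECIES_M1), (2, state.occ2, SPECIES_M2)):
        for i in range(state.nx):
            for j in range(state.ny):
                code = int(occ[i, j])
                if code:
                    lines.append(f"{mem} {i} {j} {tags[code]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> tuple[MembraneState, dict]:
    """Read a snapshot file; returns the state and the header as a dict."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    pos = 0
    while pos < len(lines) and "=" in lines[pos]:
        key, value = lines[pos].split("=", 1)
        header[key.strip()] = value.strip()
        pos += 1
    try:
        nx = int(header["nx"])
        ny = int(header["ny"])
        step_counter = int(header.get("step_counter", "0"))
    except KeyError as exc:
        raise ValueError(f"snapshot {path} is missing header key {exc}") from None
    l = np.empty((nx, ny))
    for i in range(nx):
        row = np.array([float(v) for v in lines[pos + i].split()])
        if row.size != ny:
            raise ValueError(f"snapshot {path}: field row {i} has {row.size} values, expected {ny}")
        l[i] = row
    pos += nx
    occ1 = np.zeros((nx, ny), dtype=np.int8)
    occ2 = np.zeros((nx, ny), dtype=np.int8)
    for raw in lines[pos:]:
        if not raw.strip():
            continue
        mem_s, i_s, j_s, tag = raw.split()
        mem, i, j = int(mem_s), int(i_s), int(j_s)
        if mem == 1:
            occ1[i, j] = _TAG_TO_M1[tag]
        elif mem == 2:
            occ2[i, j] = _TAG_TO_M2[tag]
        else:
            raise ValueError(f"snapshot {path}: bad membrane id {mem}")
    return MembraneState(l, occ1, occ2, step_counter), header
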