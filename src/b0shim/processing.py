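"""Field-map processing: dual-echo field computation, 3D phase unwrapping,
baseline-shim removal and database QC.

A B0 field map is computed from the phase difference of two gradient echoes:
``field = wrap(phase2 - phase1) / (2π ΔTE)``, which is unambiguous only
within ±1/(2 ΔTE).  Measured phase is wrapped into (−π, π]; the unwrapper
restores a smooth phase up to one 2π constant per connected component.
Before entering the template database, the field generated by the scanner's
baseline shim settings is removed so that maps from different sessions are
comparable, and maps whose footprint covers less than 90% of the brain are
rejected.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, UnknownTermError
from .grids import VoxelGrid, Volume
from .harmonics import CoilCalibration, HarmonicBasis, ShimSetting

__all__ = [
    "PhaseVolume", "FieldMap", "wrap_phase", "fieldmap_from_dual_echo",
    "phase_quality", "unwrap_phase", "remove_baseline_shim", "qc_coverage",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into the half-open interval (−π, π]."""
    w = np.mod(np.asarray(phi, float) + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps exact multiples of 2π+π to −π; push boundary to +π
    w = np.where(w == -np.pi, np.pi, w)
    return w


@dataclass
class PhaseVolume:
    """Phase values (radians) on a grid, tagged wrapped or unwrapped."""

    values: np.ndarray
    grid: VoxelGrid
    wrapped: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError("phase shape does not match grid")


@dataclass
class FieldMap:
    """Off-resonance field in Hz with a brain mask — the pipeline currency.

    ``provenance`` records where the map came from (measured | predicted |
    synthetic); ``shim_state`` tracks whether the scanner baseline shim has
    been removed, guarding against silent double-correction.
    """

    values: np.ndarray
    grid: VoxelGrid
    brain_mask: np.ndarray
    provenance: str = "synthetic"
    shim_state: str = "none"
    applied_shim: ShimSetting | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.brain_mask = np.asarray(self.brain_mask, bool)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError("field shape does not match grid")
        if self.brain_mask.shape != self.grid.shape:
            raise ConfigurationError("mask shape does not match grid")
        if not self.brain_mask.any():
            raise ConfigurationError("brain mask is empty")
        if not np.all(np.isfinite(self.values[self.brain_mask])):
            raise ConfigurationError("field is non-finite inside the brain mask")

    def copy(self) -> "FieldMap":
        return FieldMap(self.values.copy(), self.grid, self.brain_mask.copy(),
                        self.provenance, self.shim_state, self.applied_shim)


def fieldmap_from_dual_echo(phase1: PhaseVolume, phase2: PhaseVolume,
                            dTE_ms: float,
                            brain_mask: np.ndarray | None = None) -> FieldMap:
    """Field map (Hz) from a dual-echo phase pair.

    The phase difference is rewrapped before scaling, so the result is
    alias-free only for |field| < 1000/(2·ΔTE_ms) Hz; larger fields alias
    by multiples of 1000/ΔTE_ms.
    """
    if dTE_ms <= 0:
        raise ValueError(f"dTE_ms must be positive, got {dTE_ms}")
    if phase1.grid != phase2.grid:
        raise ConfigurationError("phase volumes are on different grids")
    dphi = wrap_phase(phase2.values - phase1.values)
    hz = dphi / (2.0 * np.pi * dTE_ms * 1e-3)
    if brain_mask is None:
        brain_mask = np.ones(phase1.grid.shape, bool)
    return FieldMap(hz, phase1.grid, brain_mask, provenance="measured")


def phase_quality(wrapped: PhaseVolume, magnitude: np.ndarray | None = None,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Quality map for unwrapping: inverse local phase-gradient variance.

    Wrapped first differences along each axis are combined into a local
    variance; low variance (smooth phase) means high quality.  If a
    magnitude image is given it multiplies the quality, down-weighting
    voxels with little signal.
    """
    w = wrapped.values
    grad_sq = np.zeros_like(w)
    for axis in range(3):
        d = wrap_phase(np.diff(w, axis=axis))
        pad = [(0, 0)] * 3
        pad[axis] = (0, 1)
        fwd = np.pad(d, pad, constant_values=0.0)
        pad[axis] = (1, 0)
        bwd = np.pad(d, pad, constant_values=0.0)
        grad_sq += 0.5 * (fwd ** 2 + bwd ** 2)
    q = 1.0 / (1.0 + grad_sq)
    if magnitude is not None:
        m = np.asarray(magnitude, float)
        mmax = m.max()
        if mmax > 0:
            q = q * (m / mmax)
    if mask is not None:
        q = np.where(np.asarray(mask, bool), q, 0.0)
    return q


_NEIGHBOR_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0),
                     (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def unwrap_phase(wrapped: PhaseVolume, quality: np.ndarray | None = None,
                 mask: np.ndarray | None = None,
                 magnitude: np.ndarray | None = None) -> PhaseVolume:
    """Quality-guided region-growing 3D phase unwrapping.

    Voxels are absorbed in decreasing quality order, each unwrapped against
    an already-unwrapped 6-neighbour, so the path of integration follows
    reliable phase first.  The output equals the input modulo 2π at every
    masked voxel; within each connected mask component the result is the
    true smooth phase up to a single 2π multiple whenever neighbouring true
    phase differences stay below π.  Each component's free 2π constant is
    fixed by bringing the component median into (−π, π].
    """
    shape = wrapped.grid.shape
    if mask is None:
        mask = np.ones(shape, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ConfigurationError("unwrap mask is empty")
    if quality is None:
        quality = phase_quality(wrapped, magnitude=magnitude, mask=mask)
    w = wrapped.values
    out = np.zeros(shape)
    done = np.zeros(shape, bool)

    labels, n_comp = ndimage.label(mask)
    counter = 0
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        q_comp = np.where(comp_mask, quality, -np.inf)
        seed = np.unravel_index(np.argmax(q_comp), shape)
        out[seed] = w[seed]
        done[seed] = True
        heap = []

        def push_neighbors(vox):
            nonlocal counter
            for off in _NEIGHBOR_OFFSETS:
                nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
                if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                        and 0 <= nb[2] < shape[2]
                        and comp_mask[nb] and not done[nb]):
                    counter += 1
                    heapq.heappush(heap, (-quality[nb], counter, nb, vox))

        push_neighbors(seed)
        while heap:
            _, _, vox, ref = heapq.heappop(heap)
            if done[vox]:
                continue
            out[vox] = out[ref] + wrap_phase(np.array(w[vox] - w[ref]))[()]
            done[vox] = True
            push_neighbors(vox)

        med = np.median(out[comp_mask])
        out[comp_mask] -= 2.0 * np.pi * np.round(med / (2.0 * np.pi))

    out[~mask] = w[~mask]
    return PhaseVolume(out, wrapped.grid, wrapped=False)


def _setting_to_coefficients(setting, basis: HarmonicBasis,
                             calibration: CoilCalibration | None):
    if calibration is not None:
        hw = setting if isinstance(setting, dict) else setting.to_dict()
        return calibration.field_coefficients(hw)
    if isinstance(setting, dict):
        setting = ShimSetting.from_dict(setting, basis.max_order)
    return setting


def remove_baseline_shim(field: FieldMap, setting, basis: HarmonicBasis,
                         calibration: CoilCalibration | None = None) -> FieldMap:
    """Subtract the field generated by recorded baseline shim settings.

    ``setting`` is either a :class:`ShimSetting` of harmonic coefficients,
    or — when ``calibration`` is given — per-coil hardware values that are
    mapped through the premeasured coil calibration first.  The subtraction
    is linear: removing settings a then b equals removing a+b, and applying
    removal twice shifts the field again by the same shim field.
    """
    coeffs = _setting_to_coefficients(setting, basis, calibration)
    unknown = [n for n in coeffs.terms if n not in basis.term_names]
    if unknown:
        raise UnknownTermError(unknown)
    shim_field = basis.synthesize(coeffs)
    out = field.copy()
    out.values = field.values - shim_field
    out.shim_state = "baseline-removed"
    return out


def qc_coverage(fieldmap_footprint, structural_brain_mask, transform,
                threshold: float = 0.90):
    """Brain-coverage QC of a field-map acquisition.

    ``fieldmap_footprint`` is the acquired field-of-view mask on the field
    map grid (a boolean :class:`~b0shim.grids.Volume`), ``transform`` maps
    field-map world coordinates into structural world coordinates.
    Coverage is the fraction of structural brain voxels that fall inside
    the footprint; scans under ``threshold`` (default the 90% database
    rule) are rejected.

    Returns ``(coverage, accepted)``.
    """
    from .spatial import resample  # deferred to avoid an import cycle

    brain = np.asarray(structural_brain_mask.values, bool)
    if not brain.any():
        raise ConfigurationError("structural brain mask is empty")
    foot = Volume(np.asarray(fieldmap_footprint.values, float),
                  fieldmap_footprint.grid)
    warped, valid = resample(foot, transform, structural_brain_mask.grid,
                             interp="nearest")
    inside = (warped.values > 0.5) & valid
    coverage = float(np.count_nonzero(inside & brain) / np.count_nonzero(brain))
    return coverage, coverage >= threshold
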