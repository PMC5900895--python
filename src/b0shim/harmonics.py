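"""Real solid spherical harmonics, field decomposition and coil calibration.

Shim coils on whole-body MR systems generate corrective fields shaped as
real solid harmonics.  This module evaluates those harmonics as Cartesian
polynomials on a voxel grid (the unnormalized shim-coil convention: 1; x;
y; z; z^2-(x^2+y^2)/2; xz; yz; x^2-y^2; xy; ...), fits measured fields to
the basis by masked linear least squares, and calibrates synthetic shim
coils from field maps acquired at a range of hardware settings.

Coefficients are in Hz·mm^-n for an order-n term, with world coordinates
in mm and the isocenter at the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateCalibrationError, SingularFitError,
                     UnknownTermError)
from .grids import VoxelGrid, Volume

__all__ = [
    "Term", "HarmonicBasis", "ShimSetting", "CoilCalibration",
    "build_basis", "decompose_field", "calibrate_coil", "term_names",
]

MAX_SUPPORTED_ORDER = 4

# Cartesian polynomial forms; every function is harmonic (Laplacian == 0),
# verified by the finite-difference property test.  rho2 = x^2 + y^2.
_TERM_TABLE = [
    # (name, order, function of (x, y, z))
    ("DC", 0, lambda x, y, z: np.ones_like(x)),
    ("X", 1, lambda x, y, z: x),
    ("Y", 1, lambda x, y, z: y),
    ("Z", 1, lambda x, y, z: z),
    ("Z2", 2, lambda x, y, z: z * z - (x * x + y * y) / 2.0),
    ("XZ", 2, lambda x, y, z: x * z),
    ("YZ", 2, lambda x, y, z: y * z),
    ("X2-Y2", 2, lambda x, y, z: x * x - y * y),
    ("XY", 2, lambda x, y, z: x * y),
    ("Z3", 3, lambda x, y, z: z ** 3 - 1.5 * z * (x * x + y * y)),
    ("XZ2", 3, lambda x, y, z: x * (z * z - (x * x + y * y) / 4.0)),
    ("YZ2", 3, lambda x, y, z: y * (z * z - (x * x + y * y) / 4.0)),
    ("Z(X2-Y2)", 3, lambda x, y, z: z * (x * x - y * y)),
    ("XYZ", 3, lambda x, y, z: x * y * z),
    ("X3", 3, lambda x, y, z: x ** 3 - 3.0 * x * y * y),
    ("Y3", 3, lambda x, y, z: 3.0 * x * x * y - y ** 3),
    ("Z4", 4, lambda x, y, z: z ** 4 - 3.0 * z * z * (x * x + y * y)
        + 0.375 * (x * x + y * y) ** 2),
    ("XZ3", 4, lambda x, y, z: x * z * (z * z - 0.75 * (x * x + y * y))),
    ("YZ3", 4, lambda x, y, z: y * z * (z * z - 0.75 * (x * x + y * y))),
    ("Z2(X2-Y2)", 4, lambda x, y, z: (x * x - y * y)
        * (6.0 * z * z - x * x - y * y)),
    ("XYZ2", 4, lambda x, y, z: x * y * (6.0 * z * z - x * x - y * y)),
    ("ZX3", 4, lambda x, y, z: z * (x ** 3 - 3.0 * x * y * y)),
    ("ZY3", 4, lambda x, y, z: z * (3.0 * x * x * y - y ** 3)),
    ("X4", 4, lambda x, y, z: x ** 4 - 6.0 * x * x * y * y + y ** 4),
    ("XY(X2-Y2)", 4, lambda x, y, z: x * y * (x * x - y * y)),
]


@dataclass(frozen=True)
class Term:
    name: str
    order: int


def term_names(max_order: int) -> tuple[str, ...]:
    """Names of all harmonic terms through ``max_order``."""
    _check_order(max_order)
    return tuple(n for n, o, _ in _TERM_TABLE if o <= max_order)


def _check_order(max_order: int) -> int:
    if not (0 <= int(max_order) <= MAX_SUPPORTED_ORDER):
        raise ValueError(
            f"max_order must be in [0, {MAX_SUPPORTED_ORDER}], got {max_order}")
    return int(max_order)


@dataclass
class ShimSetting:
    """Per-term harmonic coefficients of a shim field (Hz·mm^-n)."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    max_order: int

    def __post_init__(self):
        self.terms = tuple(self.terms)
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))
        if len(self.terms) != self.coefficients.size:
            raise ValueError("coefficient vector length does not match term list")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("shim coefficients must be finite")

    @classmethod
    def zero(cls, max_order: int) -> "ShimSetting":
        names = term_names(max_order)
        return cls(names, np.zeros(len(names)), max_order)

    @classmethod
    def from_dict(cls, d: dict, max_order: int | None = None) -> "ShimSetting":
        if max_order is None:
            orders = {n: o for n, o, _ in _TERM_TABLE}
            unknown = [k for k in d if k not in orders]
            if unknown:
                raise UnknownTermError(unknown)
            max_order = max((orders[k] for k in d), default=0)
        names = term_names(max_order)
        unknown = [k for k in d if k not in names]
        if unknown:
            raise UnknownTermError(unknown)
        coeffs = np.array([float(d.get(n, 0.0)) for n in names])
        return cls(names, coeffs, max_order)

    def to_dict(self) -> dict:
        return {n: float(c) for n, c in zip(self.terms, self.coefficients)}

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.coefficients[self.terms.index(name)])
        except ValueError:
            raise UnknownTermError([name]) from None

    def __add__(self, other: "ShimSetting") -> "ShimSetting":
        if self.terms != other.terms:
            raise UnknownTermError(set(self.terms) ^ set(other.terms))
        return ShimSetting(self.terms, self.coefficients + other.coefficients,
                           self.max_order)

    def __neg__(self) -> "ShimSetting":
        return ShimSetting(self.terms, -self.coefficients, self.max_order)

    def __mul__(self, k: float) -> "ShimSetting":
        return ShimSetting(self.terms, self.coefficients * float(k), self.max_order)

    __rmul__ = __mul__


class HarmonicBasis:
    """Solid-harmonic basis fields evaluated on a voxel grid.

    ``basis_volumes`` has shape ``(n_terms, *grid.shape)``; each volume is
    the field (Hz) produced by a unit coefficient of its term.
    """

    def __init__(self, grid: VoxelGrid, max_order: int, basis_volumes: np.ndarray,
                 terms: tuple[Term, ...]):
        self.grid = grid
        self.max_order = max_order
        self.basis_volumes = basis_volumes
        self.terms = terms

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def index(self, name: str) -> int:
        try:
            return self.term_names.index(name)
        except ValueError:
            raise UnknownTermError([name]) from None

    def subset_indices(self, max_order: int) -> np.ndarray:
        _check_order(max_order)
        if max_order > self.max_order:
            raise ValueError(
                f"basis holds orders <= {self.max_order}, requested {max_order}")
        return np.array([i for i, t in enumerate(self.terms) if t.order <= max_order])

    def design_matrix(self, mask: np.ndarray) -> np.ndarray:
        """Masked design matrix of shape (n_masked_voxels, n_terms)."""
        mask = np.asarray(mask, bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match basis grid")
        return self.basis_volumes[:, mask].T

    def synthesize(self, setting: ShimSetting) -> np.ndarray:
        """Field (Hz) generated by ``setting`` on the basis grid."""
        unknown = [n for n in setting.terms if n not in self.term_names]
        if unknown:
            raise UnknownTermError(unknown)
        out = np.zeros(self.grid.shape)
        for name, c in zip(setting.terms, setting.coefficients):
            if c != 0.0:
                out += c * self.basis_volumes[self.index(name)]
        return out


def build_basis(grid: VoxelGrid, max_order: int) -> HarmonicBasis:
    """Evaluate all real solid harmonics through ``max_order`` on ``grid``.

    Returns ``(max_order + 1)**2`` basis volumes in shim-coil term order
    (DC; X, Y, Z; Z2, XZ, YZ, X2-Y2, XY; ...).
    """
    max_order = _check_order(max_order)
    x, y, z = grid.world_coordinates()
    terms = []
    vols = []
    for name, order, fn in _TERM_TABLE:
        if order <= max_order:
            terms.append(Term(name, order))
            vols.append(fn(x, y, z))
    return HarmonicBasis(grid, max_order, np.stack(vols), tuple(terms))


def _values_of(field) -> np.ndarray:
    return np.asarray(getattr(field, "values", field), float)


def _masked_lstsq(A: np.ndarray, b: np.ndarray, names: tuple[str, ...],
                  rcond: float = 1e-10):
    """Column-scaled least squares with explicit rank-deficiency reporting."""
    scale = np.max(np.abs(A), axis=0)
    scale[scale == 0.0] = 1.0
    As = A / scale
    u, s, vt = np.linalg.svd(As, full_matrices=False)
    if s[0] == 0.0 or s[-1] < rcond * s[0]:
        bad = s < rcond * max(s[0], 1.0)
        involved = np.any(np.abs(vt[bad]) > 0.3, axis=0)
        raise SingularFitError([n for n, i in zip(names, involved) if i])
    y = vt.T @ ((u.T @ b) / s)
    coeffs = y / scale
    residual = float(np.linalg.norm(b - A @ coeffs))
    return coeffs, residual


def decompose_field(field, basis: HarmonicBasis, mask: np.ndarray,
                    max_order: int | None = None):
    """Least-squares harmonic decomposition of a field over a mask.

    Returns ``(setting, residual_norm)`` where ``setting`` minimizes the sum
    of squared residuals ``field - synthesize(setting)`` over masked voxels.
    Rank deficiency (mask too small or degenerate) raises
    :class:`~b0shim.errors.SingularFitError` naming the deficient terms.
    """
    mask = np.asarray(mask, bool)
    vals = _values_of(field)
    if vals.shape != basis.grid.shape:
        raise ValueError("field shape does not match basis grid")
    if max_order is None:
        max_order = basis.max_order
    idx = basis.subset_indices(max_order)
    names = tuple(basis.term_names[i] for i in idx)
    if mask.sum() < len(idx):
        raise SingularFitError(names)
    A = basis.design_matrix(mask)[:, idx]
    b = vals[mask]
    if not np.all(np.isfinite(b)):
        raise ValueError("field contains non-finite values inside the mask")
    coeffs, residual = _masked_lstsq(A, b, names)
    return ShimSetting(names, coeffs, max_order), residual


@dataclass
class CoilCalibration:
    """Linear map from hardware shim-coil settings to harmonic coefficients.

    ``coils[name][term]`` is the harmonic coefficient (Hz·mm^-n) produced by
    one hardware unit on that coil; ``residuals[name]`` is the RMS misfit of
    the per-coil linear model across calibration settings.
    """

    coils: dict
    residuals: dict
    max_order: int

    def field_coefficients(self, hardware: dict) -> ShimSetting:
        """Harmonic coefficients of the field for given per-coil settings."""
        unknown = [c for c in hardware if c not in self.coils]
        if unknown:
            raise UnknownTermError(unknown)
        names = term_names(self.max_order)
        coeffs = np.zeros(len(names))
        for coil, value in hardware.items():
            for term, per_unit in self.coils[coil].items():
                coeffs[names.index(term)] += per_unit * float(value)
        return ShimSetting(names, coeffs, self.max_order)

    def to_json_dict(self) -> dict:
        return {
            "max_order": self.max_order,
            "coils": {c: {t: float(v) for t, v in d.items()}
                      for c, d in self.coils.items()},
            "residuals": {c: float(r) for c, r in self.residuals.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CoilCalibration":
        return cls(coils={c: dict(t) for c, t in d["coils"].items()},
                   residuals=dict(d.get("residuals", {})),
                   max_order=int(d["max_order"]))


def calibrate_coil(measured_fields, settings, basis: HarmonicBasis,
                   mask: np.ndarray, coil_name: str = "coil") -> CoilCalibration:
    """Calibrate one shim coil from fields measured at several settings.

    Each measured field is decomposed into harmonics over ``mask``; the
    per-term coefficients are then fit linearly against the hardware setting
    values.  If a zero setting is present its field is taken as the baseline
    and the fit is forced through the origin; otherwise an intercept absorbs
    the baseline.  Returns Hz·mm^-n per hardware unit for every term.
    """
    settings = np.asarray(settings, float)
    fields = list(measured_fields)
    if len(fields) != settings.size:
        raise ValueError("need one measured field per hardware setting")
    if settings.size < 2 or np.ptp(settings) == 0.0:
        raise DegenerateCalibrationError(
            "calibration needs at least two distinct hardware settings")
    coeff_rows = []
    for f in fields:
        setting, _ = decompose_field(f, basis, mask)
        coeff_rows.append(setting.coefficients)
    C = np.vstack(coeff_rows)                    # (n_settings, n_terms)
    zero_idx = np.flatnonzero(settings == 0.0)
    if zero_idx.size:
        C = C - C[zero_idx[0]]
        s = settings
        denom = float(s @ s)
        slopes = (s @ C) / denom
        fit = np.outer(s, slopes)
    else:
        s = settings - settings.mean()
        slopes = (s @ (C - C.mean(axis=0))) / float(s @ s)
        fit = np.outer(settings - settings.mean(), slopes) + C.mean(axis=0)
        C = C  # intercept handled in fit
    residual = float(np.sqrt(np.mean((C - fit) ** 2)))
    names = term_names(basis.max_order)
    return CoilCalibration(
        coils={coil_name: {n: float(v) for n, v in zip(names, slopes)}},
        residuals={coil_name: residual},
        max_order=basis.max_order,
    )


def merge_calibrations(calibrations) -> CoilCalibration:
    """Combine single-coil calibrations into one multi-coil table."""
    calibrations = list(calibrations)
    if not calibrations:
        raise ValueError("no calibrations to merge")
    max_order = calibrations[0].max_order
    coils, residuals = {}, {}
    for c in calibrations:
        if c.max_order != max_order:
            raise ValueError("calibrations disagree on max_order")
        coils.update(c.coils)
        residuals.update(c.residuals)
    return CoilCalibration(coils, residuals, max_order)
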