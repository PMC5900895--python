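"""Synthetic cohort generator: parametric head susceptibility models,
dipole-kernel field simulation, affine subject variation and dual-echo
phase data.

The generator emulates the statistical structure a field-map template
method relies on: every subject shares a common low-order field pattern
(dominant inferior-superior and anterior-posterior gradients from the
body, plus the head-shape-induced field), on top of which sit localized
high-order perturbations near the frontal sinus and ear-canal air
cavities.  Subjects differ by a random affine (head size, position,
rotation), by cavity geometry, and by an unknown baseline shim that the
processing pipeline must remove.

The susceptibility-to-field forward model is the k-space dipole kernel
D(k) = 1/3 − kz²/|k|² with the Lorentz-sphere convention (the interior of
a uniform sphere experiences zero shift) and D(0) := 0, so the simulated
field is mean-free — shimming is invariant to the DC term, making the
mean a pure convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .grids import VoxelGrid, Volume
from .harmonics import ShimSetting, term_names
from .processing import FieldMap, PhaseVolume, wrap_phase
from .spatial import AffineTransform

__all__ = [
    "CohortConfig", "SusceptibilityModel", "Subject", "TemplateAnatomy",
    "make_head_model", "dipole_field", "template_anatomy", "sample_cohort",
    "simulate_dual_echo",
]

GAMMA_HZ_PER_PPM_7T = 297.2  # proton Larmor frequency shift per ppm at 7 T


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Geometry is specified in standard-space mm (isocenter origin,
    +y anterior, +z superior); amplitudes are the free parameters of the
    generator, chosen to give a plausible 7 T brain field (unshimmed
    standard deviation on the order of 10² Hz, localized cavity fields of
    a few tens of Hz), not as claims about any human population.
    """

    n_subjects: int = 20
    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    b0_hz_per_ppm: float = GAMMA_HZ_PER_PPM_7T
    chi_air_ppm: float = 0.36          # air vs tissue susceptibility offset

    # per-axis subject variation (sd of the sampling distributions)
    rotation_sd_deg: tuple[float, float, float] = (5.0, 5.0, 5.0)
    scale_sd_frac: tuple[float, float, float] = (0.05, 0.05, 0.05)
    translation_sd_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    # cavity variability and localized high-order field perturbations
    include_cavities: bool = True
    cavity_scale_sd_frac: float = 0.2
    sinus_amp_hz: float = 30.0
    ear_amp_hz: float = 20.0
    perturbation_sigma_mm: float = 10.0

    # common body-induced field gradients (scanner frame)
    grad_y_hz_per_mm: float = 1.0
    grad_z_hz_per_mm: float = 2.0

    noise_sd_hz: float = 1.0

    # unknown scanner state before baseline-shim removal
    baseline_order1_range_hz_per_mm: float = 0.5
    baseline_order2_range_hz_per_mm2: float = 0.01

    # head geometry (standard space)
    head_radii_mm: tuple[float, float, float] = (42.0, 50.0, 46.0)
    brain_radii_mm: tuple[float, float, float] = (36.0, 42.0, 38.0)
    brain_center_mm: tuple[float, float, float] = (0.0, 0.0, 7.0)
    sinus_center_mm: tuple[float, float, float] = (0.0, 34.0, -16.0)
    sinus_radius_mm: float = 7.0
    ear_center_mm: tuple[float, float, float] = (37.0, 0.0, -13.0)
    ear_radius_mm: float = 6.0
    neck_radius_mm: float = 30.0
    neck_center_xy_mm: tuple[float, float] = (0.0, -8.0)
    neck_top_mm: float = -38.0

    make_phases: bool = False
    TE1_ms: float = 4.08
    dTE_ms: float = 1.02

    def grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.shape, self.voxel_size_mm)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if any(s < 0 for s in self.scale_sd_frac):
            raise ConfigurationError("scale variation must be nonnegative")


@dataclass
class SusceptibilityModel:
    """Susceptibility distribution (ppm) with anatomical masks.

    ``chi`` is 0 in tissue and ``chi_air_ppm`` in air (outside the head and
    inside the cavities).  ``masks`` holds boolean volumes: head, brain,
    frontal_sinus, ear_canals, neck.  brain ⊂ head; the cavity masks are
    carved out of tissue.
    """

    chi: Volume
    masks: dict


def _ellipsoid(x, y, z, center, radii):
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def make_head_model(grid: VoxelGrid, config: CohortConfig, seed: int = 0,
                    warp: AffineTransform | None = None) -> SusceptibilityModel:
    """Build an ellipsoidal head + brain with air cavities on ``grid``.

    ``warp`` (standard→subject world) moves the whole parametric geometry;
    it is applied analytically, so a warped subject is *exactly* the
    standard anatomy under the affine, with no interpolation error.
    Cavity radii are jittered by ``cavity_scale_sd_frac`` using ``seed``
    (zero jitter leaves them at the standard size).  The model must fit
    inside the grid with a margin; a head touching the volume border is a
    configuration error.
    """
    rng = np.random.default_rng(seed)
    if config.cavity_scale_sd_frac > 0:
        sinus_scale, ear_scale = np.clip(
            1.0 + config.cavity_scale_sd_frac * rng.standard_normal(2), 0.3, 2.0)
    else:
        sinus_scale, ear_scale = 1.0, 1.0

    xs, ys, zs = grid.world_coordinates()
    if warp is not None:
        inv = warp.invert().matrix
        x = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2] * zs + inv[0, 3]
        y = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2] * zs + inv[1, 3]
        z = inv[2, 0] * xs + inv[2, 1] * ys + inv[2, 2] * zs + inv[2, 3]
    else:
        x, y, z = xs, ys, zs

    head = _ellipsoid(x, y, z, (0.0, 0.0, 0.0), config.head_radii_mm)
    brain = _ellipsoid(x, y, z, config.brain_center_mm, config.brain_radii_mm)
    nx, ny = config.neck_center_xy_mm
    neck = (((x - nx) ** 2 + (y - ny) ** 2) <= config.neck_radius_mm ** 2) \
        & (z <= config.neck_top_mm)
    neck &= ~head

    if config.include_cavities:
        r_s = config.sinus_radius_mm * sinus_scale
        sinus = _ellipsoid(x, y, z, config.sinus_center_mm, (r_s, r_s, r_s))
        r_e = config.ear_radius_mm * ear_scale
        ex, ey, ez = config.ear_center_mm
        ears = _ellipsoid(x, y, z, (ex, ey, ez), (r_e, r_e, r_e)) \
            | _ellipsoid(x, y, z, (-ex, ey, ez), (r_e, r_e, r_e))
        sinus &= head & ~brain
        ears &= head & ~brain
    else:
        sinus = np.zeros(grid.shape, bool)
        ears = np.zeros(grid.shape, bool)

    border = np.zeros(grid.shape, bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    if np.any(head & border):
        raise ConfigurationError(
            "head model touches the grid border; enlarge the grid or voxels")

    tissue = (head | neck) & ~sinus & ~ears
    chi = np.where(tissue, 0.0, config.chi_air_ppm)
    return SusceptibilityModel(
        chi=Volume(chi, grid),
        masks={"head": head, "brain": brain, "frontal_sinus": sinus,
               "ear_canals": ears, "neck": neck},
    )


def dipole_field(model, b0_hz_per_ppm: float = GAMMA_HZ_PER_PPM_7T,
                 pad_factor: int = 2) -> FieldMap:
    """Susceptibility-induced field by k-space dipole convolution.

    Accepts a :class:`SusceptibilityModel` or a bare χ :class:`Volume`
    (ppm).  The background value (mean of the volume faces) is subtracted
    before zero-padding so the finite volume behaves as an object embedded
    in infinite background medium; a constant χ offset produces no field
    under this kernel (D(0) = 0).
    """
    if pad_factor < 2:
        raise ValueError("pad_factor must be >= 2 to suppress wrap-around")
    if isinstance(model, SusceptibilityModel):
        chi_vol = model.chi
        brain = model.masks["brain"]
    else:
        chi_vol = model
        brain = np.ones(model.grid.shape, bool)
    grid = chi_vol.grid
    chi = np.asarray(chi_vol.values, float)
    if not np.all(np.isfinite(chi)):
        raise ValueError("susceptibility volume contains non-finite values")
    faces = np.concatenate([chi[0].ravel(), chi[-1].ravel(),
                            chi[:, 0].ravel(), chi[:, -1].ravel(),
                            chi[:, :, 0].ravel(), chi[:, :, -1].ravel()])
    chi = chi - faces.mean()

    shape = np.array(grid.shape)
    pshape = shape * pad_factor
    lo = (pshape - shape) // 2
    padded = np.zeros(pshape)
    sl = tuple(slice(l, l + s) for l, s in zip(lo, shape))
    padded[sl] = chi

    vox = grid.voxel_size_mm
    ks = [np.fft.fftfreq(int(n), d=v) for n, v in zip(pshape, vox)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx * kx + ky * ky + kz * kz
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - (kz * kz) / k2
    kernel[0, 0, 0] = 0.0  # mean field is a convention; shimming is DC-blind
    field = np.fft.ifftn(np.fft.fftn(padded) * kernel).real[sl]
    return FieldMap(field * b0_hz_per_ppm, grid, brain,
                    provenance="synthetic", shim_state="baseline-removed")


@dataclass
class TemplateAnatomy:
    """The cohort's shared anatomy at identity pose (the standard space)."""

    model: SusceptibilityModel
    structural: Volume
    field: FieldMap
    grid: VoxelGrid


def _structural_from(model: SusceptibilityModel, noise_rng=None,
                     noise_sd: float = 0.0) -> Volume:
    m = model.masks
    intensity = (1.0 * m["head"].astype(float)
                 + 0.6 * m["brain"].astype(float)
                 + 0.8 * (m["neck"] & ~m["head"]).astype(float)
                 - 0.9 * m["frontal_sinus"].astype(float)
                 - 0.9 * m["ear_canals"].astype(float))
    sm = ndimage.gaussian_filter(intensity, sigma=1.0)
    if noise_rng is not None and noise_sd > 0:
        sm = sm + noise_rng.normal(0.0, noise_sd, sm.shape)
    return Volume(sm, model.chi.grid)


def _common_gradients(grid: VoxelGrid, config: CohortConfig) -> np.ndarray:
    _, y, z = grid.world_coordinates()
    return config.grad_y_hz_per_mm * y + config.grad_z_hz_per_mm * z


def _gaussian_blob(grid: VoxelGrid, center, sigma_mm: float) -> np.ndarray:
    x, y, z = grid.world_coordinates()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return np.exp(-0.5 * d2 / sigma_mm ** 2)


def template_anatomy(config: CohortConfig) -> TemplateAnatomy:
    """Shared mean anatomy, its structural proxy and its field, at identity.

    This volume doubles as the package's standard space: subjects are
    registered to ``structural`` the way real pipelines register to a
    brain atlas.
    """
    grid = config.grid()
    cfg0 = replace(config, cavity_scale_sd_frac=0.0)
    model = make_head_model(grid, cfg0, seed=0)
    fld = dipole_field(model, config.b0_hz_per_ppm)
    fld.values = fld.values + _common_gradients(grid, config)
    return TemplateAnatomy(model=model, structural=_structural_from(model),
                           field=fld, grid=grid)


@dataclass
class Subject:
    """One synthetic database entry.

    ``field_true`` is the baseline-shim-free field; ``transform`` maps the
    subject's world coordinates to standard space (the ground truth a
    registration should recover); ``baseline_shim`` is the scanner state
    the processing pipeline must remove from measured data.
    """

    id: str
    field_true: FieldMap
    structural: Volume
    brain_mask: np.ndarray
    transform: AffineTransform
    baseline_shim: ShimSetting
    phase1: PhaseVolume | None = None
    phase2: PhaseVolume | None = None

    @property
    def grid(self) -> VoxelGrid:
        return self.field_true.grid


def _draw_affine(rng, config: CohortConfig, subject_space: str) -> AffineTransform:
    rot = rng.normal(0.0, config.rotation_sd_deg, 3)
    scales = np.clip(rng.normal(1.0, config.scale_sd_frac, 3), 0.7, 1.3)
    trans = rng.normal(0.0, config.translation_sd_mm, 3)
    # W: standard -> subject (geometry warp); the subject-to-standard truth
    # is its inverse.
    return AffineTransform.from_params(rotations_deg=rot, translations_mm=trans,
                                       scales=scales, source="standard",
                                       target=subject_space)


def sample_cohort(config: CohortConfig) -> list:
    """Draw a cohort of synthetic subjects; fully seeded and reproducible.

    A draw whose head pose does not fit the grid is rejected and redrawn
    from a spawned seed (up to 5 attempts), so cohort generation is robust
    to tail pose draws while staying deterministic per seed.
    """
    grid = config.grid()
    root = np.random.SeedSequence(config.seed)
    subjects = []
    for i, child in enumerate(root.spawn(config.n_subjects)):
        sid = f"sub-{i:03d}"
        for attempt, seq in enumerate([child] + list(child.spawn(4))):
            rng = np.random.default_rng(seq)
            try:
                subjects.append(_draw_subject(sid, rng, grid, config))
                break
            except ConfigurationError:
                continue
        else:
            raise ConfigurationError(
                f"{sid}: no admissible head pose in 5 draws; "
                "reduce pose variation or enlarge the grid")
    return subjects


def _draw_subject(sid: str, rng, grid: VoxelGrid, config: CohortConfig) -> "Subject":
    space = f"subject/{sid}"
    warp = _draw_affine(rng, config, space)
    model_seed = int(rng.integers(2 ** 31))
    model = make_head_model(grid, config, seed=model_seed, warp=warp)

    fld = dipole_field(model, config.b0_hz_per_ppm)
    values = fld.values + _common_gradients(grid, config)
    if config.include_cavities:
        sinus_c = warp.apply(np.asarray(config.sinus_center_mm))
        amp = rng.normal(0.0, config.sinus_amp_hz)
        values = values + amp * _gaussian_blob(grid, sinus_c,
                                               config.perturbation_sigma_mm)
        ex, ey, ez = config.ear_center_mm
        for side in (+1, -1):
            ear_c = warp.apply(np.array([side * ex, ey, ez]))
            amp = rng.normal(0.0, config.ear_amp_hz)
            values = values + amp * _gaussian_blob(
                grid, ear_c, config.perturbation_sigma_mm)
    if config.noise_sd_hz > 0:
        values = values + rng.normal(0.0, config.noise_sd_hz, grid.shape)

    brain = model.masks["brain"]
    field_true = FieldMap(values, grid, brain, provenance="synthetic",
                          shim_state="baseline-removed")

    names = term_names(2)
    coeffs = np.zeros(len(names))
    for j, name in enumerate(names):
        if name == "DC":
            continue
        r = (config.baseline_order1_range_hz_per_mm if name in ("X", "Y", "Z")
             else config.baseline_order2_range_hz_per_mm2)
        coeffs[j] = rng.uniform(-r, r)
    baseline = ShimSetting(names, coeffs, 2)

    structural = _structural_from(model)
    subj = Subject(id=sid, field_true=field_true, structural=structural,
                   brain_mask=brain, transform=warp.invert(),
                   baseline_shim=baseline)
    if config.make_phases:
        from .harmonics import build_basis
        basis = build_basis(grid, 2)
        measured = values + basis.synthesize(baseline)
        mag = np.clip(structural.values, 0.0, None) + 0.05
        p1, p2 = simulate_dual_echo(
            FieldMap(measured, grid, brain), config.TE1_ms, config.dTE_ms,
            magnitude=mag, noise_sigma=0.0)
        subj.phase1, subj.phase2 = p1, p2
    return subj


def simulate_dual_echo(field: FieldMap, TE1_ms: float, dTE_ms: float,
                       magnitude: np.ndarray | None = None,
                       noise_sigma: float = 0.0, phi0: float = 0.0,
                       seed: int = 0):
    """Wrapped dual-echo phase images of a field map.

    ``phase_i = wrap(2π · field · TE_i / 1000 + φ0)``; optional complex
    Gaussian noise of standard deviation ``noise_sigma`` is added to the
    magnitude-weighted complex signal before taking the angle, emulating
    thermal noise in the raw echoes.
    """
    if dTE_ms <= 0:
        raise ValueError(f"dTE_ms must be positive, got {dTE_ms}")
    rng = np.random.default_rng(seed)
    mag = np.ones(field.grid.shape) if magnitude is None \
        else np.asarray(magnitude, float)
    phases = []
    for te_ms in (TE1_ms, TE1_ms + dTE_ms):
        phi = 2.0 * np.pi * field.values * te_ms * 1e-3 + phi0
        if noise_sigma > 0:
            signal = mag * np.exp(1j * phi) + noise_sigma * (
                rng.standard_normal(phi.shape)
                + 1j * rng.standard_normal(phi.shape))
            phi = np.angle(signal)
            phi = np.where(phi == -np.pi, np.pi, phi)
        else:
            phi = wrap_phase(phi)
        phases.append(PhaseVolume(phi, field.grid, wrapped=True))
    return phases[0], phases[1]
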