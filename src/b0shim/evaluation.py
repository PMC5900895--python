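"""Shim computation and the strategy-comparison evaluation.

A static shim is the spherical-harmonic setting s minimizing
``‖field + synthesize(s)‖`` over the brain mask (the shim field ADDS to
the subject's field; the optimal coefficients are the negated harmonic
projection).  Because the DC term is always in the design, minimizing the
residual RMS is the same as minimizing its standard deviation, and the
measured-field shim is provably at least as good — in residual std over
the same mask and basis — as any other setting.

The evaluation reproduces the strategy comparison of the template method:
for each held-out subject of a leave-one-out cross-validation, shims are
derived from (1) the subject's own measured field, (2) every other
subject's field registered into its space, (3) the training-set template
registered into its space, (4) every other subject's own optimal shim
applied as-is, (5) the average of those shims, (6) uniform random shims
within the training set's per-term range, and (7) the tune-up (here:
all-zero) shim carrying no subject information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, LeakageError, SingularFitError
from .grids import VoxelGrid
from .harmonics import HarmonicBasis, ShimSetting, build_basis, decompose_field
from .processing import FieldMap
from .spatial import (AffineTransform, build_template, compose,
                      predict_fieldmap, resample_fieldmap)

__all__ = [
    "STRATEGIES", "EvalConfig", "StrategyResult", "ShimEvaluation",
    "compute_shim", "residual_std", "random_shims", "averaged_fixed_shim",
    "shim_ranges", "loocv_evaluate", "wilcoxon_paired",
]

STRATEGIES = ("measured", "individual_registered", "averaged_registered",
              "individual_fixed", "averaged_fixed", "random", "tuneup")

#: strategies that yield one residual per training subject or random draw
DISTRIBUTION_STRATEGIES = ("individual_registered", "individual_fixed", "random")


def compute_shim(field: FieldMap, basis: HarmonicBasis, mask: np.ndarray,
                 max_order: int = 2) -> ShimSetting:
    """Least-squares static shim for ``field`` over ``mask``.

    Returns the setting minimizing the RMS of ``field + shim_field`` over
    masked voxels, using all harmonic terms through ``max_order`` (1-3 for
    realistic hardware; the DC term is always included).
    """
    if max_order not in (1, 2, 3):
        raise ValueError(f"shim max_order must be 1, 2 or 3, got {max_order}")
    setting, _ = decompose_field(field, basis, mask, max_order=max_order)
    return -setting


def residual_std(field: FieldMap, shim: ShimSetting, basis: HarmonicBasis,
                 mask: np.ndarray) -> float:
    """Standard deviation (Hz, divisor N) of the shimmed residual field."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ConfigurationError("empty mask in residual_std")
    resid = field.values[mask] + basis.design_matrix(mask) @ _embed(shim, basis)
    return float(np.std(resid))


def _embed(shim: ShimSetting, basis: HarmonicBasis) -> np.ndarray:
    """Shim coefficients as a full-length vector in basis term order."""
    out = np.zeros(basis.n_terms)
    for name, c in zip(shim.terms, shim.coefficients):
        out[basis.index(name)] = c
    return out


def shim_ranges(shims) -> dict:
    """Per-term (min, max) envelope over a collection of shim settings."""
    shims = list(shims)
    if not shims:
        raise ValueError("no shims given")
    terms = shims[0].terms
    mat = np.vstack([s.coefficients for s in shims])
    return {t: (float(mat[:, i].min()), float(mat[:, i].max()))
            for i, t in enumerate(terms)}


def random_shims(n: int, per_term_min_max: dict, seed: int = 0) -> list:
    """Monte-Carlo shims, each term uniform on its own [min, max] envelope."""
    if n <= 0:
        raise ValueError(f"need n > 0 random shims, got {n}")
    terms = tuple(per_term_min_max)
    lo = np.array([per_term_min_max[t][0] for t in terms])
    hi = np.array([per_term_min_max[t][1] for t in terms])
    if np.any(lo > hi):
        raise ValueError("per-term min exceeds max")
    rng = np.random.default_rng(seed)
    max_order = _order_of(terms)
    return [ShimSetting(terms, rng.uniform(lo, hi), max_order) for _ in range(n)]


def _order_of(terms) -> int:
    from .harmonics import _TERM_TABLE
    orders = {n: o for n, o, _ in _TERM_TABLE}
    return max(orders[t] for t in terms)


def averaged_fixed_shim(individual_shims) -> ShimSetting:
    """Termwise arithmetic mean of individual shim settings."""
    shims = list(individual_shims)
    if not shims:
        raise ValueError("cannot average zero shims")
    terms = shims[0].terms
    for s in shims[1:]:
        if s.terms != terms:
            raise ValueError("shim settings have mismatched term sets")
    mean = np.mean(np.vstack([s.coefficients for s in shims]), axis=0)
    return ShimSetting(terms, mean, shims[0].max_order)


@dataclass(frozen=True)
class EvalConfig:
    """Options of the cross-validated strategy comparison."""

    max_order: int = 2
    n_random: int = 100
    seed: int = 0
    strategies: tuple = STRATEGIES
    use_registration: bool = False   # register localizers vs use true transforms
    standard_grid: VoxelGrid | None = None


@dataclass
class StrategyResult:
    strategy: str
    subject_id: str
    shim: ShimSetting | None
    residual_std_hz: float
    sample: str | None = None   # contributing subject / draw for distributions


@dataclass
class ShimEvaluation:
    """Residual-std table over subjects × strategies.

    ``results`` is a tidy frame (subject, strategy, sample, residual_std_hz);
    distribution strategies contribute one row per training subject or
    random draw.  ``summary()`` reduces distributions to their per-subject
    mean before averaging across subjects.
    """

    results: pd.DataFrame
    shims: dict
    config: EvalConfig

    def per_subject(self) -> pd.DataFrame:
        return (self.results
                .groupby(["subject", "strategy"], sort=False)["residual_std_hz"]
                .mean().unstack("strategy"))

    def strategy_means(self) -> pd.Series:
        return self.per_subject().mean(axis=0)

    def summary(self) -> pd.DataFrame:
        per = self.per_subject()
        return pd.DataFrame({
            "mean_hz": per.mean(), "median_hz": per.median(),
            "q25_hz": per.quantile(0.25), "q75_hz": per.quantile(0.75),
        })


def _subject_basis_cache(subjects, max_basis_order):
    """One harmonic basis per distinct grid (subjects usually share one)."""
    cache = {}
    for s in subjects:
        if s.grid not in cache:
            cache[s.grid] = build_basis(s.grid, max_basis_order)
    return cache


def loocv_evaluate(cohort, config: EvalConfig = EvalConfig(),
                   anatomy=None) -> ShimEvaluation:
    """Leave-one-out cross-validated comparison of shimming strategies.

    For each held-out subject, the field-map template and all per-term shim
    ranges are derived from the remaining subjects only; every requested
    strategy is then evaluated by the residual field standard deviation
    over the held-out subject's brain mask, with the same basis and mask
    for all strategies so the measured-field shim is a true lower bound.

    ``anatomy`` (a :class:`~b0shim.synthetic.TemplateAnatomy`) supplies the
    standard grid and, when ``config.use_registration`` is set, the
    standard-space structural that localizers are registered to; otherwise
    the subjects' stored true transforms are used.
    """
    cohort = list(cohort)
    if len(cohort) < 3:
        raise ConfigurationError("LOOCV needs a cohort of at least 3 subjects")
    unknown = set(config.strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    std_grid = config.standard_grid
    if std_grid is None:
        std_grid = anatomy.grid if anatomy is not None else cohort[0].grid

    bases = _subject_basis_cache(cohort, max_basis_order=config.max_order)
    order = config.max_order

    # Per-subject precomputation; each item depends on that subject only,
    # so per-fold training quantities are leak-free by construction.
    own_shim, own_resid, transforms = {}, {}, {}
    for s in cohort:
        basis = bases[s.grid]
        own_shim[s.id] = compute_shim(s.field_true, basis, s.brain_mask, order)
        own_resid[s.id] = residual_std(s.field_true, own_shim[s.id], basis,
                                       s.brain_mask)
        if config.use_registration:
            from .spatial import register
            transforms[s.id] = register(s.structural, anatomy.structural,
                                        dof=12, moving_label=f"subject/{s.id}")
        else:
            transforms[s.id] = s.transform

    rng = np.random.default_rng(config.seed)
    rows, shims_out = [], {}
    for held in cohort:
        training = [s for s in cohort if s.id != held.id]
        if any(t.id == held.id for t in training):
            raise LeakageError(f"held-out subject {held.id} present in training")
        basis = bases[held.grid]
        mask = held.brain_mask
        fld = held.field_true

        def record(strategy, shim, sample=None):
            r = residual_std(fld, shim, basis, mask) if shim is not None \
                else float(np.std(fld.values[mask]))
            rows.append((held.id, strategy, sample, r))
            return r

        if "measured" in config.strategies:
            shims_out[(held.id, "measured")] = own_shim[held.id]
            rows.append((held.id, "measured", None, own_resid[held.id]))

        if "tuneup" in config.strategies:
            zero = ShimSetting.zero(order)
            shims_out[(held.id, "tuneup")] = zero
            record("tuneup", zero)

        needs_template = "averaged_registered" in config.strategies
        if needs_template:
            template = build_template(
                [(t.field_true, transforms[t.id]) for t in training], std_grid,
                anatomy=anatomy.structural if anatomy is not None else None)
            predicted = predict_fieldmap(template, held.structural,
                                         subject_grid=held.grid,
                                         transform=transforms[held.id])
            fit_mask = mask & predicted.brain_mask
            if fit_mask.sum() < basis.n_terms:
                raise SingularFitError(basis.term_names)
            shim = compute_shim(predicted, basis, fit_mask, order)
            shims_out[(held.id, "averaged_registered")] = shim
            record("averaged_registered", shim)

        if "individual_registered" in config.strategies:
            to_held = transforms[held.id].invert()
            for t in training:
                tx = compose(to_held, transforms[t.id])
                warped = resample_fieldmap(t.field_true, tx, held.grid)
                fit_mask = mask & warped.brain_mask
                if fit_mask.sum() < basis.n_terms:
                    continue
                shim = compute_shim(warped, basis, fit_mask, order)
                record("individual_registered", shim, sample=t.id)

        train_fixed = [own_shim[t.id] for t in training]
        if "individual_fixed" in config.strategies:
            for t, shim in zip(training, train_fixed):
                record("individual_fixed", shim, sample=t.id)

        if "averaged_fixed" in config.strategies:
            shim = averaged_fixed_shim(train_fixed)
            shims_out[(held.id, "averaged_fixed")] = shim
            record("averaged_fixed", shim)

        if "random" in config.strategies:
            ranges = shim_ranges(train_fixed)
            fold_seed = int(rng.integers(2 ** 31))
            for k, shim in enumerate(random_shims(config.n_random, ranges,
                                                  seed=fold_seed)):
                record("random", shim, sample=f"draw-{k:04d}")

    frame = pd.DataFrame(rows, columns=["subject", "strategy", "sample",
                                        "residual_std_hz"])
    return ShimEvaluation(results=frame, shims=shims_out, config=config)


def wilcoxon_paired(a, b):
    """Two-sided Wilcoxon signed-rank test for paired residuals.

    Zero differences are dropped (Wilcoxon's original treatment) and tied
    absolute differences share mid-ranks.  For n ≤ 12 retained pairs the
    null distribution of W+ is enumerated exactly over all 2^n sign
    patterns (valid under ties); above that a normal approximation with
    tie-corrected variance is used.  If every difference is zero the
    result is (0.0, 1.0).

    Returns ``(W_plus, p_two_sided)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    expect = n * (n + 1) / 4.0
    dev = abs(w_plus - expect)
    if n <= 12:
        w_all = np.zeros(1)
        for r in ranks:          # distribution of W+ via convolution of signs
            w_all = np.concatenate([w_all, w_all + r])
        p = float(np.mean(np.abs(w_all - expect) >= dev - 1e-12))
    else:
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - float(((counts ** 3 - counts).sum())) / 48.0
        if var <= 0:
            return w_plus, 1.0
        z = dev / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(z))
    return w_plus, min(p, 1.0)
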