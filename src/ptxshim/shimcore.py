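"""Magnitude-least-squares (MLS) RF shimming for a multi-channel transmit array.

Static slice-wise shimming chooses one complex weight per transmit channel so
that the magnitude of the weighted sum of the per-channel B1+ maps is as close
as possible to a desired (usually uniform) target inside a region of interest.
The objective is

    J(b) = || |A b| - m ||^2_w  +  lambda * ||b||^2

where the rows of ``A`` are the complex per-channel field values at each
in-mask voxel, ``b`` the weight vector, ``m`` the target magnitude and ``w``
the region-of-interest mask.  Fitting only the magnitude makes the problem
non-convex (it is a phase-retrieval relative); this module provides

* :func:`adam_shim` — multi-restart first-order optimization with the Adam
  update rule over the real/imaginary parts of ``b`` (the reference arm),
* :func:`mls_variable_exchange` — the classic alternating phase-adoption /
  linear-least-squares algorithm (the conventional comparison arm),
* :func:`quadrature_weights` — the circularly-polarized drive baseline,
* :func:`exhaustive_shim` — a brute-force magnitude-by-phase grid search,
  tractable only for tiny problems, used as an independent reference.

Field homogeneity is reported as root-mean-square error in percent of the
target flip angle (RMSE [% of target FA]): the RMS of ``|Ab| - m`` over the
mask, normalized by the in-mask mean of ``m``, times 100.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fieldsim import ChannelFieldSlice, FieldVolume, RegionMask

logger = logging.getLogger(__name__)

__all__ = [
    "ShimWeights",
    "TargetMap",
    "ShimObjectiveConfig",
    "ShimResult",
    "combined_field",
    "mls_objective",
    "rmse_percent",
    "quadrature_weights",
    "random_init_weights",
    "adam_shim",
    "mls_variable_exchange",
    "exhaustive_shim",
    "shim_volume",
    "masked_system",
    "objective_and_gradient",
]


class EmptyMaskError(ValueError):
    """Raised when a shimming operation receives a mask with no voxels."""


class OptimizationError(RuntimeError):
    """Raised when every optimization restart failed."""


@dataclass(frozen=True)
class ShimWeights:
    """Complex per-channel drive weights ``b``."""

    coefficients: np.ndarray  # complex, shape (n_channels,)

    def __post_init__(self) -> None:
        coef = np.ascontiguousarray(self.coefficients, dtype=np.complex128)
        if coef.ndim != 1:
            raise ValueError("coefficients must be a 1-D complex vector")
        if not (np.all(np.isfinite(coef.real)) and np.all(np.isfinite(coef.imag))):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coef)

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]


@dataclass(frozen=True)
class TargetMap:
    """Desired field magnitude ``m`` per voxel (same units as the combined field).

    The default target used throughout the package is a constant 1.0 inside
    the mask, i.e. a perfectly uniform flip-angle distribution in the
    normalized field units produced by the simulator.
    """

    desired: np.ndarray  # float, shape (rows, cols)

    def __post_init__(self) -> None:
        des = np.asarray(self.desired, dtype=np.float64)
        if not np.all(np.isfinite(des)) or np.any(des < 0):
            raise ValueError("target map must be finite and non-negative")
        object.__setattr__(self, "desired", des)

    @classmethod
    def uniform(cls, grid_shape: tuple[int, int], level: float = 1.0) -> "TargetMap":
        return cls(np.full(grid_shape, float(level)))


@dataclass(frozen=True)
class ShimObjectiveConfig:
    """Settings for the multi-restart Adam shim optimizer.

    lambda_reg
        Regularization weight on total drive power.  ``None`` selects the
        default scaling ``1e-3 * n_voxel / n_channels``, which makes the two
        objective terms comparable for unit-magnitude weights.
    n_restarts
        Number of random initializations (300 at reference scale).
    include_quadrature_start
        Adds one extra deterministic restart initialized at the quadrature
        (CP) weights, so the returned solution can never be worse than the
        drive baseline.
    """

    lambda_reg: float | None = None
    n_restarts: int = 300
    max_iters: int = 500
    learning_rate: float = 0.05
    tolerance: float = 1e-8
    seed: int = 0
    include_quadrature_start: bool = True

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass(frozen=True)
class ShimResult:
    """Outcome of shimming one slice."""

    weights: ShimWeights
    combined_magnitude: np.ndarray
    rmse_percent: float
    objective: float
    restart_index: int
    iterations_used: int
    seconds: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def combined_field(fields: ChannelFieldSlice, b: ShimWeights) -> np.ndarray:
    """Per-voxel weighted sum of the channel fields: ``sum_c b_c * field_c``."""
    if b.n_channels != fields.channel_count:
        raise ValueError(
            f"weight vector has {b.n_channels} channels, fields have "
            f"{fields.channel_count}"
        )
    return np.tensordot(b.coefficients, fields.values, axes=1)


def masked_system(
    fields: ChannelFieldSlice, m: TargetMap, w: RegionMask
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(A, m_vec)``: the in-mask system matrix (n_voxel, n_channels)
    and target vector."""
    inside = w.inside
    if not inside.any():
        raise EmptyMaskError("region-of-interest mask has no voxels")
    A = fields.values[:, inside].T  # (V, C)
    m_vec = np.asarray(m.desired, dtype=np.float64)[inside]
    return A, m_vec


def _magnitude_error_sq(A: np.ndarray, b: np.ndarray, m_vec: np.ndarray) -> float:
    mag = np.abs(A @ b)
    return float(np.sum((mag - m_vec) ** 2))


def mls_objective(
    fields: ChannelFieldSlice,
    b: ShimWeights,
    m: TargetMap,
    w: RegionMask,
    lambda_reg: float = 0.0,
) -> float:
    """Evaluate ``|| |Ab| - m ||^2_w + lambda * ||b||^2``."""
    A, m_vec = masked_system(fields, m, w)
    err = _magnitude_error_sq(A, b.coefficients, m_vec)
    return err + float(lambda_reg) * float(np.sum(np.abs(b.coefficients) ** 2))


def rmse_percent(
    fields: ChannelFieldSlice,
    b: ShimWeights,
    m: TargetMap,
    w: RegionMask,
) -> float:
    """Masked RMS magnitude error as percent of the mean target flip angle.

    ``100 / mean(m) * sqrt( sum_in-mask (|Ab| - m)^2 / n_voxel )`` where
    ``n_voxel`` is the in-mask voxel count of the slice.  With a unit target
    this is exactly the RMS error times 100.
    """
    A, m_vec = masked_system(fields, m, w)
    n_voxel = m_vec.size
    err = _magnitude_error_sq(A, b.coefficients, m_vec)
    mean_target = float(np.mean(m_vec))
    if mean_target <= 0:
        raise ValueError("target map is zero inside the mask")
    return 100.0 / mean_target * float(np.sqrt(err / n_voxel))


def quadrature_weights(n_channels: int) -> ShimWeights:
    """Circularly-polarized (CP / quadrature) drive: unit magnitudes, phases
    stepping by ``-360/n`` degrees per channel (−45° steps for 8 channels)."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    k = np.arange(n_channels)
    return ShimWeights(np.exp(-2j * np.pi * k / n_channels))


def random_init_weights(n_channels: int, rng: np.random.Generator) -> ShimWeights:
    """Random starting point: magnitudes uniform on (0, 1], phases uniform on
    [0, 360) degrees."""
    mag = 1.0 - rng.random(n_channels)  # (0, 1]
    phase = rng.uniform(0.0, 2 * np.pi, n_channels)
    return ShimWeights(mag * np.exp(1j * phase))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def objective_and_gradient(
    A: np.ndarray, B: np.ndarray, m_vec: np.ndarray, lambda_reg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Objective value and Wirtinger-style gradient for a batch of weight
    vectors.

    Parameters
    ----------
    A : (V, C) complex system matrix.
    B : (R, C) complex batch of weight vectors.
    m_vec : (V,) target magnitudes.

    Returns
    -------
    obj : (R,) objective values.
    G : (R, C) complex gradients such that dJ/d(Re b) = Re(G) and
        dJ/d(Im b) = Im(G).
    """
    C_field = B @ A.T  # (R, V)
    mag = np.abs(C_field)
    err = mag - m_vec
    obj = np.sum(err**2, axis=1) + lambda_reg * np.sum(np.abs(B) ** 2, axis=1)
    # residual with the current phase adopted; guard the non-differentiable
    # point |c| = 0 (any phase is a subgradient there; use 0)
    safe = np.where(mag > 0, mag, 1.0)
    r = err * (C_field / safe)
    G = 2.0 * (r @ np.conj(A) + lambda_reg * B)
    return obj, G


def default_lambda(n_voxel: int, n_channels: int) -> float:
    """Default power-regularization weight: 1e-3 · n_voxel / n_channels."""
    return 1e-3 * n_voxel / n_channels


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def adam_shim(
    fields: ChannelFieldSlice,
    m: TargetMap,
    w: RegionMask,
    config: ShimObjectiveConfig | None = None,
    extra_starts: Sequence[np.ndarray] = (),
    prefer_extra_tol: float = 0.0,
) -> ShimResult:
    """Multi-restart first-order minimization of the MLS objective.

    Runs ``config.n_restarts`` independent Adam trajectories over the
    2·n_channels real parameters (real and imaginary parts of ``b``), each
    from a random initial weight vector, plus an optional deterministic
    restart at the quadrature drive.  All restarts advance in lockstep
    (vectorized); the best objective value ever visited by each restart is
    retained, and the restart with the lowest final best is returned (ties
    broken by lowest restart index).

    ``extra_starts`` appends deterministic warm starts (e.g. the previous
    slice's solution when shimming a stack coherently).  With
    ``prefer_extra_tol`` > 0, the best warm-started trajectory is returned
    instead of the global best whenever its objective is within that
    relative tolerance — a continuation rule that selects a continuous
    branch of the (multi-valued, basin-degenerate) argmin across slices.
    """
    if config is None:
        config = ShimObjectiveConfig()
    t0 = time.perf_counter()
    A, m_vec = masked_system(fields, m, w)
    n_ch = A.shape[1]
    lam = (
        config.lambda_reg
        if config.lambda_reg is not None
        else default_lambda(m_vec.size, n_ch)
    )

    rng = np.random.default_rng(config.seed)
    starts = [random_init_weights(n_ch, rng).coefficients for _ in range(config.n_restarts)]
    if config.include_quadrature_start:
        starts.append(quadrature_weights(n_ch).coefficients)
    first_extra = len(starts)
    starts.extend(np.asarray(s, dtype=np.complex128) for s in extra_starts)
    B = np.stack(starts)  # (R, C)
    R = B.shape[0]

    # Adam state over the real view (R, 2C)
    X = np.concatenate([B.real, B.imag], axis=1)
    mom = np.zeros_like(X)
    vel = np.zeros_like(X)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    obj, _ = objective_and_gradient(A, B, m_vec, lam)
    best_obj = obj.copy()
    best_B = B.copy()
    prev_obj = np.full_like(obj, np.inf)
    iterations = 0
    for t in range(1, config.max_iters + 1):
        B = X[:, :n_ch] + 1j * X[:, n_ch:]
        obj, G = objective_and_gradient(A, B, m_vec, lam)
        finite = np.isfinite(obj)
        if not finite.all():
            n_bad = int((~finite).sum())
            logger.warning("discarding %d restart(s) with non-finite objective", n_bad)
            obj = np.where(finite, obj, np.inf)
            G = np.where(finite[:, None], G, 0.0)
        improved = obj < best_obj
        best_obj = np.where(improved, obj, best_obj)
        best_B = np.where(improved[:, None], B, best_B)

        g = np.concatenate([G.real, G.imag], axis=1)
        mom = beta1 * mom + (1 - beta1) * g
        vel = beta2 * vel + (1 - beta2) * g * g
        mhat = mom / (1 - beta1**t)
        vhat = vel / (1 - beta2**t)
        X = X - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        iterations = t
        if np.max(np.abs(obj - prev_obj)) < config.tolerance:
            break
        prev_obj = obj

    # final point of each trajectory is also a candidate
    B = X[:, :n_ch] + 1j * X[:, n_ch:]
    obj, _ = objective_and_gradient(A, B, m_vec, lam)
    obj = np.where(np.isfinite(obj), obj, np.inf)
    improved = obj < best_obj
    best_obj = np.where(improved, obj, best_obj)
    best_B = np.where(improved[:, None], B, best_B)

    if not np.isfinite(best_obj).any():
        raise OptimizationError("all restarts produced non-finite objectives")
    idx = int(np.argmin(best_obj))  # argmin takes the first minimum: lowest index
    if extra_starts and prefer_extra_tol > 0:
        ex_idx = first_extra + int(np.argmin(best_obj[first_extra:]))
        if best_obj[ex_idx] <= best_obj[idx] * (1.0 + prefer_extra_tol):
            idx = ex_idx
    weights = ShimWeights(best_B[idx])
    return _finish_result(
        fields, m, w, weights, float(best_obj[idx]), idx, iterations, t0
    )


def mls_variable_exchange(
    fields: ChannelFieldSlice,
    m: TargetMap,
    w: RegionMask,
    lambda_reg: float | None = None,
    max_outer: int = 50,
    tolerance: float = 1e-10,
    init: ShimWeights | None = None,
    n_random_starts: int = 0,
    seed: int = 0,
) -> ShimResult:
    """Classic MLS via variable exchange (alternating phase adoption and
    regularized linear least squares).

    Each outer iteration (i) fixes the phase of the current combined field
    onto the target, giving a complex target ``z = m * exp(i * angle(A b))``,
    and (ii) solves ``min_b ||A b - z||^2 + lambda ||b||^2`` in closed form.
    Both steps are non-increasing in the MLS objective, so convergence to a
    fixed point is monotone — but the fixed point depends on the start.
    Starts from the quadrature drive (or ``init``); ``n_random_starts``
    additional seeded random initializations can be run, the lowest final
    objective winning, the usual remedy for the algorithm's
    initialization sensitivity.
    """
    t0 = time.perf_counter()
    A, m_vec = masked_system(fields, m, w)
    n_ch = A.shape[1]
    lam = lambda_reg if lambda_reg is not None else default_lambda(m_vec.size, n_ch)
    AhA = np.conj(A.T) @ A

    def _run(b0: np.ndarray) -> tuple[np.ndarray, float, int]:
        b = b0.copy()
        obj = _magnitude_error_sq(A, b, m_vec) + lam * float(np.sum(np.abs(b) ** 2))
        iters = 0
        for outer in range(1, max_outer + 1):
            c = A @ b
            mag = np.abs(c)
            phase = np.where(mag > 0, c / np.where(mag > 0, mag, 1.0), 1.0)
            z = m_vec * phase
            rhs = np.conj(A.T) @ z
            if lam > 0:
                b = np.linalg.solve(AhA + lam * np.eye(n_ch), rhs)
            else:
                try:
                    b = np.linalg.solve(AhA, rhs)
                except np.linalg.LinAlgError:
                    logger.warning(
                        "singular normal equations (lambda=0); using pseudo-inverse"
                    )
                    b = np.linalg.lstsq(A, z, rcond=None)[0]
            prev = obj
            obj = _magnitude_error_sq(A, b, m_vec) + lam * float(np.sum(np.abs(b) ** 2))
            iters = outer
            if prev - obj < tolerance:
                break
        return b, obj, iters

    starts = [init.coefficients if init is not None
              else quadrature_weights(n_ch).coefficients]
    rng = np.random.default_rng(seed)
    starts += [random_init_weights(n_ch, rng).coefficients
               for _ in range(n_random_starts)]
    best = None
    total_iters = 0
    for b0 in starts:
        b, obj, iters = _run(b0)
        total_iters += iters
        if best is None or obj < best[1]:
            best = (b, obj)
    return _finish_result(fields, m, w, ShimWeights(best[0]), best[1], 0, total_iters, t0)


def _finish_result(
    fields: ChannelFieldSlice,
    m: TargetMap,
    w: RegionMask,
    weights: ShimWeights,
    objective: float,
    restart_index: int,
    iterations: int,
    t0: float,
) -> ShimResult:
    mag = np.abs(combined_field(fields, weights))
    return ShimResult(
        weights=weights,
        combined_magnitude=mag,
        rmse_percent=rmse_percent(fields, weights, m, w),
        objective=objective,
        restart_index=restart_index,
        iterations_used=iterations,
        seconds=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# brute-force reference
# ---------------------------------------------------------------------------

def exhaustive_shim(
    fields: ChannelFieldSlice,
    m: TargetMap,
    w: RegionMask,
    lambda_reg: float = 0.0,
    mag_max: float = 2.0,
    mag_step: float = 0.01,
    phase_step_deg: float = 1.0,
) -> ShimResult:
    """Exhaustive magnitude-by-phase grid search over the weight vector.

    The objective is invariant to a global phase, so channel 0's phase is
    fixed to zero; every other channel scans magnitude in [0, mag_max] and
    phase in [0, 360) degrees on the given grid.  Cost grows as
    ``n_mag^C * n_phase^(C-1)`` — intended for C = 2 and a handful of voxels,
    where it serves as an independent reference for the iterative optimizers.
    """
    t0 = time.perf_counter()
    A, m_vec = masked_system(fields, m, w)
    n_ch = A.shape[1]
    if n_ch != 2:
        raise NotImplementedError("exhaustive search is implemented for 2 channels")
    mags = np.arange(0.0, mag_max + 0.5 * mag_step, mag_step)
    phases = np.deg2rad(np.arange(0.0, 360.0, phase_step_deg))

    a0 = A[:, 0]  # (V,)
    a1 = A[:, 1]
    P = np.abs(a0) ** 2  # (V,)
    Q = np.abs(a1) ** 2
    cross = a0 * np.conj(a1)  # (V,) complex

    best = np.inf
    best_combo = (0.0, 0.0, 0.0)
    m0 = mags[:, None, None]  # (M,1,1)
    m1 = mags[None, :, None]  # (1,M,1)
    reg = lambda_reg * (mags[:, None] ** 2 + mags[None, :] ** 2)  # (M, M)
    chunk = 45
    for lo in range(0, phases.size, chunk):
        ph = phases[lo : lo + chunk]
        Rterm = np.real(cross[None, :] * np.exp(-1j * ph)[:, None])  # (P, V)
        # |c|^2 for all (phase, m0, m1, voxel)
        mag2 = (
            m0[None] ** 2 * P
            + m1[None] ** 2 * Q
            + 2.0 * m0[None] * m1[None] * Rterm[:, None, None, :]
        )
        obj = np.sum((np.sqrt(mag2) - m_vec) ** 2, axis=-1) + reg[None]  # (P, M, M)
        i = int(np.argmin(obj))
        if obj.flat[i] < best:
            pi, i0, i1 = np.unravel_index(i, obj.shape)
            best = float(obj.flat[i])
            best_combo = (mags[i0], mags[i1], ph[pi])
    b = np.array([best_combo[0], best_combo[1] * np.exp(1j * best_combo[2])])
    return _finish_result(fields, m, w, ShimWeights(b), best, 0, 0, t0)


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def shim_volume(
    volume: FieldVolume,
    method: str = "adam",
    config: ShimObjectiveConfig | None = None,
    target_level: float = 1.0,
    coherent: bool = False,
    warm_start: np.ndarray | None = None,
    coherence_tol: float = 0.02,
) -> pd.DataFrame:
    """Shim every slice of a volume independently and tabulate the results.

    ``method`` is one of ``adam``, ``mls`` (variable exchange) or
    ``quadrature``.  Per-slice failures are recorded as flagged rows (``ok``
    False) rather than aborting the batch.  The returned table carries the
    weight vectors in auxiliary columns so downstream stages (training
    references, NFD map generation) can reuse them.

    With ``coherent`` (adam only), each slice also warm-starts from the
    previous slice's solution and keeps that basin when it is within
    ``coherence_tol`` relative objective of the best random restart.  The
    MLS argmin is basin-degenerate, so independently optimized slices pick
    near-equal-cost but wildly different weight vectors; the continuation
    rule selects one continuous branch, which matters when the weights
    serve as regression targets.  ``warm_start`` seeds the chain (e.g. the
    previous volume's last solution).
    """
    if method not in ("adam", "mls", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    if config is None:
        config = ShimObjectiveConfig()
    rows = []
    prev = np.asarray(warm_start, dtype=np.complex128) if warm_start is not None else None
    for s, (fields, mask) in enumerate(zip(volume.slices, volume.masks)):
        m = TargetMap.uniform(fields.grid_shape, target_level)
        try:
            if method == "adam":
                extra = [prev] if (coherent and prev is not None) else []
                res = adam_shim(
                    fields, m, mask, replace(config, seed=config.seed + s),
                    extra_starts=extra,
                    prefer_extra_tol=coherence_tol if extra else 0.0,
                )
                if coherent:
                    prev = res.weights.coefficients
            elif method == "mls":
                res = mls_variable_exchange(
                    fields, m, mask, lambda_reg=config.lambda_reg
                )
            else:
                t0 = time.perf_counter()
                wq = quadrature_weights(fields.channel_count)
                lam = (
                    config.lambda_reg
                    if config.lambda_reg is not None
                    else default_lambda(int(mask.inside.sum()), fields.channel_count)
                )
                res = _finish_result(
                    fields, m, mask, wq,
                    mls_objective(fields, wq, m, mask, lam), 0, 0, t0,
                )
            rows.append(
                dict(
                    slice=s,
                    method=method,
                    rmse_percent=res.rmse_percent,
                    objective=res.objective,
                    restarts=config.n_restarts if method == "adam" else 1,
                    iterations=res.iterations_used,
                    seconds=res.seconds,
                    ok=True,
                    weights=res.weights.coefficients.copy(),
                )
            )
        except (EmptyMaskError, OptimizationError, ValueError) as exc:
            logger.warning("slice %d failed: %s", s, exc)
            rows.append(
                dict(
                    slice=s, method=method, rmse_percent=np.nan, objective=np.nan,
                    restarts=0, iterations=0, seconds=0.0, ok=False, weights=None,
                )
            )
    return pd.DataFrame(rows)
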