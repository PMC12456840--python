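"""Learned shim-weight regression from multi-channel B1+ maps.

A residual convolutional network maps an encoded multi-channel complex
field slice directly to the complex per-channel shim weights, trained with
a physics-informed loss: the predicted weights are pushed to match the
field-homogeneity (RMSE in % of target flip angle) achieved by a strong
iterative reference optimizer, with the RMSE evaluated *through the
physics* — the weighted channel combination — so gradients flow from the
field-domain error back into the network.

Two loss forms are provided, selectable by configuration:

* ``plain`` (default): mean over the batch of
  ``RMSE_pred(i) − RMSE_ref(i)``;
* ``mse``: mean of the squared differences.

Reference RMSEs come from multi-restart Adam shimming
(:func:`ptxshim.shimcore.adam_shim`), treated as near-optimal upper bounds
for what the regressor can achieve.  Splits are made at the level of
*source* slices so rotated copies of one slice never straddle the
train/test boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .fieldsim import ChannelFieldSlice, FieldVolume, RegionMask
from .shimcore import (
    ShimResult,
    ShimWeights,
    TargetMap,
    combined_field,
    masked_system,
    mls_objective,
    rmse_percent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedSlice",
    "PredictorConfig",
    "TrainingExample",
    "TrainingHistory",
    "ShimRegressor",
    "encode_input",
    "decode_weights",
    "build_model",
    "physics_loss",
    "split_dataset",
    "build_examples",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

ENCODING_MODES = ("realimag16", "rimp32")


class SplitError(ValueError):
    """Raised when a dataset is too small to split."""


@dataclass(frozen=True)
class EncodedSlice:
    """Real-valued plane stack fed to the network.

    ``realimag16`` interleaves (real, imaginary) per channel — 16 planes for
    8 channels, lossless.  ``rimp32`` stacks (real, imaginary, magnitude,
    phase) per channel — 32 planes, matching the reference input depth; the
    extra planes are redundant but give the first convolution direct access
    to magnitude and phase.
    """

    planes: np.ndarray  # float32, (plane_count, rows, cols)
    encoding_mode: str

    def __post_init__(self) -> None:
        p = np.asarray(self.planes, dtype=np.float32)
        if p.ndim != 3:
            raise ValueError("planes must be (plane, row, col)")
        if not np.all(np.isfinite(p)):
            raise ValueError("encoded planes must be finite")
        object.__setattr__(self, "planes", p)

    @property
    def plane_count(self) -> int:
        return self.planes.shape[0]


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training protocol for the shim regressor.

    Defaults follow the reference protocol: four residual stages of two
    basic blocks with widths 64/128/256/512, Adam at 1e-3 decayed by 50 %
    every 50 epochs over 200 epochs, batch size 16, 8:1:1 splits.  Desk-
    scale runs shrink ``stage_widths`` and ``epochs``, not the protocol's
    structure.
    """

    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    output_dim: int = 16
    encoding_mode: str = "realimag16"
    learning_rate: float = 1e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 50
    epochs: int = 200
    batch_size: int = 16
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    loss_form: str = "plain"
    init_bias_quadrature: bool = True
    calibrate_scale: bool = True
    weight_supervision: float = 10.0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split_ratios must sum to 1")
        if self.encoding_mode not in ENCODING_MODES:
            raise ValueError(f"unsupported encoding mode {self.encoding_mode!r}")
        if self.output_dim not in (16, 32) and self.output_dim % 2:
            raise ValueError("output_dim must be even")
        if self.loss_form not in ("plain", "mse"):
            raise ValueError(f"unsupported loss form {self.loss_form!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainingExample:
    """One slice with everything the physics loss needs."""

    input: EncodedSlice
    fields_ref: ChannelFieldSlice
    mask: RegionMask
    target_map: TargetMap
    rmse_ref: float
    weights_ref: ShimWeights
    group: tuple  # source-slice identity; rotated copies share it

    def system(self) -> tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "_system"):
            self._system = masked_system(self.fields_ref, self.target_map, self.mask)
        return self._system


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    splits: dict = field(default_factory=dict)  # name -> index list


# ---------------------------------------------------------------------------
# encoding / decoding
# ---------------------------------------------------------------------------

def encode_input(
    fields: ChannelFieldSlice, mode: str = "realimag16",
    mask: RegionMask | None = None,
) -> EncodedSlice:
    """Stack a complex multi-channel slice into real network-input planes.

    With ``mask`` the fields are zeroed outside the region of interest
    first — the network then sees exactly the masked slices the shimming
    objective is defined on, with the ROI geometry explicit in its input.
    Phase planes (``rimp32``) are in radians, wrapped to (−π, π].
    """
    if mode not in ENCODING_MODES:
        raise ValueError(f"unsupported encoding mode {mode!r}")
    v = fields.values
    if mask is not None:
        v = np.where(mask.inside, v, 0)
    planes = []
    for c in range(fields.channel_count):
        planes.append(v[c].real)
        planes.append(v[c].imag)
        if mode == "rimp32":
            planes.append(np.abs(v[c]))
            planes.append(np.angle(v[c]))
    return EncodedSlice(np.stack(planes).astype(np.float32), mode)


def decode_weights(output: np.ndarray, n_channels: int = 8) -> ShimWeights:
    """Map a real network output vector to complex weights: entries
    (2c, 2c+1) become (real, imag) of channel c; surplus entries (a 32-wide
    head for 8 channels) are ignored."""
    out = np.asarray(output, dtype=np.float64).ravel()
    if out.size % 2:
        raise ValueError("output vector must have even length")
    if out.size < 2 * n_channels:
        raise ValueError(
            f"output of length {out.size} cannot encode {n_channels} complex weights"
        )
    pairs = out[: 2 * n_channels].reshape(n_channels, 2)
    return ShimWeights(pairs[:, 0] + 1j * pairs[:, 1])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class ShimRegressor:
    """Residual CNN: initial 3x3 convolution (stride 2), four stages of
    basic blocks with stride-2 entries from stage 2 on, global average
    pooling and a fully connected head."""

    def __init__(self, config: PredictorConfig, in_planes: int, n_channels: int):
        self.config = config
        self.in_planes = in_planes
        self.n_channels = n_channels
        rng = np.random.default_rng(config.seed)
        w = config.stage_widths
        layers: list[nn.Layer] = [
            nn.Conv2d(in_planes, w[0], 3, stride=2, rng=rng, bias=False),
            nn.BatchNorm2d(w[0]),
            nn.ReLU(),
        ]
        cin = w[0]
        for si, width in enumerate(w):
            for bi in range(config.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                layers.append(nn.BasicBlock(cin, width, stride, rng))
                cin = width
        layers.append(nn.GlobalAvgPool())
        head = nn.Linear(cin, config.output_dim, rng=rng)
        if config.init_bias_quadrature:
            # start near the circularly-polarized drive so the untrained
            # network approximately reproduces the baseline; the head weights
            # are shrunk so the random feature contribution does not swamp it
            from .shimcore import quadrature_weights

            q = quadrature_weights(n_channels).coefficients
            bias = np.zeros(config.output_dim)
            bias[0 : 2 * n_channels : 2] = q.real
            bias[1 : 2 * n_channels : 2] = q.imag
            head.b.v = bias.astype(nn.DTYPE)
            head.W.v *= 0.1
        layers.append(head)
        self.net = nn.Sequential(*layers)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.ascontiguousarray(x, dtype=np.float32), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(np.ascontiguousarray(dout, dtype=np.float32))


def build_model(
    config: PredictorConfig, in_planes: int | None = None, n_channels: int = 8
) -> ShimRegressor:
    """Construct a seeded regressor; ``in_planes`` defaults to the plane
    count implied by the encoding mode and channel count."""
    if in_planes is None:
        in_planes = 2 * n_channels if config.encoding_mode == "realimag16" else 4 * n_channels
    model = ShimRegressor(config, in_planes, n_channels)
    logger.info("regressor built: %d parameters", model.n_parameters())
    return model


# ---------------------------------------------------------------------------
# physics-informed loss
# ---------------------------------------------------------------------------

def calibrated_scale(b: np.ndarray, A: np.ndarray, m_vec: np.ndarray) -> float:
    """Optimal global drive amplitude for a weight pattern.

    The transmit voltage is calibrated separately from the shim pattern on
    real systems; for the magnitude objective the best global scale has
    the closed form ``alpha = sum(m |Ab|) / sum(|Ab|^2)``.
    """
    mag = np.abs(A @ b)
    denom = float(np.sum(mag**2))
    if denom <= 0:
        return 1.0
    return max(float(np.sum(m_vec * mag) / denom), 1e-12)


def _rmse_and_grad(
    b: np.ndarray, A: np.ndarray, m_vec: np.ndarray
) -> tuple[float, np.ndarray]:
    """RMSE [% of target FA] and its Wirtinger gradient w.r.t. ``b``."""
    c = A @ b
    mag = np.abs(c)
    err = mag - m_vec
    S = float(np.sum(err**2))
    N = m_vec.size
    mean_t = float(np.mean(m_vec))
    rmse = 100.0 / mean_t * np.sqrt(S / N)
    if S <= 0:
        return rmse, np.zeros_like(b)
    safe = np.where(mag > 0, mag, 1.0)
    r = err * (c / safe)
    G_S = 2.0 * (np.conj(A.T) @ r)
    G = (100.0 / mean_t) / (2.0 * np.sqrt(S * N)) * G_S
    return rmse, G


def _loss_and_grad(
    outputs: np.ndarray, batch: Sequence[TrainingExample], form: str,
    calibrate: bool = False, weight_supervision: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss value, gradient w.r.t. the network outputs, and per-example
    predicted RMSEs for a batch.

    With ``calibrate`` the closed-form optimal global drive amplitude is
    applied to each predicted pattern before the RMSE; by the envelope
    theorem the gradient is then the scaled pattern's gradient times the
    amplitude (the derivative through the amplitude itself vanishes at its
    optimum).

    ``weight_supervision`` adds a global-phase-aligned squared distance to
    the reference weight vector.  The per-slice physics term inherits the
    non-convexity of the magnitude objective, so gradient descent alone
    parks each slice's prediction in whatever local basin the shared
    initialization reaches; anchoring on the reference weights — the
    mapping the regressor is meant to learn — is convex in the outputs and
    pulls predictions into the reference basin, where the physics term
    takes over.
    """
    B = len(batch)
    if B == 0:
        raise ValueError("empty batch")
    dout = np.zeros_like(outputs, dtype=np.float64)
    loss = 0.0
    rmses = np.empty(B)
    for i, ex in enumerate(batch):
        n_ch = ex.fields_ref.channel_count
        b = decode_weights(outputs[i], n_ch)
        A, m_vec = ex.system()
        if calibrate:
            alpha = calibrated_scale(b.coefficients, A, m_vec)
            rmse, G = _rmse_and_grad(alpha * b.coefficients, A, m_vec)
            G = alpha * G
        else:
            rmse, G = _rmse_and_grad(b.coefficients, A, m_vec)
        rmses[i] = rmse
        diff = rmse - ex.rmse_ref
        if form == "plain":
            loss += diff / B
            coef = 1.0 / B
        else:  # mse
            loss += diff * diff / B
            coef = 2.0 * diff / B
        Gtot = coef * G
        if weight_supervision > 0:
            b_ref = ex.weights_ref.coefficients
            # align the reference's free global phase to the prediction
            inner = np.vdot(b_ref, b.coefficients)
            phase = inner / abs(inner) if abs(inner) > 0 else 1.0
            e = b.coefficients - phase * b_ref
            loss += weight_supervision * float(np.sum(np.abs(e) ** 2)) / (n_ch * B)
            Gtot = Gtot + (2.0 * weight_supervision / (n_ch * B)) * e
        dout[i, 0 : 2 * n_ch : 2] = Gtot.real
        dout[i, 1 : 2 * n_ch : 2] = Gtot.imag
    return float(loss), dout, rmses


def physics_loss(
    predicted_weights: Sequence[ShimWeights],
    batch: Sequence[TrainingExample],
    form: str = "plain",
) -> float:
    """Physics-informed loss of a batch of predicted weight vectors.

    ``plain``: mean of (RMSE_pred − RMSE_ref); ``mse``: mean of the
    squared differences.  RMSE_pred is evaluated through the weighted
    channel combination on each example's own fields, mask and target.
    Examples whose mask is empty are excluded with a warning.
    """
    if form not in ("plain", "mse"):
        raise ValueError(f"unsupported loss form {form!r}")
    kept = [(w, ex) for w, ex in zip(predicted_weights, batch) if not ex.mask.is_empty]
    if len(kept) < len(batch):
        logger.warning("excluded %d example(s) with empty masks", len(batch) - len(kept))
    if not kept:
        raise ValueError("no usable examples in batch")
    total = 0.0
    for w, ex in kept:
        rmse = rmse_percent(ex.fields_ref, w, ex.target_map, ex.mask)
        diff = rmse - ex.rmse_ref
        total += diff if form == "plain" else diff * diff
    return total / len(kept)


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def build_examples(
    volumes: Sequence[FieldVolume],
    reference_tables: Sequence[pd.DataFrame],
    mode: str = "realimag16",
    target_level: float = 1.0,
) -> list[TrainingExample]:
    """Pair every stored slice with its reference shim from a
    :func:`ptxshim.shimcore.shim_volume` table."""
    examples = []
    for v, (vol, table) in enumerate(zip(volumes, reference_tables)):
        rows = table.sort_values("slice").reset_index(drop=True)
        if len(rows) != vol.n_slices:
            raise ValueError(f"volume {v}: reference table has {len(rows)} rows "
                             f"for {vol.n_slices} slices")
        slice_meta = vol.metadata.get("slices", [{}] * vol.n_slices)
        for s in range(vol.n_slices):
            row = rows.iloc[s]
            if not row["ok"]:
                logger.warning("volume %d slice %d: reference missing; skipped", v, s)
                continue
            fields = vol.slices[s]
            meta = slice_meta[s] if s < len(slice_meta) else {}
            group = (vol.metadata.get("volume_index", v), meta.get("source_slice", s))
            examples.append(
                TrainingExample(
                    input=encode_input(fields, mode, mask=vol.masks[s]),
                    fields_ref=fields,
                    mask=vol.masks[s],
                    target_map=TargetMap.uniform(fields.grid_shape, target_level),
                    rmse_ref=float(row["rmse_percent"]),
                    weights_ref=ShimWeights(np.asarray(row["weights"])),
                    group=group,
                )
            )
    return examples


def split_dataset(
    examples: Sequence[TrainingExample],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[int], list[int], list[int]]:
    """Disjoint, exhaustive train/val/test index sets, reproducible from the
    seed.  The unit of assignment is the source slice: all rotated copies of
    one slice land in the same split."""
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative and sum to 1")
    if len(examples) < 10:
        raise SplitError("dataset must contain at least 10 slices to split 8:1:1")
    groups: dict[tuple, list[int]] = {}
    for i, ex in enumerate(examples):
        groups.setdefault(ex.group, []).append(i)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    G = len(keys)
    n_train = int(round(ratios[0] * G))
    n_val = int(round(ratios[1] * G))
    n_train = min(n_train, G)
    n_val = min(n_val, G - n_train)
    parts = (keys[:n_train], keys[n_train : n_train + n_val], keys[n_train + n_val :])
    out = tuple(sorted(i for k in part for i in groups[k]) for part in parts)
    return out  # type: ignore[return-value]


def _stack_inputs(examples: Sequence[TrainingExample], idx: Sequence[int]) -> np.ndarray:
    return np.stack([examples[i].input.planes for i in idx])


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _predicted_rmse(model: ShimRegressor, ex: TrainingExample,
                    out_row: np.ndarray) -> float:
    b = decode_weights(out_row, ex.fields_ref.channel_count)
    A, m_vec = ex.system()
    coef = b.coefficients
    if model.config.calibrate_scale:
        coef = calibrated_scale(coef, A, m_vec) * coef
    return _rmse_and_grad(coef, A, m_vec)[0]


def _mean_val_rmse(
    model: ShimRegressor, examples: Sequence[TrainingExample], idx: Sequence[int],
    batch_size: int,
) -> float:
    rmses = []
    for lo in range(0, len(idx), batch_size):
        chunk = list(idx[lo : lo + batch_size])
        out = model.forward(_stack_inputs(examples, chunk), train=False)
        for j, i in enumerate(chunk):
            rmses.append(_predicted_rmse(model, examples[i], out[j]))
    return float(np.mean(rmses))


def train(
    examples: Sequence[TrainingExample],
    config: PredictorConfig,
    splits: tuple[Sequence[int], Sequence[int], Sequence[int]] | None = None,
) -> tuple[ShimRegressor, TrainingHistory]:
    """Train the regressor with the physics-informed loss.

    Optimizes with the Adam rule under a step-decay schedule (initial rate
    halved every ``lr_decay_every`` epochs by default); the parameter state
    with the best validation mean RMSE is restored at the end.  Fully
    deterministic given (examples, config, splits).
    """
    if splits is None:
        splits = split_dataset(examples, config.split_ratios, config.seed)
    train_idx, val_idx, _ = (list(s) for s in splits)
    if not train_idx:
        raise SplitError("empty training split")
    n_ch = examples[train_idx[0]].fields_ref.channel_count
    in_planes = examples[train_idx[0]].input.plane_count
    model = build_model(config, in_planes=in_planes, n_channels=n_ch)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = TrainingHistory(splits={"train": train_idx, "val": val_idx,
                                      "test": list(splits[2])})
    rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_state = nn.state_dict(model.net)
    order = np.array(train_idx)
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        opt.lr = lr
        rng.shuffle(order)
        losses = []
        diverged = False
        for lo in range(0, len(order), config.batch_size):
            batch_idx = order[lo : lo + config.batch_size]
            batch = [examples[i] for i in batch_idx]
            x = _stack_inputs(examples, batch_idx)
            out = model.forward(x, train=True).astype(np.float64)
            loss, dout, _ = _loss_and_grad(
                out, batch, config.loss_form,
                calibrate=config.calibrate_scale,
                weight_supervision=config.weight_supervision,
            )
            if not np.isfinite(loss):
                logger.error("non-finite loss at epoch %d; aborting with last "
                             "good checkpoint", epoch)
                diverged = True
                break
            losses.append(loss)
            opt.zero_grad()
            model.backward(dout)
            opt.step()
        if diverged:
            break
        # pin the batch-norm statistics to the training population before
        # any eval-mode use; momentum-averaged stats lag while training
        nn.recalibrate_bn(
            model.net,
            (_stack_inputs(examples, order[lo : lo + config.batch_size])
             for lo in range(0, len(order), config.batch_size)),
        )
        val = (_mean_val_rmse(model, examples, val_idx, config.batch_size)
               if val_idx else float("nan"))
        history.train_loss.append(float(np.mean(losses)))
        history.val_rmse.append(val)
        history.learning_rate.append(lr)
        if val_idx and val < best_val:
            best_val = val
            best_state = nn.state_dict(model.net)
            history.best_epoch = epoch
    if history.best_epoch >= 0:
        nn.load_state_dict(model.net, best_state)
    return model, history


def predict(
    model: ShimRegressor,
    fields: ChannelFieldSlice,
    mask: RegionMask,
    target: TargetMap | None = None,
) -> ShimResult:
    """Single forward pass: fields in, populated shim result out."""
    import time as _time

    t0 = _time.perf_counter()
    if target is None:
        target = TargetMap.uniform(fields.grid_shape)
    enc = encode_input(fields, model.config.encoding_mode, mask=mask)
    if enc.plane_count != model.in_planes:
        raise ValueError(
            f"encoded input has {enc.plane_count} planes, model expects {model.in_planes}"
        )
    out = model.forward(enc.planes[None], train=False)[0]
    b = decode_weights(out, fields.channel_count)
    if model.config.calibrate_scale:
        A, m_vec = masked_system(fields, target, mask)
        b = ShimWeights(calibrated_scale(b.coefficients, A, m_vec) * b.coefficients)
    return ShimResult(
        weights=b,
        combined_magnitude=np.abs(combined_field(fields, b)),
        rmse_percent=rmse_percent(fields, b, target, mask),
        objective=mls_objective(fields, b, target, mask, 0.0),
        restart_index=0,
        iterations_used=0,
        seconds=_time.perf_counter() - t0,
    )


def evaluate(
    model: ShimRegressor,
    test_examples: Sequence[TrainingExample],
    comparisons: dict[str, Sequence[float]] | None = None,
    batch_size: int = 16,
) -> dict:
    """Fold report on a held-out test set.

    Returns a per-slice RMSE table (predicted, reference and any supplied
    comparison arms such as quadrature or variable-exchange MLS), per-method
    means, quartile summaries and paired differences against the reference.
    """
    idx = list(range(len(test_examples)))
    preds = []
    for lo in range(0, len(idx), batch_size):
        chunk = idx[lo : lo + batch_size]
        out = model.forward(_stack_inputs(test_examples, chunk), train=False)
        for j, i in enumerate(chunk):
            preds.append(_predicted_rmse(model, test_examples[i], out[j]))
    table = pd.DataFrame(
        {
            "predicted": preds,
            "reference": [ex.rmse_ref for ex in test_examples],
        }
    )
    if comparisons:
        for name, vals in comparisons.items():
            table[name] = list(vals)
    summary = table.describe(percentiles=[0.25, 0.5, 0.75])
    return {
        "per_slice": table,
        "mean": table.mean().to_dict(),
        "summary": summary,
        "paired_diff_vs_reference": (table["predicted"] - table["reference"]).describe().to_dict(),
    }


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: ShimRegressor, path: str | Path, extra: dict | None = None) -> None:
    """Write an npz checkpoint plus a JSON sidecar (config, seed, encoding)."""
    path = Path(path)
    np.savez_compressed(path, **nn.state_dict(model.net))
    sidecar = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.config.__dict__.items()
        },
        "in_planes": model.in_planes,
        "n_channels": model.n_channels,
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ShimRegressor:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg_raw = sidecar["config"]
    cfg = PredictorConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg_raw.items()
        }
    )
    model = ShimRegressor(cfg, sidecar["in_planes"], sidecar["n_channels"])
    with np.load(path) as data:
        nn.load_state_dict(model.net, dict(data))
    return model
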