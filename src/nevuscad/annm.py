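"""MLP classifier forward pass (9-10-24-2) with sigmoid activations.

Two execution modes mirror the software/hardware split of the system:

* ``float`` — reference floating point with the exact logistic sigmoid,
  as used during training;
* ``fixed`` — bit-accurate Q-format arithmetic: inputs in uQ0.10, weights
  in sQ5.10, per-neuron accumulation in sQ10.10, and the PLAN piecewise
  linear approximation of the sigmoid (power-of-two slopes, so every
  branch is a shift-and-add in hardware).

The two network outputs (u0, u1) code the classes one-hot: [1, 0] is
melanoma, [0, 1] is non-melanoma; inference takes the argmax with ties
resolved to melanoma (the clinically conservative direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .fixed_point import (
    DESCRIPTOR_FMT,
    WEIGHT_FMT,
    QFormat,
    QValue,
    fx_add,
    fx_mul,
    fx_sub,
    quantize,
)

__all__ = [
    "MELANOMA",
    "NON_MELANOMA",
    "PAPER_LAYER_SIZES",
    "MlpModel",
    "ClassificationResult",
    "sigmoid",
    "plan_sigmoid",
    "plan_sigmoid_q",
    "neuron_forward",
    "mlp_forward",
    "classify",
]

MELANOMA = "melanoma"
NON_MELANOMA = "non_melanoma"

PAPER_LAYER_SIZES = (9, 10, 24, 2)

# Per-neuron weighted sum s_k: 25 terms of sQ5.10 x uQ0.10 products plus the
# bias stay below 2**10 in magnitude, so sQ10.10 cannot overflow.
SK_FMT = QFormat(True, 10, 10)
_ONE_S = QValue(1 << 10, QFormat(True, 1, 10))
_MINUS_ONE = quantize(-1.0, WEIGHT_FMT)  # the constant bias input


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def plan_sigmoid(x: float) -> float:
    """PLAN piecewise-linear sigmoid approximation.

    y = 1                       for x >= 5
    y = 0.03125 x + 0.84375     for 2.375 <= x < 5
    y = 0.125 x + 0.625         for 1 <= x < 2.375
    y = 0.25 x + 0.5            for 0 <= x < 1
    y = 1 - y(-x)               for x < 0

    All slopes and intercepts are dyadic rationals, so the float branch is
    exact and the odd symmetry y(x) + y(-x) = 1 holds exactly.
    """
    if x < 0:
        return 1.0 - plan_sigmoid(-x)
    if x >= 5:
        return 1.0
    if x >= 2.375:
        return 0.03125 * x + 0.84375
    if x >= 1:
        return 0.125 * x + 0.625
    return 0.25 * x + 0.5


# PLAN constants at 10 fractional bits (all exact).
_PLAN_BRANCHES = (
    (5 << 10, None, None),        # saturation threshold
    (2432, 32, 864),              # 2.375 <= x < 5:  0.03125 x + 0.84375
    (1 << 10, 128, 640),          # 1 <= x < 2.375:  0.125 x + 0.625
    (0, 256, 512),                # 0 <= x < 1:      0.25 x + 0.5
)


def plan_sigmoid_q(x: QValue) -> QValue:
    """PLAN in fixed point: branch selection on the quantized value of x,
    shift-and-add evaluation, output saturated into uQ0.10.

    Note uQ0.10 cannot hold 1.0 exactly; the saturation branch returns the
    format maximum 1 - 2**-10, so the odd symmetry holds within 2**-10.
    """
    if x.fmt.frac_bits != SK_FMT.frac_bits:
        # align to 10 fractional bits by truncation before branching
        shift = x.fmt.frac_bits - SK_FMT.frac_bits
        raw = x.raw >> shift if shift > 0 else x.raw << -shift
        x = QValue(max(SK_FMT.raw_min, min(SK_FMT.raw_max, raw)), SK_FMT)
    negative = x.raw < 0
    ax = QValue(-x.raw, x.fmt) if negative else x
    if ax.raw >= _PLAN_BRANCHES[0][0]:
        y = QValue(DESCRIPTOR_FMT.raw_max, DESCRIPTOR_FMT)  # saturated 1.0
    else:
        for threshold, slope_raw, const_raw in _PLAN_BRANCHES[1:]:
            if ax.raw >= threshold:
                slope = QValue(slope_raw, DESCRIPTOR_FMT)
                const = QValue(const_raw, DESCRIPTOR_FMT)
                y = fx_add(fx_mul(slope, ax, DESCRIPTOR_FMT), const, DESCRIPTOR_FMT)
                break
    if negative:
        y = fx_sub(_ONE_S, y, DESCRIPTOR_FMT)
    return y


@dataclass
class MlpModel:
    """Feedforward MLP weights: per layer an (n_out, n_in + 1) array whose
    column 0 is the bias weight W_k0 (bias input is the constant -1)."""

    weights: list

    def __post_init__(self):
        ws = [np.asarray(w, dtype=float) for w in self.weights]
        if not ws:
            raise ValueError("model needs at least one layer")
        for a, b in zip(ws, ws[1:]):
            if b.shape[1] - 1 != a.shape[0]:
                raise ValueError(
                    f"layer shapes do not chain: {a.shape} -> {b.shape}"
                )
        self.weights = ws

    @property
    def layer_sizes(self) -> tuple:
        return (self.weights[0].shape[1] - 1,) + tuple(
            w.shape[0] for w in self.weights
        )

    # --- persistence -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "layer_sizes": list(self.layer_sizes),
            "layers": [w.tolist() for w in self.weights],
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "MlpModel":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "layers" not in data:
            raise ValueError(f"weight file {path} has no 'layers' mapping")
        return cls([np.array(layer, dtype=float) for layer in data["layers"]])

    def save_quantized(self, path) -> None:
        """Dump raw sQ5.10 integers for bit-exact replay."""
        layers = []
        for w in self.weights:
            layers.append(
                [[quantize(float(v), WEIGHT_FMT).raw for v in row] for row in w]
            )
        Path(path).write_text(
            yaml.safe_dump({"format": str(WEIGHT_FMT), "layers_raw": layers})
        )

    @classmethod
    def from_quantized(cls, path) -> "MlpModel":
        data = yaml.safe_load(Path(path).read_text())
        fmt = QFormat.parse(data["format"])
        return cls(
            [np.array(layer, dtype=float) * fmt.step for layer in data["layers_raw"]]
        )


@dataclass(frozen=True)
class ClassificationResult:
    u0: float   # melanoma output
    u1: float   # non-melanoma output
    label: str


def neuron_forward(inputs: Sequence, weights: Sequence[float], mode: str = "float"):
    """One neuron: s_k = W_k0 * (-1) + sum_m W_km x_m, then the activation.

    ``weights[0]`` is the bias weight.  In float mode inputs are reals and
    the activation is the exact sigmoid; in fixed mode inputs are uQ0.10
    :class:`QValue` (or reals, quantized on entry), every product is a
    truncating sQ5.10 x uQ0.10 multiply accumulated in sQ10.10, and the
    activation is PLAN.
    """
    if len(weights) != len(inputs) + 1:
        raise ValueError(
            f"need {len(inputs) + 1} weights (bias first), got {len(weights)}"
        )
    if mode == "float":
        s = -weights[0] + float(
            np.dot(np.asarray(weights[1:], float), np.asarray(inputs, float))
        )
        return float(sigmoid(s))
    if mode == "fixed":
        xq = [
            x if isinstance(x, QValue) else quantize(float(x), DESCRIPTOR_FMT)
            for x in inputs
        ]
        s = fx_mul(quantize(float(weights[0]), WEIGHT_FMT), _MINUS_ONE, SK_FMT)
        for w, x in zip(weights[1:], xq):
            s = fx_add(s, fx_mul(quantize(float(w), WEIGHT_FMT), x, SK_FMT), SK_FMT)
        return plan_sigmoid_q(s)
    raise ValueError(f"unknown mode: {mode!r}")


def mlp_forward(descriptors, model: MlpModel, mode: str = "float") -> tuple:
    """Full forward pass; returns the output pair (u0, u1) as floats.

    Fixed-mode outputs are multiples of 2**-10 (the uQ0.10 step).
    """
    x = np.asarray(
        descriptors.values if hasattr(descriptors, "values") else descriptors,
        dtype=float,
    )
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(
            f"descriptor size {x.shape} does not match model input "
            f"{model.layer_sizes[0]}"
        )
    if mode == "float":
        a = x
        for w in model.weights:
            a = sigmoid(w[:, 1:] @ a - w[:, 0])
        return tuple(float(v) for v in a)
    if mode == "fixed":
        acts = [quantize(float(v), DESCRIPTOR_FMT) for v in x]
        for w in model.weights:
            acts = [neuron_forward(acts, row, mode="fixed") for row in w]
        return tuple(q.value for q in acts)
    raise ValueError(f"unknown mode: {mode!r}")


def classify(u0: float, u1: float) -> str:
    """Argmax decision; ties go to melanoma (maximizes sensitivity)."""
    return MELANOMA if u0 >= u1 else NON_MELANOMA
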