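"""Digital image processing: two-pass streaming extraction of the nine
ABCD-rule lesion descriptors.

The descriptor vector d0..d8 summarizes a lesion the way a dermatologist's
ABCD checklist does:

* ``d0``, ``d1`` — asymmetry about the mask's center of mass, measured as
  the absolute difference between lesion-pixel counts on either side of the
  centroid row (d0) and centroid column (d1);
* ``d2`` — a diameter surrogate: the larger of the row extent and the
  column extent of the lesion's bounding box;
* ``d3``/``d5``/``d7`` — mean R/G/B intensity over the lesion;
* ``d4``/``d6``/``d8`` — population variance of R/G/B over the lesion.

Extraction needs exactly two scans of the pixel stream: the first collects
the pixel count, centroid, bounding extents and channel sums; the second
(which needs the centroid and means) collects the symmetry counts and the
squared deviations for the variances.

Two execution modes are provided.  ``float`` mode is the reference
floating-point computation.  ``fixed`` mode reproduces, bit for bit, a
fixed-point hardware datapath: wide uQ35.15 accumulators, truncating
division and multiplication, and final descriptors saturated into uQ0.10.
The normative fixed datapath is the per-pixel streaming scan
(:func:`extract_descriptors_fixed_streaming`); the default fixed path is a
raw-integer vectorized equivalent (accumulating same-format integers
without saturation is exact integer addition, so the two are identical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .fixed_point import (
    ACC_UFMT,
    DESCRIPTOR_FMT,
    QFormat,
    QValue,
    fx_add,
    fx_div,
    fx_mul,
    fx_sub,
    quantize,
)
from .image_io import EmptyMaskError, MaskedChannels, apply_mask, as_binary_mask, as_rgb_image

__all__ = [
    "PassOneSummary",
    "RawDescriptors",
    "NormalizationGains",
    "DescriptorVector",
    "GainError",
    "pass_one",
    "symmetry_raw",
    "diameter_raw",
    "variance_raw",
    "extract_raw",
    "fit_gains",
    "extract_descriptors",
    "extract_descriptors_fixed_streaming",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = tuple(f"d{i}" for i in range(9))

# Fixed-mode intermediate formats.  The datapath bounds are 35 integer and
# 15 fractional bits; intermediates use the widths their value ranges need.
_CX_FMT = QFormat(False, 20, 15)    # centroid coordinate (fractional)
_MEAN_FMT = QFormat(False, 8, 15)   # channel mean in [0, 255]
_VAR_FMT = QFormat(False, 16, 15)   # channel variance, <= 255^2 / 4
_DIFF_FMT = QFormat(True, 9, 15)    # pixel minus mean
_SQ_FMT = QFormat(False, 18, 15)    # squared deviation


class GainError(ValueError):
    """A normalization gain cannot be formed (zero reference maximum)."""


@dataclass(frozen=True)
class PassOneSummary:
    """Everything the first scan of the pixel stream yields."""

    nr: int                      # lesion pixel count (L)
    cx: float                    # centroid row coordinate
    cy: float                    # centroid column coordinate
    z1: int                      # first row containing a lesion pixel
    z2: int                      # last row
    z3: int                      # first column
    z4: int                      # last column
    sum_r: int
    sum_g: int
    sum_b: int
    mean_r: float
    mean_g: float
    mean_b: float


@dataclass(frozen=True)
class RawDescriptors:
    """Unnormalized descriptors in d0..d8 order fields."""

    symmetry_row: float   # d0
    symmetry_col: float   # d1
    diameter: float       # d2
    mean_r: float         # d3
    var_r: float          # d4
    mean_g: float         # d5
    var_g: float          # d6
    mean_b: float         # d7
    var_b: float          # d8

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.symmetry_row,
                self.symmetry_col,
                self.diameter,
                self.mean_r,
                self.var_r,
                self.mean_g,
                self.var_g,
                self.mean_b,
                self.var_b,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class NormalizationGains:
    """Per-descriptor reference maxima; the gain G_i is their reciprocal.

    Fitted over a reference image set so each normalized descriptor spans
    (0, 1] on that set; at inference, values exceeding the reference
    maximum clamp to 1.
    """

    maxima: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.maxima, dtype=float)
        if m.shape != (9,):
            raise GainError(f"expected 9 reference maxima, got shape {m.shape}")
        if not np.all(m > 0):
            bad = int(np.argmin(m > 0))
            raise GainError(f"non-positive reference maximum for d{bad}")
        object.__setattr__(self, "maxima", m)

    @property
    def gains(self) -> np.ndarray:
        return 1.0 / self.maxima

    def to_yaml(self, path) -> None:
        data = {name: float(v) for name, v in zip(DESCRIPTOR_NAMES, self.maxima)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "NormalizationGains":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise GainError(f"unparseable gains file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise GainError(f"gains file {path} is not a mapping")
        maxima = []
        for i, name in enumerate(DESCRIPTOR_NAMES):
            if name in data:
                maxima.append(float(data[name]))
            elif i in data:
                maxima.append(float(data[i]))
            else:
                raise GainError(f"gains file {path} missing entry for {name}")
        return cls(np.array(maxima))


@dataclass(frozen=True)
class DescriptorVector:
    """The normalized nine-vector in [0, 1]; fixed mode holds uQ0.10 steps."""

    values: np.ndarray
    mode: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (9,):
            raise ValueError(f"descriptor vector must have 9 entries, got {v.shape}")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("descriptor values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def as_array(self) -> np.ndarray:
        return self.values.copy()


# ---------------------------------------------------------------------------
# float-mode extraction


def pass_one(img: np.ndarray, mask: np.ndarray) -> PassOneSummary:
    """First scan: pixel count, centroid, bounding extents, channel sums."""
    img = as_rgb_image(img)
    mask = as_binary_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.nonzero(mask)
    nr = rows.size
    if nr == 0:
        raise EmptyMaskError("mask contains no lesion pixels")
    sum_i = int(rows.sum(dtype=np.int64))
    sum_j = int(cols.sum(dtype=np.int64))
    masked = apply_mask(img, mask)
    sum_r = int(masked.rm.sum(dtype=np.int64))
    sum_g = int(masked.gm.sum(dtype=np.int64))
    sum_b = int(masked.bm.sum(dtype=np.int64))
    return PassOneSummary(
        nr=nr,
        cx=sum_i / nr,
        cy=sum_j / nr,
        z1=int(rows.min()),
        z2=int(rows.max()),
        z3=int(cols.min()),
        z4=int(cols.max()),
        sum_r=sum_r,
        sum_g=sum_g,
        sum_b=sum_b,
        mean_r=sum_r / nr,
        mean_g=sum_g / nr,
        mean_b=sum_b / nr,
    )


def symmetry_raw(mask: np.ndarray, cx: float, cy: float) -> tuple[int, int]:
    """Asymmetry counts about the centroid row and column.

    A lesion pixel at (i, j) falls in the "first half" of the row split
    when ``i < cx`` (strict), otherwise the second; likewise columns
    against ``cy``.  Returns the absolute count differences (d0, d1).
    """
    mask = as_binary_mask(mask)
    rows, cols = np.nonzero(mask)
    nr = rows.size
    first_row = int((rows < cx).sum())
    first_col = int((cols < cy).sum())
    return abs(first_row - (nr - first_row)), abs(first_col - (nr - first_col))


def diameter_raw(z1: int, z2: int, z3: int, z4: int) -> int:
    """Diameter surrogate: the larger bounding extent, max(z2-z1, z4-z3)."""
    if z1 > z2 or z3 > z4:
        raise ValueError("extremity points out of order")
    return max(z2 - z1, z4 - z3)


def variance_raw(
    masked: MaskedChannels,
    mask: np.ndarray,
    means: tuple[float, float, float],
    nr: int,
) -> tuple[float, float, float]:
    """Second scan: per-channel population variance over the lesion.

    The squared-deviation sums are accumulated with ``math.fsum`` so the
    result is the correctly rounded sum, independent of pixel order.
    """
    mask = as_binary_mask(mask).astype(bool)
    out = []
    for ch, mean in zip((masked.rm, masked.gm, masked.bm), means):
        dev = ch[mask].astype(float) - mean
        out.append(math.fsum(dev * dev) / nr)
    return tuple(out)


def extract_raw(img: np.ndarray, mask: np.ndarray) -> RawDescriptors:
    """Run both scans and assemble the unnormalized descriptor vector."""
    p1 = pass_one(img, mask)
    d0, d1 = symmetry_raw(mask, p1.cx, p1.cy)
    d2 = diameter_raw(p1.z1, p1.z2, p1.z3, p1.z4)
    masked = apply_mask(img, mask)
    var_r, var_g, var_b = variance_raw(
        masked, mask, (p1.mean_r, p1.mean_g, p1.mean_b), p1.nr
    )
    return RawDescriptors(
        symmetry_row=d0,
        symmetry_col=d1,
        diameter=d2,
        mean_r=p1.mean_r,
        var_r=var_r,
        mean_g=p1.mean_g,
        var_g=var_g,
        mean_b=p1.mean_b,
        var_b=var_b,
    )


def fit_gains(raws: Sequence[RawDescriptors] | Iterable[RawDescriptors]) -> NormalizationGains:
    """Reference maxima over an image set; gain G_i = 1 / max_k raw_d_i(k)."""
    mat = np.array([r.as_array() for r in raws], dtype=float)
    if mat.size == 0:
        raise GainError("need at least one image to fit gains")
    maxima = mat.max(axis=0)
    for i, m in enumerate(maxima):
        if m <= 0:
            raise GainError(
                f"descriptor d{i} has zero maximum over the reference set; "
                "cannot form a normalization gain"
            )
    return NormalizationGains(maxima)


def extract_descriptors(
    img: np.ndarray,
    mask: np.ndarray,
    gains: NormalizationGains,
    mode: str = "float",
) -> DescriptorVector:
    """Extract the normalized nine-descriptor vector.

    ``mode="float"`` divides the raw descriptors by the reference maxima in
    floating point and clamps to [0, 1].  ``mode="fixed"`` reproduces the
    fixed-point datapath exactly; its outputs are multiples of 2**-10.
    """
    if mode == "float":
        raw = extract_raw(img, mask)
        vals = np.clip(raw.as_array() / gains.maxima, 0.0, 1.0)
        return DescriptorVector(vals, "float")
    if mode == "fixed":
        return _extract_fixed(img, mask, gains)
    raise ValueError(f"unknown mode: {mode!r}")


# ---------------------------------------------------------------------------
# fixed-mode extraction
#
# All intermediates carry 15 fractional bits; a raw integer r at 15
# fractional bits represents r * 2**-15.  Accumulations are exact integer
# sums (the wide uQ35.15 accumulator never saturates for supported image
# sizes), truncation happens only at the divider/multiplier outputs, and
# normalization is a truncating division by the quantized reference
# maximum saturated into uQ0.10.


def _fixed_norm(raw15: int, maximum: float) -> int:
    """Normalize a 15-frac-bit raw value: truncating divide, uQ0.10 out."""
    num = QValue(raw15, ACC_UFMT)
    den = quantize(maximum, ACC_UFMT)
    return fx_div(num, den, DESCRIPTOR_FMT, context="descriptor normalization").raw


def _extract_fixed(
    img: np.ndarray, mask: np.ndarray, gains: NormalizationGains
) -> DescriptorVector:
    """Vectorized raw-integer implementation of the fixed datapath."""
    img = as_rgb_image(img)
    mask = as_binary_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.nonzero(mask)
    nr = rows.size
    if nr == 0:
        raise EmptyMaskError("mask contains no lesion pixels")

    # pass 1: integer accumulators (exact)
    sum_i = int(rows.sum(dtype=np.int64))
    sum_j = int(cols.sum(dtype=np.int64))
    masked = apply_mask(img, mask)
    lesion = mask.astype(bool)
    ch_vals = [masked.rm[lesion].astype(np.int64),
               masked.gm[lesion].astype(np.int64),
               masked.bm[lesion].astype(np.int64)]
    ch_sums = [int(v.sum()) for v in ch_vals]
    z1, z2 = int(rows.min()), int(rows.max())
    z3, z4 = int(cols.min()), int(cols.max())

    # dividers: centroid at _CX_FMT precision, means at _MEAN_FMT
    nr_q = QValue(nr << 15, ACC_UFMT)
    cx_raw = fx_div(QValue(sum_i << 15, ACC_UFMT), nr_q, _CX_FMT,
                    context="center of mass").raw
    cy_raw = fx_div(QValue(sum_j << 15, ACC_UFMT), nr_q, _CX_FMT,
                    context="center of mass").raw
    mean_raws = [fx_div(QValue(s << 15, ACC_UFMT), nr_q, _MEAN_FMT,
                        context="channel mean").raw for s in ch_sums]

    # pass 2: symmetry counters (raw comparison against the fixed centroid)
    first_row = int(((rows.astype(np.int64) << 15) < cx_raw).sum())
    first_col = int(((cols.astype(np.int64) << 15) < cy_raw).sum())
    d0_count = abs(first_row - (nr - first_row))
    d1_count = abs(first_col - (nr - first_col))

    # pass 2: variance — per-pixel truncating square at 15 fractional bits
    var_raws = []
    for vals, mean_raw in zip(ch_vals, mean_raws):
        diff = (vals << 15) - mean_raw          # sQ9.15, exact
        sq = (diff * diff) >> 15                # uQ18.15, floor per pixel
        acc = int(sq.sum())                     # uQ35.15, exact
        var_raws.append(
            fx_div(QValue(acc, ACC_UFMT), nr_q, _VAR_FMT, context="variance").raw
        )

    d2_count = diameter_raw(z1, z2, z3, z4)

    raw15 = [
        d0_count << 15,
        d1_count << 15,
        d2_count << 15,
        mean_raws[0],
        var_raws[0],
        mean_raws[1],
        var_raws[1],
        mean_raws[2],
        var_raws[2],
    ]
    out_raw = [_fixed_norm(r, m) for r, m in zip(raw15, gains.maxima)]
    return DescriptorVector(np.array(out_raw, dtype=float) * DESCRIPTOR_FMT.step,
                            "fixed")


def extract_descriptors_fixed_streaming(
    img: np.ndarray, mask: np.ndarray, gains: NormalizationGains
) -> DescriptorVector:
    """Reference fixed datapath: per-pixel streaming scans with Q-format ops.

    Slow (pure-Python per-pixel loop); intended for small images and as the
    normative semantics the vectorized fixed path must match bit for bit.
    """
    img = as_rgb_image(img)
    mask = as_binary_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    n, m = mask.shape
    masked = apply_mask(img, mask)
    channels = (masked.rm, masked.gm, masked.bm)

    # --- scan 1: counters, coordinate accumulators, extents, channel sums
    zero = QValue(0, ACC_UFMT)
    nr = 0
    acc_i = acc_j = zero
    acc_ch = [zero, zero, zero]
    z1 = z2 = z3 = z4 = None
    for i in range(n):
        for j in range(m):
            if not mask[i, j]:
                continue
            nr += 1
            acc_i = fx_add(acc_i, QValue(i << 15, ACC_UFMT), ACC_UFMT)
            acc_j = fx_add(acc_j, QValue(j << 15, ACC_UFMT), ACC_UFMT)
            for c, ch in enumerate(channels):
                acc_ch[c] = fx_add(
                    acc_ch[c], QValue(int(ch[i, j]) << 15, ACC_UFMT), ACC_UFMT
                )
            z1 = i if z1 is None else z1
            z2 = i
            z3 = j if z3 is None or j < z3 else z3
            z4 = j if z4 is None or j > z4 else z4
    if nr == 0:
        raise EmptyMaskError("mask contains no lesion pixels")
    nr_q = QValue(nr << 15, ACC_UFMT)
    cx = fx_div(acc_i, nr_q, _CX_FMT, context="center of mass")
    cy = fx_div(acc_j, nr_q, _CX_FMT, context="center of mass")
    means = [fx_div(a, nr_q, _MEAN_FMT, context="channel mean") for a in acc_ch]

    # --- scan 2: symmetry counters and variance accumulators
    cnt = [0, 0, 0, 0]  # rows before/after centroid, cols before/after
    acc_var = [zero, zero, zero]
    for i in range(n):
        for j in range(m):
            if not mask[i, j]:
                continue
            if (i << 15) < cx.raw:
                cnt[0] += 1
            else:
                cnt[1] += 1
            if (j << 15) < cy.raw:
                cnt[2] += 1
            else:
                cnt[3] += 1
            for c, ch in enumerate(channels):
                pix = QValue(int(ch[i, j]), QFormat(False, 8, 0))
                diff = fx_sub(pix, means[c], _DIFF_FMT)
                sq = fx_mul(diff, diff, _SQ_FMT)
                acc_var[c] = fx_add(acc_var[c], sq, ACC_UFMT)
    variances = [fx_div(a, nr_q, _VAR_FMT, context="variance") for a in acc_var]

    raw15 = [
        abs(cnt[0] - cnt[1]) << 15,
        abs(cnt[2] - cnt[3]) << 15,
        diameter_raw(z1, z2, z3, z4) << 15,
        means[0].raw,
        variances[0].raw,
        means[1].raw,
        variances[1].raw,
        means[2].raw,
        variances[2].raw,
    ]
    out_raw = [_fixed_norm(r, mx) for r, mx in zip(raw15, gains.maxima)]
    return DescriptorVector(np.array(out_raw, dtype=float) * DESCRIPTOR_FMT.step,
                            "fixed")
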