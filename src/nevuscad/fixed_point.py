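"""Bit-accurate Q-format fixed-point arithmetic.

Emulates the number system of a hardware datapath: values are stored as
scaled integers (``raw = value * 2**frac_bits``), quantization truncates
toward negative infinity, and out-of-range results saturate to the format
bounds instead of wrapping.  Integer and fractional widths are bounded at
35 and 15 bits respectively, the widest signals the datapath carries.

The arithmetic here is deliberately exact-integer underneath: every
operation computes the mathematically exact result on raw integers, then
truncates/saturates into the requested output format.  That makes the
fixed-point pipeline bit-reproducible across platforms.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "QFormat",
    "QValue",
    "FixedPointError",
    "FixedPointDivisionError",
    "quantize",
    "fx_add",
    "fx_sub",
    "fx_mul",
    "fx_div",
    "PIXEL_FMT",
    "DESCRIPTOR_FMT",
    "WEIGHT_FMT",
    "ACC_UFMT",
    "ACC_SFMT",
]

MAX_INT_BITS = 35
MAX_FRAC_BITS = 15


class FixedPointError(ValueError):
    """Invalid fixed-point format or operand."""


class FixedPointDivisionError(ZeroDivisionError):
    """Division by a zero fixed-point value; names the consuming block."""

    def __init__(self, context: str = ""):
        self.context = context
        msg = "fixed-point division by zero"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


_FMT_RE = re.compile(r"^([su])Q(\d+)\.(\d+)$")


@dataclass(frozen=True)
class QFormat:
    """A fixed-point format: sign flag, integer bits, fractional bits.

    A ``QFormat(signed, i, f)`` represents multiples of ``2**-f`` in
    ``[-2**i, 2**i - 2**-f]`` when signed, ``[0, 2**i - 2**-f]`` when
    unsigned.
    """

    signed: bool
    int_bits: int
    frac_bits: int

    def __post_init__(self):
        if not (0 <= self.int_bits <= MAX_INT_BITS):
            raise FixedPointError(f"int_bits out of range: {self.int_bits}")
        if not (0 <= self.frac_bits <= MAX_FRAC_BITS):
            raise FixedPointError(f"frac_bits out of range: {self.frac_bits}")
        if self.int_bits + self.frac_bits + (1 if self.signed else 0) < 1:
            raise FixedPointError("format must carry at least one bit")

    # raw-integer bounds (value bounds scaled by 2**frac_bits)
    @property
    def raw_min(self) -> int:
        return -(1 << (self.int_bits + self.frac_bits)) if self.signed else 0

    @property
    def raw_max(self) -> int:
        return (1 << (self.int_bits + self.frac_bits)) - 1

    @property
    def step(self) -> float:
        return 2.0 ** -self.frac_bits

    @property
    def min_value(self) -> float:
        return self.raw_min * self.step

    @property
    def max_value(self) -> float:
        return self.raw_max * self.step

    @classmethod
    def parse(cls, text: str) -> "QFormat":
        """Parse a format string like ``"sQ5.10"`` or ``"uQ0.10"``."""
        m = _FMT_RE.match(text.strip())
        if not m:
            raise FixedPointError(f"unparseable Q-format string: {text!r}")
        return cls(m.group(1) == "s", int(m.group(2)), int(m.group(3)))

    def __str__(self) -> str:
        return f"{'s' if self.signed else 'u'}Q{self.int_bits}.{self.frac_bits}"


@dataclass(frozen=True)
class QValue:
    """A number held in a :class:`QFormat`; real value = raw * 2**-frac_bits."""

    raw: int
    fmt: QFormat

    def __post_init__(self):
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise FixedPointError(
                f"raw {self.raw} outside range of {self.fmt}"
            )

    @property
    def value(self) -> float:
        return self.raw * self.fmt.step

    def __float__(self) -> float:
        return self.value


# Formats the datapath documents explicitly.
PIXEL_FMT = QFormat(False, 8, 0)        # 8-bit RGB channel values
DESCRIPTOR_FMT = QFormat(False, 0, 10)  # descriptors and network outputs in [0, 1)
WEIGHT_FMT = QFormat(True, 5, 10)       # trained MLP weights
ACC_UFMT = QFormat(False, 35, 15)       # wide unsigned accumulator
ACC_SFMT = QFormat(True, 35, 15)        # wide signed accumulator


def _saturate(raw: int, fmt: QFormat) -> QValue:
    if raw < fmt.raw_min:
        raw = fmt.raw_min
    elif raw > fmt.raw_max:
        raw = fmt.raw_max
    return QValue(raw, fmt)


def _requantize(raw: int, frac_bits: int, out_fmt: QFormat) -> QValue:
    """Exact raw integer at ``frac_bits`` -> truncate/saturate into out_fmt."""
    shift = frac_bits - out_fmt.frac_bits
    if shift > 0:
        raw >>= shift  # arithmetic shift on Python ints floors, as required
    elif shift < 0:
        raw <<= -shift
    return _saturate(raw, out_fmt)


def quantize(x: float, fmt: QFormat) -> QValue:
    """Truncate ``x`` toward -inf to the format step, then saturate."""
    raw = math.floor(x * (1 << fmt.frac_bits))
    return _saturate(raw, fmt)


def fx_add(a: QValue, b: QValue, out_fmt: QFormat) -> QValue:
    """Exact addition after aligning fractional bits, then truncate/saturate."""
    f = max(a.fmt.frac_bits, b.fmt.frac_bits)
    ra = a.raw << (f - a.fmt.frac_bits)
    rb = b.raw << (f - b.fmt.frac_bits)
    return _requantize(ra + rb, f, out_fmt)


def fx_sub(a: QValue, b: QValue, out_fmt: QFormat) -> QValue:
    """Exact subtraction ``a - b``, then truncate/saturate."""
    f = max(a.fmt.frac_bits, b.fmt.frac_bits)
    ra = a.raw << (f - a.fmt.frac_bits)
    rb = b.raw << (f - b.fmt.frac_bits)
    return _requantize(ra - rb, f, out_fmt)


def fx_mul(a: QValue, b: QValue, out_fmt: QFormat) -> QValue:
    """Exact product, truncated toward -inf to the output step, saturated."""
    return _requantize(a.raw * b.raw, a.fmt.frac_bits + b.fmt.frac_bits, out_fmt)


def fx_div(num: QValue, den: QValue, out_fmt: QFormat, context: str = "") -> QValue:
    """Truncated quotient at output precision; error < one output step.

    ``context`` names the consuming submodule in the division-by-zero error.
    """
    if den.raw == 0:
        raise FixedPointDivisionError(context)
    # exact: floor(num_raw * 2**e / den_raw), e chosen so the result is at
    # out_fmt's fractional precision.  Python's // floors for any signs.
    e = den.fmt.frac_bits - num.fmt.frac_bits + out_fmt.frac_bits
    if e >= 0:
        raw = (num.raw << e) // den.raw
    else:
        raw = num.raw // (den.raw << -e)
    return _saturate(raw, out_fmt)
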