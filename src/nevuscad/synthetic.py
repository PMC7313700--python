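"""Synthetic dermoscopy-like lesion generator with known ground truth.

Emulates the inputs the pipeline consumes — an RGB image plus a binary
lesion mask — with controllable asymmetry, extent, boundary roughness and
per-channel color statistics, so every stage of the system is testable
without any external image database.  Lesions are filled ellipses whose
boundary can be roughened by a smooth periodic radial perturbation and
made asymmetric by enlarging the semi-axes on the positive row/column
side; lesion pixel colors are drawn per channel from a normal
distribution truncated to [0, 255] and rounded to integers, on a constant
background.

The generator does not attempt photorealism (no hair, gel or ruler
artifacts, no texture); what it guarantees is that the realized mask and
color statistics are recorded exactly, so extracted descriptors can be
checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annm import MELANOMA, NON_MELANOMA

__all__ = [
    "LesionSpec",
    "GroundTruth",
    "LesionSample",
    "ClassParams",
    "BENIGN_PARAMS",
    "MELANOMA_PARAMS",
    "LesionError",
    "generate_lesion",
    "generate_dataset",
]


class LesionError(ValueError):
    pass


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic lesion; deterministic given ``seed``."""

    canvas: tuple = (112, 112)
    shape: str = "ellipse"                    # "ellipse" or "blob"
    center: tuple | None = None               # (row, col); None -> canvas center
    axes: tuple = (20, 15)                    # semi-axes (rows, cols), pixels
    boundary_roughness: float = 0.0           # relative radial perturbation
    asymmetry_shift: tuple = (0, 0)           # extra semi-axis on +row/+col side
    channel_means: tuple = (120.0, 90.0, 80.0)
    channel_sds: tuple = (0.0, 0.0, 0.0)
    background_color: tuple = (200, 170, 150)
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("ellipse", "blob"):
            raise LesionError(f"unknown lesion shape: {self.shape!r}")
        if min(self.axes) <= 0:
            raise LesionError("semi-axes must be positive")
        if self.boundary_roughness < 0:
            raise LesionError("boundary_roughness must be >= 0")
        if min(self.channel_sds) < 0:
            raise LesionError("channel_sds must be >= 0")

    @property
    def effective_roughness(self) -> float:
        # a "blob" is a roughened ellipse; give it texture if none requested
        if self.shape == "blob" and self.boundary_roughness == 0:
            return 0.3
        return self.boundary_roughness


@dataclass(frozen=True)
class GroundTruth:
    """Realized (not nominal) statistics of the generated lesion."""

    pixel_count: int
    bounds: tuple                 # (z1, z2, z3, z4) first/last row, first/last col
    channel_means: tuple          # realized per-channel mean of lesion pixels
    channel_sds: tuple            # realized population standard deviation
    label: str | None = None


@dataclass(frozen=True)
class LesionSample:
    image: np.ndarray
    mask: np.ndarray
    label: str
    truth: GroundTruth
    spec: LesionSpec


def _boundary_field(dr, dc, roughness, rng):
    """Smooth periodic radial perturbation factor, clipped away from 0."""
    if roughness == 0:
        return 1.0
    # low-order harmonics give a wobbly but connected boundary
    coeffs = rng.normal(0.0, 1.0, size=(2, 4))
    theta = np.arctan2(dc, dr)
    g = np.zeros_like(theta)
    for k in range(2, 6):
        g += coeffs[0, k - 2] * np.cos(k * theta) + coeffs[1, k - 2] * np.sin(k * theta)
    g /= np.sqrt((coeffs ** 2).sum()) + 1e-12
    return np.clip(1.0 + roughness * g, 0.3, None)


def generate_lesion(spec: LesionSpec):
    """Rasterize one lesion; returns (image, mask, ground_truth).

    Byte-identical output for identical specs (all randomness comes from
    ``spec.seed``).  Raises :class:`LesionError` if the lesion reaches the
    canvas border (it must fit with background margin on all sides).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.canvas
    cr, cc = spec.center if spec.center is not None else ((n - 1) / 2, (m - 1) / 2)
    a, b = spec.axes
    da, db = spec.asymmetry_shift

    ii, jj = np.mgrid[0:n, 0:m]
    dr = ii - cr
    dc = jj - cc
    # asymmetric semi-axes: the +row / +col sides may be enlarged
    ar = np.where(dr >= 0, a + da, a).astype(float)
    bc = np.where(dc >= 0, b + db, b).astype(float)
    t = (dr / ar) ** 2 + (dc / bc) ** 2
    f = _boundary_field(dr, dc, spec.effective_roughness, rng)
    mask = (t <= f ** 2).astype(np.uint8)

    if not mask.any():
        raise LesionError("degenerate spec: empty lesion")
    rows, cols = np.nonzero(mask)
    if rows.min() == 0 or cols.min() == 0 or rows.max() == n - 1 or cols.max() == m - 1:
        raise LesionError("lesion exceeds the canvas (touches the border)")

    nr = rows.size
    img = np.empty((n, m, 3), dtype=np.uint8)
    for c in range(3):
        img[:, :, c] = spec.background_color[c]
    lesion_vals = []
    for c, (mu, sd) in enumerate(zip(spec.channel_means, spec.channel_sds)):
        if sd > 0:
            vals = rng.normal(mu, sd, size=nr)
        else:
            vals = np.full(nr, float(mu))
        vals = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
        img[rows, cols, c] = vals
        lesion_vals.append(vals.astype(float))

    truth = GroundTruth(
        pixel_count=int(nr),
        bounds=(int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())),
        channel_means=tuple(float(v.mean()) for v in lesion_vals),
        channel_sds=tuple(float(v.std()) for v in lesion_vals),
    )
    return img, mask, truth


@dataclass(frozen=True)
class ClassParams:
    """Sampling ranges for one class's lesion population."""

    axes_range: tuple = (10, 18)               # semi-axis, uniform
    roughness_range: tuple = (0.0, 0.15)
    asymmetry_range: tuple = (0, 2)            # integer extra semi-axis
    mean_ranges: tuple = ((140, 180), (100, 140), (90, 130))
    sd_range: tuple = (4.0, 12.0)


# Study conditions for the two classes, chosen along the ABCD directions:
# melanomas are larger (D), more asymmetric (A), more irregular (B) and
# more color-variable and darker (C) than benign nevi.
BENIGN_PARAMS = ClassParams()
MELANOMA_PARAMS = ClassParams(
    axes_range=(22, 34),
    roughness_range=(0.2, 0.45),
    asymmetry_range=(4, 10),
    mean_ranges=((60, 110), (40, 85), (35, 80)),
    sd_range=(18.0, 38.0),
)


def _draw_spec(params: ClassParams, canvas, rng) -> LesionSpec:
    a = rng.uniform(*params.axes_range)
    b = rng.uniform(*params.axes_range)
    return LesionSpec(
        canvas=canvas,
        axes=(a, b),
        boundary_roughness=float(rng.uniform(*params.roughness_range)),
        asymmetry_shift=(
            int(rng.integers(params.asymmetry_range[0], params.asymmetry_range[1] + 1)),
            int(rng.integers(params.asymmetry_range[0], params.asymmetry_range[1] + 1)),
        ),
        channel_means=tuple(float(rng.uniform(lo, hi)) for lo, hi in params.mean_ranges),
        channel_sds=tuple(float(rng.uniform(*params.sd_range)) for _ in range(3)),
        seed=int(rng.integers(0, 2 ** 31)),
    )


def generate_dataset(
    n_per_class: tuple,
    melanoma_params: ClassParams = MELANOMA_PARAMS,
    benign_params: ClassParams = BENIGN_PARAMS,
    seed: int = 0,
    canvas: tuple = (192, 192),
) -> list:
    """Generate a labeled lesion set.

    ``n_per_class`` is (n_benign, n_melanoma) — e.g. (160, 40) reproduces
    the reference database's class ratio.  Deterministic given ``seed``.
    """
    n_benign, n_melanoma = n_per_class
    rng = np.random.default_rng(seed)
    samples = []
    for label, count, params in (
        (NON_MELANOMA, n_benign, benign_params),
        (MELANOMA, n_melanoma, melanoma_params),
    ):
        for _ in range(count):
            spec = _draw_spec(params, canvas, rng)
            img, mask, truth = generate_lesion(spec)
            truth = replace(truth, label=label)
            samples.append(LesionSample(img, mask, label, truth, spec))
    return samples
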