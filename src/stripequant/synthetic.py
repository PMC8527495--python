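"""Synthetic embryo images and cohorts with known ground truth.

The generator emulates a lateral-view blastoderm embryo imaged by
fluorescent in situ HCR: an ellipse of uniform nuclear signal carrying a
target channel whose intensity is a sum of Gaussian stripes in the AP
fraction ``u`` (uniform across DV), on a constant background, with optional
additive Gaussian and Poisson noise.  Pair-rule genes such as *ftz* show
seven stripes roughly four cells (~4% egg length) wide, which sets the
default stripe width sigma ≈ 0.017 egg lengths.

Ground truth per stripe — integration (a.u.·%EL), centroid and width
(%EL) — is computed analytically from the noiseless continuous profile
using the same boundary rule the quantification pipeline applies
(:func:`stripequant.profile.call_stripes` on a dense profile), so recovery
tests compare like with like.  Because stripe geometry is defined in embryo
coordinates, ground truth is invariant under rotation of the imaging frame.

Cohorts emulate the per-embryo integration tables of the published
experiment: each embryo's per-stripe integration is drawn from a normal
distribution truncated at zero (integrations are nonnegative), with
per-stripe, per-genotype means and SDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.ndimage import uniform_filter1d
from scipy.stats import truncnorm

from .profile import APProfile, StripeCall, call_stripes

#: default stripe width, egg-length fraction (~4 cells ≈ 4% EL full width)
DEFAULT_SIGMA = 0.017

#: default AP centers of the seven stripes, egg-length fraction
DEFAULT_CENTERS = tuple(np.linspace(0.25, 0.73, 7))


class StripeSpec(BaseModel):
    """One Gaussian stripe: center and sigma in egg-length fractions."""

    model_config = {"extra": "forbid"}

    index: int = Field(ge=1, le=7)
    center: float = Field(gt=0.0, lt=1.0)
    sigma: float = Field(gt=0.0)
    amplitude: float = Field(ge=0.0, description="peak intensity above background, a.u.")


class EmbryoImageSpec(BaseModel):
    """Parameters of one synthetic embryo image."""

    model_config = {"extra": "forbid"}

    image_shape: tuple[int, int] = (220, 400)
    semi_axes: tuple[float, float] = (170.0, 70.0)  # (AP, DV) half-lengths, px
    rotation: float = 0.0  # degrees, AP axis from image x-axis
    anterior_side: str = Field("low", pattern="^(low|high)$")
    stripes: list[StripeSpec] = Field(default_factory=lambda: default_wildtype_stripes())
    background: float = Field(10.0, ge=0.0)
    noise_sd: Optional[float] = Field(
        None, ge=0.0, description="additive Gaussian noise SD; default 2% of max amplitude"
    )
    shot_noise: bool = False
    control_channel: bool = False
    nuclear_intensity: float = Field(100.0, gt=0.0)
    seed: int = 0

    @field_validator("semi_axes")
    @classmethod
    def _axes_valid(cls, v):
        a, b = v
        if a <= 2 or b <= 2:
            raise ValueError("degenerate ellipse: semi-axis <= 2 px")
        if a <= b:
            raise ValueError("AP semi-axis must exceed DV semi-axis")
        return v

    @field_validator("stripes")
    @classmethod
    def _stripes_valid(cls, v):
        centers = [s.center for s in v]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("stripe centers must be strictly increasing with index")
        for s in v:
            if s.center - 3 * s.sigma < 0 or s.center + 3 * s.sigma > 1:
                raise ValueError(
                    f"stripe {s.index} extends beyond embryo (center ± 3 sigma outside [0, 1])"
                )
        return v

    @model_validator(mode="after")
    def _ellipse_fits(self):
        rows, cols = self.image_shape
        a, b = self.semi_axes
        theta = np.deg2rad(self.rotation)
        bx = np.hypot(a * np.cos(theta), b * np.sin(theta))
        by = np.hypot(a * np.sin(theta), b * np.cos(theta))
        if bx > cols / 2 - 3 or by > rows / 2 - 3:
            raise ValueError("embryo ellipse does not fit inside image with margin")
        return self

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        amax = max((s.amplitude for s in self.stripes), default=0.0)
        return 0.02 * amax


def default_wildtype_stripes(scale: float = 1.0) -> list[StripeSpec]:
    """Seven stripes with amplitudes proportional to the published
    wild-type per-stripe integration means."""
    amps = (63.9, 69.1, 56.9, 58.6, 68.9, 90.3, 157.0)
    return [
        StripeSpec(index=i + 1, center=c, sigma=DEFAULT_SIGMA, amplitude=a * scale)
        for i, (c, a) in enumerate(zip(DEFAULT_CENTERS, amps))
    ]


def mutant_like_stripes(scale: float = 1.0) -> list[StripeSpec]:
    """Seven stripes with amplitudes proportional to the published
    zebra-element-deletion per-stripe integration means (stripe 4 weak)."""
    amps = (47.4, 60.9, 34.6, 16.1, 34.1, 63.2, 63.9)
    return [
        StripeSpec(index=i + 1, center=c, sigma=DEFAULT_SIGMA, amplitude=a * scale)
        for i, (c, a) in enumerate(zip(DEFAULT_CENTERS, amps))
    ]


@dataclass(frozen=True)
class StripeTruth:
    index: int
    center: float
    sigma: float
    amplitude: float
    integration: float  # a.u.·%EL, band-restricted, pipeline boundary rule
    centroid: float  # %EL
    width: float  # %EL


@dataclass(frozen=True)
class GroundTruth:
    stripes: list[StripeTruth]
    mask_area: int

    def to_dict(self) -> dict:
        return {
            "mask_area": self.mask_area,
            "stripes": [
                {
                    "index": s.index,
                    "center": s.center,
                    "sigma": s.sigma,
                    "amplitude": s.amplitude,
                    "integration": s.integration,
                    "centroid": s.centroid,
                    "width": s.width,
                }
                for s in self.stripes
            ],
        }


def stripe_signal(u: np.ndarray, stripes: list[StripeSpec]) -> np.ndarray:
    """Noiseless stripe signal above background at AP fractions ``u``."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    for s in stripes:
        out += s.amplitude * np.exp(-((u - s.center) ** 2) / (2 * s.sigma**2))
    return out


def analytic_ground_truth(
    stripes: list[StripeSpec],
    grid: int = 20001,
    peak_prominence: float = 0.05,
    boundary_fraction: float = 0.2,
    fallback_halfwidth: float = 2.5,
    smooth_u: float = 0.03,
) -> list[StripeTruth]:
    """Per-stripe metrics of the noiseless continuous profile.

    Applies the pipeline's stripe boundary rule to a dense sampling of the
    analytic profile, so the truth is defined at the same boundaries the
    quantification stage uses (integrations are therefore band-restricted:
    tails beyond the boundaries are excluded by construction).  ``smooth_u``
    is the moving-average width in egg-length fractions; the default equals
    the pipeline's default smoothing (3 bins of 1% EL), making the truth
    the infinite-resolution limit of the full measurement rule — without it,
    smoothing-induced shifts of asymmetric interstripe minima would appear
    as spurious recovery error.  Set ``smooth_u=0`` for the raw profile.
    """
    u = (np.arange(grid) + 0.5) / grid
    y = stripe_signal(u, stripes)
    if smooth_u > 0:
        window = max(int(round(smooth_u * grid)), 1)
        y = uniform_filter1d(y, size=window, mode="nearest")
    prof = APProfile(bin_centers=u, intensity=y, bin_width=1.0 / grid)
    calls = call_stripes(
        prof,
        expected=len(stripes),
        reference_centers=[s.center * 100 for s in stripes],
        peak_prominence=peak_prominence,
        boundary_fraction=boundary_fraction,
        fallback_halfwidth=fallback_halfwidth,
    )
    return [
        StripeTruth(
            index=s.index,
            center=s.center,
            sigma=s.sigma,
            amplitude=s.amplitude,
            integration=c.integration,
            centroid=c.centroid,
            width=c.width,
        )
        for s, c in zip(stripes, calls)
    ]


def ellipse_mask(spec: EmbryoImageSpec) -> np.ndarray:
    """Analytic embryo mask (the segmentation oracle)."""
    _, _, inside = _embryo_frame(spec)
    return inside


def _embryo_frame(spec: EmbryoImageSpec):
    """Per-pixel AP fraction u, DV fraction v, and inside-ellipse mask."""
    rows, cols = spec.image_shape
    a, b = spec.semi_axes
    theta = np.deg2rad(spec.rotation)
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx - (cols - 1) / 2.0
    y = yy - (rows - 1) / 2.0
    ax = x * np.cos(theta) + y * np.sin(theta)  # axial (AP) coordinate, px
    dv = -x * np.sin(theta) + y * np.cos(theta)
    inside = (ax / a) ** 2 + (dv / b) ** 2 <= 1.0
    u = (ax + a) / (2 * a)
    if spec.anterior_side == "high":
        u = 1.0 - u
    v = dv / (2 * b)
    return u, v, inside


#: fixed offset of the control-gene (eve-like) stripes, egg-length fraction
_CONTROL_SHIFT = -0.035
_CONTROL_AMPLITUDE = 80.0


def generate_embryo_image(spec: EmbryoImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic embryo.

    Returns ``(image, ground_truth)`` where ``image`` has shape
    ``(channels, rows, cols)``: channel 0 the target gene, channel 1 the
    control gene (only when ``spec.control_channel``), and the last channel
    the nuclear stain.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    u, _, inside = _embryo_frame(spec)

    target = np.where(inside, spec.background + stripe_signal(u, spec.stripes), 0.0)
    channels = [target]
    if spec.control_channel:
        ctrl_stripes = [
            StripeSpec(
                index=s.index,
                center=s.center + _CONTROL_SHIFT,
                sigma=s.sigma,
                amplitude=_CONTROL_AMPLITUDE,
            )
            for s in spec.stripes
        ]
        channels.append(
            np.where(inside, spec.background + stripe_signal(u, ctrl_stripes), 0.0)
        )
    channels.append(np.where(inside, spec.nuclear_intensity, 0.0))

    image = np.stack(channels)
    if spec.shot_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    sd = spec.effective_noise_sd
    if sd > 0:
        image = image + rng.normal(0.0, sd, size=image.shape)

    truth = GroundTruth(
        stripes=analytic_ground_truth(spec.stripes),
        mask_area=int(inside.sum()),
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohort simulation


class GroupLevels(BaseModel):
    """Per-genotype stripe-integration distribution parameters."""

    model_config = {"extra": "forbid"}

    genotype: str
    n: int = Field(ge=2)
    mean: list[float]
    sd: list[float]

    @model_validator(mode="after")
    def _lengths_and_signs(self):
        if len(self.mean) != len(self.sd):
            raise ValueError("mean and sd must have the same length")
        if any(m < 0 for m in self.mean) or any(s < 0 for s in self.sd):
            raise ValueError("means and SDs must be nonnegative")
        return self


class CohortSpec(BaseModel):
    """Two-or-more genotype cohort of per-embryo stripe integrations."""

    model_config = {"extra": "forbid"}

    groups: list[GroupLevels]
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self):
        if not self.groups:
            raise ValueError("cohort needs at least one genotype group")
        k = len(self.groups[0].mean)
        if any(len(g.mean) != k for g in self.groups):
            raise ValueError("all groups must parameterize the same stripes")
        return self


def cohort_spec_from_summaries(summaries: pd.DataFrame, seed: int = 0) -> CohortSpec:
    """Build a :class:`CohortSpec` from a tidy summary frame with columns
    ``stripe, genotype, n, mean, sd`` (e.g.
    :func:`stripequant.datasets.zebra_deletion_summaries`)."""
    groups = []
    for genotype, grp in summaries.groupby("genotype", sort=False):
        grp = grp.sort_values("stripe")
        n = grp["n"].unique()
        if len(n) != 1:
            raise ValueError(f"inconsistent n for genotype {genotype}")
        groups.append(
            GroupLevels(
                genotype=str(genotype),
                n=int(n[0]),
                mean=grp["mean"].tolist(),
                sd=grp["sd"].tolist(),
            )
        )
    return CohortSpec(groups=groups, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-embryo stripe-integration table.

    Each integration is drawn from Normal(mean, sd) truncated at zero
    (a zero-SD stripe degenerates to its mean).  Deterministic for a fixed
    seed.  Returns a tidy frame ``embryo_id, genotype, stripe, integration``
    with one row per embryo and stripe.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.groups:
        draws = np.empty((group.n, len(group.mean)))
        for j, (m, s) in enumerate(zip(group.mean, group.sd)):
            if s == 0:
                draws[:, j] = m
            else:
                a = (0.0 - m) / s
                draws[:, j] = truncnorm.rvs(
                    a, np.inf, loc=m, scale=s, size=group.n, random_state=rng
                )
        for i in range(group.n):
            for j in range(len(group.mean)):
                rows.append(
                    (f"{group.genotype}_{i + 1}", group.genotype, j + 1, draws[i, j])
                )
    return pd.DataFrame(rows, columns=["embryo_id", "genotype", "stripe", "integration"])


# ---------------------------------------------------------------------------
# file output


def write_embryo_tiff(
    path: str | Path,
    image: np.ndarray,
    truth: GroundTruth,
    spec: EmbryoImageSpec,
) -> Path:
    """Write a multi-page TIFF (one page per channel) plus a sidecar JSON
    carrying the generating spec and ground truth."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    roles = ["target"]
    if spec.control_channel:
        roles.append("control")
    roles.append("nuclear")
    sidecar = {
        "channels": roles,
        "spec": spec.model_dump(),
        "ground_truth": truth.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path
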