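"""Ground-truthed synthetic spread nuclei and a STED-like renderer.

Real spread-nucleus micrographs behind the published focus statistics are not
deposited anywhere, so every downstream stage of this package is exercised on
synthetic fields whose population structure copies the published per-strain
moments: per-nucleus focus counts, focus-length distributions, and a
DSB-coupled fraction of Dmc1 foci anchored next to an RPA focus.

Coordinates are in nanometres throughout, origin at the top-left pixel center
of the rendered image, x rightward, y downward.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "NucleusGeometry", "LengthDistribution", "PopulationSpec", "PairingSpec",
    "GroundTruthFocus", "RenderSpec", "strain_preset", "sample_focus_field",
    "render_channel", "simulate_nuclei", "nucleus_rng", "unpaired_component",
    "STRAIN_PRESETS",
]

DMC1 = "DMC1"
RPA = "RPA"

#: Retry budget for re-drawing an offset that pushes a paired focus outside
#: the nucleus before giving up with an error.
PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class NucleusGeometry:
    """Elliptical sampling region standing in for one spread nucleus."""

    nucleus_id: str
    center_xy: tuple[float, float] = (0.0, 0.0)
    semi_axes: tuple[float, float] = (1800.0, 1800.0)  # nm; default: circle
    orientation: float = 0.0  # radians

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a > 0 and b > 0):
            raise ValueError("semi-axes must be positive")
        if not (500.0 <= a <= 5000.0 and 500.0 <= b <= 5000.0):
            raise ValueError(
                f"semi-axes {self.semi_axes} outside the realistic spread "
                "range [500, 5000] nm"
            )

    @property
    def area_nm2(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized ellipse-inequality test for an (n, 2) array of points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        d = xy - np.asarray(self.center_xy)
        u = d[:, 0] * c + d[:, 1] * s
        v = -d[:, 0] * s + d[:, 1] * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n points uniform over the ellipse (area-uniform disc mapping)."""
        r = np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        u = r * np.cos(phi) * self.semi_axes[0]
        v = r * np.sin(phi) * self.semi_axes[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        x = u * c - v * s + self.center_xy[0]
        y = u * s + v * c + self.center_xy[1]
        return np.column_stack([x, y])


@dataclass(frozen=True)
class LengthDistribution:
    """Focus-length law parameterized by its first two moments.

    Only mean ± SD are published for focus lengths, so the family is a
    modelling choice; the default is a moment-matched lognormal, which keeps
    lengths positive and right-skewed as focus-length populations are.
    """

    mean_nm: float
    sd_nm: float = 0.0
    family: Literal["lognormal", "gamma", "fixed"] = "lognormal"

    def __post_init__(self) -> None:
        if self.mean_nm <= 0:
            raise ValueError("mean_nm must be positive")
        if self.sd_nm < 0:
            raise ValueError("sd_nm must be non-negative")
        if self.family == "fixed" and self.sd_nm != 0:
            raise ValueError("family='fixed' requires sd_nm = 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.family == "fixed" or self.sd_nm == 0:
            return np.full(n, self.mean_nm)
        if self.family == "lognormal":
            # moment matching: E = exp(mu + s^2/2), Var = E^2 (exp(s^2) - 1)
            s2 = math.log1p((self.sd_nm / self.mean_nm) ** 2)
            mu = math.log(self.mean_nm) - s2 / 2.0
            return rng.lognormal(mu, math.sqrt(s2), size=n)
        if self.family == "gamma":
            k = (self.mean_nm / self.sd_nm) ** 2
            theta = self.sd_nm**2 / self.mean_nm
            return rng.gamma(k, theta, size=n)
        raise ValueError(f"unknown length family {self.family!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """One channel's focus population for a nucleus."""

    channel: str
    count_mean: float
    length_dist: LengthDistribution
    count_model: Literal["poisson", "fixed"] = "poisson"

    def __post_init__(self) -> None:
        if self.channel not in (DMC1, RPA):
            raise ValueError(f"channel must be {DMC1} or {RPA}, got {self.channel!r}")
        if self.count_mean < 0:
            raise ValueError("count mean must be >= 0")

    def sample_count(self, rng: np.random.Generator) -> int:
        if self.count_model == "fixed":
            return int(round(self.count_mean))
        return int(rng.poisson(self.count_mean))


@dataclass(frozen=True)
class PairingSpec:
    """How Dmc1 foci couple to RPA foci.

    ``paired_fraction`` of the Dmc1 foci are anchored next to an RPA focus at
    a center-to-center distance drawn from a zero-truncated normal;
    the remainder ("DSB-independent", off-pathway) are placed uniformly.
    ``paired_length_dist``, when set, gives paired Dmc1 foci their own length
    law (the published RPA-colocalized moments); otherwise paired foci share
    the channel's overall length distribution.
    """

    paired_fraction: float = 0.0
    offset_mean_nm: float = 90.0
    offset_sd_nm: float = 40.0
    paired_length_dist: Optional[LengthDistribution] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.offset_mean_nm < 0:
            raise ValueError("offset mean must be >= 0")
        if self.offset_sd_nm < 0:
            raise ValueError("offset sd must be >= 0")

    def sample_offset(self, rng: np.random.Generator) -> float:
        """Zero-truncated normal offset distance (rejection sampling)."""
        if self.offset_sd_nm == 0:
            return self.offset_mean_nm
        for _ in range(1000):
            d = rng.normal(self.offset_mean_nm, self.offset_sd_nm)
            if d >= 0:
                return float(d)
        return 0.0  # pathological mean << -sd; effectively point mass at 0


@dataclass(frozen=True)
class GroundTruthFocus:
    focus_id: str
    channel: str
    center_xy: tuple[float, float]
    length_nm: float
    orientation: float
    partner_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_nm <= 0:
            raise ValueError("length_nm must be positive")


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for STED-like (post-deconvolution) images.

    The default PSF sigma of 15 nm gives a FWHM of ~35 nm, i.e. below the
    ~50 nm resolution limit of the depletion microscope being emulated.
    """

    pixel_size_nm: float = 20.0
    psf_sigma_nm: float = 15.0
    background_level: float = 100.0
    amplitude_per_nm: float = 50.0  # counts per nm of filament
    poisson_gain: float = 0.0  # 0 disables photon noise
    gaussian_sd: float = 0.0  # additive read-noise sd, 0 disables
    bit_depth: int = 16
    margin_nm: float = 250.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be >= 0")


# Published per-strain moments: (count mean,) per-nucleus focus counts and
# (mean, sd) pooled focus lengths, both channels, plus the pairing defaults.
# Strains without a published colocalization percentage get paired_fraction
# 0.5, an explicitly arbitrary stand-in.
_P = {
    "wild-type": dict(
        dmc1_count=26.9, dmc1_len=(97.1, 38.8),
        rpa_count=70.0, rpa_len=(76.8, 27.0),
        paired_fraction=0.355, paired_len=(118.9, 40.0),
    ),
    "rad51": dict(
        dmc1_count=23.3, dmc1_len=(82.5, 30.0),
        rpa_count=140.5, rpa_len=(134.0, 70.4),
        paired_fraction=0.5, paired_len=None,
    ),
    "dmc1-E157D": dict(
        dmc1_count=114.0, dmc1_len=(134.1, 61.5),
        rpa_count=111.5, rpa_len=(107.4, 49.5),
        paired_fraction=0.701, paired_len=(149.5, 66.8),
    ),
    "dmc1-E157D mei5": dict(
        dmc1_count=119.2, dmc1_len=(147.1, 66.4),
        rpa_count=130.8, rpa_len=(97.7, 39.6),
        paired_fraction=0.691, paired_len=(168.0, 66.4),
    ),
    "dmc1-E157D rad51": dict(
        dmc1_count=105.3, dmc1_len=(161.9, 78.9),
        rpa_count=132.0, rpa_len=(136.0, 77.8),
        paired_fraction=0.5, paired_len=None,
    ),
    "dmc1-E157D mei5 rad51": dict(
        dmc1_count=106.8, dmc1_len=(143.3, 64.7),
        rpa_count=131.3, rpa_len=(130.8, 63.8),
        paired_fraction=0.5, paired_len=None,
    ),
}

STRAIN_PRESETS: tuple[str, ...] = tuple(_P)


def strain_preset(name: str) -> tuple[list[PopulationSpec], PairingSpec]:
    """Population and pairing specs matching a profiled strain's moments.

    Parameters
    ----------
    name
        One of :data:`STRAIN_PRESETS` (``wild-type``, ``rad51``,
        ``dmc1-E157D`` and its double/triple mutant combinations).

    Returns
    -------
    (specs, pairing)
        Per-channel :class:`PopulationSpec` list (DMC1 then RPA) and the
        strain's :class:`PairingSpec`.
    """
    try:
        p = _P[name]
    except KeyError:
        raise ValueError(
            f"unknown strain {name!r}; valid presets: {', '.join(STRAIN_PRESETS)}"
        ) from None
    specs = [
        PopulationSpec(DMC1, p["dmc1_count"], LengthDistribution(*p["dmc1_len"])),
        PopulationSpec(RPA, p["rpa_count"], LengthDistribution(*p["rpa_len"])),
    ]
    paired_len = (
        LengthDistribution(*p["paired_len"]) if p["paired_len"] is not None else None
    )
    pairing = PairingSpec(
        paired_fraction=p["paired_fraction"], paired_length_dist=paired_len
    )
    return specs, pairing


def unpaired_component(
    overall: LengthDistribution,
    paired: LengthDistribution,
    paired_fraction: float,
) -> LengthDistribution:
    """Length law for unpaired foci such that the paired/unpaired mixture
    reproduces the overall (mean, sd).

    With fraction ``f`` of foci drawn from ``paired``, the complement must
    have ``mu_u = (mu - f mu_p)/(1 - f)`` and a variance solved from the
    mixture second moment. Raises if the published moments admit no valid
    complement (negative mean or variance).
    """
    f = paired_fraction
    if f <= 0:
        return overall
    if f >= 1:
        return paired
    mu_u = (overall.mean_nm - f * paired.mean_nm) / (1.0 - f)
    if mu_u <= 0:
        raise ValueError(
            "no unpaired length component: paired mean too large for the "
            f"overall mean at paired_fraction {f}"
        )
    m2 = overall.sd_nm**2 + overall.mean_nm**2  # mixture second moment
    m2_p = paired.sd_nm**2 + paired.mean_nm**2
    var_u = (m2 - f * m2_p) / (1.0 - f) - mu_u**2
    if var_u < 0:
        raise ValueError(
            "no unpaired length component: mixture variance constraint "
            f"infeasible at paired_fraction {f}"
        )
    return LengthDistribution(mu_u, math.sqrt(var_u), family=overall.family)


def nucleus_rng(root_seed: int, nucleus_id: str | int) -> np.random.Generator:
    """Deterministic per-nucleus stream derived from (root seed, nucleus id)."""
    tag = zlib.crc32(str(nucleus_id).encode())
    return np.random.default_rng([int(root_seed), tag])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_focus_field(
    geometry: NucleusGeometry,
    specs: Sequence[PopulationSpec],
    pairing: PairingSpec,
    seed: int | np.random.Generator,
) -> list[GroundTruthFocus]:
    """Sample one nucleus's two-channel ground-truth focus field.

    RPA foci are placed uniformly in the nucleus ellipse. A fraction
    ``round(paired_fraction * n_dmc1)`` of Dmc1 foci is anchored to an RPA
    partner at a zero-truncated-normal center distance in a uniform
    direction; the rest are uniform (DSB-independent). Identical arguments
    and seed give identical output.

    Raises
    ------
    RuntimeError
        If a paired focus cannot be placed inside the nucleus within the
        retry budget (offset repeatedly lands outside the ellipse).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_channel = {s.channel: s for s in specs}
    foci: list[GroundTruthFocus] = []

    n_rpa = by_channel[RPA].sample_count(rng) if RPA in by_channel else 0
    rpa_centers = geometry.sample_uniform(rng, n_rpa)
    rpa_lengths = by_channel[RPA].length_dist.sample(rng, n_rpa) if n_rpa else []
    rpa_ids = [f"{geometry.nucleus_id}:RPA:{i:04d}" for i in range(n_rpa)]
    for i in range(n_rpa):
        foci.append(
            GroundTruthFocus(
                focus_id=rpa_ids[i],
                channel=RPA,
                center_xy=(float(rpa_centers[i, 0]), float(rpa_centers[i, 1])),
                length_nm=float(rpa_lengths[i]),
                orientation=float(rng.uniform(0.0, math.pi)),
            )
        )

    n_dmc1 = by_channel[DMC1].sample_count(rng) if DMC1 in by_channel else 0
    if n_dmc1 == 0:
        return foci
    n_paired = _round_half_up(pairing.paired_fraction * n_dmc1)
    if n_paired > 0 and n_rpa == 0:
        raise RuntimeError(
            f"nucleus {geometry.nucleus_id}: cannot pair {n_paired} Dmc1 foci "
            "with zero RPA foci"
        )

    # partner assignment: without replacement while distinct RPA foci remain
    if n_paired:
        if n_paired <= n_rpa:
            partners = rng.choice(n_rpa, size=n_paired, replace=False)
        else:
            partners = rng.choice(n_rpa, size=n_paired, replace=True)
    else:
        partners = np.empty(0, dtype=int)

    dmc1_dist = by_channel[DMC1].length_dist
    if pairing.paired_length_dist is not None:
        paired_dist = pairing.paired_length_dist
        # unpaired foci use the complement law so the pooled Dmc1 lengths
        # keep the channel's stated overall moments
        free_dist = unpaired_component(dmc1_dist, paired_dist, pairing.paired_fraction)
    else:
        paired_dist = free_dist = dmc1_dist
    n_free = n_dmc1 - n_paired
    free_centers = geometry.sample_uniform(rng, n_free)
    paired_lengths = paired_dist.sample(rng, n_paired)
    free_lengths = free_dist.sample(rng, n_free)

    for i in range(n_paired):
        fid = f"{geometry.nucleus_id}:DMC1:{i:04d}"
        anchor = rpa_centers[partners[i]]
        for _ in range(PLACEMENT_RETRIES):
            d = pairing.sample_offset(rng)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            xy = anchor + d * np.array([math.cos(phi), math.sin(phi)])
            if geometry.contains(xy)[0]:
                break
        else:
            raise RuntimeError(
                f"focus {fid}: no valid placement inside nucleus "
                f"{geometry.nucleus_id} after {PLACEMENT_RETRIES} offset draws"
            )
        foci.append(
            GroundTruthFocus(
                focus_id=fid,
                channel=DMC1,
                center_xy=(float(xy[0]), float(xy[1])),
                length_nm=float(paired_lengths[i]),
                orientation=float(rng.uniform(0.0, math.pi)),
                partner_id=rpa_ids[partners[i]],
            )
        )
    for j in range(n_free):
        foci.append(
            GroundTruthFocus(
                focus_id=f"{geometry.nucleus_id}:DMC1:{n_paired + j:04d}",
                channel=DMC1,
                center_xy=(float(free_centers[j, 0]), float(free_centers[j, 1])),
                length_nm=float(free_lengths[j]),
                orientation=float(rng.uniform(0.0, math.pi)),
            )
        )
    return foci


def _segment_intensity(
    xx: np.ndarray,
    yy: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    sigma: float,
    density: float,
) -> np.ndarray:
    """Closed-form image of a uniform line segment under an isotropic
    Gaussian PSF: separable into a perpendicular Gaussian profile and a
    difference of normal CDFs along the segment axis."""
    from scipy.special import ndtr

    seg = p1 - p0
    length = float(np.hypot(*seg))
    if length == 0.0:  # point source
        r2 = (xx - p0[0]) ** 2 + (yy - p0[1]) ** 2
        return density * np.exp(-r2 / (2 * sigma**2)) / (2 * math.pi * sigma**2)
    u = seg / length
    dx = xx - p0[0]
    dy = yy - p0[1]
    t = dx * u[0] + dy * u[1]
    d = -dx * u[1] + dy * u[0]
    perp = np.exp(-(d**2) / (2 * sigma**2)) / (math.sqrt(2 * math.pi) * sigma)
    along = ndtr(t / sigma) - ndtr((t - length) / sigma)
    return density * perp * along


def render_channel(
    foci: Sequence[GroundTruthFocus],
    geometry: NucleusGeometry,
    render: RenderSpec,
    seed: int | np.random.Generator = 0,
):
    """Render one channel's foci as a STED-like image.

    Each focus contributes a uniform-intensity line segment of its length and
    orientation convolved with an isotropic Gaussian PSF (evaluated in closed
    form at pixel centers), on a constant background; optional Poisson photon
    noise and additive Gaussian read noise follow. With both noise terms off
    the output is deterministic, and the above-background integrated
    intensity is proportional to total segment length.

    Returns a :class:`spreadfoci.detect.Image`.
    """
    from spreadfoci.detect import Image

    channels = {f.channel for f in foci}
    if len(channels) > 1:
        raise ValueError(f"render_channel expects one channel, got {sorted(channels)}")
    channel = channels.pop() if channels else "EMPTY"

    px = render.pixel_size_nm
    a, b = geometry.semi_axes
    half = max(a, b) + render.margin_nm
    x0 = geometry.center_xy[0] - half
    y0 = geometry.center_xy[1] - half
    n_px = int(math.ceil(2 * half / px)) + 1
    img = np.full((n_px, n_px), float(render.background_level))

    lengths = [f.length_nm for f in foci]
    if lengths and px >= min(lengths):
        warnings.warn(
            f"pixel size {px} nm is not smaller than the shortest focus "
            f"({min(lengths):.1f} nm); sub-pixel foci will render as spots",
            stacklevel=2,
        )

    sigma = max(render.psf_sigma_nm, 1e-3)  # avoid a true delta at sigma=0
    for f in foci:
        cx, cy = f.center_xy
        hx = 0.5 * f.length_nm * math.cos(f.orientation)
        hy = 0.5 * f.length_nm * math.sin(f.orientation)
        p0 = np.array([cx - hx, cy - hy])
        p1 = np.array([cx + hx, cy + hy])
        # window: segment bbox padded by 6 sigma
        pad = 6.0 * sigma
        j0 = max(0, int((min(p0[0], p1[0]) - pad - x0) // px))
        j1 = min(n_px - 1, int((max(p0[0], p1[0]) + pad - x0) // px) + 1)
        i0 = max(0, int((min(p0[1], p1[1]) - pad - y0) // px))
        i1 = min(n_px - 1, int((max(p0[1], p1[1]) + pad - y0) // px) + 1)
        if j1 < j0 or i1 < i0:
            continue
        xs = x0 + np.arange(j0, j1 + 1) * px
        ys = y0 + np.arange(i0, i1 + 1) * px
        xx, yy = np.meshgrid(xs, ys)
        img[i0 : i1 + 1, j0 : j1 + 1] += (
            _segment_intensity(xx, yy, p0, p1, sigma, render.amplitude_per_nm) * px**2
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if render.poisson_gain > 0:
        img = render.poisson_gain * rng.poisson(
            np.maximum(img, 0.0) / render.poisson_gain
        ).astype(float)
    if render.gaussian_sd > 0:
        img = img + rng.normal(0.0, render.gaussian_sd, size=img.shape)
    vmax = 2**render.bit_depth - 1
    img = np.clip(np.round(img), 0, vmax)
    dtype = np.uint16 if render.bit_depth <= 16 else np.uint32
    return Image(
        data=img.astype(dtype),
        pixel_size_nm=px,
        channel=channel,
        nucleus_id=geometry.nucleus_id,
        origin_xy=(x0, y0),
    )


def simulate_nuclei(
    strain: str,
    n_nuclei: int,
    seed: int,
    geometry: Optional[NucleusGeometry] = None,
    specs: Optional[Sequence[PopulationSpec]] = None,
    pairing: Optional[PairingSpec] = None,
) -> list[tuple[NucleusGeometry, list[GroundTruthFocus]]]:
    """Simulate ``n_nuclei`` spread nuclei for a strain preset.

    Each nucleus uses its own RNG stream derived from ``(seed, nucleus_id)``,
    so per-nucleus output is independent of how many nuclei are requested.
    """
    if specs is None or pairing is None:
        preset_specs, preset_pairing = strain_preset(strain)
        specs = specs if specs is not None else preset_specs
        pairing = pairing if pairing is not None else preset_pairing
    out = []
    for k in range(n_nuclei):
        nid = f"{strain}:{k:04d}"
        geo = (
            replace(geometry, nucleus_id=nid)
            if geometry is not None
            else NucleusGeometry(nucleus_id=nid)
        )
        rng = nucleus_rng(seed, nid)
        out.append((geo, sample_focus_field(geo, specs, pairing, rng)))
    return out
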