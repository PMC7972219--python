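"""Synthetic fluorescence microscopy with exact ground truth.

No raw confocal data accompany the measurements this package reimplements, so
every downstream stage is validated on simulated images: GFP-filled dendrite
segments bearing laterally attached spines, Iba-1-like microglia (bright soma
plus radiating processes), and diffuse staining fields with a known positive
area fraction.  Each generator emits, alongside the image stack, a ground
truth record listing every rendered structure, plus the line ROI a human
analyst would have drawn.

Rendering model
---------------
Structures are drawn as Gaussian intensity components on a constant
background, convolved with an isotropic Gaussian PSF, replicated over a small
z-stack (out-of-focus planes dimmed and extra-blurred), then passed through a
Poisson shot-noise + additive Gaussian read-noise camera model and quantized
to the requested bit depth.  Spine amplitudes are analytically compensated
for PSF attenuation so that, without noise, the *normalized* profile apex of
a spine of amplitude ``a`` sits at ``1 + a`` dendrite units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .roi_profiles import LineROI, SAMPLING_STEP_PX

GENOTYPES = ("WT", "5XFAD")
TREATMENTS = ("vehicle", "L-AAA")

#: Lateral distance from the shaft surface to a spine-head center, μm.
SPINE_NECK_UM = 0.2
#: Background spur appended to dendrite ROIs so the profile contains genuine
#: background samples for the percentile background estimator.
BACKGROUND_SPUR_UM = 3.0
#: Spine-free stretch at the start of the dendrite used as the adjacent-
#: dendrite normalization segment, μm.
DENDRITE_SEGMENT_UM = 2.5
#: Spines are kept this far from the dendrite ends, μm.
SPINE_EDGE_MARGIN_UM = 1.0

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM factor


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging model: sampling, optics, camera."""

    pixel_size: float  # μm per pixel
    psf_sigma: float = 0.15  # μm, in-plane Gaussian PSF sigma
    photon_scale: float = 5.0  # expected photons per intensity unit
    read_noise_sd: float = 1.0  # additive Gaussian noise, intensity units
    bit_depth: int = 16
    n_z: int = 3

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")


def default_dendrite_acquisition() -> AcquisitionParams:
    """High-NA settings for spine imaging (0.1 μm/px)."""
    return AcquisitionParams(pixel_size=0.1, psf_sigma=0.15, photon_scale=5.0,
                             read_noise_sd=1.0, bit_depth=16, n_z=3)


def default_microglia_acquisition() -> AcquisitionParams:
    """Lower-magnification settings for whole-cell microglia imaging."""
    return AcquisitionParams(pixel_size=0.3, psf_sigma=0.3, photon_scale=20.0,
                             read_noise_sd=1.0, bit_depth=16, n_z=3)


@dataclass(frozen=True)
class DendriteSpec:
    """Geometry and photometry of one synthetic dendrite segment.

    Spine amplitudes are dimensionless: relative fluorescence above the
    adjacent-dendrite level along the measurement line, i.e. a spine of
    amplitude 1.0 peaks at twice the local dendrite fluorescence.
    """

    length: float = 20.0  # μm
    shaft_intensity: float = 100.0  # a.u. at shaft center
    shaft_width: float = 1.0  # μm FWHM of the shaft cross-section
    background_intensity: float = 10.0  # a.u.
    spine_density_true: float = 0.5  # spines / μm
    spine_size_mean: float = 2.0  # relative amplitude above dendrite level
    spine_size_sd: float = 0.4
    spine_width_mean: float = 0.7  # μm FWHM of a spine head
    min_spine_spacing: float = 1.5  # μm
    poisson_count: bool = False  # Poisson spine count instead of round(d*L)

    def __post_init__(self) -> None:
        if self.length < 1.0:
            raise ValueError("dendrite length must be at least 1 μm")
        if self.spine_density_true < 0:
            raise ValueError("spine_density_true must be >= 0")
        if self.shaft_intensity <= self.background_intensity:
            raise ValueError("shaft_intensity must exceed background_intensity")
        if self.min_spine_spacing <= 0:
            raise ValueError("min_spine_spacing must be > 0")
        n = int(np.round(self.spine_density_true * self.length))
        span = self.length - DENDRITE_SEGMENT_UM - 1.0 - SPINE_EDGE_MARGIN_UM
        if n > 1 and (n - 1) * self.min_spine_spacing > span:
            raise ValueError(
                f"requested density {self.spine_density_true}/μm is infeasible: "
                f"{n} spines need {(n - 1) * self.min_spine_spacing:.1f} μm at "
                f"min_spine_spacing={self.min_spine_spacing} μm but only "
                f"{span:.1f} μm are available"
            )


@dataclass(frozen=True)
class MicrogliaSpec:
    """Geometry and photometry of one synthetic microglial cell.

    Intensities are absolute in-focus levels; processes are rendered as
    narrow ramified arms crossing the measurement line once each.
    """

    soma_diameter: float = 10.0  # μm, along the measurement line
    soma_intensity: float = 100.0  # a.u.
    n_processes_true: int = 6
    process_length_mean: float = 12.0  # μm
    process_width: float = 1.0  # μm FWHM
    process_intensity: float = 35.0  # a.u. peak level
    background_intensity: float = 20.0  # a.u.
    field_size: float = 60.0  # μm, square field of view

    def __post_init__(self) -> None:
        if self.process_intensity <= self.background_intensity:
            raise ValueError("process_intensity must exceed background_intensity")
        if self.soma_intensity < self.process_intensity:
            raise ValueError("soma_intensity must be >= process_intensity")
        if self.n_processes_true < 0:
            raise ValueError("n_processes_true must be >= 0")
        if self.soma_diameter <= 0:
            raise ValueError("soma_diameter must be > 0")
        slots = _process_slots(self)
        if self.n_processes_true > len(slots):
            raise ValueError(
                f"{self.n_processes_true} processes cannot be placed without "
                f"overlap at process_width={self.process_width} μm in a "
                f"{self.field_size} μm field (max {len(slots)})"
            )


@dataclass(frozen=True)
class ConditionPreset:
    """Multiplicative effect sizes of one genotype × treatment condition,
    relative to the WT-vehicle baseline."""

    genotype: str
    treatment: str
    spine_density_factor: float = 1.0
    spine_size_factor: float = 1.0
    microglia_process_factor: float = 1.0
    soma_size_factor: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.spine_density_factor, self.spine_size_factor,
                  self.microglia_process_factor, self.soma_size_factor):
            if f <= 0:
                raise ValueError("preset factors must be > 0")


# L-AAA removes one third of spines in every genotype; spine size drops a
# further 47% under L-AAA only on the amyloid (5XFAD) background.  Microglia
# under L-AAA retract processes and enlarge their soma (direction observed,
# magnitude a modelling choice).
_SPINE_SIZE = {
    ("WT", "vehicle"): 1.0,
    ("WT", "L-AAA"): 1.0,
    ("5XFAD", "vehicle"): 0.8,
    ("5XFAD", "L-AAA"): 0.8 * 0.53,
}
_PROCESS = {
    ("WT", "vehicle"): 1.0,
    ("WT", "L-AAA"): 0.6,
    ("5XFAD", "vehicle"): 0.85,
    ("5XFAD", "L-AAA"): 0.85 * 0.6,
}
_SOMA = {
    ("WT", "vehicle"): 1.0,
    ("WT", "L-AAA"): 1.25,
    ("5XFAD", "vehicle"): 1.1,
    ("5XFAD", "L-AAA"): 1.4,
}


def condition_preset(genotype: str, treatment: str) -> ConditionPreset:
    """Effect-size preset for one of the four study conditions."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    key = (genotype, treatment)
    return ConditionPreset(
        genotype=genotype,
        treatment=treatment,
        spine_density_factor=0.67 if treatment == "L-AAA" else 1.0,
        spine_size_factor=_SPINE_SIZE[key],
        microglia_process_factor=_PROCESS[key],
        soma_size_factor=_SOMA[key],
    )


def apply_preset_to_dendrite(spec: DendriteSpec, preset: ConditionPreset) -> DendriteSpec:
    return replace(
        spec,
        spine_density_true=spec.spine_density_true * preset.spine_density_factor,
        spine_size_mean=spec.spine_size_mean * preset.spine_size_factor,
        spine_size_sd=spec.spine_size_sd * preset.spine_size_factor,
    )


def apply_preset_to_microglia(spec: MicrogliaSpec, preset: ConditionPreset) -> MicrogliaSpec:
    return replace(
        spec,
        n_processes_true=int(np.round(spec.n_processes_true * preset.microglia_process_factor)),
        soma_diameter=spec.soma_diameter * preset.soma_size_factor,
    )


@dataclass
class SyntheticGroundTruth:
    """Exact description of every structure rendered into an image."""

    kind: str  # "dendrite" | "microglia" | "area"
    pixel_size: float
    # dendrite
    dendrite_length_um: float | None = None
    spine_positions_um: list[float] = field(default_factory=list)
    spine_amplitudes: list[float] = field(default_factory=list)
    spine_widths_um: list[float] = field(default_factory=list)
    # microglia
    n_processes: int | None = None
    process_positions_um: list[float] = field(default_factory=list)
    soma_span_um: tuple[float, float] | None = None
    soma_span_idx: tuple[int, int] | None = None
    soma_diameter_um: float | None = None
    # staining field
    true_area_fraction: float | None = None

    @property
    def n_spines(self) -> int:
        return len(self.spine_positions_um)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        d = json.loads(text)
        for key in ("soma_span_um", "soma_span_idx"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _apply_acquisition(
    clean: np.ndarray, acq: AcquisitionParams, rng: np.random.Generator,
    noise: bool, blur: bool = True,
) -> np.ndarray:
    """PSF blur, z-replication with defocus, camera noise, quantization."""
    sigma_px = acq.psf_sigma / acq.pixel_size
    planes = []
    mid = (acq.n_z - 1) / 2.0
    background = float(clean.min())
    signal = clean - background
    for k in range(acq.n_z):
        defocus = abs(k - mid)
        plane = background + signal * (0.6 ** defocus)
        if blur and sigma_px > 0:
            s = sigma_px * (1.0 + 0.8 * defocus)
            plane = background + ndimage.gaussian_filter(plane - background, s)
        planes.append(plane)
    stack = np.stack(planes, axis=0)
    if noise:
        photons = rng.poisson(np.maximum(stack, 0.0) * acq.photon_scale)
        stack = photons / acq.photon_scale
        if acq.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, acq.read_noise_sd, size=stack.shape)
    vmax = 2 ** acq.bit_depth - 1
    return np.clip(np.round(stack), 0, vmax).astype(np.uint16 if acq.bit_depth == 16 else np.uint8)


def _gaussian_attenuation(sigma_um: float, psf_um: float) -> float:
    """Peak attenuation of an isotropic 2D Gaussian under Gaussian blur."""
    s2 = sigma_um**2
    return s2 / (s2 + psf_um**2)


def _ridge_profile_value(amp: float, sigma_um: float, psf_um: float, offset_um: float) -> float:
    """Blurred cross-section value of a Gaussian ridge at a lateral offset."""
    sb = math.sqrt(sigma_um**2 + psf_um**2)
    return amp * (sigma_um / sb) * math.exp(-(offset_um**2) / (2.0 * sb**2))


def _draw_spaced_positions(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_gap: float
) -> np.ndarray:
    """n sorted positions in [lo, hi], pairwise gaps >= min_gap, uniform."""
    if n == 0:
        return np.array([])
    slack = (hi - lo) - (n - 1) * min_gap
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + np.arange(n) * min_gap


def generate_dendrite_image(
    spec: DendriteSpec,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    noise: bool = True,
) -> tuple[np.ndarray, SyntheticGroundTruth, LineROI]:
    """Render a dendrite segment with laterally attached spines.

    The returned ROI runs along the line of spine-head centers (offset
    shaft_width/2 + neck from the dendrite axis) for the full dendrite
    length — the "spine protrusions and a section of the adjacent dendrite"
    an analyst traces — then hooks away perpendicular into the background so
    the profile's low percentile reflects the true image background.
    """
    acq = acq or default_dendrite_acquisition()
    rng = np.random.default_rng(seed)
    px = acq.pixel_size

    sigma_shaft = spec.shaft_width / _FWHM
    sigma_spine = spec.spine_width_mean / _FWHM
    offset = spec.shaft_width / 2.0 + SPINE_NECK_UM  # spine row from axis, μm

    margin_um = 1.5
    width_um = spec.length + 2 * margin_um
    spur_um = BACKGROUND_SPUR_UM
    top_um = spur_um + 1.0  # space above the spine row
    bottom_um = 3.0  # space below the shaft
    h = int(round((top_um + offset + bottom_um) / px))
    w = int(round(width_um / px))
    y_row = top_um / px  # spine row, px
    y_shaft = (top_um + offset) / px
    x0 = margin_um / px
    x1 = x0 + spec.length / px

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    clean = np.full((h, w), spec.background_intensity)

    # dendritic shaft: Gaussian ridge along x over [x0, x1]
    shaft_amp = spec.shaft_intensity - spec.background_intensity
    # soft ends (0.3 μm roll-off) to avoid ringing hard edges through the PSF.
    # The shaft extends 1 μm beyond the ROI at both ends so the normalization
    # segment sees a uniform dendrite, not the dimmed end taper.
    roll = 0.3 / px
    ext = 1.0 / px
    endcap = np.minimum(
        np.clip((xx - (x0 - ext)) / roll, 0, 1), np.clip((x1 + ext - xx) / roll, 0, 1)
    )
    clean += shaft_amp * np.exp(-((yy - y_shaft) ** 2) / (2 * (sigma_shaft / px) ** 2)) * endcap

    # spine count and placement
    if spec.poisson_count:
        n_spines = int(rng.poisson(spec.spine_density_true * spec.length))
    else:
        n_spines = int(np.round(spec.spine_density_true * spec.length))
    # spines start 1 μm past the normalization segment so their blurred tails
    # cannot contaminate the adjacent-dendrite reference
    lo = DENDRITE_SEGMENT_UM + 1.0
    hi = spec.length - SPINE_EDGE_MARGIN_UM
    if n_spines > 0 and (n_spines - 1) * spec.min_spine_spacing > (hi - lo):
        raise ValueError("spine placement infeasible for requested density/spacing")
    positions = _draw_spaced_positions(rng, n_spines, lo, hi, spec.min_spine_spacing)
    amplitudes = np.maximum(
        rng.normal(spec.spine_size_mean, spec.spine_size_sd, size=n_spines), 0.05
    )

    # reference level the analyst will normalize to: blurred shaft flank at
    # the spine row, averaged across the ROI sampling width (the convex flank
    # averages high, the bump crest averages low).  Spine peaks are
    # compensated for both PSF attenuation and this sampling-width averaging
    # so the noiseless normalized apex is 1 + amplitude.
    width_offsets = (np.arange(3) - 1) * px  # matches the emitted ROI width
    ref_level = float(np.mean([
        _ridge_profile_value(shaft_amp, sigma_shaft, acq.psf_sigma, offset + k)
        for k in width_offsets
    ]))
    sigma_eff2 = sigma_spine**2 + acq.psf_sigma**2
    bump_att = _gaussian_attenuation(sigma_spine, acq.psf_sigma) * float(
        np.mean(np.exp(-(width_offsets**2) / (2.0 * sigma_eff2)))
    )
    for pos, amp in zip(positions, amplitudes):
        peak = amp * ref_level / bump_att
        xc = x0 + pos / px
        clean += peak * np.exp(
            -(((yy - y_row) ** 2) + ((xx - xc) ** 2)) / (2 * (sigma_spine / px) ** 2)
        )

    stack = _apply_acquisition(clean, acq, rng, noise=noise)

    # ROI: along the spine row over the dendrite, then a background spur up
    roi = LineROI(
        vertices=((y_row, x0), (y_row, x1), (y_row - spur_um / px, x1)),
        sampling_width=3,
        dendrite_segment=(0, int(round(DENDRITE_SEGMENT_UM / (SAMPLING_STEP_PX * px)))),
        dendrite_length_um=spec.length,
    )
    gt = SyntheticGroundTruth(
        kind="dendrite",
        pixel_size=px,
        dendrite_length_um=spec.length,
        spine_positions_um=[float(p) for p in positions],
        spine_amplitudes=[float(a) for a in amplitudes],
        spine_widths_um=[spec.spine_width_mean] * n_spines,
    )
    return stack, gt, roi


def _process_slots(spec: MicrogliaSpec) -> list[float]:
    """Candidate process crossing offsets (μm from soma center, signed)."""
    gap = max(2.5 * spec.process_width, 2.0)
    # processes start beyond the delineated soma span (which covers the
    # soma's blurred shoulder, ~1.4x its radius)
    inner = 1.4 * spec.soma_diameter / 2.0 + 1.5
    outer = spec.field_size / 2.0 - 3.0
    slots: list[float] = []
    d = inner
    while d <= outer:
        slots.append(d)
        slots.append(-d)
        d += gap
    return slots


def generate_microglia_image(
    spec: MicrogliaSpec,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    noise: bool = True,
) -> tuple[np.ndarray, SyntheticGroundTruth, LineROI]:
    """Render a microglial cell: bright soma plus ramified processes.

    The measurement line runs through the soma's longest dimension and across
    a cross-section of the process arbor; each process is rendered as a
    narrow elongated arm crossing that line exactly once, so the noiseless
    profile shows one supra-background bump per process outside the soma.
    """
    acq = acq or default_microglia_acquisition()
    rng = np.random.default_rng(seed)
    px = acq.pixel_size

    side = int(round(spec.field_size / px))
    cy = cx = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    clean = np.full((side, side), spec.background_intensity)

    # soma: flat-topped ellipse (super-Gaussian), long axis along the ROI
    a = spec.soma_diameter / 2.0 / px
    b = 0.7 * a
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    clean += (spec.soma_intensity - spec.background_intensity) * np.exp(-(r2**2))

    # processes: anisotropic Gaussian arms crossing the row at chosen offsets
    slots = _process_slots(spec)
    order = rng.permutation(len(slots))
    chosen = sorted(slots[i] for i in order[: spec.n_processes_true])
    jitter = rng.uniform(-0.4, 0.4, size=len(chosen))
    sigma_w = spec.process_width / _FWHM / px
    amp = spec.process_intensity - spec.background_intensity
    positions_um: list[float] = []
    for off, j in zip(chosen, jitter):
        x_cross = cx + (off + j) / px
        sigma_l = spec.process_length_mean / _FWHM / px
        clean += amp * np.exp(
            -((xx - x_cross) ** 2) / (2 * sigma_w**2)
            - ((yy - cy) ** 2) / (2 * sigma_l**2)
        )
        positions_um.append(x_cross * px)

    stack = _apply_acquisition(clean, acq, rng, noise=noise)

    roi_margin = 1.0 / px
    roi = LineROI(
        vertices=((cy, roi_margin), (cy, side - 1 - roi_margin)),
        sampling_width=3,
    )
    # soma span along the profile: the soma's flat top plus its blurred
    # shoulder, so nothing of the cell body leaks into process detection
    pad = 1.4 * spec.soma_diameter / 2.0 + 2.0 * acq.psf_sigma
    span_lo_um = (cx - roi_margin) * px - pad
    span_hi_um = (cx - roi_margin) * px + pad
    step_um = SAMPLING_STEP_PX * px
    span_idx = (int(span_lo_um / step_um), int(math.ceil(span_hi_um / step_um)) + 1)
    gt = SyntheticGroundTruth(
        kind="microglia",
        pixel_size=px,
        n_processes=spec.n_processes_true,
        process_positions_um=[p - roi_margin * px for p in positions_um],
        soma_span_um=(span_lo_um, span_hi_um),
        soma_span_idx=span_idx,
        soma_diameter_um=spec.soma_diameter,
    )
    return stack, gt, roi


def generate_area_field(
    true_fraction: float,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    noise: bool = True,
    shape: tuple[int, int] = (200, 200),
    foreground: float = 100.0,
    background: float = 10.0,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Diffuse staining field with an exactly known positive-area fraction.

    A smooth random field is thresholded at the order statistic that marks
    exactly ``round(true_fraction * H * W)`` pixels positive before noise, so
    percent-area quantification has a hard oracle.  No PSF is applied: the
    positive-pixel count is the ground truth and blur would redistribute it.
    """
    if not (0.0 <= true_fraction <= 1.0):
        raise ValueError("true_fraction must lie in [0, 1]")
    acq = acq or AcquisitionParams(pixel_size=0.5, psf_sigma=0.0, photon_scale=20.0,
                                   read_noise_sd=1.0, n_z=1)
    rng = np.random.default_rng(seed)
    h, w = shape
    n_pos = int(round(true_fraction * h * w))
    field = ndimage.gaussian_filter(rng.normal(size=(h, w)), 5.0)
    order = np.argsort(field, axis=None, kind="stable")
    mask = np.zeros(h * w, dtype=bool)
    if n_pos:
        mask[order[h * w - n_pos:]] = True
    mask = mask.reshape(h, w)
    clean = np.where(mask, foreground, background).astype(float)
    img = _apply_acquisition(clean, acq, rng, noise=noise, blur=False)[0]
    gt = SyntheticGroundTruth(kind="area", pixel_size=acq.pixel_size,
                              true_area_fraction=true_fraction)
    return img, gt


# ---------------------------------------------------------------------------
# per-condition sampling used by the pipeline and the recovery protocol
# ---------------------------------------------------------------------------

def condition_dendrite_spec(
    genotype: str, treatment: str, rng: np.random.Generator,
    base: DendriteSpec | None = None,
) -> DendriteSpec:
    """Draw one dendrite spec for a study condition.

    Traced segment lengths vary from cell to cell; lengths are drawn uniform
    ±5 μm around the base length, which also decorrelates the rounding of the
    deterministic spine count from the density estimate.
    """
    base = base or DendriteSpec()
    preset = condition_preset(genotype, treatment)
    length = float(rng.uniform(base.length - 5.0, base.length + 5.0))
    return apply_preset_to_dendrite(replace(base, length=length), preset)


def condition_microglia_spec(
    genotype: str, treatment: str, rng: np.random.Generator,
    base: MicrogliaSpec | None = None,
) -> MicrogliaSpec:
    """Draw one microglia spec for a study condition (soma-size jitter ±10%)."""
    base = base or MicrogliaSpec()
    preset = condition_preset(genotype, treatment)
    spec = apply_preset_to_microglia(base, preset)
    return replace(spec, soma_diameter=spec.soma_diameter * float(rng.uniform(0.9, 1.1)))
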