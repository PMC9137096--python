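"""Synthetic 3D-culture scenes and their rendering into multi-channel z-stacks.

A :class:`Scene` holds ground-truth spherical objects (microspheres or
organoids) suspended in a virtual gel dome, typically ~1100 µm deep.  The
module models the phenomena the downstream pipeline has to cope with:

* defocus blur that grows with axial distance from the focal plane,
* saturating dose x time staining kinetics of a live-cell dye
  (Calcein-AM-like, green channel) with a dead-cell counterstain
  (PI-like, red channel),
* nonspecific green gel background that accumulates with staining time and
  is quenched by Cu2+,
* post-treatment morphology: a shrunken live core surrounded by a loose
  shell of scattered dead cells.

Everything is seeded and bit-reproducible, so detection, fusion and assay
analytics can be validated against exact ground truth without a microscope.

Units: lengths in µm, time in min, concentrations in µM (dye) or mM (Cu2+),
intensities in arbitrary units with in-focus object contrast ~1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .acquisition import AcquisitionPlan
from .errors import InvalidParameterError
from .stacks import ImageStack

__all__ = [
    "SceneObject",
    "Scene",
    "OpticalModel",
    "StainingModel",
    "TreatmentEffect",
    "generate_scene",
    "apply_staining",
    "apply_treatment",
    "render_stack",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("brightfield", "green", "red")

#: in-focus contrast of an object footprint in the brightfield channel
_BRIGHTFIELD_AMPLITUDE = 1.0
#: peak green intensity of a fully live, labeled object
_GREEN_AMPLITUDE = 1.0
#: red intensity of dead material (dead objects and dead-cell shells)
_RED_AMPLITUDE = 0.8


@dataclass
class SceneObject:
    """One spherical object (microsphere or organoid) in the gel.

    ``diameter`` is the diameter of the live core; ``shell_width`` is the
    radial extent of the loose dead-cell annulus that surrounds survivors
    after treatment (0 for untreated objects).
    """

    id: int
    center: tuple[float, float, float]  # (x, y, z) µm, z=0 at gel bottom
    diameter: float
    live_fraction: float = 1.0
    labeled: bool = False
    green_intensity: float = 0.0
    red_intensity: float = 0.0
    shell_width: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError(f"diameter must be > 0, got {self.diameter}")
        if not 0.0 <= self.live_fraction <= 1.0:
            raise InvalidParameterError(
                f"live_fraction must be in [0, 1], got {self.live_fraction}"
            )
        if self.green_intensity < 0 or self.red_intensity < 0:
            raise InvalidParameterError("intensities must be >= 0")
        if not self.labeled and self.green_intensity != 0:
            raise InvalidParameterError("unlabeled objects must have green_intensity 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def outer_radius(self) -> float:
        """Radius of the full footprint including any dead-cell shell."""
        return self.radius + self.shell_width


@dataclass
class Scene:
    """Ground-truth objects in a gel volume of known geometry."""

    objects: list[SceneObject]
    gel_depth: float  # µm
    xy_extent: tuple[float, float]  # (width, height) µm
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.xy_extent
        if self.gel_depth <= 0 or w <= 0 or h <= 0:
            raise InvalidParameterError("scene dimensions must be positive")
        for obj in self.objects:
            x, y, z = obj.center
            if not (0 <= x <= w and 0 <= y <= h and 0 <= z <= self.gel_depth):
                raise InvalidParameterError(
                    f"object {obj.id} center {obj.center} outside the gel volume"
                )

    @property
    def volume_ul(self) -> float:
        """Gel volume in µL (1 µL = 1e9 µm^3)."""
        return self.xy_extent[0] * self.xy_extent[1] * self.gel_depth / 1e9

    @property
    def density(self) -> float:
        """Objects per µL."""
        return len(self.objects) / self.volume_ul

    @property
    def n_objects(self) -> int:
        return len(self.objects)


@dataclass(frozen=True)
class OpticalModel:
    """Abstraction of the microscope's axial response.

    ``blur_coeff`` converts axial distance from a focal plane into the sigma
    of a Gaussian defocus kernel.  ``dof_half_depth`` is the detectability
    half-depth: an object whose *surface* is farther than this from every
    focal plane leaves no usable footprint in any layer.  It is the single
    knob that links the rendered stacks to the closed-form capture model.
    """

    pixel_size: float = 1.0  # µm per pixel
    blur_coeff: float = 0.05  # px of Gaussian sigma per µm of defocus
    dof_half_depth: float = 80.0  # µm
    noise_sd: float = 0.01  # additive Gaussian read noise, intensity units
    background_base: float = 0.05  # gel autofluorescence floor, green channel

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.dof_half_depth) <= 0:
            raise InvalidParameterError("pixel_size and dof_half_depth must be > 0")
        if min(self.blur_coeff, self.noise_sd, self.background_base) < 0:
            raise InvalidParameterError("optical parameters must be >= 0")


@dataclass(frozen=True)
class StainingModel:
    """Saturating dose x time staining kinetics with Cu2+ background quench.

    An object with live cells is labeled with probability
    ``p = min(1, concentration * time / saturation_constant)``; the default
    ``saturation_constant`` of 120 µM·min puts full labeling exactly at the
    standard working point of 2 µM for 60 min.

    Nonspecific gel background in the green channel grows linearly with
    staining time and is suppressed multiplicatively by Cu2+:
    ``B(t) = B0 + background_rate * t * max(0, 1 - cu / quench_reference)``,
    so 0.1 mM Cu2+ (the reference) quenches the time-dependent part fully.
    """

    concentration: float = 2.0  # µM
    time: float = 60.0  # min
    saturation_constant: float = 120.0  # µM·min
    cu_concentration: float = 0.0  # mM
    background_rate: float = 0.003  # intensity units per min
    quench_reference: float = 0.1  # mM

    def __post_init__(self) -> None:
        if min(self.concentration, self.time, self.saturation_constant,
               self.background_rate) < 0:
            raise InvalidParameterError("staining parameters must be >= 0")
        if self.cu_concentration < 0 or self.quench_reference <= 0:
            raise InvalidParameterError("Cu2+ concentrations must be valid")

    @property
    def labeling_probability(self) -> float:
        if self.saturation_constant == 0:
            return 1.0
        return min(1.0, self.concentration * self.time / self.saturation_constant)

    def background_level(self, background_base: float) -> float:
        quench = max(0.0, 1.0 - self.cu_concentration / self.quench_reference)
        return background_base + self.background_rate * self.time * quench


@dataclass(frozen=True)
class TreatmentEffect:
    """Effect of a drug or irradiation dose on a well of organoids.

    ``kill_fraction`` of objects die outright (red, no live core); survivors
    keep a live core shrunk by ``shrink_factor`` surrounded by a loose
    dead-cell shell ``dead_shell_width`` µm wide.
    """

    kill_fraction: float = 0.6
    shrink_factor: float = 0.7
    dead_shell_width: float = 10.0  # µm

    def __post_init__(self) -> None:
        if not 0.0 <= self.kill_fraction <= 1.0:
            raise InvalidParameterError("kill_fraction must be in [0, 1]")
        if not 0.0 < self.shrink_factor <= 1.0:
            raise InvalidParameterError("shrink_factor must be in (0, 1]")
        if self.dead_shell_width < 0:
            raise InvalidParameterError("dead_shell_width must be >= 0")


def _draw_diameters(diameter_spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve a diameter specification into per-object diameters.

    Accepts a scalar (monodisperse), a ``(low, high)`` pair (uniform), or an
    explicit sequence of length ``n``.
    """
    if np.isscalar(diameter_spec):
        d = np.full(n, float(diameter_spec))
    elif len(diameter_spec) == 2 and np.isscalar(diameter_spec[0]):
        lo, hi = float(diameter_spec[0]), float(diameter_spec[1])
        if not 0 < lo <= hi:
            raise InvalidParameterError(f"bad diameter range ({lo}, {hi})")
        d = rng.uniform(lo, hi, size=n)
    else:
        d = np.asarray(diameter_spec, dtype=float)
        if d.shape != (n,):
            raise InvalidParameterError("diameter sequence length must equal n_objects")
    if n and d.min() <= 0:
        raise InvalidParameterError("diameters must be > 0")
    return d


def generate_scene(
    n_objects: int,
    diameter_spec,
    gel_depth: float = 1100.0,
    xy_extent: tuple[float, float] = (512.0, 512.0),
    seed: int = 0,
    xy_margin: float = 0.0,
) -> Scene:
    """Plant ``n_objects`` spheres uniformly at random in a gel volume.

    ``xy_margin`` keeps centers away from the lateral field edges so that
    footprints are not clipped; axial placement always spans the full gel
    depth, as objects settle throughout the dome.
    """
    if n_objects < 0:
        raise InvalidParameterError(f"n_objects must be >= 0, got {n_objects}")
    if gel_depth <= 0 or min(xy_extent) <= 0:
        raise InvalidParameterError("gel_depth and xy_extent must be positive")
    w, h = float(xy_extent[0]), float(xy_extent[1])
    if 2 * xy_margin >= min(w, h):
        raise InvalidParameterError("xy_margin leaves no room for objects")

    rng = np.random.default_rng(seed)
    xs = rng.uniform(xy_margin, w - xy_margin, size=n_objects)
    ys = rng.uniform(xy_margin, h - xy_margin, size=n_objects)
    zs = rng.uniform(0.0, gel_depth, size=n_objects)
    diameters = _draw_diameters(diameter_spec, n_objects, rng)

    objects = [
        SceneObject(id=i, center=(float(xs[i]), float(ys[i]), float(zs[i])),
                    diameter=float(diameters[i]))
        for i in range(n_objects)
    ]
    return Scene(objects=objects, gel_depth=float(gel_depth), xy_extent=(w, h),
                 seed=seed)


def apply_staining(scene: Scene, staining: StainingModel, seed: int = 0) -> Scene:
    """Label live objects with probability ``min(1, c*t/K)``.

    Labeled objects acquire a green intensity proportional to their live
    fraction; dead objects are never labeled by the live-cell dye.  Returns
    a new scene; the input is untouched.
    """
    p = staining.labeling_probability
    rng = np.random.default_rng(seed)
    draws = rng.random(len(scene.objects))
    new_objects = []
    for obj, u in zip(scene.objects, draws):
        if obj.live_fraction > 0 and u < p:
            new_objects.append(replace(
                obj, labeled=True,
                green_intensity=_GREEN_AMPLITUDE * obj.live_fraction))
        else:
            new_objects.append(replace(obj, labeled=False, green_intensity=0.0))
    return replace(scene, objects=new_objects)


def apply_treatment(scene: Scene, effect: TreatmentEffect, seed: int = 0) -> Scene:
    """Kill a random fraction of objects and shrink/shell the survivors.

    Killed objects keep their size but become fully dead (red, unlabeled).
    Survivors' live cores shrink by ``shrink_factor`` and gain a red
    dead-cell shell of ``dead_shell_width``.  Staining state is reset — the
    well is stained after treatment, not before.
    """
    rng = np.random.default_rng(seed)
    draws = rng.random(len(scene.objects))
    is_identity = (effect.kill_fraction == 0 and effect.shrink_factor == 1.0
                   and effect.dead_shell_width == 0)
    if is_identity:
        return replace(scene, objects=list(scene.objects))
    new_objects = []
    for obj, u in zip(scene.objects, draws):
        if u < effect.kill_fraction:
            new_objects.append(replace(
                obj, live_fraction=0.0, labeled=False, green_intensity=0.0,
                red_intensity=_RED_AMPLITUDE, shell_width=0.0))
        else:
            new_objects.append(replace(
                obj,
                diameter=obj.diameter * effect.shrink_factor,
                shell_width=effect.dead_shell_width,
                red_intensity=_RED_AMPLITUDE if effect.dead_shell_width > 0
                else obj.red_intensity,
                labeled=False, green_intensity=0.0))
    return replace(scene, objects=new_objects)


def _add_disk(img: np.ndarray, cx: float, cy: float, r_out: float,
              sigma: float, amplitude: float, r_in: float = 0.0) -> None:
    """Accumulate an (optionally annular) anti-aliased disk, blurred in place.

    Coordinates and radii in pixels; works on a local patch for speed.
    """
    if amplitude <= 0 or r_out <= 0:
        return
    pad = int(np.ceil(r_out + 4.0 * sigma + 2))
    x0 = int(np.floor(cx)) - pad
    x1 = int(np.ceil(cx)) + pad + 1
    y0 = int(np.floor(cy)) - pad
    y1 = int(np.ceil(cy)) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, img.shape[1])
    y0c, y1c = max(y0, 0), min(y1, img.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    yy = np.arange(y0, y1, dtype=np.float64) + 0.5 - cy
    xx = np.arange(x0, x1, dtype=np.float64) + 0.5 - cx
    dist = np.hypot(yy[:, None], xx[None, :])
    # sub-pixel coverage: linear ramp one pixel wide at the rim
    patch = np.clip(r_out + 0.5 - dist, 0.0, 1.0)
    if r_in > 0:
        patch -= np.clip(r_in + 0.5 - dist, 0.0, 1.0)
    if sigma > 0.05:
        patch = ndi.gaussian_filter(patch, sigma, mode="constant")
    img[y0c:y1c, x0c:x1c] += amplitude * patch[y0c - y0:y1c - y0, x0c - x0:x1c - x0]


def render_stack(
    scene: Scene,
    plan: AcquisitionPlan,
    optics: OpticalModel = OpticalModel(),
    channels: Sequence[str] = DEFAULT_CHANNELS,
    staining: StainingModel | None = None,
    seed: int = 0,
) -> ImageStack:
    """Render a scene into a multi-layer, multi-channel image stack.

    Per layer, each object is drawn as the disk of its projected silhouette
    (the equatorial, maximum cross-section), blurred with a Gaussian of
    sigma ``blur_coeff * |z_obj - z_layer|``.
    Objects whose surface lies beyond ``dof_half_depth`` of a plane
    contribute nothing to that plane — the hard detectability envelope that
    the closed-form capture model integrates over.

    The staining model (if given) sets the time/Cu2+-dependent gel
    background added to the green channel; Gaussian read noise is added to
    every channel.  Deterministic for a fixed seed.
    """
    if len(channels) == 0:
        raise InvalidParameterError("channel set must be non-empty")
    channels = list(channels)
    positions = np.asarray(plan.layer_positions, dtype=float)
    if positions.min() < 0 or positions.max() > scene.gel_depth:
        warnings.warn(
            "acquisition planes extend outside the gel depth; objects are "
            "rendered wherever the detectability envelope permits",
            stacklevel=2,
        )

    px = optics.pixel_size
    ny = int(round(scene.xy_extent[1] / px))
    nx = int(round(scene.xy_extent[0] / px))
    pixels = np.zeros((len(positions), len(channels), ny, nx), dtype=np.float64)

    ich = {name: i for i, name in enumerate(channels)}
    for il, z_layer in enumerate(positions):
        for obj in scene.objects:
            x, y, z = obj.center
            dz = abs(z - z_layer)
            defocus = max(0.0, dz - obj.radius)
            if defocus > optics.dof_half_depth:
                continue
            sigma = optics.blur_coeff * dz
            # projected silhouette: a sphere at small defocus still images as
            # its full equatorial disk, which is what EDF measurement targets
            r_core = obj.radius
            r_core_px = r_core / px
            r_outer_px = (r_core + obj.shell_width) / px
            cx, cy = x / px, y / px
            if "brightfield" in ich:
                _add_disk(pixels[il, ich["brightfield"]], cx, cy, r_outer_px,
                          sigma, _BRIGHTFIELD_AMPLITUDE)
            if "green" in ich and obj.labeled and obj.green_intensity > 0:
                _add_disk(pixels[il, ich["green"]], cx, cy, r_core_px,
                          sigma, obj.green_intensity)
            if "red" in ich and obj.red_intensity > 0:
                if obj.shell_width > 0 and obj.live_fraction > 0:
                    _add_disk(pixels[il, ich["red"]], cx, cy, r_outer_px,
                              sigma, obj.red_intensity, r_in=r_core_px)
                elif obj.live_fraction == 0:
                    _add_disk(pixels[il, ich["red"]], cx, cy, r_core_px,
                              sigma, obj.red_intensity)

    if "green" in ich:
        if staining is not None:
            bg = staining.background_level(optics.background_base)
        else:
            bg = optics.background_base
        pixels[:, ich["green"]] += bg

    if optics.noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels += rng.normal(0.0, optics.noise_sd, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)

    return ImageStack(
        pixels=pixels.astype(np.float32),
        pixel_size=px,
        layer_positions=positions,
        channel_names=channels,
    )
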