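"""Image-stack containers and TIFF input/output.

An :class:`ImageStack` is the in-memory form of one z-stacked field of view:
a ``(layer, channel, row, col)`` array plus physical calibration (µm pixel
size and the focal-plane positions).  Stacks round-trip losslessly through
two on-disk dialects:

* plain multi-page TIFF in layer-major page order with a JSON sidecar
  (``<path>.json``) holding ``pixel_size_um``, ``layer_positions_um`` and
  ``channels``;
* OME-TIFF (``ome=True``) with the same calibration embedded in the OME-XML
  header, readable by any OME-compliant tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError, MissingMetadataError

__all__ = ["ImageStack", "CompositeImage", "read_stack", "write_stack"]

_SIDECAR_FIELDS = ("pixel_size_um", "layer_positions_um", "channels")


@dataclass
class ImageStack:
    """Multi-layer, multi-channel image with physical calibration."""

    pixels: np.ndarray  # (layer, channel, row, col)
    pixel_size: float  # µm/px
    layer_positions: np.ndarray  # µm, strictly increasing
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.layer_positions = np.asarray(self.layer_positions, dtype=float)
        if self.pixels.ndim != 4:
            raise InvalidParameterError("pixels must be a (L, C, Y, X) array")
        n_layers, n_channels = self.pixels.shape[:2]
        if len(self.layer_positions) != n_layers:
            raise InvalidParameterError("layer_positions length != number of layers")
        if len(self.channel_names) != n_channels:
            raise InvalidParameterError("channel_names length != number of channels")
        if n_layers > 1 and not np.all(np.diff(self.layer_positions) > 0):
            raise InvalidParameterError("layer_positions must be strictly increasing")
        if self.pixels.size and self.pixels.min() < 0:
            raise InvalidParameterError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def n_layers(self) -> int:
        return self.pixels.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"channel {name!r} not in stack (has {self.channel_names})"
            ) from None


@dataclass
class CompositeImage:
    """All-in-focus composite: fused channels plus the winning-layer map."""

    pixels: np.ndarray  # (channel, row, col)
    index_map: np.ndarray  # (row, col) layer indices
    pixel_size: float
    channel_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.index_map = np.asarray(self.index_map)
        if self.pixels.ndim != 3:
            raise InvalidParameterError("composite pixels must be (C, Y, X)")
        if self.index_map.shape != self.pixels.shape[1:]:
            raise InvalidParameterError("index_map shape must match image shape")

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"channel {name!r} not in composite (has {self.channel_names})"
            ) from None
        return self.pixels[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: ImageStack, path, ome: bool = False) -> Path:
    """Write a stack to TIFF; returns the written path.

    Plain TIFF gets a JSON sidecar with the calibration; OME-TIFF embeds it
    in the OME-XML header instead.
    """
    path = Path(path)
    data = stack.pixels
    if ome:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "ZCYX",
                "PhysicalSizeX": stack.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size,
                "PhysicalSizeYUnit": "µm",
                "Channel": {"Name": list(stack.channel_names)},
                "Plane": {
                    "PositionZ": [
                        float(z)
                        for z in stack.layer_positions
                        for _ in stack.channel_names
                    ],
                    "PositionZUnit": ["µm"]
                    * (stack.n_layers * len(stack.channel_names)),
                },
            },
        )
    else:
        # layer-major page order: layer 0 / all channels, layer 1 / ...
        tifffile.imwrite(path, data.reshape(-1, *data.shape[2:]))
        sidecar = {
            "pixel_size_um": stack.pixel_size,
            "layer_positions_um": [float(z) for z in stack.layer_positions],
            "channels": list(stack.channel_names),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_ome(tif: tifffile.TiffFile) -> ImageStack:
    import xml.etree.ElementTree as ET

    series = tif.series[0]
    data = series.asarray()
    axes = series.axes
    if set(axes) - set("ZCYX"):
        raise MissingMetadataError(f"unsupported OME axes {axes!r}")
    # normalise to ZCYX
    order = [axes.index(a) for a in "ZCYX" if a in axes]
    data = np.transpose(data, order)
    while data.ndim < 4:
        data = data[np.newaxis]
    root = ET.fromstring(tif.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px_el = root.find(".//ome:Pixels", ns)
    if px_el is None or px_el.get("PhysicalSizeX") is None:
        raise MissingMetadataError("OME header lacks PhysicalSizeX")
    pixel_size = float(px_el.get("PhysicalSizeX"))
    channels = [
        c.get("Name") or f"ch{i}"
        for i, c in enumerate(px_el.findall("ome:Channel", ns))
    ]
    z_positions: dict[int, float] = {}
    for plane in px_el.findall("ome:Plane", ns):
        if plane.get("PositionZ") is not None:
            z_positions[int(plane.get("TheZ", "0"))] = float(plane.get("PositionZ"))
    if len(z_positions) == data.shape[0]:
        layer_positions = np.array([z_positions[i] for i in range(data.shape[0])])
    else:
        layer_positions = np.arange(data.shape[0], dtype=float)
    return ImageStack(
        pixels=data,
        pixel_size=pixel_size,
        layer_positions=layer_positions,
        channel_names=channels or [f"ch{i}" for i in range(data.shape[1])],
    )


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (plain+sidecar or OME)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if tif.is_ome and tif.ome_metadata:
            return _read_ome(tif)
        data = tif.asarray()
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingMetadataError(
            f"{path} is a plain TIFF without calibration; provide a sidecar "
            f"{sidecar.name} with fields {_SIDECAR_FIELDS}"
        )
    meta = json.loads(sidecar.read_text())
    missing = [f for f in _SIDECAR_FIELDS if f not in meta]
    if missing:
        raise MissingMetadataError(f"sidecar {sidecar} missing fields {missing}")
    channels = meta["channels"]
    positions = np.asarray(meta["layer_positions_um"], dtype=float)
    n_layers = len(positions)
    if data.ndim == 3:
        data = data.reshape(n_layers, len(channels), *data.shape[1:])
    return ImageStack(
        pixels=data,
        pixel_size=float(meta["pixel_size_um"]),
        layer_positions=positions,
        channel_names=list(channels),
    )
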