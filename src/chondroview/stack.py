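"""Multi-channel Z-stack container and TIFF + sidecar-JSON I/O.

A :class:`MicrographStack` holds a ``(planes, channels, height, width)``
intensity array together with channel semantics (``live``/``dead`` for the
viability assay, ``expression``/``nuclei`` for immunofluorescence) and the
physical pixel size in micrometres per pixel.

On disk a stack is a multi-page TIFF with one page per (plane, channel)
pair, plane-major (plane 0 channel 0, plane 0 channel 1, plane 1 channel 0,
...), plus a sidecar JSON next to it carrying ``channel_names``,
``pixel_size_um`` and ``n_planes`` — TIFF alone cannot carry the channel
semantics portably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class ChannelError(KeyError):
    """Requested channel is not present in the stack."""


@dataclass
class MicrographStack:
    """An in-memory confocal stack.

    Parameters
    ----------
    data
        Float or integer array of shape ``(planes, channels, height, width)``.
    channel_names
        One name per channel, e.g. ``("live", "dead")``.
    pixel_size
        Physical pixel size in μm/pixel; must be positive.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4-D (planes, channels, h, w), got shape {self.data.shape}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelError(
                f"no channel {name!r}; available channels: {list(self.channel_names)}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """All planes of one channel, shape ``(planes, height, width)``."""
        return self.data[:, self.channel_index(name)]

    def pixel_area_um2(self) -> float:
        return float(self.pixel_size) ** 2


def write_stack(stack: MicrographStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus ``<path>.json`` sidecar."""
    path = Path(path)
    p, c, h, w = stack.data.shape
    pages = stack.data.reshape(p * c, h, w)
    data = pages.astype(np.float32) if pages.dtype.kind == "f" else pages
    tifffile.imwrite(path, data)
    sidecar = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size),
        "n_planes": int(p),
        "page_order": "plane-major",
    }
    sidecar.update(stack.meta)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_stack(path: str | Path) -> MicrographStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}; channel names and pixel size are required"
        )
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_planes = int(meta["n_planes"])
    names = tuple(meta["channel_names"])
    n_channels = len(names)
    data = pages.reshape(n_planes, n_channels, *pages.shape[-2:])
    extra = {k: v for k, v in meta.items()
             if k not in ("channel_names", "pixel_size_um", "n_planes", "page_order")}
    return MicrographStack(data, names, float(meta["pixel_size_um"]), meta=extra)
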