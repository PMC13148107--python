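"""In-memory container for multichannel microscopy stacks.

An :class:`ImageStack` is a named mapping of channels (each a 2-D ``(Y, X)``
image or 3-D ``(Z, Y, X)`` stack) plus the physical pixel size. It round-trips
through a multi-page TIFF with a JSON sidecar carrying the metadata that TIFF
tags do not reliably preserve (channel names, pixel size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from ._util import write_json


@dataclass
class ImageStack:
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ImageStack needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"channels differ in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim not in (2, 3):
                raise ValidationError(f"channel {name!r} must be 2-D or 3-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"channel {name!r} has non-finite or negative pixels")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_zstack(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    def write(self, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        names = list(self.channels)
        data = np.stack([self.channels[n] for n in names]).astype(np.float32)
        tiff_path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(tiff_path, data, photometric="minisblack")
        if sidecar_path is None:
            sidecar_path = tiff_path.with_suffix(".json")
        write_json(
            {
                "pixel_size_um": self.pixel_size_um,
                "channels": names,
                "axes": "CZYX" if self.is_zstack else "CYX",
                "bit_depth": self.bit_depth,
            },
            sidecar_path,
        )

    @classmethod
    def read(cls, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> "ImageStack":
        tiff_path = Path(tiff_path)
        if sidecar_path is None:
            sidecar_path = tiff_path.with_suffix(".json")
        meta = json.loads(Path(sidecar_path).read_text())
        data = tifffile.imread(tiff_path)
        names = meta["channels"]
        if data.shape[0] != len(names):
            raise ValidationError(
                f"TIFF has {data.shape[0]} pages but sidecar names {len(names)} channels"
            )
        return cls(
            channels={n: np.asarray(data[i]) for i, n in enumerate(names)},
            pixel_size_um=float(meta["pixel_size_um"]),
            bit_depth=int(meta.get("bit_depth", 8)),
        )
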