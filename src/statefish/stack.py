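"""Multi-bit image stack container and TIFF round trip.

A codestack holds one field of view of a combinatorial FISH experiment:
an intensity array of shape (y, x, bit, z) where each "bit" is one
hybridization-round x color image and z indexes optical sections (raw) or
pseudo-sections (after preprocessing).  Bit index = 3 * (hybridization - 1)
+ color, 0-based, which fixes the TIFF page ordering contract: pages are
written z-major, then bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["CodeStack"]


@dataclass
class CodeStack:
    """One field of view of multi-bit FISH imaging.

    intensities : float32 array (y, x, bit, z), non-negative
    pixel_size  : um per pixel in x/y
    z_step      : um per z index
    bead_channel: optional (y, x, z) fiducial-bead image shared by all bits
    processed   : whether preprocessing (pseudo-z projection, filtering,
                  percentile normalization) has been applied
    """

    intensities: np.ndarray
    pixel_size: float = 0.103
    z_step: float = 0.4
    bead_channel: np.ndarray | None = None
    processed: bool = False

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float32)
        if arr.ndim != 4:
            raise ValueError("intensities must be a 4-D (y, x, bit, z) array")
        self.intensities = arr

    @property
    def n_bits(self) -> int:
        return self.intensities.shape[2]

    @property
    def n_z(self) -> int:
        return self.intensities.shape[3]

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    # ---- TIFF + JSON manifest round trip --------------------------------
    def to_tiff(self, path) -> None:
        """Write pages z-major then bit, with a JSON sidecar manifest."""
        path = Path(path)
        ny, nx, nb, nz = self.intensities.shape
        pages = np.moveaxis(self.intensities, (3, 2), (0, 1)).reshape(nz * nb, ny, nx)
        tifffile.imwrite(path, pages, photometric='minisblack')
        manifest = {
            "pixel_size_um": self.pixel_size,
            "z_step_um": self.z_step,
            "n_bits": nb,
            "n_z": nz,
            "page_order": "z-major then bit",
            "bit_order": "bit = 3*(hyb-1) + color, 0-based",
            "processed": self.processed,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
        if self.bead_channel is not None:
            bead = np.moveaxis(np.asarray(self.bead_channel, dtype=np.float32), 2, 0)
            tifffile.imwrite(path.with_name(path.stem + "_beads.tif"), bead, photometric='minisblack')

    @classmethod
    def from_tiff(cls, path) -> "CodeStack":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        pages = tifffile.imread(path)
        nb, nz = manifest["n_bits"], manifest["n_z"]
        ny, nx = pages.shape[-2:]
        arr = np.moveaxis(pages.reshape(nz, nb, ny, nx), (0, 1), (3, 2))
        bead_path = path.with_name(path.stem + "_beads.tif")
        bead = None
        if bead_path.exists():
            bead = np.moveaxis(tifffile.imread(bead_path), 0, 2)
        return cls(
            intensities=np.ascontiguousarray(arr),
            pixel_size=manifest["pixel_size_um"],
            z_step=manifest["z_step_um"],
            bead_channel=bead,
            processed=manifest.get("processed", False),
        )
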