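"""Synthetic codestacks: diffraction-limited spots painted into barcode bits.

Each true RNA spot paints a 2-D Gaussian (the point-spread function) into
every ON bit of its gene's barcode, with each bit independently retained
with probability ``per_bit_detection`` — the simulated analog of a readout
failure ("dropout").  Gaussian background noise is added everywhere and
fiducial beads are painted identically in all bits at known coordinates.
Optics are deliberately simple: no photobleaching, no aberration, and at
most a single rigid translation per bit (used by registration tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import Codebook
from .stack import CodeStack

__all__ = ["generate_codestack", "simulate_bead_field", "random_spots"]


def random_spots(
    codebook: Codebook,
    n_spots: int,
    shape: tuple[int, int],
    n_z: int,
    seed: int,
    margin: int = 6,
) -> pd.DataFrame:
    """Uniformly placed true spots assigned to random gene (never blank)
    barcodes.  Coordinates are float pixels/slices within the margins."""
    rng = np.random.default_rng(seed)
    genes = rng.choice(codebook.gene_names, size=n_spots)
    ny, nx = shape
    return pd.DataFrame(
        {
            "gene": genes,
            "x": rng.uniform(margin, nx - margin, n_spots),
            "y": rng.uniform(margin, ny - margin, n_spots),
            "z": rng.integers(0, n_z, n_spots).astype(float),
        }
    )


def _paint_gaussian(img: np.ndarray, y: float, x: float, amplitude: float, sigma: float, radius: int = 5):
    ny, nx = img.shape
    yi, xi = int(round(y)), int(round(x))
    y0, y1 = max(yi - radius, 0), min(yi + radius + 1, ny)
    x0, x1 = max(xi - radius, 0), min(xi + radius + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
    )


def generate_codestack(
    true_spots: pd.DataFrame,
    codebook: Codebook,
    per_bit_detection: float = 1.0,
    background_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_z: int = 3,
    amplitude: float = 1000.0,
    psf_sigma: float = 1.0,
    n_beads: int = 0,
    pixel_size: float = 0.103,
    z_step: float = 0.4,
) -> tuple[CodeStack, pd.DataFrame]:
    """Paint true spots into a raw codestack and return it with the truth.

    Returns (stack, truth) where truth extends ``true_spots`` with the
    per-spot number of retained bits (``bits_detected``).  Spots assigned
    to blank barcodes are rejected — blank calls must only ever arise from
    noise.  The truth list length always equals the number of painted
    spots (every requested spot is painted, possibly with zero bits).
    """
    if not (0.0 < per_bit_detection <= 1.0):
        raise ValueError("per_bit_detection must be in (0, 1]")
    if background_sd < 0:
        raise ValueError("background_sd must be non-negative")
    ny, nx = shape
    spots = true_spots.reset_index(drop=True)
    name_to_idx = {n: i for i, n in enumerate(codebook.names)}
    roles = codebook.role_array()
    for g in pd.unique(spots["gene"]) if len(spots) else []:
        if g not in name_to_idx:
            raise ValueError(f"unknown gene {g!r}")
        if roles[name_to_idx[g]] == "blank":
            raise ValueError(
                f"spot assigned to blank codeword {g!r}; blanks must arise only from noise"
            )
    if len(spots):
        if ((spots["x"] < 0) | (spots["x"] > nx - 1) | (spots["y"] < 0) | (spots["y"] > ny - 1)).any():
            raise ValueError("spot coordinates outside stack bounds")
        if ((spots["z"] < 0) | (spots["z"] > n_z - 1)).any():
            raise ValueError("spot z outside stack bounds")

    rng = np.random.default_rng(seed)
    stack = np.zeros((ny, nx, codebook.n_bits, n_z), dtype=np.float32)
    bits_detected = np.zeros(len(spots), dtype=int)

    barcodes = codebook.barcodes
    for i, row in enumerate(spots.itertuples(index=False)):
        on_bits = np.flatnonzero(barcodes[name_to_idx[row.gene]])
        keep = rng.random(len(on_bits)) < per_bit_detection
        bits_detected[i] = int(keep.sum())
        zi = int(round(row.z))
        for bit in on_bits[keep]:
            _paint_gaussian(stack[:, :, bit, zi], row.y, row.x, amplitude, psf_sigma)

    bead_channel = None
    if n_beads > 0:
        bead_channel = np.zeros((ny, nx, n_z), dtype=np.float32)
        by = rng.uniform(5, ny - 5, n_beads)
        bx = rng.uniform(5, nx - 5, n_beads)
        bz = rng.integers(0, n_z, n_beads)
        for y, x, z in zip(by, bx, bz):
            _paint_gaussian(bead_channel[:, :, int(z)], y, x, amplitude, psf_sigma)
        # beads appear identically in every bit (and in their own channel)
        stack += bead_channel[:, :, None, :]

    if background_sd > 0:
        stack += rng.normal(0.0, background_sd, stack.shape).astype(np.float32)
        np.clip(stack, 0.0, None, out=stack)

    truth = spots.copy()
    truth["bits_detected"] = bits_detected
    code_stack = CodeStack(
        intensities=stack,
        pixel_size=pixel_size,
        z_step=z_step,
        bead_channel=bead_channel,
    )
    return code_stack, truth


def simulate_bead_field(
    n_beads: int,
    shape: tuple[int, int, int] = (128, 128, 9),
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spurious_fraction: float = 0.0,
    sigma: float = 1.2,
    z_sigma: float = 1.0,
    amplitude: float = 1000.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A 3-D fiducial bead image and its true bead coordinates.

    ``shift`` (dy, dx, dz) rigidly translates every true bead; a
    ``spurious_fraction`` of additional beads is placed at unrelated random
    positions (false detections for robustness tests).  Returns
    (image (y, x, z), true shifted coordinates (n, 3) as (y, x, z)).
    """
    rng = np.random.default_rng(seed)
    ny, nx, nz = shape
    margin = 8
    coords = np.column_stack(
        [
            rng.uniform(margin, ny - margin, n_beads),
            rng.uniform(margin, nx - margin, n_beads),
            rng.uniform(2.0, nz - 3.0, n_beads),
        ]
    )
    shifted = coords + np.asarray(shift)[None, :]
    n_spur = int(round(spurious_fraction * n_beads))
    spur = np.column_stack(
        [
            rng.uniform(margin, ny - margin, n_spur),
            rng.uniform(margin, nx - margin, n_spur),
            rng.uniform(2.0, nz - 3.0, n_spur),
        ]
    )
    img = np.zeros(shape, dtype=np.float32)
    zz = np.arange(nz)
    for y, x, z in np.vstack([shifted, spur]):
        zprof = np.exp(-0.5 * ((zz - z) / z_sigma) ** 2)
        for zi in range(max(0, int(z) - 3), min(nz, int(z) + 4)):
            _paint_gaussian(img[:, :, zi], y, x, amplitude * zprof[zi], sigma)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return img, shifted
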