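"""Fiducial-bead registration between hybridization rounds.

Every imaging round contains the same field of fiducial beads; a rigid 3-D
translation per bit is estimated from them.  Bead candidates are peaks of
the normalized cross-correlation between the image and a Gaussian bead
template, refined to subpixel precision on a locally upsampled grid.  The
matching step is deliberately robust to false detections: all candidate
pair displacements within the maximum plausible shift are density
clustered, and only pairs from the largest cluster enter the least-squares
translation fit.  Fits whose residuals exceed 0.5 px laterally or 1.2 um
axially are marked rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from sklearn.cluster import DBSCAN

__all__ = ["Registration", "detect_beads", "estimate_translation", "register_stack"]

#: acceptance rule for a registered field of view
MAX_RESIDUAL_XY = 0.5  # px
MAX_RESIDUAL_Z = 1.2  # um


@dataclass(frozen=True)
class Registration:
    """A fitted per-bit rigid translation.

    translation : (dy, dx, dz) in pixels / z frames (moving -> reference
                  displacement; subtract it from moving coordinates)
    residual_xy : RMS lateral residual of matched bead pairs, px
    residual_z  : RMS axial residual, um
    n_beads     : bead pairs in the consensus cluster
    accepted    : residual_xy <= 0.5 px and residual_z <= 1.2 um
    """

    translation: tuple[float, float, float]
    residual_xy: float
    residual_z: float
    n_beads: int
    accepted: bool


def _gaussian_template(sigma: float, z_sigma: float) -> np.ndarray:
    r = max(int(np.ceil(3 * sigma)), 2)
    rz = max(int(np.ceil(3 * z_sigma)), 1)
    yy, xx, zz = np.mgrid[-r : r + 1, -r : r + 1, -rz : rz + 1]
    return np.exp(-(yy**2 + xx**2) / (2 * sigma**2) - zz**2 / (2 * z_sigma**2))


def detect_beads(
    image: np.ndarray,
    template_sigma: float = 1.2,
    z_sigma: float = 1.0,
    upsample: int = 5,
    corr_threshold: float = 0.5,
    min_distance: int = 3,
) -> np.ndarray:
    """Subpixel bead coordinates from a 3-D (y, x, z) image.

    Peaks of the normalized cross-correlation against a Gaussian template
    are refined by cubic interpolation of the correlation surface on an
    ``upsample``-times finer local grid.

    Returns an (n, 3) array of (y, x, z) coordinates.
    """
    img = np.asarray(image, dtype=np.float64)
    template = _gaussian_template(template_sigma, z_sigma)
    corr = match_template(img, template, pad_input=True)
    peaks = peak_local_max(
        corr, min_distance=min_distance, threshold_abs=corr_threshold, exclude_border=2
    )
    coords = []
    shape = np.array(corr.shape)
    for pk in peaks:
        # cubic upsampling of the local correlation surface followed by a
        # parabolic (quadratic) fit around its maximum: localization well
        # below the 1/upsample grid step
        lo = pk - 2
        hi = pk + 3
        if (lo < 0).any() or (hi > shape).any():
            coords.append(pk.astype(float))
            continue
        patch = corr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        fine = ndimage.zoom(patch, upsample, order=3, mode="nearest", grid_mode=True)
        sub = np.array(np.unravel_index(np.argmax(fine), fine.shape), dtype=float)
        for ax in range(3):
            i = int(sub[ax])
            if 0 < i < fine.shape[ax] - 1:
                sel = [int(s) for s in sub]
                sel_lo, sel_hi = list(sel), list(sel)
                sel_lo[ax] -= 1
                sel_hi[ax] += 1
                c0, c1, c2 = fine[tuple(sel_lo)], fine[tuple(sel)], fine[tuple(sel_hi)]
                denom = c0 - 2 * c1 + c2
                if denom != 0:
                    sub[ax] += 0.5 * (c0 - c2) / denom
        # grid_mode zoom convention: fine sample i sits at (i + 0.5)/u - 0.5
        coords.append(lo + (sub + 0.5) / upsample - 0.5)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def estimate_translation(
    ref_beads: np.ndarray,
    mov_beads: np.ndarray,
    max_shift: float = 100.0,
    cluster_eps: float = 1.0,
    min_cluster_size: int = 3,
    z_step: float = 0.4,
) -> Registration:
    """Robust 3-D translation from two candidate bead sets.

    All displacement vectors between reference and moving beads lying
    within ``max_shift`` (lateral, px) are density clustered (DBSCAN,
    ``cluster_eps`` px); the largest cluster is taken as the consensus
    matching and its least-squares translation (the mean displacement) is
    returned with RMS residuals.
    """
    ref = np.asarray(ref_beads, dtype=float).reshape(-1, 3)
    mov = np.asarray(mov_beads, dtype=float).reshape(-1, 3)
    if len(ref) < min_cluster_size or len(mov) < min_cluster_size:
        raise ValueError(
            f"too few bead candidates ({len(ref)} reference, {len(mov)} moving)"
        )
    disp = mov[None, :, :] - ref[:, None, :]  # (n_ref, n_mov, 3)
    lateral = np.linalg.norm(disp[:, :, :2], axis=2)
    keep = lateral <= max_shift
    if not keep.any():
        raise ValueError("no bead pairs within the maximum shift")
    vectors = disp[keep]

    labels = DBSCAN(eps=cluster_eps, min_samples=min_cluster_size).fit_predict(vectors)
    valid = labels >= 0
    if not valid.any():
        raise ValueError("displacement clustering found no consensus cluster")
    counts = np.bincount(labels[valid])
    members = vectors[labels == np.argmax(counts)]

    translation = members.mean(axis=0)
    resid = members - translation
    residual_xy = float(np.sqrt((resid[:, :2] ** 2).sum(axis=1).mean()))
    residual_z = float(np.sqrt((resid[:, 2] ** 2).mean())) * z_step
    accepted = residual_xy <= MAX_RESIDUAL_XY and residual_z <= MAX_RESIDUAL_Z
    return Registration(
        translation=tuple(float(v) for v in translation),
        residual_xy=residual_xy,
        residual_z=residual_z,
        n_beads=int(members.shape[0]),
        accepted=accepted,
    )


def register_stack(
    bead_images: list[np.ndarray],
    reference_index: int = 0,
    template_sigma: float = 1.2,
    upsample: int = 5,
    max_shift: float = 100.0,
    z_step: float = 0.4,
) -> list[Registration]:
    """Register each bit's bead image to the reference bit."""
    ref_beads = detect_beads(bead_images[reference_index], template_sigma, upsample=upsample)
    out = []
    for i, img in enumerate(bead_images):
        if i == reference_index:
            out.append(
                Registration((0.0, 0.0, 0.0), 0.0, 0.0, len(ref_beads), True)
            )
            continue
        mov_beads = detect_beads(img, template_sigma, upsample=upsample)
        out.append(
            estimate_translation(
                ref_beads, mov_beads, max_shift=max_shift, z_step=z_step
            )
        )
    return out
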