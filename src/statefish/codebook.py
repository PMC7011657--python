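"""Combinatorial barcode codebooks for multiplexed FISH decoding.

Genes are encoded as constant-weight binary barcodes read out over sequential
hybridization rounds.  A minimum pairwise Hamming distance of 4 between
barcodes allows any single dropped bit to be corrected: the weight-3 vector
left by a dropout is still uniquely closest to its parent codeword.  A subset
of codewords is deliberately left unassigned ("blanks"); calls landing on a
blank barcode estimate the decoder's false-positive rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "CodebookCapacityError",
    "build_codebook",
    "decoding_threshold",
    "pairwise_hamming",
]


class CodebookCapacityError(ValueError):
    """Raised when a code large enough for the request cannot be built.

    Attributes
    ----------
    achieved : int
        Size of the largest code found by the search.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


@dataclass(frozen=True)
class Codebook:
    """A constant-weight binary code with gene/blank assignments.

    Parameters
    ----------
    n_bits : int
        Barcode length (e.g. 24 = 8 hybridization rounds x 3 colors).
    weight : int
        Number of ON bits per barcode.
    min_hamming_distance : int
        Guaranteed minimum pairwise Hamming distance.
    names, roles, barcodes :
        Parallel sequences; ``roles[i]`` is ``"gene"`` or ``"blank"`` and
        ``barcodes`` is an ``(n_entries, n_bits)`` uint8 array.
    """

    n_bits: int
    weight: int
    min_hamming_distance: int
    names: tuple[str, ...]
    roles: tuple[str, ...]
    barcodes: np.ndarray = field(repr=False)

    def __post_init__(self):
        bc = np.asarray(self.barcodes, dtype=np.uint8)
        object.__setattr__(self, "barcodes", bc)
        if bc.ndim != 2 or bc.shape[1] != self.n_bits:
            raise ValueError("barcode matrix shape does not match n_bits")
        if len(self.names) != bc.shape[0] or len(self.roles) != bc.shape[0]:
            raise ValueError("names/roles/barcodes lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("barcode names must be unique")
        if not set(self.roles) <= {"gene", "blank"}:
            raise ValueError("roles must be 'gene' or 'blank'")
        if not np.all(bc.sum(axis=1) == self.weight):
            raise ValueError(f"every barcode must have exactly {self.weight} ON bits")
        if bc.shape[0] >= 2:
            dmin = pairwise_hamming(bc).min()
            if dmin < self.min_hamming_distance:
                raise ValueError(
                    f"pairwise Hamming distance {dmin} violates the declared "
                    f"minimum {self.min_hamming_distance}"
                )

    def __len__(self) -> int:
        return self.barcodes.shape[0]

    @property
    def gene_names(self) -> list[str]:
        return [n for n, r in zip(self.names, self.roles) if r == "gene"]

    @property
    def blank_names(self) -> list[str]:
        return [n for n, r in zip(self.names, self.roles) if r == "blank"]

    @property
    def n_blanks(self) -> int:
        return len(self.blank_names)

    def normalized_barcodes(self) -> np.ndarray:
        """Barcodes L2-normalized to unit vectors (float64).

        Every ON bit of a weight-w barcode maps to 1/sqrt(w); for w = 4 that
        is exactly 0.5.
        """
        bc = self.barcodes.astype(float)
        return bc / np.linalg.norm(bc, axis=1, keepdims=True)

    def role_array(self) -> np.ndarray:
        return np.asarray(self.roles)

    # ---- CSV round trip -------------------------------------------------
    def to_csv(self, path) -> None:
        strings = ["".join(map(str, row)) for row in self.barcodes]
        pd.DataFrame({"name": self.names, "role": self.roles, "barcode": strings}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        df = pd.read_csv(path, dtype={"barcode": str})
        bc = np.array([[int(c) for c in s] for s in df["barcode"]], dtype=np.uint8)
        n_bits = bc.shape[1]
        weight = int(bc[0].sum())
        dmin = int(pairwise_hamming(bc).min()) if bc.shape[0] >= 2 else n_bits
        return cls(
            n_bits=n_bits,
            weight=weight,
            min_hamming_distance=dmin,
            names=tuple(df["name"]),
            roles=tuple(df["role"]),
            barcodes=bc,
        )


def pairwise_hamming(barcodes: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise Hamming distances (exhaustive)."""
    bc = np.asarray(barcodes, dtype=np.int16)
    if bc.shape[0] < 2:
        return np.empty(0, dtype=int)
    diffs = (bc[:, None, :] != bc[None, :, :]).sum(axis=2)
    iu = np.triu_indices(bc.shape[0], k=1)
    return diffs[iu]


def _greedy_code(n_bits: int, weight: int, min_distance: int, order: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Greedy scan over candidate words, accepting those at distance
    >= min_distance from every previously accepted word."""
    accepted: list[np.ndarray] = []
    acc_mat = np.empty((0, n_bits), dtype=np.int16)
    for idx in order:
        cand = candidates[idx]
        if acc_mat.shape[0]:
            d = np.abs(acc_mat - cand).sum(axis=1)
            if d.min() < min_distance:
                continue
        accepted.append(cand)
        acc_mat = np.asarray(accepted, dtype=np.int16)
    return acc_mat.astype(np.uint8)


def build_codebook(
    n_bits: int,
    weight: int,
    min_distance: int,
    n_genes: int,
    n_blanks: int,
    seed: int = 0,
    n_restarts: int = 8,
    gene_names: Sequence[str] | None = None,
) -> Codebook:
    """Construct a constant-weight code and assign genes and blanks.

    The search is greedy: candidates (all weight-``weight`` vectors) are
    scanned in lexicographic order first, then in ``n_restarts - 1`` seeded
    shuffles, and a candidate is accepted iff its Hamming distance to every
    already-accepted word is at least ``min_distance``.  The largest code
    found across restarts is kept.  Codewords are then split into gene and
    blank assignments by a seeded random draw.

    Raises
    ------
    CodebookCapacityError
        If the achieved code is smaller than ``n_genes + n_blanks``; the
        achieved size is reported on the exception.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive; a distance-0 code is degenerate")
    if not (0 < weight < n_bits):
        raise ValueError("weight must satisfy 0 < weight < n_bits")
    if n_genes < 1 or n_blanks < 0:
        raise ValueError("need at least one gene and a non-negative blank count")

    candidates = np.array(
        list(itertools.combinations(range(n_bits), weight)), dtype=np.int64
    )
    cand_mat = np.zeros((candidates.shape[0], n_bits), dtype=np.int16)
    rows = np.repeat(np.arange(candidates.shape[0]), weight)
    cand_mat[rows, candidates.ravel()] = 1

    rng = np.random.default_rng(seed)
    n_requested = n_genes + n_blanks
    best = np.empty((0, n_bits), dtype=np.uint8)
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            order = np.arange(cand_mat.shape[0])
        else:
            order = rng.permutation(cand_mat.shape[0])
        code = _greedy_code(n_bits, weight, min_distance, order, cand_mat)
        if code.shape[0] > best.shape[0]:
            best = code
        if best.shape[0] >= n_requested:
            break

    achieved = best.shape[0]
    if achieved < n_requested:
        raise CodebookCapacityError(
            f"requested {n_requested} codewords ({n_genes} genes + {n_blanks} "
            f"blanks) but the {n_bits}-bit weight-{weight} MHD{min_distance} "
            f"search achieved only {achieved}",
            achieved=achieved,
        )

    chosen = rng.choice(achieved, size=n_requested, replace=False)
    gene_rows = np.sort(chosen[:n_genes])
    blank_rows = np.sort(chosen[n_genes:])
    if gene_names is None:
        gene_names = [f"gene_{i:03d}" for i in range(n_genes)]
    elif len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    names = list(gene_names) + [f"blank_{i:03d}" for i in range(n_blanks)]
    roles = ["gene"] * n_genes + ["blank"] * n_blanks
    barcodes = np.vstack([best[gene_rows], best[blank_rows]])
    return Codebook(
        n_bits=n_bits,
        weight=weight,
        min_hamming_distance=min_distance,
        names=tuple(names),
        roles=tuple(roles),
        barcodes=barcodes,
    )


def decoding_threshold(codebook: Codebook) -> float:
    """Pixel-classification distance threshold for a codebook.

    Each pixel's intensity vector is L2-normalized and compared to the
    L2-normalized barcodes, so classification happens on the unit sphere.
    The largest non-ambiguous assignment radius is half the minimum angular
    separation between any two normalized barcodes; this function returns the
    Euclidean chord length subtending that half-angle:

        threshold = 2 * sin(theta_min / 4),  cos(theta_min) = max dot product.

    For a weight-4 code at minimum Hamming distance 4 the closest pair of
    normalized barcodes has dot product 0.5 (theta_min = 60 deg), giving
    2*sin(15 deg) = 0.5176.  An ideal 1-bit dropout (three equal ON bits)
    lies exactly at this distance from its parent codeword, so the decoder
    treats the boundary as inclusive.
    """
    nb = codebook.normalized_barcodes()
    if nb.shape[0] < 2:
        raise ValueError("need at least two barcodes to derive a threshold")
    dots = nb @ nb.T
    np.fill_diagonal(dots, -np.inf)
    max_dot = float(dots.max())
    if max_dot >= 1.0 - 1e-12:
        raise ValueError("codebook contains duplicate barcodes (zero angular separation)")
    theta_min = np.arccos(np.clip(max_dot, -1.0, 1.0))
    return float(2.0 * np.sin(theta_min / 4.0))
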