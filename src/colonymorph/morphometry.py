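"""Translation/rotation-invariant colony fingerprints: size + Zernike moments.

Each segmented colony is represented by a 33-dimensional morphometric vector:
its size (log10 area in pixels) plus the magnitudes of 32 Zernike moments of
the colony's gradient-magnitude image.  Zernike moments project an image onto
the orthogonal polynomials V_nm(rho, theta) = R_nm(rho) * exp(i m theta) over
the unit disk (Teague's formulation):

    A_nm = (n + 1) / pi * sum_{rho <= 1} f(x, y) * conj(V_nm(rho, theta)) * dA

with n >= m >= 0 and n - m even.  The colony centroid is mapped to the disk
center and the minimal enclosing radius to rho = 1, which makes the
representation translation invariant; moment magnitudes are additionally
invariant to rotation.  Computing them on the gradient magnitude (rather than
raw intensity) makes the fingerprint invariant to contrast reversal and
shading, and normalizing by |A_00| bounds the features and removes overall
contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import center_of_mass
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import ColonyRegion

__all__ = [
    "ZernikeSpec",
    "MorphometricVector",
    "default_moment_indices",
    "zernike_moments",
    "colony_fingerprint",
    "ZernikeFingerprinter",
]


def default_moment_indices() -> tuple[tuple[int, int], ...]:
    """The default 32 (n, m) index pairs.

    All valid pairs with 2 <= n <= 9 (28 pairs, (n, m)-lexicographic) plus
    (10, 0), (10, 2), (10, 4), (10, 6); together with the size feature this
    yields the standard 33-dimensional fingerprint.  (0,0) and (1,1) are
    excluded as degenerate after normalization and centering.
    """
    pairs = [(n, m) for n in range(2, 10) for m in range(n % 2, n + 1, 2)]
    pairs += [(10, 0), (10, 2), (10, 4), (10, 6)]
    return tuple(pairs)


@dataclass(frozen=True)
class ZernikeSpec:
    """Which Zernike moments to compute and how to embed the colony."""

    moment_indices: tuple[tuple[int, int], ...] = default_moment_indices()

    def __post_init__(self) -> None:
        seen = set()
        for n, m in self.moment_indices:
            if not (n >= m >= 0):
                raise ValueError(f"invalid Zernike index (n={n}, m={m}): need n >= m >= 0")
            if (n - m) % 2 != 0:
                raise ValueError(f"invalid Zernike index (n={n}, m={m}): n - m must be even")
            if (n, m) in seen:
                raise ValueError(f"duplicate Zernike index (n={n}, m={m})")
            seen.add((n, m))

    @property
    def dimension(self) -> int:
        """Fingerprint dimension: size + one magnitude per index pair."""
        return 1 + len(self.moment_indices)


@lru_cache(maxsize=None)
def _radial_coeffs(n: int, m: int) -> tuple[tuple[int, float], ...]:
    """Coefficients of the radial polynomial R_nm as (power, coefficient)."""
    out = []
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out.append((n - 2 * s, float(c)))
    return tuple(out)


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for p, c in _radial_coeffs(n, m):
        out += c * rho ** p
    return out


def zernike_moments(
    patch: np.ndarray,
    mask: np.ndarray,
    spec: ZernikeSpec | None = None,
    indices: tuple[tuple[int, int], ...] | None = None,
) -> dict[tuple[int, int], complex]:
    """Zernike moments of ``patch`` over the disk enclosing ``mask``.

    The mask centroid maps to the disk center and the minimal enclosing
    radius to rho = 1; pixels outside the unit disk are ignored.
    """
    patch = np.asarray(patch, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask must have the same shape")
    if not mask.any():
        raise ValueError("empty mask: cannot compute Zernike moments")
    if indices is None:
        indices = (spec or ZernikeSpec()).moment_indices

    cy, cx = center_of_mass(mask)
    ys, xs = np.nonzero(mask)
    r_max = float(np.hypot(ys - cy, xs - cx).max())
    if r_max <= 0:
        raise ValueError("degenerate mask: zero enclosing radius")

    yy, xx = np.nonzero(np.ones_like(mask))
    dy = (yy - cy) / r_max
    dx = (xx - cx) / r_max
    rho = np.hypot(dy, dx)
    inside = rho <= 1.0
    rho = rho[inside]
    theta = np.arctan2(dy[inside], dx[inside])
    f = patch.ravel()[inside]
    dA = 1.0 / r_max ** 2

    out: dict[tuple[int, int], complex] = {}
    for n, m in indices:
        v_conj = _radial_poly(n, m, rho) * np.exp(-1j * m * theta)
        out[(n, m)] = complex((n + 1) / np.pi * np.sum(f * v_conj) * dA)
    return out


@dataclass(frozen=True)
class MorphometricVector:
    """Per-colony fingerprint: size plus normalized Zernike magnitudes."""

    colony_id: str
    line_id: str
    size: float                               # log10(area_px)
    magnitudes: np.ndarray                    # |A_nm| / |A_00|, per index pair
    moment_indices: tuple[tuple[int, int], ...]
    truncated: bool = False                   # region touched the image border

    @property
    def dimension(self) -> int:
        return 1 + len(self.magnitudes)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([[self.size], self.magnitudes])

    def feature_names(self) -> list[str]:
        return ["size"] + [f"z_{n}_{m}" for n, m in self.moment_indices]


def colony_fingerprint(
    region: ColonyRegion,
    image: np.ndarray,
    spec: ZernikeSpec | None = None,
    colony_id: str = "",
    line_id: str = "",
    pad: int = 2,
) -> MorphometricVector:
    """Fingerprint one segmented colony.

    The gradient magnitude (3x3 central differences) of the colony crop is
    computed, Zernike moments are taken over the minimal enclosing disk, and
    magnitudes are normalized by |A_00| of the gradient patch.  The size
    feature is log10 of the colony area in pixels.
    """
    spec = spec or ZernikeSpec()
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    r0, c0, r1, c1 = region.bbox
    pr0, pc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    pr1, pc1 = min(r1 + pad, H), min(c1 + pad, W)
    crop = image[pr0:pr1, pc0:pc1]
    mask = np.zeros(crop.shape, dtype=bool)
    mask[r0 - pr0:r0 - pr0 + region.mask.shape[0],
         c0 - pc0:c0 - pc0 + region.mask.shape[1]] = region.mask

    gy, gx = np.gradient(crop)
    gmag = np.hypot(gy, gx)

    wanted = ((0, 0),) + tuple(spec.moment_indices)
    moments = zernike_moments(gmag, mask, indices=wanted)
    a00 = abs(moments[(0, 0)])
    if a00 < 1e-12:
        mags = np.zeros(len(spec.moment_indices))
    else:
        mags = np.array([abs(moments[nm]) / a00 for nm in spec.moment_indices])
    return MorphometricVector(
        colony_id=colony_id, line_id=line_id,
        size=math.log10(max(region.area_px, 1)),
        magnitudes=mags, moment_indices=spec.moment_indices,
        truncated=region.touches_border)


class ZernikeFingerprinter(BaseEstimator, TransformerMixin):
    """Transformer from (image, regions) pairs to a fingerprint table.

    ``transform`` accepts an iterable of ``(line_id, image, regions)`` triples
    and returns a tidy DataFrame with one row per colony: colony_id, line_id,
    size, z_n_m..., truncated.
    """

    def __init__(self, moment_indices: tuple[tuple[int, int], ...] | None = None):
        self.moment_indices = moment_indices

    def _spec(self) -> ZernikeSpec:
        if self.moment_indices is None:
            return ZernikeSpec()
        return ZernikeSpec(moment_indices=tuple(self.moment_indices))

    def fit(self, X=None, y=None) -> "ZernikeFingerprinter":
        self.spec_ = self._spec()
        return self

    def transform(self, X) -> pd.DataFrame:
        spec = getattr(self, "spec_", None) or self._spec()
        rows = []
        for line_id, image, regions in X:
            for i, region in enumerate(regions):
                fp = colony_fingerprint(region, image, spec,
                                        colony_id=f"{line_id}_r{i:03d}",
                                        line_id=line_id)
                row = {"colony_id": fp.colony_id, "line_id": fp.line_id,
                       "size": fp.size, "truncated": fp.truncated}
                row.update(dict(zip([f"z_{n}_{m}" for n, m in fp.moment_indices],
                                    fp.magnitudes)))
                rows.append(row)
        return pd.DataFrame(rows)
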