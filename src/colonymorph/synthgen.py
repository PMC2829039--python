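"""Synthetic phase-contrast-like colony images and expression matrices with planted structure.

Colonies grown in 3D laminin-rich ECM culture fall into three broad
morphological archetypes when imaged by phase contrast: *round* (compact,
approximately convex acinus-like colonies), *grape-like* (clusters of loosely
adherent lobes) and *stellate* (invasive colonies with radiating processes).
This module emulates a study of ``n_lines`` cell lines, each assigned one
archetype, producing per-line image sets with ground-truth masks plus a
normalized log-scale expression matrix in which some genes are differentially
expressed in one archetype group and others are linearly or logistically tied
to colony size.

The colonies are deliberately *texture*-defined: the colony interior carries
band-limited oriented noise while the mean intensity offset between colony
and background is small compared to the texture swing, so that single-point
thresholding fails and segmentation must rely on the texture operator.
Polarity ("bright_on_dark" vs "dark_on_bright") is implemented as an exact
intensity negation about mid-gray, which flips the foreground/background
intensity ordering without changing the ground-truth mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from scipy.special import logit

ARCHETYPES = ("round", "grape_like", "stellate")
POLARITIES = ("bright_on_dark", "dark_on_bright")

__all__ = [
    "ARCHETYPES",
    "ArchetypeSpec",
    "SizeLinkedGene",
    "SyntheticStudySpec",
    "SyntheticStudy",
    "archetype_defaults",
    "generate_colony_image",
    "generate_study",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Geometry and texture of one colony archetype.

    Parameters
    ----------
    name : {"round", "grape_like", "stellate"}
    radius_px : float
        Mean colony radius in pixels.
    texture_amplitude : float
        Interior intensity modulation as a fraction of the dynamic range,
        in (0, 1].
    n_lobes : int
        Blob count (grape_like) or process count (stellate); ignored for
        round colonies. Must be >= 3 for non-round archetypes.
    polarity : {"bright_on_dark", "dark_on_bright"}
    jitter : float
        Per-colony shape noise scale (dimensionless).
    """

    name: str
    radius_px: float
    texture_amplitude: float = 0.5
    n_lobes: int = 0
    polarity: str = "bright_on_dark"
    jitter: float = 0.08

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}; expected one of {ARCHETYPES}")
        if not self.radius_px > 0:
            raise ValueError("radius_px must be > 0")
        if not (0.0 < self.texture_amplitude <= 1.0):
            raise ValueError("texture_amplitude must be in (0, 1]")
        if self.name != "round" and self.n_lobes < 3:
            raise ValueError("n_lobes must be >= 3 for non-round archetypes")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def archetype_defaults(name: str, polarity: str = "bright_on_dark") -> ArchetypeSpec:
    """Default archetype geometry used by the synthetic study.

    Radii differ across archetypes (stellate colonies are the largest, as
    aggressive lines produce the biggest structures), giving the colony-size
    feature real between-line variation.
    """
    if name == "round":
        return ArchetypeSpec("round", radius_px=32.0, texture_amplitude=0.5,
                             n_lobes=0, polarity=polarity, jitter=0.05)
    if name == "grape_like":
        return ArchetypeSpec("grape_like", radius_px=40.0, texture_amplitude=0.5,
                             n_lobes=5, polarity=polarity, jitter=0.08)
    if name == "stellate":
        return ArchetypeSpec("stellate", radius_px=48.0, texture_amplitude=0.5,
                             n_lobes=6, polarity=polarity, jitter=0.10)
    raise ValueError(f"unknown archetype {name!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _wrap_angle(t: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return (t + np.pi) % (2.0 * np.pi) - np.pi


def _colony_mask(spec: ArchetypeSpec, image_size: int, rng: np.random.Generator) -> np.ndarray:
    r0 = spec.radius_px
    c = image_size / 2.0
    # small center jitter keeps colonies off the exact grid center
    cy = c + rng.uniform(-0.05, 0.05) * r0
    cx = c + rng.uniform(-0.05, 0.05) * r0
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_cap = image_size / 2.0 - 3.0

    if spec.name == "round":
        # smoothed disk: low-order Fourier perturbation of the radius
        radius = np.full_like(theta, r0)
        for h in range(2, 6):
            amp = spec.jitter * r0 * rng.normal() / h
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius + amp * np.cos(h * theta + phase)
        radius = np.clip(radius, 0.6 * r0, min(1.3 * r0, r_cap))
        return rho <= radius

    if spec.name == "grape_like":
        # union of overlapping lobes on a ring plus a connecting core
        mask = rho <= 0.45 * r0
        ring = 0.55 * r0
        for i in range(spec.n_lobes):
            ang = 2 * np.pi * i / spec.n_lobes + rng.uniform(-0.5, 0.5) * spec.jitter * 2 * np.pi
            lr = 0.50 * r0 * (1.0 + spec.jitter * rng.normal())
            ly = cy + ring * np.sin(ang)
            lx = cx + ring * np.cos(ang)
            mask |= np.hypot(yy - ly, xx - lx) <= min(lr, r_cap - ring)
        return mask

    # stellate: disk with tapering radial processes
    radius = np.full_like(theta, 0.50 * r0)
    width = 0.35  # angular half-width of a process, radians
    for i in range(spec.n_lobes):
        ang = 2 * np.pi * i / spec.n_lobes + rng.uniform(-0.5, 0.5) * spec.jitter * 2 * np.pi
        amp = 0.70 * r0 * (1.0 + 0.3 * spec.jitter * rng.normal())
        d = np.abs(_wrap_angle(theta - ang)) / width
        bump = np.clip(1.0 - d, 0.0, None) ** 1.5
        radius = radius + amp * bump
    radius = np.clip(radius, 0.3 * r0, min(1.3 * r0, r_cap))
    return rho <= radius


def _oriented_texture(image_size: int, rng: np.random.Generator,
                      freq: float = 0.18, sigma: float = 2.5) -> np.ndarray:
    """Band-limited oriented noise, unit standard deviation."""
    noise = rng.standard_normal((image_size, image_size))
    phi = rng.uniform(0, np.pi)
    r = int(math.ceil(3 * sigma))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    xr = x * np.cos(phi) + y * np.sin(phi)
    yr = -x * np.sin(phi) + y * np.cos(phi)
    kern = np.exp(-(xr ** 2 + yr ** 2) / (2 * sigma ** 2)) * np.cos(2 * np.pi * freq * xr)
    kern -= kern.mean()
    tex = fftconvolve(noise, kern, mode="same")
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def generate_colony_image(
    spec: ArchetypeSpec,
    image_size: int = 224,
    seed=None,
    background_noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one colony image and its ground-truth mask.

    Returns
    -------
    image : (image_size, image_size) float64 in [0, 1]
    truth_mask : (image_size, image_size) bool
    """
    if image_size < 4 * spec.radius_px:
        raise ValueError(
            f"colony would exceed image bounds: image_size={image_size} "
            f"< 4 * radius_px={4 * spec.radius_px:g}"
        )
    rng = _as_rng(seed)
    mask = _colony_mask(spec, image_size, rng)

    # smooth background: mid-gray + low-frequency shading + pixel noise
    shading = gaussian_filter(rng.standard_normal((image_size, image_size)),
                              sigma=image_size / 3.0)
    sd = shading.std()
    if sd > 0:
        shading = shading / sd * 0.02
    image = 0.5 + shading + background_noise_sd * rng.standard_normal((image_size, image_size))

    # colony interior: small mean offset + dominant oriented texture
    amp = spec.texture_amplitude
    tex = _oriented_texture(image_size, rng)
    image = image + mask * (0.15 * amp + 0.35 * amp * tex)
    image = np.clip(image, 0.02, 0.98)

    if spec.polarity == "dark_on_bright":
        image = 1.0 - image
    return image, mask


@dataclass(frozen=True)
class SizeLinkedGene:
    """A planted gene tied to per-line median colony size."""

    gene_index: int
    slope: float
    intercept: float
    link: str  # "linear" | "logistic"

    def __post_init__(self) -> None:
        if self.link not in ("linear", "logistic"):
            raise ValueError("link must be 'linear' or 'logistic'")


def _default_size_linked(n_genes: int) -> tuple[SizeLinkedGene, ...]:
    linear = tuple(SizeLinkedGene(20 + i, slope=2.0 + 0.2 * i, intercept=7.0, link="linear")
                   for i in range(5))
    logistic = tuple(SizeLinkedGene(25 + i, slope=1.0 + 0.1 * i, intercept=7.0, link="logistic")
                     for i in range(5))
    return linear + logistic


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full design of a synthetic morphometry + expression study.

    Defaults emulate a 24-line panel split evenly over the three archetypes,
    a dozen colonies per line, RMA-like log2 expression around a baseline of
    ~7 with replicate noise sd 0.25, 20 genes shifted by ``de_effect`` in the
    stellate group and 10 genes tied to per-line median colony size (5 linear,
    5 logistic links).
    """

    n_lines: int = 24
    archetype_of_line: Mapping[str, ArchetypeSpec] | None = None
    colonies_per_line: int | Sequence[int] = 12
    image_size: int = 224
    background_noise_sd: float = 0.02
    n_genes: int = 1000
    de_gene_ids: tuple[int, ...] = tuple(range(20))
    de_effect: float = 2.0
    de_archetype: str = "stellate"
    size_linked_genes: tuple[SizeLinkedGene, ...] | None = None
    expr_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not np.isfinite(self.de_effect):
            raise ValueError("de_effect must be finite")
        if any(g < 0 or g >= self.n_genes for g in self.de_gene_ids):
            raise ValueError("every planted DE gene id must be < n_genes")
        for g in self.size_linked() :
            if not (0 <= g.gene_index < self.n_genes):
                raise ValueError("every planted size-linked gene id must be < n_genes")
        if self.de_archetype not in ARCHETYPES:
            raise ValueError(f"de_archetype must be one of {ARCHETYPES}")
        if self.expr_noise_sd < 0:
            raise ValueError("expr_noise_sd must be >= 0")

    def size_linked(self) -> tuple[SizeLinkedGene, ...]:
        if self.size_linked_genes is not None:
            return tuple(self.size_linked_genes)
        return _default_size_linked(self.n_genes)

    def line_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]

    def resolved_archetypes(self) -> dict[str, ArchetypeSpec]:
        """Line -> archetype map; default splits lines evenly over the three
        archetypes and alternates contrast polarity between lines."""
        lines = self.line_ids()
        if self.archetype_of_line is not None:
            out = dict(self.archetype_of_line)
            missing = set(lines) - set(out)
            if missing:
                raise ValueError(f"archetype_of_line missing lines: {sorted(missing)}")
            return {k: out[k] for k in lines}
        per = int(math.ceil(self.n_lines / 3))
        out = {}
        for i, line in enumerate(lines):
            name = ARCHETYPES[min(i // per, 2)]
            polarity = POLARITIES[i % 2]
            out[line] = archetype_defaults(name, polarity=polarity)
        return out

    def counts_per_line(self) -> dict[str, int]:
        lines = self.line_ids()
        if isinstance(self.colonies_per_line, int):
            return {ln: self.colonies_per_line for ln in lines}
        counts = list(self.colonies_per_line)
        if len(counts) != self.n_lines:
            raise ValueError("colonies_per_line sequence length must equal n_lines")
        return dict(zip(lines, counts))


@dataclass
class SyntheticStudy:
    """In-memory artifacts of one synthetic study (see :func:`generate_study`)."""

    spec: SyntheticStudySpec
    manifest: pd.DataFrame          # line_id, colony_id, image_path
    images: dict[str, np.ndarray]   # colony_id -> image
    masks: dict[str, np.ndarray]    # colony_id -> truth mask
    expression: pd.DataFrame        # genes x lines
    truth_lines: pd.DataFrame       # line_id, archetype, polarity, median_log10_size
    truth_genes: pd.DataFrame       # gene_id, role, effect/slope/intercept/link
    line_size: pd.Series            # per-line median log10 truth-mask area

    @property
    def line_ids(self) -> list[str]:
        return list(self.expression.columns)

    def archetype_labels(self) -> pd.Series:
        return self.truth_lines.set_index("line_id")["archetype"]

    def write(self, outdir: str | Path) -> Path:
        """Write the study to disk: 16-bit grayscale TIFF images, 0/255 PNG
        masks, manifest CSV, expression TSV and truth CSVs."""
        outdir = Path(outdir)
        img_dir = outdir / "images"
        mask_dir = outdir / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for _, row in manifest.iterrows():
            cid = row["colony_id"]
            img16 = np.round(self.images[cid] * 65535.0).astype(np.uint16)
            path = img_dir / f"{cid}.tif"
            tifffile.imwrite(path, img16)
            iio.imwrite(mask_dir / f"{cid}.png",
                        (self.masks[cid].astype(np.uint8) * 255))
            paths.append(str(path.relative_to(outdir)))
        manifest["image_path"] = paths
        manifest.to_csv(outdir / "manifest.csv", index=False)
        expr = self.expression.copy()
        expr.index.name = "gene_id"
        expr.to_csv(outdir / "expression.tsv", sep="\t")
        self.truth_lines.to_csv(outdir / "truth_lines.csv", index=False)
        self.truth_genes.to_csv(outdir / "truth_genes.csv", index=False)
        return outdir


def _expression_matrix(spec: SyntheticStudySpec, feat: np.ndarray,
                       groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Genes x lines matrix with planted DE and size-linked rows.

    ``feat`` is the per-line median log10 colony size; ``groups`` is a boolean
    vector marking lines of the DE archetype group.
    """
    G, L = spec.n_genes, spec.n_lines
    baseline = rng.normal(7.0, 1.0, size=G)
    X = baseline[:, None] + rng.normal(0.0, spec.expr_noise_sd, size=(G, L))
    for g in spec.de_gene_ids:
        X[g, groups] += spec.de_effect
    # size-linked rows are regenerated wholesale so the zero-noise case is exact
    for gene in spec.size_linked():
        noise = rng.normal(0.0, spec.expr_noise_sd, size=L)
        if gene.link == "linear":
            X[gene.gene_index] = gene.intercept + gene.slope * feat + noise
        else:
            lo, hi = feat.min(), feat.max()
            if hi > lo:
                y = 0.05 + 0.90 * (feat - lo) / (hi - lo)
            else:
                y = np.full_like(feat, 0.5)
            X[gene.gene_index] = gene.intercept + gene.slope * logit(y) + noise
    return X


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate the full synthetic study deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    arch = spec.resolved_archetypes()
    counts = spec.counts_per_line()
    lines = spec.line_ids()

    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    rows = []
    sizes: dict[str, list[float]] = {ln: [] for ln in lines}
    for ln in lines:
        base = arch[ln]
        line_factor = rng.uniform(0.85, 1.15)
        for j in range(counts[ln]):
            radius = base.radius_px * line_factor * (1.0 + 0.05 * rng.normal())
            radius = min(radius, (spec.image_size - 8) / 4.0)
            cspec = replace(base, radius_px=radius)
            img, mask = generate_colony_image(
                cspec, image_size=spec.image_size, seed=rng,
                background_noise_sd=spec.background_noise_sd)
            cid = f"{ln}_c{j:03d}"
            images[cid] = img
            masks[cid] = mask
            sizes[ln].append(math.log10(max(int(mask.sum()), 1)))
            rows.append({"line_id": ln, "colony_id": cid, "image_path": f"images/{cid}.tif"})

    manifest = pd.DataFrame(rows)
    feat = np.array([float(np.median(sizes[ln])) for ln in lines])
    groups = np.array([arch[ln].name == spec.de_archetype for ln in lines])
    X = _expression_matrix(spec, feat, groups, rng)
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    expression = pd.DataFrame(X, index=gene_ids, columns=lines)

    truth_lines = pd.DataFrame({
        "line_id": lines,
        "archetype": [arch[ln].name for ln in lines],
        "polarity": [arch[ln].polarity for ln in lines],
        "n_colonies": [counts[ln] for ln in lines],
        "median_log10_size": feat,
    })
    gene_rows = []
    for g in spec.de_gene_ids:
        gene_rows.append({"gene_id": gene_ids[g], "role": "de",
                          "effect": spec.de_effect, "slope": np.nan,
                          "intercept": np.nan, "link": ""})
    for gene in spec.size_linked():
        gene_rows.append({"gene_id": gene_ids[gene.gene_index], "role": "size_linked",
                          "effect": np.nan, "slope": gene.slope,
                          "intercept": gene.intercept, "link": gene.link})
    truth_genes = pd.DataFrame(gene_rows)

    return SyntheticStudy(
        spec=spec, manifest=manifest, images=images, masks=masks,
        expression=expression, truth_lines=truth_lines, truth_genes=truth_genes,
        line_size=pd.Series(feat, index=lines, name="median_log10_size"),
    )
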