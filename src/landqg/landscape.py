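"""Landscape composition and configuration metrics over categorical rasters.

Metrics are computed inside circular buffers: small buffers around each
sampling site (node level, default 500 m) and larger buffers around the
midpoint of a site pair (link level, 2/4/6 km).  A raster cell belongs to a
buffer when its *center* lies within the radius — a reproducible convention
that converges with resolution.

The landscape-quality index (LQ) follows a split-matrix-quality approach:
expert scores of each land-cover class for the pollinator and seed-disperser
guilds are combined by a centered PCA; the first component's class scores are
ranked and rescaled to weights on [1, 10], and LQ is the composition-weighted
mean of those weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

__all__ = [
    "LandscapeRaster",
    "BufferSpec",
    "LandCoverComposition",
    "ResistanceWeights",
    "ConnectivityResult",
    "buffer_composition",
    "habitat_percent",
    "shdi",
    "functional_connectivity",
    "lq_resistance_weights",
    "landscape_quality",
]

SQ_M_PER_HA = 10_000.0


@dataclass
class LandscapeRaster:
    """Categorical land-cover grid.

    ``origin`` is the (x, y) of the lower-left corner; row 0 of ``grid`` is
    the top row, matching the ESRI ASCII grid convention.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not self.legend:
            self.legend = {int(c): f"class_{int(c)}" for c in np.unique(self.grid)}
        else:
            codes = set(np.unique(self.grid).tolist())
            unknown = codes - set(self.legend)
            if unknown:
                raise ValueError(f"grid codes missing from legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell center (2-D arrays)."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def code_for(self, name_or_code) -> int:
        if isinstance(name_or_code, str):
            for code, name in self.legend.items():
                if name == name_or_code:
                    return code
            raise KeyError(f"unknown land-cover class {name_or_code!r}")
        code = int(name_or_code)
        if code not in self.legend:
            raise KeyError(f"unknown land-cover code {code}")
        return code


@dataclass(frozen=True)
class BufferSpec:
    """Circular analysis window: node (site) or link (pair midpoint) buffer."""

    center: tuple[float, float]
    radius: float
    level: str = "node"
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.level not in ("node", "link"):
            raise ValueError("level must be 'node' or 'link'")


@dataclass
class LandCoverComposition:
    """Per-class percentage cover within one buffer."""

    percentages: dict[int, float]
    total_cells: int
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.percentages and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")

    def proportion(self, code: int) -> float:
        return self.percentages.get(code, 0.0) / 100.0


@dataclass
class ResistanceWeights:
    """Per-class landscape-quality weight on [1, 10] from PC1 of the score matrix."""

    weights: dict[int, float]
    pc1_variance_fraction: float


@dataclass
class ConnectivityResult:
    """Functional connectivity: habitat area (ha) reachable through a buffer."""

    area_ha: float
    focal_on_habitat: bool = True
    n_patches: int = 0


def _buffer_mask(raster: LandscapeRaster, buf: BufferSpec) -> np.ndarray:
    xs, ys = raster.cell_centers()
    cx, cy = buf.center
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= buf.radius**2
    if not mask.any():
        raise ValueError("buffer does not intersect the raster")
    return mask


def buffer_composition(raster: LandscapeRaster, buf: BufferSpec) -> LandCoverComposition:
    """Percentage of each land-cover class among cells whose center falls in the buffer."""
    mask = _buffer_mask(raster, buf)
    values = raster.grid[mask]
    codes, counts = np.unique(values, return_counts=True)
    total = counts.sum()
    pct = {int(c): 100.0 * n / total for c, n in zip(codes, counts)}
    return LandCoverComposition(percentages=pct, total_cells=int(total), legend=dict(raster.legend))


def habitat_percent(comp: LandCoverComposition, habitat_class) -> float:
    """Percentage cover of the habitat class (savanna in the motivating system)."""
    if isinstance(habitat_class, str):
        matches = [c for c, n in comp.legend.items() if n == habitat_class]
        if not matches:
            raise KeyError(f"unknown land-cover class {habitat_class!r}")
        code = matches[0]
    else:
        code = int(habitat_class)
        if comp.legend and code not in comp.legend:
            raise KeyError(f"unknown land-cover code {code}")
    return comp.percentages.get(code, 0.0)


def shdi(comp: LandCoverComposition | np.ndarray) -> float:
    """Shannon diversity of land-cover composition, -sum(p_i ln p_i).

    Accepts either a :class:`LandCoverComposition` or a raw categorical array
    (the whole-raster case); both routes agree by construction.
    """
    if isinstance(comp, LandCoverComposition):
        p = np.array([v / 100.0 for v in comp.percentages.values()], dtype=float)
    else:
        arr = np.asarray(comp)
        _, counts = np.unique(arr, return_counts=True)
        p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _label_patches(raster: LandscapeRaster, habitat_code: int, connectivity: int = 8):
    structure = np.ones((3, 3)) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(raster.grid == habitat_code, structure=structure)
    return labels, n


def functional_connectivity(
    raster: LandscapeRaster,
    focal: BufferSpec,
    habitat_class,
    level: str | None = None,
    connectivity: int = 8,
) -> ConnectivityResult:
    """Summed habitat-patch area (ha) reachable within a buffer.

    Node level: area of the focal site's patch plus every habitat patch with
    at least one cell inside the buffer.  Link level: area of every habitat
    patch intersecting the buffer.  Patches are connected components of
    habitat cells (8-neighbor rule by default); areas are cell counts times
    cell area, in hectares.
    """
    level = level or focal.level
    code = raster.code_for(habitat_class)
    labels, _ = _label_patches(raster, code, connectivity)
    mask = _buffer_mask(raster, focal)
    in_buffer = np.unique(labels[mask & (labels > 0)])

    focal_on_habitat = True
    if level == "node":
        # focal patch = patch containing the buffer center cell
        xs, ys = raster.cell_centers()
        cx, cy = focal.center
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        r, c = np.unravel_index(np.argmin(d2), d2.shape)
        focal_label = labels[r, c]
        if focal_label == 0:
            focal_on_habitat = False
            if in_buffer.size == 0:
                warnings.warn("focal point off habitat and no habitat patch within buffer")
                return ConnectivityResult(0.0, focal_on_habitat=False, n_patches=0)
            warnings.warn("focal point not on habitat; using patches within buffer only")
            selected = in_buffer
        else:
            selected = np.unique(np.concatenate([[focal_label], in_buffer]))
    else:
        selected = in_buffer

    if selected.size == 0:
        return ConnectivityResult(0.0, focal_on_habitat=focal_on_habitat, n_patches=0)
    cells = int(np.isin(labels, selected).sum())
    area_ha = cells * raster.cell_size**2 / SQ_M_PER_HA
    return ConnectivityResult(area_ha, focal_on_habitat=focal_on_habitat, n_patches=int(selected.size))


def lq_resistance_weights(scores: pd.DataFrame, rank_rescale: bool = True) -> ResistanceWeights:
    """Per-class quality weights from PC1 of a class-by-species score matrix.

    A centered PCA is run on the matrix (rows = land-cover classes, columns =
    pollinator/disperser species).  PC1 class scores are ranked and linearly
    rescaled to [1, 10]; with ``rank_rescale=False`` the raw PC1 scores are
    min-max rescaled instead.  The PC1 sign is oriented so the class with the
    highest mean raw score gets the highest weight, making weights
    reproducible despite the sign ambiguity of PCA.
    """
    if scores.isna().any().any():
        raise ValueError("score matrix has missing entries")
    X = scores.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 classes and >= 2 species columns")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("score matrix has zero variance")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    var_frac = float(s[0] ** 2 / (s**2).sum())

    mean_quality = X.mean(axis=1)
    if np.corrcoef(pc1, mean_quality)[0, 1] < 0:
        pc1 = -pc1

    if rank_rescale:
        vals = rankdata(pc1, method="average")
    else:
        vals = pc1
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-15:
        rescaled = np.full_like(vals, 5.5, dtype=float)
    else:
        rescaled = 1.0 + 9.0 * (vals - lo) / (hi - lo)
    weights = {key: float(w) for key, w in zip(scores.index, rescaled)}
    return ResistanceWeights(weights=weights, pc1_variance_fraction=var_frac)


def landscape_quality(comp: LandCoverComposition, weights: ResistanceWeights) -> float:
    """Composition-weighted mean quality, LQ = sum_i (P_i / 100) * W_i, in [1, 10]."""
    lq = 0.0
    for code, pct in comp.percentages.items():
        if pct <= 0:
            continue
        key = code
        if key not in weights.weights:
            name = comp.legend.get(code)
            if name in weights.weights:
                key = name
            else:
                raise KeyError(f"no quality weight for present class {code} ({name})")
        lq += (pct / 100.0) * weights.weights[key]
    return lq
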