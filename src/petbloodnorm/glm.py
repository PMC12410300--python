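"""Voxelwise statistics across subjects and cluster-extent thresholding.

Implements the minimal statistical-parametric-mapping toolkit this
pipeline needs: a per-voxel simple regression against a subject-level
covariate (the biodistribution blood vector), a per-voxel pooled
two-sample t contrast, parametric t thresholds, and connected-component
cluster extraction with an extent criterion ("more than k voxels",
strict by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .volio import Volume, SubjectScan

#: scipy.ndimage binary structures for the three standard 3-D
#: neighbourhoods.  18-connectivity is the SPM convention.
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class TMap:
    """A voxelwise t-statistic map.

    ``t`` is 0 outside the analysis mask and at degenerate
    (zero-variance) voxels; the latter are flagged in ``degenerate`` so
    map geometry stays stable without propagating NaNs.
    """

    t: Volume
    dof: int
    contrast: str
    mask: Volume
    degenerate: np.ndarray = field(repr=False)
    slope: Volume | None = None

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise ValueError("degrees of freedom must be >= 1")
        inside = self.mask.values.astype(bool)
        if not np.all(np.isfinite(self.t.values[inside & ~self.degenerate])):
            # +/- inf is allowed (perfect fits in noise-free data); NaN is not
            if np.any(np.isnan(self.t.values[inside])):
                raise ValueError("NaN t value inside mask")


@dataclass
class ClusterVOI:
    """A connected suprathreshold component of a t-map."""

    voxel_indices: np.ndarray  # (n, 3) int array, 0-based
    size_voxels: int
    peak_t: float
    peak_index: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp)
        if self.size_voxels != len(self.voxel_indices):
            raise ValueError("size_voxels inconsistent with voxel_indices")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m


def _stack(scans: Sequence[SubjectScan | Volume], mask: np.ndarray) -> np.ndarray:
    """(n_subjects, n_masked_voxels) data matrix."""
    vols = [s.volume if isinstance(s, SubjectScan) else s for s in scans]
    first = vols[0]
    for v in vols[1:]:
        if not v.same_grid(first):
            raise ValueError("all volumes must share grid shape and spacing")
    return np.stack([v.values[mask] for v in vols], axis=0)


def regression_tmap(
    scans: Sequence[SubjectScan | Volume],
    covariate: Sequence[float],
    mask: Volume,
    contrast: str = "positive slope vs covariate",
) -> TMap:
    """Per-voxel OLS of voxel value on a subject-level covariate.

    t = slope / SE(slope) with dof = n - 2; positive t means uptake
    increases with the covariate.  Voxels fitting perfectly (zero
    residual, as in noise-free data) get t = +/-inf; zero-slope
    zero-residual voxels get t = 0 and are flagged degenerate.
    The fitted slope map is retained (``TMap.slope``) because the
    data-driven blood-VOI refinement needs it.
    """
    n = len(scans)
    if n < 3:
        raise ValueError(f"regression needs >= 3 subjects, got {n}")
    x = np.asarray(covariate, dtype=np.float64)
    if x.shape != (n,):
        raise ValueError("need exactly one covariate value per scan")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise ValueError("covariate has zero variance")

    inside = mask.values.astype(bool)
    Y = _stack(scans, inside)  # (n, m)
    ybar = Y.mean(axis=0)
    slope = (xc @ Y) / sxx
    resid = Y - ybar[None, :] - np.outer(xc, slope)
    dof = n - 2
    ss_res = np.einsum("ij,ij->j", resid, resid)
    # guard tiny negative rounding
    ss_res = np.maximum(ss_res, 0.0)
    se = np.sqrt(ss_res / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    perfect = se == 0.0
    t[perfect] = np.sign(slope[perfect]) * np.inf
    degenerate_flat = perfect & (slope == 0.0)
    t[degenerate_flat] = 0.0

    t_vol = np.zeros(mask.values.shape, dtype=np.float64)
    t_vol[inside] = t
    slope_vol = np.zeros_like(t_vol)
    slope_vol[inside] = slope
    degen = np.zeros(mask.values.shape, dtype=bool)
    degen[inside] = degenerate_flat
    spacing = mask.voxel_size_mm
    return TMap(
        t=Volume(t_vol, spacing, "t"),
        dof=dof,
        contrast=contrast,
        mask=mask,
        degenerate=degen,
        slope=Volume(slope_vol, spacing, "ratio"),
    )


def two_sample_tmap(
    scansA: Sequence[SubjectScan | Volume],
    scansB: Sequence[SubjectScan | Volume],
    mask: Volume,
    contrast: str = "groupA > groupB",
) -> TMap:
    """Pooled-variance unpaired t per masked voxel; positive where
    mean(A) > mean(B); dof = nA + nB - 2.  Zero pooled variance at a
    voxel yields t = 0 with a degeneracy flag."""
    nA, nB = len(scansA), len(scansB)
    if nA < 2 or nB < 2:
        raise ValueError("each group needs >= 2 subjects")
    inside = mask.values.astype(bool)
    A = _stack(scansA, inside)
    B = _stack(scansB, inside)
    dof = nA + nB - 2
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    ssA = np.einsum("ij,ij->j", A - mA, A - mA)
    ssB = np.einsum("ij,ij->j", B - mB, B - mB)
    sp2 = (ssA + ssB) / dof
    se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    diff = mA - mB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_var = se == 0.0
    t[zero_var & (diff > 0)] = np.inf
    t[zero_var & (diff < 0)] = -np.inf
    degenerate_flat = zero_var & (diff == 0.0)
    t[degenerate_flat] = 0.0

    t_vol = np.zeros(mask.values.shape, dtype=np.float64)
    t_vol[inside] = t
    degen = np.zeros(mask.values.shape, dtype=bool)
    degen[inside] = degenerate_flat
    return TMap(
        t=Volume(t_vol, mask.voxel_size_mm, "t"),
        dof=dof,
        contrast=contrast,
        mask=mask,
        degenerate=degen,
    )


def t_threshold(p_uncorrected: float, dof: int, sided: str = "one") -> float:
    """Critical t at an uncorrected tail probability.

    ``sided='one'`` returns t with P(T > t) = p; ``sided='two'`` returns
    t with P(|T| > t) = p (equivalently the one-sided threshold at p/2).
    """
    if not 0.0 < p_uncorrected < 1.0:
        raise ValueError("p must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if sided == "one":
        return float(stats.t.isf(p_uncorrected, dof))
    if sided == "two":
        return float(stats.t.isf(p_uncorrected / 2.0, dof))
    raise ValueError("sided must be 'one' or 'two'")


def extract_clusters(
    tmap: TMap,
    t_crit: float,
    min_size: int = 50,
    connectivity: int = 18,
    strict_extent: bool = True,
) -> list[ClusterVOI]:
    """Connected components of ``{t > t_crit}`` within the mask.

    Components with ``size > min_size`` (strict, reading "more than
    k voxels" literally; set ``strict_extent=False`` for >=) are
    retained, sorted by peak t descending with ties broken by size then
    by lexicographic peak index.  An empty list is a valid result.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    supra = (tmap.t.values > t_crit) & tmap.mask.values.astype(bool)
    labeled, n_comp = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters: list[ClusterVOI] = []
    for lbl in range(1, n_comp + 1):
        idx = np.argwhere(labeled == lbl)
        size = len(idx)
        if (size <= min_size) if strict_extent else (size < min_size):
            continue
        tvals = tmap.t.values[tuple(idx.T)]
        peak = float(np.max(tvals))
        peak_candidates = idx[tvals == peak]
        # lexicographically smallest peak location
        order = np.lexsort(peak_candidates.T[::-1])
        peak_index = tuple(int(v) for v in peak_candidates[order[0]])
        clusters.append(
            ClusterVOI(
                voxel_indices=idx,
                size_voxels=size,
                peak_t=peak,
                peak_index=peak_index,  # type: ignore[arg-type]
            )
        )
    clusters.sort(key=lambda c: (-c.peak_t, -c.size_voxels, c.peak_index))
    return clusters
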