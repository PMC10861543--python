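"""Diffusion tensor reconstruction: tensor fit, eigenvalue maps, ROI stats.

From seven magnitude images (six diffusion directions at one b-value plus
a b=0 image) the symmetric tensor D is estimated per voxel from the
log-linear model log(S_i/S_0) = -b_i * g_i^T D g_i, the tensor is
eigen-decomposed, and ADC (mean diffusivity, trace/3) and fractional
anisotropy maps are derived, followed by per-region statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulate import DWIDataset

__all__ = [
    "TensorField",
    "ScalarMap",
    "ROIStats",
    "design_matrix",
    "fit_tensor",
    "eigen_adc",
    "fa_map",
    "roi_stats",
]

ADC_REPORT_UNITS = "1e-3 mm^2/s"


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor.

    ``tensors[..., :]`` = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm²/s;
    ``valid`` flags voxels where the fit was possible (positive signals).
    """

    tensors: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.tensors.shape[-1] != 6 or self.tensors.ndim != 4:
            raise ValueError("tensors must be (x, y, z, 6)")
        if self.valid.shape != self.tensors.shape[:3]:
            raise ValueError("valid mask must match the grid")

    def as_matrices(self) -> np.ndarray:
        """Full (x, y, z, 3, 3) symmetric matrices."""
        t = self.tensors
        m = np.empty(t.shape[:3] + (3, 3))
        m[..., 0, 0] = t[..., 0]
        m[..., 1, 1] = t[..., 1]
        m[..., 2, 2] = t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m

    def eigenvalues(self) -> np.ndarray:
        """Per-voxel eigenvalues in descending order, NaN where invalid."""
        lam = np.linalg.eigvalsh(self.as_matrices())[..., ::-1]
        lam[~self.valid] = np.nan
        return lam


@dataclass
class ScalarMap:
    """A per-voxel scalar (ADC, FA or a single eigenvalue) with units."""

    data: np.ndarray
    kind: str
    units: str = ""
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.data)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass(frozen=True)
class ROIStats:
    """Mean +/- SD of a scalar map over one labeled region."""

    label: int
    name: str
    n_voxels: int
    mean: float
    sd: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("an ROI must contain at least one voxel")


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b_i * (gx², gy², gz², 2gxgy, 2gxgz, 2gygz) for the b>0 encodings."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    rows = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    return b[:, None] * rows


def fit_tensor(dwi: DWIDataset, weighted: bool = False) -> TensorField:
    """Least-squares tensor fit per voxel.

    Solves ``-log(S_i/S_0) = b_i * g_i^T D g_i`` by ordinary least squares
    (the log-linear estimator); ``weighted=True`` re-weights rows by the
    squared signal, the usual variance-stabilizing correction for
    log-transformed Rician data.  Voxels with any non-positive signal are
    flagged invalid.

    Requires at least one b=0 volume and >= 6 non-collinear directions.
    """
    b0_sel = dwi.bvals == 0
    if not b0_sel.any():
        raise ValueError("a b=0 volume is required")
    dw_sel = ~b0_sel
    if dw_sel.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted volumes are required")
    a = design_matrix(dwi.bvals[dw_sel], dwi.bvecs[dw_sel])
    if np.linalg.matrix_rank(a) < 6:
        raise ValueError("encoding directions do not span the tensor space "
                         "(rank-deficient design)")

    s0 = dwi.volumes[..., b0_sel].mean(axis=-1)
    s = dwi.volumes[..., dw_sel]
    valid = dwi.mask & (s0 > 0) & np.all(s > 0, axis=-1)

    shape = dwi.volumes.shape[:3]
    tensors = np.zeros(shape + (6,))
    if valid.any():
        y = -np.log(s[valid] / s0[valid, None])  # (nvox, ndw)
        if weighted:
            w = s[valid]  # weights ~ signal (rows scaled by S_i)
            sol = np.empty((y.shape[0], 6))
            for i in range(y.shape[0]):
                aw = a * w[i][:, None]
                sol[i] = np.linalg.lstsq(aw, y[i] * w[i], rcond=None)[0]
        else:
            sol = (np.linalg.pinv(a) @ y.T).T
        tensors[valid] = sol
    return TensorField(tensors, valid)


def eigen_adc(tf: TensorField) -> ScalarMap:
    """ADC (mean diffusivity) map: (lambda1 + lambda2 + lambda3) / 3.

    Equals trace(D)/3; negative noise-driven eigenvalues are retained so
    the trace stays unbiased.  Units mm²/s (scale by 1e3 for the
    conventional 10⁻³ mm²/s reporting).
    """
    lam = tf.eigenvalues()
    adc = lam.mean(axis=-1)
    return ScalarMap(adc, kind="ADC", units="mm^2/s", valid=tf.valid)


def fa_map(tf: TensorField) -> ScalarMap:
    """Fractional anisotropy map, clipped to [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, with
    eigenvalues clamped at zero (the FA domain requires non-negativity);
    all-zero tensors yield NaN.
    """
    lam = np.clip(tf.eigenvalues(), 0.0, None)
    norm2 = np.sum(lam ** 2, axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum((lam - mean) ** 2, axis=-1) / norm2)
    fa[norm2 == 0] = np.nan
    fa = np.clip(fa, 0.0, 1.0)
    fa[~tf.valid] = np.nan
    return ScalarMap(fa, kind="FA", units="", valid=tf.valid & (norm2 > 0))


def roi_stats(scalar_map: ScalarMap, region_map: np.ndarray,
              labels: Sequence[int] | None = None,
              names: dict | None = None) -> list[ROIStats]:
    """Per-region mean and SD over valid voxels.

    SD uses the n-1 denominator (0 for single-voxel regions).  Raises on a
    label with no valid voxels.
    """
    region_map = np.asarray(region_map)
    if labels is None:
        labels = sorted(set(np.unique(region_map)) - {0})
    names = names or {}
    out = []
    for lab in labels:
        sel = (region_map == lab) & scalar_map.valid & \
            np.isfinite(scalar_map.data)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"region label {lab} has no valid voxels")
        vals = scalar_map.data[sel]
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out.append(ROIStats(int(lab), names.get(lab, f"region_{lab}"),
                            n, float(np.mean(vals)), sd,
                            units=scalar_map.units))
    return out
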