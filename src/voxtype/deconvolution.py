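"""Nonnegative least-squares estimation of cell-type densities per voxel.

At each voxel the density vector over types minimizes

    sum_g (E(v,g) - sum_t nu(t) C(t,g))^2  +  l1_penalty * sum_t nu(t)

subject to nu >= 0. Voxels are independent, so the field fit is a plain
loop over rows; the solver is the Lawson-Hanson active-set method
(scipy.optimize.nnls), exact for small type counts. Panel rows are not
normalized before fitting; an optional per-gene scaling is exposed but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls

from voxtype.data_model_io import CellTypePanel, DensityField, ExpressionAtlas


@dataclass(frozen=True)
class DeconvolutionOptions:
    l1_penalty: float = 0.0
    solver_tolerance: float = 1e-10
    max_iterations: int | None = None  # None -> solver default (3 x n_types)
    per_gene_scale: bool = False  # divide each gene column by its panel max

    def __post_init__(self) -> None:
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be nonnegative")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")


_DEFAULT_OPTIONS = DeconvolutionOptions()


def _design_matrix(panel: CellTypePanel, options: DeconvolutionOptions) -> np.ndarray:
    A = panel.values.T.copy()  # (n_genes, n_types)
    if options.per_gene_scale:
        scale = A.max(axis=1)
        scale[scale == 0] = 1.0
        A /= scale[:, None]
    return A


def _solve_nnls(A: np.ndarray, b: np.ndarray, options: DeconvolutionOptions) -> np.ndarray:
    if options.l1_penalty == 0.0:
        x, _ = nnls(A, b, maxiter=options.max_iterations)
        return x
    # The linear penalty shifts the constant term of the normal equations:
    # minimize nu'G nu - 2 h'nu with G = A'A, h = A'b - lambda/2, which is
    # an NNLS problem in the Cholesky factor of G.
    G = A.T @ A
    h = A.T @ b - options.l1_penalty / 2.0
    jitter = 0.0
    scale = np.trace(G) / G.shape[0]
    for _ in range(6):
        try:
            c, low = cho_factor(G + jitter * np.eye(G.shape[0]), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * max(scale, 1.0))
    else:  # pragma: no cover - pathological panel
        raise ValueError("panel Gram matrix is numerically singular")
    L = np.tril(c) if low else np.triu(c).T
    rhs = cho_solve((c, low), h)
    x, _ = nnls(L.T, L.T @ rhs, maxiter=options.max_iterations)
    return x


def fit_voxel_density(
    expression_row: np.ndarray,
    panel: CellTypePanel,
    options: DeconvolutionOptions | None = None,
) -> np.ndarray:
    """Fit one voxel's nonnegative density vector over cell types."""
    options = options or _DEFAULT_OPTIONS
    b = np.asarray(expression_row, dtype=float)
    if b.ndim != 1 or b.size != panel.n_genes:
        raise ValueError(
            f"expression row has length {b.size}, expected {panel.n_genes}"
        )
    if not np.all(np.isfinite(b)):
        raise ValueError("expression row contains non-finite values")
    if not np.any(panel.values):
        raise ValueError("panel is all zeros; densities are unidentifiable")
    A = _design_matrix(panel, options)
    if options.per_gene_scale:
        scale = panel.values.max(axis=0)
        scale[scale == 0] = 1.0
        b = b / scale
    return _solve_nnls(A, b, options)


def fit_density_field(
    atlas: ExpressionAtlas,
    panel: CellTypePanel,
    options: DeconvolutionOptions | None = None,
) -> DensityField:
    """Fit every voxel independently; row v of the result is
    ``fit_voxel_density(atlas.values[v], panel)``."""
    options = options or _DEFAULT_OPTIONS
    if atlas.gene_ids != panel.gene_ids:
        raise ValueError("atlas and panel gene columns are not aligned")
    out = np.empty((atlas.n_voxels, panel.n_types), dtype=float)
    for v in range(atlas.n_voxels):
        try:
            out[v] = fit_voxel_density(atlas.values[v], panel, options)
        except Exception as exc:
            raise RuntimeError(f"deconvolution failed at voxel {v}: {exc}") from exc
    return DensityField(values=out, type_labels=panel.type_labels)


def residual_fraction(
    atlas: ExpressionAtlas, panel: CellTypePanel, field: DensityField
) -> float:
    """Frobenius norm of (E - rho C) over Frobenius norm of E; 0 for a zero atlas."""
    if field.n_voxels != atlas.n_voxels or field.n_types != panel.n_types:
        raise ValueError("inconsistent shapes")
    denom = float(np.linalg.norm(atlas.values))
    if denom == 0.0:
        return 0.0
    resid = atlas.values - field.values @ panel.values
    return float(np.linalg.norm(resid)) / denom
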