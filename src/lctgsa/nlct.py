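"""Nonlinear combination test (NLCT): spline basis expansion + LCT.

Each gene in the set is replaced by a natural cubic spline basis expansion
(5 basis functions per gene by default), after which the linear machinery
tests the broader null hypothesis that there is *no relationship of any
form* between the gene set and the phenotypes.  The phenotypes are left
untransformed: expanding both blocks would demand a much larger sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from patsy.mgcv_cubic_splines import _get_all_sorted_knots, _get_free_crs_dmatrix

from .lct import LCTResult, lct_test
from .shrinkage import StandardizedMatrix, center_scale

__all__ = ["SplineExpansion", "spline_expand", "nlct_test"]

logger = logging.getLogger(__name__)


@dataclass
class SplineExpansion(StandardizedMatrix):
    """Standardized spline-basis expansion of a gene block.

    Inherits the standardized ``values`` / ``variable_ids`` contract, so it
    can be fed directly to the LCT machinery.  ``source_map`` records, for
    every expanded column, the originating gene and basis index; ``knots``
    the per-gene knot locations (boundary knots at the observed min/max,
    interior knots at equally spaced quantiles).
    """

    df: int
    source_map: list[tuple[str, int]]
    knots: dict[str, np.ndarray]


def _gene_basis(x: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Natural cubic spline basis for one gene, degrading gracefully on ties.

    Returns ``(basis, knots, df_used)``.  Genes with fewer than ``df + 1``
    distinct values get a reduced basis (down to the raw column itself), so
    that discretized expression values never produce a singular expansion.
    For an effective df of 1 or 2 a polynomial basis of that degree is used,
    since a cubic spline needs at least three knots.
    """
    n_distinct = np.unique(x).size
    df_eff = min(df, n_distinct - 1)
    df_eff = max(df_eff, 1)
    while df_eff >= 3:
        try:
            # mgcv-style cubic regression spline: df_eff knots at equally
            # spaced quantiles (boundary at min/max), df_eff basis functions.
            knots = _get_all_sorted_knots(x, n_inner_knots=df_eff - 2)
            basis = np.asarray(_get_free_crs_dmatrix(x, knots), dtype=float)
            quantiles = np.asarray(knots, dtype=float)
        except Exception:  # coincident quantile knots on heavily tied data
            df_eff -= 1
            continue
        if np.all(basis.std(axis=0, ddof=1) > 0):
            return basis, quantiles, df_eff
        df_eff -= 1
    if df_eff == 2:
        return np.column_stack([x, x**2]), np.array([x.min(), x.max()]), 2
    return x[:, None], np.array([x.min(), x.max()]), 1


def spline_expand(X: StandardizedMatrix, df: int = 5) -> SplineExpansion:
    """Expand every gene into a standardized natural cubic spline basis.

    Parameters
    ----------
    X
        Standardized gene block.
    df
        Basis functions per gene (default 5).  Knots sit at ``df`` equally
        spaced quantiles of each gene's values, the outermost two at the
        observed min/max; the basis is linear beyond those boundary knots.

    Raises
    ------
    ValueError
        If ``df < 2`` or ``n <= df + 1`` (basis not identifiable).
    """
    if df < 2:
        raise ValueError("df must be at least 2")
    if X.n <= df + 1:
        raise ValueError(f"n = {X.n} too small for df = {df} (need n > df + 1)")
    columns: list[np.ndarray] = []
    source_map: list[tuple[str, int]] = []
    knots: dict[str, np.ndarray] = {}
    ids: list[str] = []
    for j, gene in enumerate(X.variable_ids):
        basis, gene_knots, df_used = _gene_basis(X.values[:, j], df)
        if df_used < df:
            logger.warning(
                "gene %s: spline df reduced from %d to %d (tied values)", gene, df, df_used
            )
        knots[gene] = gene_knots
        for k in range(basis.shape[1]):
            columns.append(basis[:, k])
            source_map.append((gene, k))
            ids.append(f"{gene}:ns{k + 1}")
    std = center_scale(np.column_stack(columns), ids)
    return SplineExpansion(
        values=std.values, variable_ids=std.variable_ids, df=df, source_map=source_map, knots=knots
    )


def nlct_test(
    X: StandardizedMatrix,
    Y: StandardizedMatrix,
    df: int = 5,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> LCTResult:
    """NLCT: apply :func:`lct_test` to the spline expansion of the gene block.

    The result is exactly ``lct_test(spline_expand(X, df), Y, n_perm, seed)``;
    ``coef_genes`` therefore has one entry per expanded basis column.
    """
    return lct_test(spline_expand(X, df), Y, n_perm=n_perm, seed=seed)
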