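"""Aitchison-simplex machinery for activity-behaviour compositions.

Minutes of a waking day split into sedentary time (ST), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA) carry
only relative information: the parts are co-dependent because they sum
to a fixed total (16 waking hours if 8 hours of sleep are assumed).
Analysing them with ordinary linear models therefore goes through the
isometric log-ratio (ilr) transform, which maps a D-part composition to
D-1 unconstrained, orthonormal real coordinates.

This module implements the *pivot* ilr basis (the sequential binary
partition in which the first coordinate contrasts one part of interest
against the geometric mean of the rest), its inverse, closure, zero
replacement, compositional geometric means, and the rotation bookkeeping
needed to read off the first pivot coordinate for every part in turn.

All functions are vectorised: a composition argument may be a single
1-d vector or a 2-d array with one composition per row.  Natural
logarithms are used throughout.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gmean

from .schema import PARTS

#: closure constant for a 16-hour waking day, in minutes
WAKING_DAY_MINUTES = 960.0

__all__ = [
    "WAKING_DAY_MINUTES",
    "closure",
    "zero_replace",
    "geometric_mean_composition",
    "pivot_basis",
    "ilr_pivot",
    "ilr_inverse",
    "pivot_rotations",
    "rotation_perms",
    "basis_in_canonical",
    "first_pivot_betas",
    "canonical_betas_from_first_pivots",
    "clr",
    "aitchison_distance",
]


def closure(x: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Rescale positive parts so each composition sums to ``kappa``.

    Scale invariant: ``closure(c * x, kappa) == closure(x, kappa)`` for
    any positive scalar ``c``.
    """
    x = np.asarray(x, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if np.any(x <= 0):
        raise ValueError(
            "closure requires strictly positive parts; route zero or negative "
            "entries through zero_replace first"
        )
    return kappa * x / x.sum(axis=-1, keepdims=True)


def zero_replace(x: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Multiplicative replacement of zero parts.

    Zeros become ``delta`` and the non-zero parts are shrunk
    multiplicatively so every row keeps its original total.  Rows with
    no zeros are returned unchanged.

    Parameters
    ----------
    x : array of non-negative parts (rows are compositions)
    delta : imputed value for a zero part, on the scale of ``x``
        (default 1 min day^-1, the smallest epoch aggregate).
    """
    x = np.asarray(x, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if np.any(x < 0):
        raise ValueError("parts must be non-negative")
    one_d = x.ndim == 1
    x2 = np.atleast_2d(x).copy()
    totals = x2.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("each composition needs at least one positive part")
    zero = x2 == 0
    nzeros = zero.sum(axis=1)
    rows = nzeros > 0
    if rows.any():
        scale = (totals[rows] - nzeros[rows] * delta) / totals[rows]
        if np.any(scale <= 0):
            raise ValueError("delta too large: replacement would exhaust the total")
        x2[rows] *= scale[:, None]
        x2[zero] = delta
    return x2[0] if one_d else x2


def geometric_mean_composition(rows: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Part-wise geometric mean over compositions, closed to ``kappa``.

    This is the compositional centre: the natural summary of where a
    sample of compositions sits on the simplex.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] < 1:
        raise ValueError("need at least one composition")
    if np.any(rows <= 0):
        raise ValueError("all parts must be positive")
    return closure(gmean(rows, axis=0), kappa)


def pivot_basis(d: int) -> np.ndarray:
    """Contrast matrix V (d x d-1) of the pivot ilr basis.

    For log-composition ``ln x`` (in pivot order) the coordinates are
    ``z = ln(x) @ V`` with

        z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1..D}) )

    for k = 1..D-1.  Columns are orthonormal and sum to zero, so V maps
    clr space isometrically onto R^{d-1}.
    """
    if d < 2:
        raise ValueError("compositions need at least two parts")
    v = np.zeros((d, d - 1))
    for k in range(d - 1):
        rest = d - k - 1
        c = np.sqrt(rest / (rest + 1.0))
        v[k, k] = c
        v[k + 1:, k] = -c / rest
    return v


def _check_perm(perm: Sequence[int], d: int) -> tuple[int, ...]:
    perm = tuple(int(i) for i in perm)
    if sorted(perm) != list(range(d)):
        raise ValueError(f"pivot order {perm} is not a permutation of 0..{d - 1}")
    return perm


def ilr_pivot(x: np.ndarray, perm: Sequence[int] | None = None) -> np.ndarray:
    """Pivot ilr coordinates of composition(s) ``x``.

    ``perm`` gives the part ordering as indices into the columns of
    ``x``; the part placed first (``perm[0]``) is the part of interest
    whose first coordinate ``z1`` contrasts it against the geometric
    mean of the remaining parts.  Scale invariant, so ``x`` need not be
    closed.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts")
    d = x.shape[-1]
    if perm is None:
        perm = tuple(range(d))
    perm = _check_perm(perm, d)
    return np.log(x[..., list(perm)]) @ pivot_basis(d)


def ilr_inverse(
    z: np.ndarray, kappa: float = 1.0, perm: Sequence[int] | None = None
) -> np.ndarray:
    """Inverse pivot ilr: coordinates back to a composition closed to ``kappa``.

    ``perm`` must match the ordering used in :func:`ilr_pivot`; the
    output columns are returned in the original (unpermuted) order.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    d = z.shape[-1] + 1
    v = pivot_basis(d)
    xp = closure(np.exp(z @ v.T), kappa)
    if perm is None:
        return xp
    perm = _check_perm(perm, d)
    inv = np.argsort(perm)
    return xp[..., inv]


def pivot_rotations(labels: Sequence[str] = PARTS) -> list[tuple[str, ...]]:
    """The D cyclic orderings placing each part first in turn.

    For (ST, LPA, MVPA) these are the three rows of the association
    table: "ST: LPA & MVPA", "LPA: MVPA & ST", "MVPA: ST & LPA".
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("part labels must be unique")
    if len(labels) < 2:
        raise ValueError("need at least two parts")
    return [labels[i:] + labels[:i] for i in range(len(labels))]


def rotation_perms(d: int) -> list[tuple[int, ...]]:
    """Index permutations matching :func:`pivot_rotations`."""
    idx = tuple(range(d))
    return [idx[i:] + idx[:i] for i in range(d)]


def basis_in_canonical(perm: Sequence[int], d: int | None = None) -> np.ndarray:
    """Pivot basis for ordering ``perm``, expressed on canonically ordered parts.

    Returns B (d x d-1) such that ``z_perm = ln(x) @ B`` for ``x`` in
    canonical part order.  Columns remain orthonormal and zero-sum.
    """
    perm = tuple(perm)
    if d is None:
        d = len(perm)
    perm = _check_perm(perm, d)
    v = pivot_basis(d)
    b = np.zeros_like(v)
    b[list(perm), :] = v
    return b


def first_pivot_betas(
    beta: Sequence[float], labels: Sequence[str] = PARTS
) -> dict[str, float]:
    """First-pivot regression coefficient implied by ``beta`` for each rotation.

    ``beta`` is the coefficient vector on the canonical-order ilr
    coordinates of a linear predictor ``beta' z``.  Re-expressing the
    same predictor in the rotation placing part p first gives first
    coordinate coefficient ``b(p) = B_p[:, 0]' B_c beta``; because the
    first basis vectors of the D rotations sum to zero, so do the D
    values returned here.
    """
    labels = tuple(labels)
    d = len(labels)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (d - 1,):
        raise ValueError(f"beta must have length {d - 1}")
    bc = basis_in_canonical(range(d))
    out: dict[str, float] = {}
    for perm in rotation_perms(d):
        bp = basis_in_canonical(perm)
        out[labels[perm[0]]] = float(bp[:, 0] @ bc @ beta)
    return out


def canonical_betas_from_first_pivots(
    values: Mapping[str, float], labels: Sequence[str] = PARTS
) -> np.ndarray:
    """Invert :func:`first_pivot_betas`.

    Given the D first-pivot coefficients (which must sum to zero, up to
    rounding), recover the unique canonical-basis coefficient vector
    producing them.  Raises if the supplied values are inconsistent.
    """
    labels = tuple(labels)
    d = len(labels)
    rows = []
    b_vec = []
    bc = basis_in_canonical(range(d))
    for perm in rotation_perms(d):
        bp = basis_in_canonical(perm)
        rows.append(bp[:, 0] @ bc)
        b_vec.append(float(values[labels[perm[0]]]))
    a = np.asarray(rows)
    b_vec = np.asarray(b_vec)
    beta, *_ = np.linalg.lstsq(a, b_vec, rcond=None)
    resid = a @ beta - b_vec
    scale = max(1.0, float(np.abs(b_vec).max()))
    # printed coefficient triples carry ~3 decimals of rounding
    if np.abs(resid).max() > 1e-3 * scale + 1e-3:
        raise ValueError(
            "first-pivot coefficients are inconsistent (they must sum to zero): "
            f"residual {resid}"
        )
    return beta


def clr(x: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform (test utility)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance between two compositions (test utility)."""
    return float(np.linalg.norm(clr(x) - clr(y)))


def compositions_to_frame(rows: np.ndarray, kappa: float, labels: Iterable[str] = PARTS):
    """CSV round-trip helper: label columns and record the closure constant."""
    import pandas as pd

    df = pd.DataFrame(np.atleast_2d(rows), columns=[f"{p}_min" for p in labels])
    df.attrs["kappa"] = kappa
    return df
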