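"""Compositional-data primitives for time-use analysis.

Daily time-use data are *compositional*: the minutes a worker spends on
moderate-to-vigorous physical activity (MVPA), sedentary behavior, standing,
light physical activity (LIPA) and, in leisure, time in bed carry only
relative information, because more time on one behavior necessarily means
less on the others. This module provides the simplex machinery the rest of
the package builds on:

* closure (rescaling parts to a fixed total),
* multiplicative replacement of zero parts,
* the pivot (sequential-binary-partition) isometric log-ratio (ilr)
  transform and its inverse, with MVPA as the first pivot so that the first
  coordinate contrasts MVPA against the geometric mean of the remaining
  behaviors,
* the compositional (geometric) mean of a sample of compositions.

Work is modelled as a four-part composition (MVPA, sedentary, standing,
LIPA) and leisure as a five-part composition (the same four plus time in
bed); each domain is treated as its own composition closed to its own
duration rather than as a sub-composition of the 1440-minute day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WORK_PART_ORDER",
    "LEISURE_PART_ORDER",
    "PART_ORDER",
    "DomainComposition",
    "IlrCoordinates",
    "SbpBasis",
    "closure",
    "zero_replace",
    "sbp_basis",
    "ilr",
    "inverse_ilr",
    "compositional_mean",
    "PivotIlr",
]

#: Fixed pivot order per domain: MVPA first, then the listing order of the
#: remaining behaviors.
WORK_PART_ORDER: tuple[str, ...] = ("mvpa", "sedentary", "standing", "lipa")
LEISURE_PART_ORDER: tuple[str, ...] = (
    "mvpa",
    "sedentary",
    "standing",
    "lipa",
    "time_in_bed",
)
PART_ORDER: dict[str, tuple[str, ...]] = {
    "work": WORK_PART_ORDER,
    "leisure": LEISURE_PART_ORDER,
}

_REL_TOL = 1e-9


def _as_vector(parts) -> np.ndarray:
    x = np.asarray(parts, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d part vector, got shape {x.shape}")
    return x


@dataclass(frozen=True)
class DomainComposition:
    """Named non-negative part durations (minutes) for one time domain.

    Parameters
    ----------
    domain : {'work', 'leisure'}
        Time domain the composition belongs to.
    minutes : sequence of float
        Part durations aligned with ``part_names``.
    part_names : tuple of str, optional
        Part ordering; defaults to the domain's fixed pivot order.
    """

    domain: str
    minutes: tuple[float, ...]
    part_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.domain not in PART_ORDER:
            raise ValueError(f"unknown domain {self.domain!r}")
        names = tuple(self.part_names) or PART_ORDER[self.domain]
        vals = tuple(float(v) for v in self.minutes)
        if len(vals) != len(names):
            raise ValueError(
                f"{self.domain} composition needs {len(names)} parts, got {len(vals)}"
            )
        if any(v < 0 for v in vals):
            raise ValueError("negative part duration")
        object.__setattr__(self, "minutes", vals)
        object.__setattr__(self, "part_names", names)

    @classmethod
    def from_mapping(cls, domain: str, mapping, part_names=None) -> "DomainComposition":
        names = tuple(part_names) if part_names else PART_ORDER[domain]
        return cls(domain, tuple(float(mapping[n]) for n in names), names)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.minutes, dtype=float)

    @property
    def total_minutes(self) -> float:
        return float(sum(self.minutes))

    @property
    def n_parts(self) -> int:
        return len(self.minutes)

    def __getitem__(self, part: str) -> float:
        return self.minutes[self.part_names.index(part)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.part_names, self.minutes))

    def with_values(self, values) -> "DomainComposition":
        return DomainComposition(self.domain, tuple(float(v) for v in values), self.part_names)

    def closed(self, kappa: float) -> "DomainComposition":
        return self.with_values(closure(self.values, kappa))

    def ilr(self, basis: "SbpBasis | None" = None) -> "IlrCoordinates":
        basis = basis or sbp_basis(self.n_parts)
        return IlrCoordinates(
            values=ilr(self.values, basis),
            part_order=self.part_names,
            domain=self.domain,
        )


@dataclass(frozen=True)
class IlrCoordinates:
    """The D-1 pivot log-ratio coordinates of a composition."""

    values: np.ndarray
    part_order: tuple[str, ...]
    domain: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.part_order) - 1,):
            raise ValueError("ilr coordinate length must be D-1")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite ilr coordinate")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SbpBasis:
    """Pivot sequential-binary-partition contrast matrix, shape (D-1, D).

    Row ``k`` (0-based) contrasts part ``k`` against the geometric mean of
    parts ``k+1 .. D-1``; rows are orthonormal and sum to zero.
    """

    contrast_matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.contrast_matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] - 1:
            raise ValueError("contrast matrix must have shape (D-1, D)")
        object.__setattr__(self, "contrast_matrix", m)

    @property
    def n_parts(self) -> int:
        return self.contrast_matrix.shape[1]


def closure(parts, kappa: float) -> np.ndarray:
    """Rescale non-negative parts so they sum to ``kappa`` exactly.

    Parameters
    ----------
    parts : array-like
        Non-negative part values, at least one strictly positive.
    kappa : float
        Target total (> 0).
    """
    x = _as_vector(parts)
    if kappa <= 0:
        raise ValueError("closure total kappa must be positive")
    if np.any(x < 0):
        raise ValueError("negative part in composition")
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate composition: all parts zero")
    return x * (kappa / total)


def zero_replace(parts, delta: float = 0.5) -> np.ndarray:
    """Multiplicative replacement of zero parts.

    Zeros become ``delta`` and the non-zero parts shrink proportionally so
    the total is preserved. Idempotent on zero-free input.

    Parameters
    ----------
    parts : array-like
        Non-negative part values.
    delta : float, default 0.5
        Imputed value in the same units as ``parts`` (minutes); must be
        smaller than the smallest non-zero part.
    """
    x = _as_vector(parts)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if np.any(x < 0):
        raise ValueError("negative part in composition")
    zero = x == 0
    if not zero.any():
        return x.copy()
    nonzero = x[~zero]
    if nonzero.size == 0:
        raise ValueError("degenerate composition: all parts zero")
    if delta >= nonzero.min():
        raise ValueError(
            f"delta={delta} must be below the smallest nonzero part {nonzero.min()}"
        )
    total = x.sum()
    n_zero = int(zero.sum())
    out = x * (1.0 - n_zero * delta / total)
    out[zero] = delta
    return out


def sbp_basis(n_parts: int) -> SbpBasis:
    """Pivot-coordinate contrast matrix for ``n_parts`` parts.

    Row ``k`` (0-based) carries ``+sqrt((D-k-1)/(D-k))`` on part ``k`` and
    ``-sqrt((D-k-1)/(D-k))/(D-k-1)`` on each later part, the standard pivot
    (sequential binary partition) construction in which each coordinate
    contrasts one part against the geometric mean of those after it.
    """
    D = int(n_parts)
    if D < 2:
        raise ValueError("a composition needs at least 2 parts")
    m = np.zeros((D - 1, D))
    for k in range(D - 1):
        r = D - k - 1  # number of parts in the denominator
        coef = np.sqrt(r / (r + 1.0))
        m[k, k] = coef
        m[k, k + 1 :] = -coef / r
    return SbpBasis(m)


def ilr(comp, basis: SbpBasis | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of a strictly positive composition.

    ``values[k] = sum_j contrast[k, j] * ln(part_j)``; scale-invariant, so
    closing the composition first does not change the output.
    """
    if isinstance(comp, DomainComposition):
        comp = comp.values
    x = _as_vector(comp)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts (apply zero_replace first)")
    basis = basis or sbp_basis(x.size)
    if basis.n_parts != x.size:
        raise ValueError("basis/composition size mismatch")
    return basis.contrast_matrix @ np.log(x)


def inverse_ilr(coords, basis: SbpBasis | None = None, kappa: float = 1.0) -> np.ndarray:
    """Map ilr coordinates back to a composition closed to ``kappa``."""
    z = _as_vector(coords)
    basis = basis or sbp_basis(z.size + 1)
    if basis.n_parts != z.size + 1:
        raise ValueError("basis/coordinate size mismatch")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite ilr coordinates")
    logx = basis.contrast_matrix.T @ z
    x = np.exp(logx - logx.max())  # guard against overflow; closure rescales
    return closure(x, kappa)


def compositional_mean(comps: Iterable, kappa: float | None = None):
    """Part-wise geometric mean of compositions, closed to ``kappa``.

    Parameters
    ----------
    comps : iterable of DomainComposition or of part vectors
        Strictly positive compositions sharing one part order (and domain,
        if `DomainComposition`s are given).
    kappa : float, optional
        Closure total for the mean. Defaults to the arithmetic mean of the
        input totals, i.e. the geometric means are closed to the average
        domain duration.

    Returns
    -------
    DomainComposition or ndarray, matching the input element type.
    """
    comps = list(comps)
    if not comps:
        raise ValueError("compositional_mean of an empty collection")
    typed = isinstance(comps[0], DomainComposition)
    if typed:
        domains = {c.domain for c in comps}
        if len(domains) > 1:
            raise ValueError(f"mixed domains {domains}")
        mat = np.vstack([c.values for c in comps])
    else:
        mat = np.vstack([_as_vector(c) for c in comps])
    if np.any(mat <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    if kappa is None:
        kappa = float(mat.sum(axis=1).mean())
    gm = np.exp(np.log(mat).mean(axis=0))
    out = closure(gm, kappa)
    if typed:
        return comps[0].with_values(out)
    return out


class PivotIlr(BaseEstimator, TransformerMixin):
    """Pivot-ilr transformer over rows of part minutes.

    A thin scikit-learn-style wrapper around :func:`ilr` /
    :func:`inverse_ilr` so compositional covariates can sit inside sklearn
    pipelines. Rows with zero parts are repaired with multiplicative
    replacement before the log-ratio transform.

    Parameters
    ----------
    delta : float, default 0.5
        Zero-replacement value in minutes (half the 1-minute resolution of
        the day-level summaries).
    """

    def __init__(self, delta: float = 0.5):
        self.delta = delta

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-d with at least 2 parts")
        self.n_parts_ = X.shape[1]
        self.basis_ = sbp_basis(self.n_parts_)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_parts_:
            raise ValueError("part count changed between fit and transform")
        out = np.empty((X.shape[0], self.n_parts_ - 1))
        for i, row in enumerate(X):
            out[i] = ilr(zero_replace(row, self.delta), self.basis_)
        return out

    def inverse_transform(self, Z, kappa: float = 1.0) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return np.vstack([inverse_ilr(z, self.basis_, kappa) for z in Z])
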