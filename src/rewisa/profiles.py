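"""Site-by-condition methylation profiles and their quantification.

MeRIP-Seq profiles the m6A epi-transcriptome with two paired measurements per
site and condition: an IP (immunoprecipitated, methylation-enriched) abundance
``t`` and an input (background expression) abundance ``h``, both in FPKM-like
units.  The methylation level of a site is the pseudocount-stabilised IP
fraction

    p = (t + alpha) / (t + h + 2 * alpha),        0 < p < 1,

and the matching expression weight is

    w = log(t + h + 1) >= 0,

so that low-coverage sites — whose IP fraction is dominated by sampling noise —
contribute little to the downstream weighted signature scores.

This module houses the container types (:class:`CountProfile`,
:class:`MethylationProfile`, :class:`NormalizedProfile`), the quantification
and normalisation operations, and biological-replicate merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProfileError",
    "AlignmentError",
    "CountProfile",
    "MethylationProfile",
    "NormalizedProfile",
    "quantify_methylation",
    "compute_weights",
    "merge_replicates",
    "minmax_normalize",
    "zscore_normalize",
    "normalize_profile",
]

DEFAULT_ALPHA = 1e-6


class ProfileError(ValueError):
    """Invalid profile contents (negative counts, shape mismatch, ...)."""


class AlignmentError(ProfileError):
    """Axis labels of two profiles do not line up."""


def _as_labels(labels: Sequence, n: int, name: str) -> tuple:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ProfileError(f"{name}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ProfileError(f"{name}: duplicate identifiers")
    return labels


def _check_nonnegative(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        i, j = np.argwhere(~np.isfinite(x))[0]
        raise ProfileError(f"{name}[{i},{j}] is not finite")
    if np.any(x < 0):
        i, j = np.argwhere(x < 0)[0]
        raise ProfileError(f"{name}[{i},{j}] = {x[i, j]} is negative")


@dataclass(frozen=True)
class CountProfile:
    """Paired IP / input abundance matrices over sites x conditions.

    Attributes
    ----------
    site_ids, condition_ids : tuple of str
        External identifiers for the two axes.
    t : ndarray, shape (n_sites, n_conditions)
        IP-sample abundances (t_ij >= 0).
    h : ndarray, shape (n_sites, n_conditions)
        Input-sample abundances (h_ij >= 0).
    """

    site_ids: tuple
    condition_ids: tuple
    t: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if t.ndim != 2 or t.shape != h.shape:
            raise ProfileError(
                f"t and h must be 2-D with identical shape, got {t.shape} vs {h.shape}"
            )
        _check_nonnegative(t, "t")
        _check_nonnegative(h, "h")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "site_ids", _as_labels(self.site_ids, t.shape[0], "site_ids"))
        object.__setattr__(
            self, "condition_ids", _as_labels(self.condition_ids, t.shape[1], "condition_ids")
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.t.shape


@dataclass(frozen=True)
class MethylationProfile:
    """Methylation-level matrix P with its expression-weight matrix W.

    ``P`` holds per-cell methylation levels p_ij strictly inside (0, 1);
    ``W`` holds the matching non-negative expression weights w_ij.  ``alpha``
    records the pseudocount used during quantification.
    """

    site_ids: tuple
    condition_ids: tuple
    P: np.ndarray
    W: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        W = np.asarray(self.W, dtype=float)
        if P.ndim != 2 or P.shape != W.shape:
            raise ProfileError(
                f"P and W must be 2-D with identical shape, got {P.shape} vs {W.shape}"
            )
        if not np.all(np.isfinite(P)) or np.any(P <= 0) or np.any(P >= 1):
            raise ProfileError("methylation levels must lie strictly in (0, 1)")
        _check_nonnegative(W, "W")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "site_ids", _as_labels(self.site_ids, P.shape[0], "site_ids"))
        object.__setattr__(
            self, "condition_ids", _as_labels(self.condition_ids, P.shape[1], "condition_ids")
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.P.shape


@dataclass(frozen=True)
class NormalizedProfile:
    """Row- and column-wise min-max normalised copies of P (P^R and P^C)."""

    P_R: np.ndarray
    P_C: np.ndarray


def compute_weights(counts: CountProfile, base: float | None = None) -> np.ndarray:
    """Expression weights w_ij = log(t_ij + h_ij + 1).

    The +1 offset guarantees w_ij >= 0.  The logarithm is natural by default;
    ``base`` rescales W globally (the threshold auto-tuner re-optimises T_R and
    T_C on whatever scale W has, so the base is a pure convention).
    """
    w = np.log1p(counts.t + counts.h)
    if base is not None:
        if base <= 0 or base == 1:
            raise ValueError(f"invalid logarithm base {base}")
        w = w / np.log(base)
    return w


def quantify_methylation(
    counts: CountProfile, alpha: float = DEFAULT_ALPHA, *, log_base: float | None = None
) -> MethylationProfile:
    """Quantify methylation levels and weights from paired IP/input abundances.

    p_ij = (t_ij + alpha) / (t_ij + h_ij + 2 * alpha); the pseudocount alpha
    keeps cells where both samples are zero defined (they land exactly on 0.5)
    and every level strictly inside (0, 1).
    """
    if not (np.isscalar(alpha) and alpha > 0):
        raise ValueError(f"alpha must be a positive scalar, got {alpha!r}")
    P = (counts.t + alpha) / (counts.t + counts.h + 2.0 * alpha)
    W = compute_weights(counts, base=log_base)
    return MethylationProfile(counts.site_ids, counts.condition_ids, P, W, alpha=float(alpha))


def merge_replicates(
    profiles: Sequence[MethylationProfile], *, weight_rule: str = "mean"
) -> MethylationProfile:
    """Merge biological replicates by per-cell averaging.

    The merged methylation level is the arithmetic mean of the replicate
    levels; weights are averaged the same way (``weight_rule="mean"``).  All
    replicates must share the site axis; condition axes must agree as well
    since cells are averaged positionally.
    """
    profiles = list(profiles)
    if not profiles:
        raise ProfileError("need at least one replicate profile")
    if weight_rule != "mean":
        raise ValueError(f"unknown weight_rule {weight_rule!r}")
    ref = profiles[0]
    for k, prof in enumerate(profiles[1:], start=2):
        if prof.site_ids != ref.site_ids:
            raise AlignmentError(f"replicate {k}: site identifiers do not match replicate 1")
        if prof.shape != ref.shape:
            raise AlignmentError(f"replicate {k}: shape {prof.shape} != {ref.shape}")
    P = np.mean([p.P for p in profiles], axis=0)
    W = np.mean([p.W for p in profiles], axis=0)
    return MethylationProfile(ref.site_ids, ref.condition_ids, P, W, alpha=ref.alpha)


def _axis_index(axis) -> int:
    if axis in ("rows", "row", 1):
        return 1  # reduce over columns -> per-row statistics
    if axis in ("columns", "column", "cols", 0):
        return 0
    raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")


def minmax_normalize(X: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Per-row (or per-column) min-max rescaling onto [0, 1].

    Constant slices have no dynamic range and are mapped to all-zeros, which
    makes them inert in the signature scores downstream.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ProfileError("cannot normalize an empty matrix")
    if not np.all(np.isfinite(X)):
        raise ProfileError("matrix contains non-finite values")
    ax = _axis_index(axis)
    lo = X.min(axis=ax, keepdims=True)
    span = X.max(axis=ax, keepdims=True) - lo
    out = np.zeros_like(X)
    np.divide(X - lo, span, out=out, where=span > 0)
    return out


def zscore_normalize(X: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Per-row (or per-column) standardisation to mean 0, sd 1.

    Used by the plain (unweighted) ISA mode.  Zero-variance slices map to
    zeros.  The sd uses the population convention (ddof=0).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ProfileError("cannot normalize an empty matrix")
    if not np.all(np.isfinite(X)):
        raise ProfileError("matrix contains non-finite values")
    ax = _axis_index(axis)
    mu = X.mean(axis=ax, keepdims=True)
    sd = X.std(axis=ax, keepdims=True)
    out = np.zeros_like(X)
    np.divide(X - mu, sd, out=out, where=sd > 0)
    return out


def normalize_profile(profile: MethylationProfile, mode: str = "minmax") -> NormalizedProfile:
    """Build the (P^R, P^C) pair used by the signature iteration.

    ``mode="minmax"`` is the weighted algorithm's choice; ``mode="zscore"``
    is the conventional-ISA preprocessing.
    """
    if mode == "minmax":
        fn = minmax_normalize
    elif mode == "zscore":
        fn = zscore_normalize
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizedProfile(P_R=fn(profile.P, "rows"), P_C=fn(profile.P, "columns"))
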