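"""Automatic (T_R, T_C) threshold selection for the signature search.

The thresholds control bicluster stringency, and the right values depend on
the data scale.  The tuner runs the search over a threshold grid and distils
the block-count landscape into one (T_R, T_C) pair and a block count:

1. **Grid scan** — at each grid pair the search is repeated several times
   (distinct derived seeds); the per-pair block count is the mode over
   repeats, giving the count matrix L.
2. **Upper shrink** — keep only thresholds at or below the pair(s) attaining
   the maximum of L: the same count is reachable with smaller thresholds,
   which retain more sites/conditions per block.
3. **Lower shrink** — globally min-max normalise L, compute per-row and
   per-column (population) variances; drop the leading rows/columns whose
   variance sits below the respective variance mean.  Near the grid origin
   the count barely moves (one giant block), carrying no information.
4. **Stability window** — a sliding window of odd size
   eta = 2*ceil(0.1/step) + 1 per axis (clipped at the borders) marks a grid
   cell stable when the windowed mode equals the centre value; S = L' * LS.
5. **Count vote** — the relative frequency f of each nonzero count in S is
   tabulated; the modal count wins (ties to the smaller count).
6. **ASwC filter** — among stable pairs yielding the winning count, keep
   those with below-mean ASwC (undefined ASwC excludes a pair).
7. **SDwC argmax** — return the survivor maximising SDwC; ties resolve to
   the lexicographically smallest (T_R, T_C).

All mode-style tie-breaks go to the smaller value, consistent with the
preference for smaller thresholds (larger, more informative blocks).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as _metrics
from .isa import run_rewisa
from .profiles import MethylationProfile, normalize_profile

__all__ = [
    "TuningError",
    "ThresholdGrid",
    "GridScan",
    "StabilityResult",
    "TuningSelection",
    "scan_grid",
    "shrink_upper",
    "shrink_lower",
    "window_sizes",
    "stability_filter",
    "select_lfb_number",
    "aswc_filter",
    "sdwc_select",
    "optimize_thresholds",
    "RewISATuner",
]

logger = logging.getLogger(__name__)


class TuningError(RuntimeError):
    """Threshold optimisation could not proceed (e.g. no blocks anywhere)."""


def _grid_values(lo: float, hi: float, step: float) -> tuple:
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return tuple(round(lo + k * step, 10) for k in range(n))


@dataclass(frozen=True)
class ThresholdGrid:
    """The T_R x T_C lattice scanned by the tuner."""

    tr_values: tuple = field(default_factory=lambda: _grid_values(0.1, 5.0, 0.1))
    tc_values: tuple = field(default_factory=lambda: _grid_values(0.05, 3.0, 0.05))

    def __post_init__(self):
        tr = tuple(float(x) for x in self.tr_values)
        tc = tuple(float(x) for x in self.tc_values)
        for name, vals in (("tr_values", tr), ("tc_values", tc)):
            if not vals:
                raise TuningError(f"{name} is empty")
            if any(v <= 0 for v in vals) or any(b <= a for a, b in zip(vals, vals[1:])):
                raise TuningError(f"{name} must be strictly ascending and positive")
        object.__setattr__(self, "tr_values", tr)
        object.__setattr__(self, "tc_values", tc)

    @classmethod
    def from_ranges(cls, tr_min=0.1, tr_max=5.0, tr_step=0.1,
                    tc_min=0.05, tc_max=3.0, tc_step=0.05) -> "ThresholdGrid":
        if tr_step <= 0 or tc_step <= 0:
            raise TuningError("grid step sizes must be positive")
        return cls(_grid_values(tr_min, tr_max, tr_step), _grid_values(tc_min, tc_max, tc_step))

    @property
    def step_r(self) -> float:
        return self.tr_values[1] - self.tr_values[0] if len(self.tr_values) > 1 else 0.1

    @property
    def step_c(self) -> float:
        return self.tc_values[1] - self.tc_values[0] if len(self.tc_values) > 1 else 0.05

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.tr_values), len(self.tc_values)


@dataclass(frozen=True)
class GridScan:
    """Modal block counts L over a grid, plus the blocks backing the metrics.

    ``lfbs[(i, j)]`` holds the block list of the first repeat that achieved
    the modal count at grid cell (i, j) — the blocks the ASwC/SDwC surfaces
    are computed from.
    """

    grid: ThresholdGrid
    L: np.ndarray              # (rn, cn) modal counts
    repeats: int
    lfbs: dict

    def subset(self, row_idx, col_idx) -> "GridScan":
        row_idx = list(row_idx)
        col_idx = list(col_idx)
        grid = ThresholdGrid(
            tuple(self.grid.tr_values[i] for i in row_idx),
            tuple(self.grid.tc_values[j] for j in col_idx),
        )
        L = self.L[np.ix_(row_idx, col_idx)]
        remap = {
            (a, b): self.lfbs[(i, j)]
            for a, i in enumerate(row_idx)
            for b, j in enumerate(col_idx)
            if (i, j) in self.lfbs
        }
        return GridScan(grid=grid, L=L, repeats=self.repeats, lfbs=remap)


@dataclass(frozen=True)
class StabilityResult:
    L_prime: np.ndarray
    LS: np.ndarray
    S: np.ndarray
    f: dict                    # count -> relative frequency over nonzero S
    eta_r: int
    eta_c: int


@dataclass(frozen=True)
class TuningSelection:
    """Outcome of the full optimisation, with its audit trail."""

    t_r: float
    t_c: float
    n_lfbs: int
    audit: dict


def _mode_smallest(values) -> int:
    """Mode of an integer collection; ties resolve to the smaller value."""
    values = np.asarray(list(values), dtype=int)
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])   # uniq ascending, argmax takes first


def scan_grid(profile: MethylationProfile, grid: ThresholdGrid, repeats: int = 40,
              random_state: int = 0, **core_kwargs) -> GridScan:
    """Run the search over every grid pair, ``repeats`` times each.

    Per-repeat rng seeds derive deterministically from ``random_state`` and
    the (pair, repeat) index, so the scan is reproducible and could be
    sharded.  The per-pair count is the mode over repeats (ties to the
    smaller count); the block list of the first modal repeat is retained for
    the metric surfaces.
    """
    if repeats < 1:
        raise TuningError(f"repeats must be >= 1, got {repeats}")
    mode = core_kwargs.get("mode", "weighted-minmax")
    norm = normalize_profile(profile, "minmax" if mode == "weighted-minmax" else "zscore")
    rn, cn = grid.shape
    L = np.zeros((rn, cn), dtype=int)
    stored: dict = {}
    for i, t_r in enumerate(grid.tr_values):
        for j, t_c in enumerate(grid.tc_values):
            counts = []
            runs = []
            for rep in range(repeats):
                ss = np.random.SeedSequence(int(random_state), spawn_key=(i, j, rep))
                lfbs = run_rewisa(profile, t_r, t_c, random_state=np.random.default_rng(ss),
                                  norm=norm, **core_kwargs)
                counts.append(len(lfbs))
                runs.append(lfbs)
            modal = _mode_smallest(counts)
            L[i, j] = modal
            first = next(k for k, c in enumerate(counts) if c == modal)
            stored[(i, j)] = runs[first]
    return GridScan(grid=grid, L=L, repeats=repeats, lfbs=stored)


def shrink_upper(scan: GridScan) -> GridScan:
    """Drop thresholds above the componentwise maxima of the argmax-L pairs."""
    if scan.L.max() == 0:
        raise TuningError("no LFBs anywhere on the grid; cannot shrink thresholds")
    where = np.argwhere(scan.L == scan.L.max())
    i_max = where[:, 0].max()
    j_max = where[:, 1].max()
    return scan.subset(range(i_max + 1), range(j_max + 1))


def shrink_lower(scan: GridScan) -> GridScan:
    """Raise the lower bounds using the variance profile of normalised L.

    Rows/columns near the origin where the (globally min-max normalised)
    count surface is flat carry no selection signal; everything before the
    first row/column whose variance reaches the mean variance is dropped.
    """
    L = scan.L.astype(float)
    span = L.max() - L.min()
    if span == 0:
        logger.warning("count matrix is constant; lower bounds left unchanged")
        return scan
    Ln = (L - L.min()) / span
    vr = Ln.var(axis=1)          # population variance, per Eqs. with 1/cn
    vc = Ln.var(axis=0)
    i_first = int(np.flatnonzero(vr >= vr.mean())[0])
    j_first = int(np.flatnonzero(vc >= vc.mean())[0])
    return scan.subset(range(i_first, scan.grid.shape[0]), range(j_first, scan.grid.shape[1]))


def window_sizes(step_r: float, step_c: float) -> tuple[int, int]:
    """Odd sliding-window sizes eta = 2*ceil(0.1/step) + 1 per grid axis."""
    if step_r <= 0 or step_c <= 0:
        raise TuningError("grid step sizes must be positive")
    return (2 * math.ceil(0.1 / step_r - 1e-9) + 1, 2 * math.ceil(0.1 / step_c - 1e-9) + 1)


def stability_filter(L_prime: np.ndarray, eta_r: int, eta_c: int):
    """Mark grid cells whose windowed modal count equals the centre value.

    Windows are centred and clipped at the matrix boundary (only in-bounds
    cells vote).  Returns ``(LS, S, f)``: the stability mask, the stable
    count matrix S = L' * LS, and the relative frequency f of each nonzero
    count in S.
    """
    if eta_r < 1 or eta_c < 1 or eta_r % 2 == 0 or eta_c % 2 == 0:
        raise TuningError(f"window sizes must be odd and >= 1, got ({eta_r}, {eta_c})")
    L_prime = np.asarray(L_prime, dtype=int)
    rn, cn = L_prime.shape
    hr, hc = eta_r // 2, eta_c // 2
    LS = np.zeros_like(L_prime)
    for i in range(rn):
        for j in range(cn):
            window = L_prime[max(0, i - hr):i + hr + 1, max(0, j - hc):j + hc + 1]
            if _mode_smallest(window.ravel()) == L_prime[i, j]:
                LS[i, j] = 1
    S = L_prime * LS
    nz = S[S > 0]
    f = {}
    if nz.size:
        uniq, counts = np.unique(nz, return_counts=True)
        f = {int(u): float(c) / nz.size for u, c in zip(uniq, counts)}
    return LS, S, f


def select_lfb_number(f: dict) -> int:
    """The modal stable block count; frequency ties go to the smaller count."""
    if not f:
        raise TuningError("no stable nonzero block counts on the grid")
    best = max(f.values())
    return min(k for k, v in f.items() if v == best)


def aswc_filter(candidates: list, aswc_values: dict) -> list:
    """Keep candidate pairs whose ASwC is strictly below the candidate mean.

    Pairs with undefined (NaN) ASwC are excluded up front.  If the filter
    would empty the set (all survivors equal to the mean), every defined
    candidate is kept instead.
    """
    if not candidates:
        raise TuningError("no candidate threshold pairs to filter")
    defined = [c for c in candidates if np.isfinite(aswc_values[c])]
    if not defined:
        logger.warning("ASwC undefined for every candidate pair; keeping all")
        return list(candidates)
    mean = float(np.mean([aswc_values[c] for c in defined]))
    kept = [c for c in defined if aswc_values[c] < mean]
    if not kept:
        logger.warning("no candidate below the mean ASwC; keeping all defined pairs")
        return defined
    return kept


def sdwc_select(survivors: list, sdwc_values: dict, grid: ThresholdGrid) -> tuple:
    """The surviving pair maximising SDwC; ties to the smallest (T_R, T_C)."""
    if not survivors:
        raise TuningError("no surviving threshold pairs")
    best = max(sdwc_values[c] for c in survivors)
    tied = [c for c in survivors if sdwc_values[c] == best]
    return min(tied, key=lambda ij: (grid.tr_values[ij[0]], grid.tc_values[ij[1]]))


def optimize_thresholds(profile: MethylationProfile, grid: ThresholdGrid | None = None,
                        repeats: int = 40, random_state: int = 0,
                        **core_kwargs) -> TuningSelection:
    """Run the full threshold-optimisation pipeline on a profile.

    Composes grid scan, upper/lower range shrinking, sliding-window
    stability, the count vote, the ASwC filter and the SDwC argmax; the
    returned :class:`TuningSelection` carries an audit of every stage.
    Raises :class:`TuningError` (stage-named) when a stage leaves nothing.
    """
    grid = grid or ThresholdGrid()
    scan = scan_grid(profile, grid, repeats=repeats, random_state=random_state, **core_kwargs)
    audit: dict = {
        "grid": {"tr": list(grid.tr_values), "tc": list(grid.tc_values)},
        "L": scan.L.tolist(),
        "repeats": repeats,
    }
    upper = shrink_upper(scan)
    audit["upper_bounds"] = {"tr_max": upper.grid.tr_values[-1], "tc_max": upper.grid.tc_values[-1]}
    shrunk = shrink_lower(upper)
    audit["lower_bounds"] = {"tr_min": shrunk.grid.tr_values[0], "tc_min": shrunk.grid.tc_values[0]}
    audit["L_prime"] = shrunk.L.tolist()

    eta_r, eta_c = window_sizes(shrunk.grid.step_r, shrunk.grid.step_c)
    LS, S, f = stability_filter(shrunk.L, eta_r, eta_c)
    stability = StabilityResult(L_prime=shrunk.L, LS=LS, S=S, f=f,
                                eta_r=eta_r, eta_c=eta_c)
    audit.update({"eta_r": eta_r, "eta_c": eta_c, "LS": LS.tolist(), "S": S.tolist(),
                  "f": {str(k): v for k, v in f.items()}})
    n_lfbs = select_lfb_number(stability.f)
    audit["n_lfbs"] = n_lfbs

    P, W = profile.P, profile.W
    candidates = [tuple(ij) for ij in np.argwhere(S == n_lfbs)]
    aswc_values: dict = {}
    sdwc_values: dict = {}
    for ij in candidates:
        lfbs = shrunk.lfbs[ij]
        try:
            aswc_values[ij] = _metrics.aswc(lfbs, P, W)
        except ValueError:
            aswc_values[ij] = float("nan")
        sdwc_values[ij] = _metrics.sdwc(lfbs, P, W)
    audit["aswc"] = {str(ij): aswc_values[ij] for ij in candidates}
    audit["sdwc"] = {str(ij): sdwc_values[ij] for ij in candidates}

    survivors = aswc_filter(candidates, aswc_values)
    audit["aswc_survivors"] = [list(map(int, ij)) for ij in survivors]
    i, j = sdwc_select(survivors, sdwc_values, shrunk.grid)
    t_r = shrunk.grid.tr_values[i]
    t_c = shrunk.grid.tc_values[j]
    audit["selected"] = {"T_R": t_r, "T_C": t_c, "n_lfbs": n_lfbs}
    return TuningSelection(t_r=t_r, t_c=t_c, n_lfbs=n_lfbs, audit=audit)


class RewISATuner(BaseEstimator):
    """Grid-search threshold selection wrapped as an estimator.

    ``fit(X, weights=...)`` runs the full optimisation and then refits the
    search at the selected thresholds.

    Attributes
    ----------
    t_r_, t_c_ : float
        Selected thresholds.
    n_lfbs_ : int
        Selected block count.
    lfbs_ : list of LFB
        Blocks of the modal repeat at the selected grid cell.
    audit_ : dict
        Intermediate matrices of every tuning stage.
    """

    def __init__(self, *, tr_min=0.1, tr_max=5.0, tr_step=0.1,
                 tc_min=0.05, tc_max=3.0, tc_step=0.05, repeats=40,
                 n_seeds=100, seed_fraction=0.02, epsilon=0.01, max_iter=100,
                 mode="weighted-minmax", selection="auto", dedup_jaccard=0.9,
                 min_basin=0.05, random_state=0):
        self.tr_min = tr_min
        self.tr_max = tr_max
        self.tr_step = tr_step
        self.tc_min = tc_min
        self.tc_max = tc_max
        self.tc_step = tc_step
        self.repeats = repeats
        self.n_seeds = n_seeds
        self.seed_fraction = seed_fraction
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.mode = mode
        self.selection = selection
        self.dedup_jaccard = dedup_jaccard
        self.min_basin = min_basin
        self.random_state = random_state

    def _core_kwargs(self) -> dict:
        return dict(n_seeds=self.n_seeds, seed_fraction=self.seed_fraction,
                    epsilon=self.epsilon, max_iter=self.max_iter, mode=self.mode,
                    selection=self.selection, dedup_jaccard=self.dedup_jaccard,
                    min_basin=self.min_basin)

    def fit(self, X, y=None, *, weights=None):
        if isinstance(X, MethylationProfile):
            profile = X
        else:
            X = np.asarray(X, dtype=float)
            if weights is None:
                raise ValueError("pass weights= alongside a plain array")
            sites = [f"site_{i}" for i in range(X.shape[0])]
            conds = [f"cond_{j}" for j in range(X.shape[1])]
            profile = MethylationProfile(sites, conds, X, np.asarray(weights, dtype=float))
        grid = ThresholdGrid.from_ranges(self.tr_min, self.tr_max, self.tr_step,
                                         self.tc_min, self.tc_max, self.tc_step)
        sel = optimize_thresholds(profile, grid, repeats=self.repeats,
                                  random_state=self.random_state, **self._core_kwargs())
        self.t_r_ = sel.t_r
        self.t_c_ = sel.t_c
        self.n_lfbs_ = sel.n_lfbs
        self.audit_ = sel.audit
        ss = np.random.SeedSequence(int(self.random_state), spawn_key=(2**16,))
        self.lfbs_ = run_rewisa(profile, sel.t_r, sel.t_c,
                                random_state=np.random.default_rng(ss), **self._core_kwargs())
        return self
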