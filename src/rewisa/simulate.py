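"""Synthetic MeRIP-Seq-like counts with planted co-methylation blocks.

Each cell of the site-by-condition matrix gets a total coverage
n_ij ~ NegBin(mean mu, dispersion r) and a methylation proportion
theta_ij ~ Beta(a, b), where (a, b) comes from the planted block covering the
cell, or from the background component otherwise; the IP count is then
t_ij ~ Binomial(n_ij, theta_ij) and the input count h_ij = n_ij - t_ij.
Marginally each cell is therefore beta-binomial, and the default
configuration is a mixture of four beta-binomials: three disjoint
hyper-methylated blocks (Beta(9, 1), mean level 0.9) over a symmetric
background (Beta(2, 2), mean level 0.5).

The default geometry — a 1000 x 15 matrix with three 150-site x 5-condition
blocks on disjoint ranges — is the study condition for the recovery
experiments; the planted rectangles double as ground-truth masks for SoBC
scoring.  Expression weights are *not* simulated separately: they derive
from the simulated counts through the standard quantification, exactly as
for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .isa import LFB
from .profiles import CountProfile, MethylationProfile, quantify_methylation

__all__ = ["BlockSpec", "SimulationSpec", "SyntheticDataset", "generate", "truth_masks"]


@dataclass(frozen=True)
class BlockSpec:
    """One planted block: half-open site/condition ranges and its beta law."""

    sites: tuple          # (start, stop), half-open
    conditions: tuple     # (start, stop), half-open
    a: float = 9.0
    b: float = 1.0

    def site_range(self) -> range:
        return range(int(self.sites[0]), int(self.sites[1]))

    def condition_range(self) -> range:
        return range(int(self.conditions[0]), int(self.conditions[1]))


def _default_blocks() -> tuple:
    return (
        BlockSpec(sites=(0, 150), conditions=(0, 5)),
        BlockSpec(sites=(150, 300), conditions=(5, 10)),
        BlockSpec(sites=(300, 450), conditions=(10, 15)),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the beta-binomial mixture simulator.

    ``background`` is the (a, b) of the non-block component; ``coverage_mean``
    and ``coverage_dispersion`` parameterise the negative-binomial total
    coverage (variance mu + mu^2 / dispersion).
    """

    n_sites: int = 1000
    n_conditions: int = 15
    blocks: tuple = field(default_factory=_default_blocks)
    background: tuple = (2.0, 2.0)
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    allow_overlap: bool = False

    def __post_init__(self):
        for blk in self.blocks:
            if not (0 <= blk.sites[0] < blk.sites[1] <= self.n_sites):
                raise ValueError(f"block site range {blk.sites} outside [0, {self.n_sites})")
            if not (0 <= blk.conditions[0] < blk.conditions[1] <= self.n_conditions):
                raise ValueError(
                    f"block condition range {blk.conditions} outside [0, {self.n_conditions})"
                )
            if blk.a <= 0 or blk.b <= 0:
                raise ValueError("beta parameters must be positive")
        if self.background[0] <= 0 or self.background[1] <= 0:
            raise ValueError("background beta parameters must be positive")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage mean and dispersion must be positive")
        if not self.allow_overlap:
            seen = np.zeros((self.n_sites, self.n_conditions), dtype=bool)
            for blk in self.blocks:
                cells = np.ix_(blk.site_range(), blk.condition_range())
                if seen[cells].any():
                    raise ValueError("planted blocks overlap (set allow_overlap=True to permit)")
                seen[cells] = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        blocks = tuple(
            BlockSpec(sites=tuple(b["sites"]), conditions=tuple(b["conditions"]),
                      a=float(b.get("a", 9.0)), b=float(b.get("b", 1.0)))
            for b in d.pop("blocks", [])
        ) or _default_blocks()
        d["background"] = tuple(d.get("background", (2.0, 2.0)))
        return cls(blocks=blocks, **d)


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated counts, their quantified profile, and the planted truth."""

    counts: CountProfile
    truth: tuple          # tuple of LFB, one per planted block
    spec: SimulationSpec

    def profile(self, alpha: float = 1e-6) -> MethylationProfile:
        return quantify_methylation(self.counts, alpha=alpha)


def generate(spec: SimulationSpec | None = None, random_state=None) -> SyntheticDataset:
    """Draw one synthetic dataset; bit-reproducible for a fixed random_state."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(random_state)
    shape = (spec.n_sites, spec.n_conditions)

    a = np.full(shape, spec.background[0])
    b = np.full(shape, spec.background[1])
    for blk in spec.blocks:
        cells = np.ix_(blk.site_range(), blk.condition_range())
        a[cells] = blk.a
        b[cells] = blk.b

    r = spec.coverage_dispersion
    p_nb = r / (r + spec.coverage_mean)
    coverage = rng.negative_binomial(r, p_nb, size=shape)
    theta = rng.beta(a, b, size=shape)
    t = rng.binomial(coverage, theta)
    h = coverage - t

    site_ids = [f"site_{i}" for i in range(spec.n_sites)]
    cond_ids = [f"cond_{j}" for j in range(spec.n_conditions)]
    counts = CountProfile(site_ids, cond_ids, t.astype(float), h.astype(float))
    truth = tuple(
        LFB(sites=tuple(blk.site_range()), conditions=tuple(blk.condition_range()),
            t_r=float("nan"), t_c=float("nan"))
        for blk in spec.blocks
    )
    return SyntheticDataset(counts=counts, truth=truth, spec=spec)


def truth_masks(dataset: SyntheticDataset) -> list:
    """One rectangular cell-index set (frozenset of (i, j)) per planted block."""
    return [
        frozenset((i, j) for i in blk.sites for j in blk.conditions)
        for blk in dataset.truth
    ]
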