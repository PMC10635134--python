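"""Weighted-ensemble resampling with minimal adaptive binning.

Many weighted trajectory replicas ("walkers") are propagated in parallel;
after each propagation interval the progress coordinate is re-binned,
under-populated bins split their heaviest walkers and over-populated bins
merge their lightest ones, conserving total probability exactly.  Binning
follows a minimal adaptive scheme: one bin tracks the lagging (minimum)
walker, one the leading (maximum) walker, and the remaining bins tile the
interval between them linearly, so the layout follows the ensemble as it
advances.

The propagator is pluggable; an overdamped-Langevin double well stands in
for a molecular-dynamics engine at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "Walker",
    "WEConfig",
    "BinLayout",
    "mab_bins",
    "split_merge",
    "run_we",
    "DoubleWell",
    "double_well_propagator",
]


@dataclass(frozen=True)
class Walker:
    """A weighted trajectory replica."""

    state: Any
    pcoord: float
    weight: float

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError("walker weight must be positive")
        if not math.isfinite(self.pcoord):
            raise ValueError("walker progress coordinate must be finite")


@dataclass(frozen=True)
class WEConfig:
    n_bins: int = 15
    target_per_bin: int = 8
    n_iterations: int = 600
    tau_steps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError("minimal adaptive binning needs n_bins >= 3")
        if self.target_per_bin < 1:
            raise ValueError("target_per_bin must be >= 1")


@dataclass(frozen=True)
class BinLayout:
    """Bin layout: lagging bin, linear interior bins, leading bin.

    ``boundaries`` has n_bins−1 strictly increasing interior edges; bin 0 is
    (−∞, b0] restricted to the current minimum walker, bin n−1 the maximum.
    Assignment: the walker(s) at the current minimum go to bin 0, at the
    maximum to bin n−1, everything else to the linear bin its pcoord falls in.
    """

    boundaries: tuple[float, ...]
    lo: float
    hi: float
    n_bins: int

    def assign(self, pcoords: Sequence[float]) -> np.ndarray:
        p = np.asarray(pcoords, dtype=float)
        edges = np.asarray(self.boundaries)
        idx = np.searchsorted(edges, p, side="right")  # 0..n_bins-1 over edges
        inner = np.clip(idx, 0, self.n_bins - 3) + 1  # interior bins 1..n-2
        out = np.where(p <= self.lo, 0, np.where(p >= self.hi, self.n_bins - 1, inner))
        return out.astype(int)


def mab_bins(pcoords: Sequence[float], n_bins: int = 15) -> BinLayout:
    """Minimal adaptive binning over the current walker pcoords.

    One bin each for the lagging (min) and leading (max) walkers; n_bins−2
    bins linearly spaced between them.  A degenerate all-equal ensemble gets
    a symmetric ε-width layout centred on the common value.
    """
    if n_bins < 3:
        raise ValueError("minimal adaptive binning needs n_bins >= 3")
    p = np.asarray(pcoords, dtype=float)
    if p.size == 0:
        raise ValueError("mab_bins needs at least one pcoord")
    lo, hi = float(p.min()), float(p.max())
    if hi - lo < 1e-12:
        eps = max(1e-9, abs(lo) * 1e-9)
        lo, hi = lo - eps, lo + eps
    interior = np.linspace(lo, hi, n_bins - 1)  # n_bins-2 linear bins
    return BinLayout(boundaries=tuple(interior[1:-1]) if n_bins > 3 else (),
                     lo=lo, hi=hi, n_bins=n_bins)


def _split(walkers: list[Walker], target: int) -> list[Walker]:
    # split the heaviest walker into enough equal-weight copies in one shot
    while len(walkers) < target:
        walkers.sort(key=lambda w: (-w.weight,))
        top = walkers.pop(0)
        n_copies = target - len(walkers)
        walkers.extend(replace(top, weight=top.weight / n_copies) for _ in range(n_copies))
    return walkers


def _merge(walkers: list[tuple[int, Walker]], target: int, rng: np.random.Generator) -> list[tuple[int, Walker]]:
    # iteratively merge the two lightest; survivor drawn ∝ weight,
    # equal weights resolved toward the lower original index
    while len(walkers) > target:
        walkers.sort(key=lambda iw: (iw[1].weight, iw[0]))
        (ia, wa), (ib, wb) = walkers[0], walkers[1]
        total = wa.weight + wb.weight
        if wa.weight == wb.weight:
            keep_first = ia < ib  # deterministic tie-break: lowest index wins
        else:
            keep_first = rng.random() < wa.weight / total
        idx, survivor = (ia, wa) if keep_first else (ib, wb)
        walkers = walkers[2:]
        walkers.append((idx, replace(survivor, weight=total)))
    return walkers


def split_merge(walkers: Sequence[Walker],
                layout: BinLayout,
                target_per_bin: int,
                rng: np.random.Generator) -> list[Walker]:
    """Resample so every occupied bin holds exactly ``target_per_bin`` walkers.

    Total weight is conserved to machine precision; empty bins are untouched.
    """
    total_in = sum(w.weight for w in walkers)
    bins = layout.assign([w.pcoord for w in walkers])
    out: list[Walker] = []
    for b in range(layout.n_bins):
        members = [(i, w) for i, w in enumerate(walkers) if bins[i] == b]
        if not members:
            continue
        if len(members) > target_per_bin:
            members = _merge(members, target_per_bin, rng)
        bin_walkers = [w for _, w in sorted(members, key=lambda iw: iw[0])]
        if len(bin_walkers) < target_per_bin:
            bin_walkers = _split(bin_walkers, target_per_bin)
        out.extend(bin_walkers)
    total_out = sum(w.weight for w in out)
    if abs(total_out - total_in) > 1e-12 * max(1.0, total_in):
        raise AssertionError("weight conservation broken in split/merge")
    return out


@dataclass
class WEIteration:
    iteration: int
    walkers: list[Walker]
    layout: BinLayout

    @property
    def total_weight(self) -> float:
        return sum(w.weight for w in self.walkers)


def run_we(propagator: Callable[[Any, int, np.random.Generator], Any],
           pcoord_fn: Callable[[Any], float],
           config: WEConfig,
           initial_states: Sequence[Any]) -> list[WEIteration]:
    """Run weighted-ensemble resampling; fully reproducible from the seed.

    Each iteration: propagate every walker for ``tau_steps``, recompute the
    progress coordinate, rebuild the adaptive bins, then split/merge to the
    per-bin target.  Walkers start with equal weights summing to one.
    """
    if not initial_states:
        raise ValueError("need at least one initial state")
    n0 = len(initial_states)
    walkers = [Walker(state=s, pcoord=pcoord_fn(s), weight=1.0 / n0) for s in initial_states]
    layout = mab_bins([w.pcoord for w in walkers], config.n_bins)
    history = [WEIteration(0, list(walkers), layout)]
    master = np.random.SeedSequence(config.seed)
    for it in range(1, config.n_iterations + 1):
        it_seed, resample_seed, master = master.spawn(3)
        child_seeds = it_seed.spawn(len(walkers))
        new_walkers = []
        for w, ss in zip(walkers, child_seeds):
            rng = np.random.default_rng(ss)
            try:
                state = propagator(w.state, config.tau_steps, rng)
            except Exception as exc:
                raise RuntimeError(f"propagator failed at iteration {it}") from exc
            new_walkers.append(Walker(state=state, pcoord=pcoord_fn(state), weight=w.weight))
        layout = mab_bins([w.pcoord for w in new_walkers], config.n_bins)
        walkers = split_merge(new_walkers, layout, config.target_per_bin,
                              np.random.default_rng(resample_seed))
        history.append(WEIteration(it, list(walkers), layout))
    return history


# ---------------------------------------------------------------------------
# toy propagator: overdamped Langevin dynamics on a 1-D double well
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoubleWell:
    """U(x) = h ((x/w)² − 1)²: minima at ±w, barrier height h at x = 0."""

    barrier: float = 4.0  # h, in units of kT when kT = 1
    half_width: float = 1.0  # w

    def potential(self, x: float | np.ndarray) -> float | np.ndarray:
        s = (np.asarray(x) / self.half_width) ** 2 - 1.0
        return self.barrier * s * s

    def force(self, x: float | np.ndarray) -> float | np.ndarray:
        w2 = self.half_width ** 2
        return -4.0 * self.barrier * np.asarray(x) * ((np.asarray(x) ** 2 / w2) - 1.0) / w2

    def boltzmann_well_probability(self, side: str = "+", kT: float = 1.0,
                                   span: float = 6.0, n: int = 200001) -> float:
        """Equilibrium probability of one well by numerical quadrature."""
        x = np.linspace(-span * self.half_width, span * self.half_width, n)
        p = np.exp(-self.potential(x) / kT)
        z = np.trapezoid(p, x)
        mask = x > 0 if side == "+" else x < 0
        return float(np.trapezoid(np.where(mask, p, 0.0), x) / z)


def double_well_propagator(x: float, n_steps: int, dt: float, kT: float,
                           rng: np.random.Generator,
                           well: DoubleWell | None = None) -> float:
    """Overdamped Langevin steps on the double well (unit friction).

    x ← x + F(x) dt + √(2 kT dt) ξ.  With kT = 0 a minimum is a fixed point.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    well = well or DoubleWell()
    x = float(x)
    if kT > 0:
        noise = rng.standard_normal(n_steps) * math.sqrt(2.0 * kT * dt)
    else:
        noise = np.zeros(n_steps)
    h, w2 = well.barrier, well.half_width ** 2
    for k in range(n_steps):
        f = -4.0 * h * x * ((x * x / w2) - 1.0) / w2
        x = x + f * dt + noise[k]
    return x
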