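"""Synthetic data with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_tree` — forward birth-death simulation from two crown
  lineages, with optional instantaneous mass-extinction events (independent
  per-lineage Bernoulli survival), optional smooth time dependence of the
  rates, per-tip Bernoulli(rho) sampling, and rejection resampling until the
  sampled tip count falls in an acceptance window with at least one sampled
  descendant on each side of the root (so the reconstructed crown age equals
  the simulated crown age, matching the likelihood's conditioning).
* :func:`simulate_temperature` — a Cenozoic-style cooling curve: warm
  plateau, sigmoid drop centred on a configurable midpoint (default the
  Eocene-Oligocene boundary at 34 Ma), Gaussian observation noise.
* :func:`make_clade_fixture` — categorical clade tables in the fossil-table
  schema, with the observability asymmetry of the real record (extinct
  clades have unknown colonization status).

All randomness flows from one integer seed through a counter-based Philox
generator, so runs are reproducible and platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, PulseTreeError
from .envmodels import EnvCurve, smooth_series
from .treeio import TimeTree, read_newick


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed))


class AcceptanceWindowError(PulseTreeError):
    """Rejection sampling exhausted its attempt budget."""


# ---------------------------------------------------------------------------
# birth-death tree simulation
# ---------------------------------------------------------------------------


@dataclass
class TreeSimConfig:
    """Study conditions for one batch of simulated trees.

    Defaults emulate the empirical setting all scan analyses assume: crown
    age 50 Ma, sampling fraction 0.74, and a sampled-tip acceptance window
    of 60-130 (the empirical tree has 89 tips).
    """

    crown_age: float = 50.0
    lambda0: float = 0.25
    mu0: float = 0.11
    lambda_fn: Optional[Callable] = None  # age -> rate; overrides lambda0
    mu_fn: Optional[Callable] = None
    events: Sequence[tuple] = ()  # (age, survival probability)
    rho: float = 0.74
    min_tips: Optional[int] = 60
    max_tips: Optional[int] = 130
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.lambda0 < 0 or self.mu0 < 0:
            raise DomainError("rates must be non-negative")
        if not 0 < self.rho <= 1:
            raise DomainError("rho must lie in (0, 1]")
        for age, s in self.events:
            if not 0 < age < self.crown_age:
                raise DomainError("event ages must lie inside (0, crown_age)")
            if not 0 <= s <= 1:
                raise DomainError("event survival must lie in [0, 1]")

    def truth(self) -> dict:
        d = {
            "crown_age": self.crown_age,
            "lambda0": self.lambda0,
            "mu0": self.mu0,
            "events": [list(e) for e in self.events],
            "rho": self.rho,
            "min_tips": self.min_tips,
            "max_tips": self.max_tips,
            "seed": self.seed,
        }
        return d


class _Lineage:
    __slots__ = ("parent", "birth_age", "end_age", "children", "sampled")

    def __init__(self, parent, birth_age):
        self.parent = parent
        self.birth_age = birth_age
        self.end_age = None  # age at which it speciated/died; 0.0 if extant
        self.children = []
        self.sampled = False


def _forward_once(cfg: TreeSimConfig, rng: np.random.Generator):
    """One forward pass; returns (root_children, extant lineages)."""
    lam_fn, mu_fn = cfg.lambda_fn, cfg.mu_fn
    const = lam_fn is None and mu_fn is None
    if not const:
        probe = np.linspace(0.0, cfg.crown_age, 2001)
        lam_probe = lam_fn(probe) if lam_fn else np.full_like(probe, cfg.lambda0)
        mu_probe = mu_fn(probe) if mu_fn else np.full_like(probe, cfg.mu0)
        bound = float(np.max(lam_probe + mu_probe)) * 1.05 + 1e-12

    events = sorted(cfg.events, key=lambda e: -e[0])  # oldest first
    left = _Lineage(None, cfg.crown_age)
    right = _Lineage(None, cfg.crown_age)
    alive = [left, right]
    age = cfg.crown_age
    ev_i = 0
    while alive and age > 0:
        n = len(alive)
        if const:
            total = n * (cfg.lambda0 + cfg.mu0)
            dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        else:
            dt = rng.exponential(1.0 / (n * bound))
        next_age = age - dt
        # mass-extinction events between age and next_age: thinning applied
        # to lineages alive at exactly the event age, before any same-age
        # speciation
        while ev_i < len(events) and events[ev_i][0] >= max(next_age, 0.0):
            e_age, s = events[ev_i]
            if e_age > age:
                ev_i += 1
                continue
            survive = rng.random(len(alive)) < s
            for lin, ok in zip(alive, survive):
                if not ok:
                    lin.end_age = e_age
            alive = [lin for lin, ok in zip(alive, survive) if ok]
            ev_i += 1
            if not alive:
                return [left, right], []
        if next_age <= 0:
            break
        age = next_age
        if const:
            lam_here, mu_here = cfg.lambda0, cfg.mu0
        else:
            lam_here = float(lam_fn(age)) if lam_fn else cfg.lambda0
            mu_here = float(mu_fn(age)) if mu_fn else cfg.mu0
            if rng.random() >= (lam_here + mu_here) / bound:
                continue  # thinned-out candidate event
        idx = rng.integers(len(alive))
        lin = alive[idx]
        if rng.random() < lam_here / (lam_here + mu_here):
            lin.end_age = age
            c1, c2 = _Lineage(lin, age), _Lineage(lin, age)
            lin.children = [c1, c2]
            alive[idx] = c1
            alive.append(c2)
        else:
            lin.end_age = age
            alive.pop(idx)
    for lin in alive:
        lin.end_age = 0.0
    return [left, right], alive


def _reconstruct_newick(root_children, crown_age: float) -> str:
    """Newick of the reconstructed tree over sampled tips, rooted at the
    crown with both sides represented (caller guarantees this)."""
    counter = [0]

    def rec(lin, top_age):
        # returns newick fragment for the sampled part below ``lin`` with a
        # branch starting at top_age, or None
        while True:
            if lin.end_age == 0.0 and lin.sampled and not lin.children:
                counter[0] += 1
                return f"t{counter[0]}:{top_age:.12g}"
            kept = [c for c in lin.children if _has_sampled(c)]
            if len(kept) == 2:
                a = rec(kept[0], lin.end_age)
                b = rec(kept[1], lin.end_age)
                return f"({a},{b}):{top_age - lin.end_age:.12g}"
            if len(kept) == 1:
                lin = kept[0]  # suppress unifurcation; branch keeps top_age
                continue
            return None

    memo = {}

    def _has_sampled(lin):
        key = id(lin)
        if key in memo:
            return memo[key]
        if not lin.children:
            out = lin.end_age == 0.0 and lin.sampled
        else:
            out = any(_has_sampled(c) for c in lin.children)
        memo[key] = out
        return out

    parts = [rec(lin, crown_age) for lin in root_children]
    return f"({parts[0]},{parts[1]});"


def simulate_tree(cfg: TreeSimConfig):
    """Simulate one reconstructed ultrametric tree; returns
    ``(TimeTree, truth_record)``.

    Raises :class:`AcceptanceWindowError` with diagnostics if the acceptance
    window cannot be reached within ``cfg.max_attempts`` forward passes.
    """
    rng = _rng(cfg.seed)
    counts = []
    for attempt in range(1, cfg.max_attempts + 1):
        root_children, extant = _forward_once(cfg, rng)
        if extant:
            sampled_mask = rng.random(len(extant)) < cfg.rho
            for lin, ok in zip(extant, sampled_mask):
                lin.sampled = bool(ok)
        n_sampled = sum(lin.sampled for lin in extant)
        counts.append(n_sampled)
        if n_sampled < 2:
            continue
        if cfg.min_tips is not None and n_sampled < cfg.min_tips:
            continue
        if cfg.max_tips is not None and n_sampled > cfg.max_tips:
            continue
        left_ok = any(lin.sampled for lin in _tips_below(root_children[0]))
        right_ok = any(lin.sampled for lin in _tips_below(root_children[1]))
        if not (left_ok and right_ok):
            continue
        newick = _reconstruct_newick(root_children, cfg.crown_age)
        tree = read_newick(newick)
        truth = cfg.truth()
        truth.update(
            {
                "n_extant": len(extant),
                "n_sampled": n_sampled,
                "attempts": attempt,
            }
        )
        return tree, truth
    raise AcceptanceWindowError(
        f"no accepted tree in {cfg.max_attempts} attempts; sampled-tip counts: "
        f"min={min(counts)}, median={int(np.median(counts))}, max={max(counts)}, "
        f"window=[{cfg.min_tips}, {cfg.max_tips}]"
    )


def _tips_below(lin):
    stack = [lin]
    while stack:
        x = stack.pop()
        if x.children:
            stack.extend(x.children)
        elif x.end_age == 0.0:
            yield x


# ---------------------------------------------------------------------------
# temperature curves
# ---------------------------------------------------------------------------


@dataclass
class TempSimConfig:
    """A greenhouse-to-icehouse cooling curve: plateau at ``baseline``, a
    sigmoid drop of ``drop_magnitude`` centred at ``drop_midpoint``, and
    iid Gaussian noise.  The noiseless maximum cooling rate is
    ``drop_magnitude / (4 * drop_width)`` per Myr, reached at the midpoint
    (defaults give ~17 per Myr, the steepest drop of the era)."""

    baseline: float = 25.0
    drop_midpoint: float = 34.0
    drop_magnitude: float = 8.0
    drop_width: float = 0.12
    noise_sd: float = 0.5
    grid_step: float = 0.05
    support: tuple = (0.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.drop_width <= 0:
            raise DomainError("drop_width must be positive")
        if self.grid_step <= 0:
            raise DomainError("grid_step must be positive")

    @property
    def max_drop_rate(self) -> float:
        return self.drop_magnitude / (4.0 * self.drop_width)


@dataclass
class TempSimResult:
    grid: np.ndarray  # (n, 2) raw (age, value)
    curve: EnvCurve  # smoothed
    config: TempSimConfig


def simulate_temperature(cfg: TempSimConfig, knots: int = 300) -> TempSimResult:
    """Deterministic given the seed; returns the raw grid and its P-spline
    smooth."""
    rng = _rng(cfg.seed)
    lo, hi = cfg.support
    ages = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    vals = cfg.baseline - cfg.drop_magnitude / (
        1.0 + np.exp((ages - cfg.drop_midpoint) / cfg.drop_width)
    )
    if cfg.noise_sd > 0:
        vals = vals + rng.normal(0.0, cfg.noise_sd, size=len(ages))
    grid = np.column_stack([ages, vals])
    curve = smooth_series(grid, knots=knots)
    return TempSimResult(grid=grid, curve=curve, config=cfg)


# ---------------------------------------------------------------------------
# clade-table fixtures
# ---------------------------------------------------------------------------

CLADE_COLUMNS = [
    "name",
    "taxon_class",
    "status",
    "widespread",
    "dispersal_advantaged",
    "colonized_early",
    "crossed_eo",
    "arrival_period",
]


def make_clade_fixture(
    n_extinct: int = 50,
    n_extant: int = 25,
    p_colonize: float = 0.44,
    p_widespread: float = 0.5,
    p_dispersal: float = 0.36,
    p_crossed_eo: float = 0.22,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli-sampled clade table in the fossil-table CSV schema.

    Extinct clades get ``colonized_early = unknown`` — the record cannot show
    whether a clade with no surviving descendants ever reached the island —
    and only extinct clades carry a ``crossed_eo`` coding.  Defaults mirror
    the published tallies (50 extinct / 25 extant source clades, 44%
    observed colonization among the extant).
    """
    if n_extinct < 0 or n_extant < 0:
        raise DomainError("counts must be non-negative")
    for p in (p_colonize, p_widespread, p_dispersal, p_crossed_eo):
        if not 0 <= p <= 1:
            raise DomainError("probabilities must lie in [0, 1]")
    rng = _rng(seed)
    rows = []
    for i in range(n_extinct + n_extant):
        extinct = i < n_extinct
        rows.append(
            {
                "name": f"{'extinct' if extinct else 'extant'}_clade_{i:03d}",
                "taxon_class": "synthetic",
                "status": "extinct" if extinct else "extant",
                "widespread": "yes" if rng.random() < p_widespread else "no",
                "dispersal_advantaged": "yes" if rng.random() < p_dispersal else "no",
                "colonized_early": (
                    "unknown"
                    if extinct
                    else ("yes" if rng.random() < p_colonize else "no")
                ),
                "crossed_eo": (
                    ("yes" if rng.random() < p_crossed_eo else "no")
                    if extinct
                    else "unknown"
                ),
                "arrival_period": "unknown",
            }
        )
    return pd.DataFrame(rows, columns=CLADE_COLUMNS)
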