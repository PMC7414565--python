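"""Fossil clade-table calculus.

Operations on categorical clade tables (one row per clade in the Malagasy
sense: the descendant group of a single colonization): 2x2 cross-tabulation
and exact Fisher tests, projection of unobservable early colonizers from the
extant-clade colonization proportion, the end-Eocene disappearance bound,
arrival-period tallies, and a constant arrival/extinction survival model.

Tables are pandas DataFrames in the schema of :data:`CLADE_COLUMNS`
(see :mod:`pulsetree.simdata`); categorical flags are tri-state
('yes'/'no'/'unknown') and unknowns are excluded per test with an explicit
exclusion count — never silently imputed.  The one deliberate exception is
the published convention that clades with *no positive evidence* of early
colonization are tabulated as non-colonizers: pass ``unknown_as`` to
:func:`cross_tabulate` to apply it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, ValidationError
from .simdata import CLADE_COLUMNS


def load_clade_table(path) -> pd.DataFrame:
    """Read a clade CSV and validate its schema."""
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    missing = [c for c in CLADE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clade table missing columns: {missing}")
    return df


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the clade tables shipped with the package
    ('african_families' or 'malagasy_clades')."""
    ref = resources.files("pulsetree.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return load_clade_table(p)


# ---------------------------------------------------------------------------
# 2x2 tables and the exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoByTwo:
    """Counts [[a, b], [c, d]] with row/column labels and the number of
    records excluded for unknown codings."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("yes", "no")
    col_labels: tuple = ("extinct", "extant")
    excluded: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("grand total must be positive")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def cross_tabulate(
    table: pd.DataFrame,
    row_factor: str,
    col_factor: str,
    row_levels: Sequence[str] = ("yes", "no"),
    col_levels: Sequence[str] = ("extinct", "extant"),
    unknown_as: Optional[dict] = None,
) -> TwoByTwo:
    """2x2 cross-tabulation of two tri-state factors.

    Records with 'unknown' in either factor are excluded and counted in
    ``excluded`` — unless ``unknown_as`` maps a factor name to a level, in
    which case unknowns in that factor are recoded first (the published
    tables' "not believed to have colonized" convention).
    """
    if len(table) == 0:
        raise ValidationError("empty clade table")
    df = table.copy()
    for fac, lvl in (unknown_as or {}).items():
        df[fac] = df[fac].replace("unknown", lvl)
    known = df[(df[row_factor] != "unknown") & (df[col_factor] != "unknown")]
    excluded = len(df) - len(known)
    for fac, levels in ((row_factor, row_levels), (col_factor, col_levels)):
        observed = set(known[fac])
        if len(observed & set(levels)) < 2:
            raise ValidationError(
                f"factor {fac!r} has fewer than 2 observed levels: {sorted(observed)}"
            )
        stray = observed - set(levels)
        if stray:
            raise ValidationError(f"factor {fac!r} has unexpected levels {sorted(stray)}")
    r0, r1 = row_levels
    c0, c1 = col_levels
    count = lambda rv, cv: int(((known[row_factor] == rv) & (known[col_factor] == cv)).sum())
    return TwoByTwo(
        a=count(r0, c0), b=count(r0, c1), c=count(r1, c0), d=count(r1, c1),
        row_labels=tuple(row_levels), col_labels=tuple(col_levels),
        excluded=excluded,
    )


def fisher_exact_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value by the point-probability method.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (relative tolerance 1e-7 on the comparison), in exact integer
    arithmetic.  Degenerate margins give p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    # num_i <= obs * (1 + 1e-7), kept in exact integers
    scale = 10**7
    acc = 0
    for x in range(lo, hi + 1):
        num = math.comb(r1, x) * math.comb(r2, c1 - x)
        if num * scale <= obs * (scale + 1):
            acc += num
    p = Fraction(acc, math.comb(n, c1))
    return min(1.0, float(p))


# ---------------------------------------------------------------------------
# projections and bounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectedTable:
    """Inferred early-colonization table assuming extinct clades dispersed
    at the extant clades' observed rate."""

    projected_extinct_colonizers: int
    extant_colonizers: int
    extinct_total: int
    extant_total: int

    @property
    def total_colonizers(self) -> int:
        return self.projected_extinct_colonizers + self.extant_colonizers

    @property
    def counts(self) -> np.ndarray:
        pe = self.projected_extinct_colonizers
        return np.array(
            [
                [pe, self.extant_colonizers],
                [self.extinct_total - pe, self.extant_total - self.extant_colonizers],
            ]
        )


def project_missing_colonizers(
    extinct_total: int, extant_colonized: int, extant_total: int
) -> ProjectedTable:
    """Project the extant early-colonization proportion onto the extinct
    clades (banker's rounding); e.g. 50 x 11/25 = 22 inferred colonizers
    whose dispersal record has been lost."""
    if extant_total <= 0:
        raise DomainError("extant_total must be positive")
    if not 0 <= extant_colonized <= extant_total:
        raise DomainError("extant_colonized must lie in [0, extant_total]")
    if extinct_total < 0:
        raise DomainError("extinct_total must be non-negative")
    projected = _round_half_even(extinct_total * extant_colonized / extant_total)
    return ProjectedTable(
        projected_extinct_colonizers=projected,
        extant_colonizers=extant_colonized,
        extinct_total=extinct_total,
        extant_total=extant_total,
    )


def _round_half_even(x: float) -> int:
    return int(Fraction(x).limit_denominator(10**9).__round__())


def eo_disappearance_bound(
    extinct_total: int, extinct_crossing_eo: int, grand_total: int
) -> float:
    """Upper-bound percentage of clades that may have disappeared at or
    around the end of the Eocene: 100 * (extinct - crossing) / total."""
    if not 0 <= extinct_crossing_eo <= extinct_total <= grand_total:
        raise DomainError("need 0 <= crossing <= extinct_total <= grand_total")
    if grand_total == 0:
        raise DomainError("grand total must be positive")
    return 100.0 * (extinct_total - extinct_crossing_eo) / grand_total


def summarize_arrivals(table: pd.DataFrame) -> dict:
    """Clade counts per arrival period.

    A clade (one colonization) counts once per period: rows are de-duplicated
    on (name, arrival_period).  Unknown periods are reported under
    'unknown', never dropped.
    """
    if len(table) == 0:
        return {"pre_eo": 0, "post_eo": 0, "cretaceous": 0, "unknown": 0, "total_known": 0}
    dedup = table.drop_duplicates(subset=["name", "arrival_period"])
    counts = dedup["arrival_period"].value_counts().to_dict()
    out = {
        "pre_eo": int(counts.get("pre_eo", 0)),
        "post_eo": int(counts.get("post_eo", 0)),
        "cretaceous": int(counts.get("cretaceous", 0)),
        "unknown": int(counts.get("unknown", 0)),
    }
    stray = set(counts) - {"pre_eo", "post_eo", "cretaceous", "unknown"}
    if stray:
        raise ValidationError(f"unexpected arrival periods: {sorted(stray)}")
    out["total_known"] = out["pre_eo"] + out["post_eo"] + out["cretaceous"]
    return out


# ---------------------------------------------------------------------------
# constant arrival/extinction survival model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalModelReport:
    """Constant-hazard clade survival under uniform arrivals.

    ``m_hat`` is the per-clade extinction hazard (per Myr) matching the
    extant pre/post-EOT ratio; ``surviving_fraction`` is the expected
    fraction of pre-EOT arrivals still extant today under that hazard.
    """

    m_hat: float
    surviving_fraction: float
    target_ratio: float
    achieved_ratio: float
    feasible: bool
    cenozoic_start: float
    eo_age: float
    sensitivity: tuple  # ((m, surviving fraction), ...)


def _pre_post_ratio(m: float, start: float, eo: float) -> float:
    # extant clades arriving in [eo, start] vs [0, eo] under uniform
    # arrival and exp(-m * age-of-arrival) survival
    if m == 0.0:
        return (start - eo) / eo
    return (math.exp(-m * eo) - math.exp(-m * start)) / (1.0 - math.exp(-m * eo))


def _surviving_fraction(m: float, start: float, eo: float) -> float:
    if m == 0.0:
        return 1.0
    return (math.exp(-m * eo) - math.exp(-m * start)) / (m * (start - eo))


def constant_rate_survival(
    pre_count: int,
    post_count: int,
    cenozoic_start: float = 66.0,
    eo_age: float = 34.0,
    m_grid: Optional[Sequence[float]] = None,
) -> SurvivalModelReport:
    """Fit the constant arrival/extinction model to the extant arrival
    tallies and report the implied survival of pre-EOT arrivals.

    Solves (e^{-m*eo} - e^{-m*start}) / (1 - e^{-m*eo}) = pre/post for the
    hazard m, then reports F(m) = (e^{-m*eo} - e^{-m*start}) / (m (start-eo)).
    If the observed ratio is unattainable for any m > 0, the boundary
    solution m = 0 is reported with ``feasible=False``.
    """
    if pre_count <= 0 or post_count <= 0:
        raise DomainError("counts must be positive")
    if not 0 < eo_age < cenozoic_start:
        raise DomainError("need 0 < eo_age < cenozoic_start")
    target = pre_count / post_count
    limit0 = (cenozoic_start - eo_age) / eo_age
    if target >= limit0:
        m_hat, feasible = 0.0, False
    else:
        f = lambda m: _pre_post_ratio(m, cenozoic_start, eo_age) - target
        hi = 1.0
        while f(hi) > 0 and hi < 1e6:
            hi *= 2
        m_hat = brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-14)
        feasible = True
    if m_grid is None:
        m_grid = np.round(np.arange(0.01, 0.21, 0.01), 10)
    sens = tuple(
        (float(m), _surviving_fraction(float(m), cenozoic_start, eo_age)) for m in m_grid
    )
    return SurvivalModelReport(
        m_hat=m_hat,
        surviving_fraction=_surviving_fraction(m_hat, cenozoic_start, eo_age),
        target_ratio=target,
        achieved_ratio=_pre_post_ratio(m_hat, cenozoic_start, eo_age),
        feasible=feasible,
        cenozoic_start=cenozoic_start,
        eo_age=eo_age,
        sensitivity=sens,
    )
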