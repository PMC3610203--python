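"""Median dichotomization and 2x2 diagnostic statistics.

The clinical endpoint (condition-positive) is appropriate ICD therapy; a
patient is test-positive when a scar index lies strictly above the cut-off
(the sample median, or a clinically stated threshold such as "> 2 segments
with transmural extent >= 50 %" or "> 20 g").  Sensitivity, specificity and
predictive values are reported both as raw fractions and as percentages
rounded half-up to integers, matching clinical reporting practice.

The association test is Fisher's exact test: the two-sided p-value sums the
hypergeometric probabilities of all tables (with the observed margins) that
are no more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import InputError


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table: condition = event, test = index above cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def events(self) -> int:
        return self.tp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fp

    @classmethod
    def from_cohort(cls, values, events, cutoff: float) -> "TwoByTwo":
        """Cross-tabulate index values (test-positive strictly above cutoff) vs events."""
        v = np.asarray(values, dtype=float)
        e = np.asarray(events).astype(bool)
        if v.shape != e.shape:
            raise InputError("values and events must have the same length")
        pos = v > cutoff
        return cls(int((pos & e).sum()), int((pos & ~e).sum()),
                   int((~pos & e).sum()), int((~pos & ~e).sum()))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DiagnosticStats:
    """Sensitivity/specificity/PPV/NPV as raw fractions (None when undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def _pct(self, v: float | None) -> int | None:
        return None if v is None else _round_half_up(100.0 * v)

    @property
    def sensitivity_pct(self) -> int | None:
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self) -> int | None:
        return self._pct(self.specificity)

    @property
    def ppv_pct(self) -> int | None:
        return self._pct(self.ppv)

    @property
    def npv_pct(self) -> int | None:
        return self._pct(self.npv)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct, "npv_pct": self.npv_pct,
        }


def diagnostic_stats(table: TwoByTwo) -> DiagnosticStats:
    """Sensitivity, specificity, PPV and NPV of a 2x2 table (None on zero denominator)."""
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return DiagnosticStats(
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.tn + table.fn),
    )


def dichotomize_median(values) -> tuple[float, np.ndarray]:
    """Split at the sample median: positive strictly above, negative at-or-below.

    Returns ``(cutoff, above)`` where ``above`` is a boolean array.  With all
    values identical one group is empty (flagged with a warning by callers
    that care); ties at the median fall in the at-or-below group.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("median dichotomization needs at least 2 values")
    cutoff = float(np.median(v))
    return cutoff, v > cutoff


def fisher_exact(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose probability does
    not exceed the observed table's (with the conventional 1 + 1e-7 relative
    tolerance for ties).  Exact for any table size; intended for n <= 1e4.
    """
    n = table.n
    if n == 0:
        return 1.0
    if n > 10_000:
        raise InputError("fisher_exact enumeration supports n <= 10^4")
    r1 = table.events
    c1 = table.positives
    dist = hypergeom(n, r1, c1)
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(table.tp)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)
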