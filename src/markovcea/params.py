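"""Derivation of annual transition probabilities from clinical summary statistics.

Each treatment arm is summarised by four published quantities: a relative
risk of response (RR, dimensionless) and three median durations in months
(overall survival OS, time to progression TTP, duration of response DOR).
These feed two exponential conversion formulas:

* response transition (stable -> remission):  ``1 - exp(-RR / 3)``
* annual exit from a state whose sojourn has median ``m`` months:
  ``1 - exp(-0.75 * ln 2 / m)`` (the expression ``exp(-0.75 ln2 / m)``
  itself is the annual *stay* probability).

The constants 0.75 and 3 are unexplained model constants of the source
analysis; they are exposed as ``DerivationConstants`` fields rather than
buried as magic numbers, but no attempt is made to re-derive them.

Two rounding modes are supported.  ``full_precision`` never rounds and the
derived rows sum to 1 exactly.  ``printed_precision`` rounds each derived
probability to the precision used in the published parameter table before
chaining (the stable->relapse probability is four times the *rounded*
remission->relapse probability), which is the only convention that
reproduces every printed cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import pandas as pd

from .errors import InfeasibleMatrixError, InvalidParameterError

RoundingMode = Literal["printed_precision", "full_precision"]

#: Default fractional half-width of one-way sensitivity ranges (+/-20%).
DEFAULT_SA_FRACTION = 0.2


@dataclass(frozen=True)
class DerivationConstants:
    """Fixed constants of the probability-derivation formulas.

    ``median_scale`` multiplies ln 2 in the median-to-annual-rate
    conversion; ``rr_divisor`` scales the relative risk in the response
    formula.  Both are model constants of the source analysis, carried as
    named configuration rather than re-derived.
    """

    median_scale: float = 0.75
    rr_divisor: float = 3.0


DEFAULT_CONSTANTS = DerivationConstants()


@dataclass(frozen=True)
class ClinicalSummary:
    """Per-arm clinical summary statistics (medians in months).

    Invariants: ``rr > 0``; ``os_median > ttp_median > 0``; ``dor_median > 0``.
    ``rp_decimals`` records the precision at which the remission->relapse
    probability is printed for this arm (3 for AC-TH, 2 for TCH) and only
    matters in ``printed_precision`` mode.
    """

    arm_label: str
    rr: float
    os_median: float
    ttp_median: float
    dor_median: float
    rp_decimals: int = 3

    def __post_init__(self) -> None:
        if not self.rr > 0:
            raise InvalidParameterError(f"rr must be > 0, got {self.rr}")
        if not self.ttp_median > 0:
            raise InvalidParameterError(
                f"ttp_median must be > 0, got {self.ttp_median}"
            )
        if not self.os_median > self.ttp_median:
            raise InvalidParameterError(
                f"os_median ({self.os_median}) must exceed ttp_median "
                f"({self.ttp_median})"
            )
        if not self.dor_median > 0:
            raise InvalidParameterError(
                f"dor_median must be > 0, got {self.dor_median}"
            )


#: The two study arms, as published.
ACTH_SUMMARY = ClinicalSummary(
    arm_label="ACTH", rr=0.837, os_median=44.3, ttp_median=7.2, dor_median=5.6
)
TCH_SUMMARY = ClinicalSummary(
    arm_label="TCH", rr=0.704, os_median=35.0, ttp_median=10.35,
    dor_median=4.0, rp_decimals=2,
)


@dataclass(frozen=True)
class DerivedProbabilities:
    """Annual transition probabilities for one arm of the 4-state model.

    States are stable (s), remission (r), relapse (p), death (d).  Rows:
    stable -> {stable, remission, relapse}; remission -> {remission,
    relapse}; relapse -> {relapse, death}.  Death is absorbing and is only
    reachable from relapse.
    """

    arm_label: str
    p_ss: float
    p_sr: float
    p_sp: float
    p_rr: float
    p_rp: float
    p_pp: float
    p_pd: float
    rounding_mode: RoundingMode = "full_precision"

    def as_dict(self) -> dict[str, float]:
        return {
            "ss": self.p_ss, "sr": self.p_sr, "sp": self.p_sp,
            "rr": self.p_rr, "rp": self.p_rp,
            "pp": self.p_pp, "pd": self.p_pd,
        }


def derive_response_transition(
    rr: float, constants: DerivationConstants = DEFAULT_CONSTANTS
) -> float:
    """Annual stable->remission probability from a relative risk.

    Returns ``1 - exp(-rr / rr_divisor)``; strictly increasing in ``rr``
    and bounded in (0, 1).
    """
    if not rr > 0:
        raise InvalidParameterError(f"relative risk must be > 0, got {rr}")
    return 1.0 - math.exp(-rr / constants.rr_divisor)


def median_to_annual_exit_prob(
    median: float, constants: DerivationConstants = DEFAULT_CONSTANTS
) -> float:
    """Annual probability of leaving a state with median sojourn ``median`` months.

    ``exp(-median_scale * ln 2 / median)`` is the annual stay probability;
    this returns its complement.  Strictly decreasing in ``median``.
    """
    if not median > 0:
        raise InvalidParameterError(f"median must be > 0, got {median}")
    return 1.0 - math.exp(-constants.median_scale * math.log(2.0) / median)


def build_arm_matrix(
    summary: ClinicalSummary,
    rounding_mode: RoundingMode = "full_precision",
    constants: DerivationConstants = DEFAULT_CONSTANTS,
) -> DerivedProbabilities:
    """Derive all seven per-arm transition probabilities from a summary.

    Chain: p_rp from DOR; p_pd from OS - TTP; p_sr from RR; p_sp = 4*p_rp;
    stay probabilities are complements.  In ``printed_precision`` mode each
    step is rounded to its table precision before the next uses it.
    """

    def rnd(x: float, dp: int = 3) -> float:
        return round(x, dp) if rounding_mode == "printed_precision" else x

    p_rp = rnd(median_to_annual_exit_prob(summary.dor_median, constants),
               summary.rp_decimals)
    p_pd = rnd(median_to_annual_exit_prob(
        summary.os_median - summary.ttp_median, constants))
    p_sr = rnd(derive_response_transition(summary.rr, constants))
    p_sp = rnd(4.0 * p_rp)
    if p_sp + p_sr >= 1.0:
        raise InfeasibleMatrixError(
            f"{summary.arm_label}: stable-row exits sum to "
            f"{p_sp + p_sr:.4f} >= 1 (negative stay probability)"
        )
    p_ss = rnd(1.0 - p_sp - p_sr)
    return DerivedProbabilities(
        arm_label=summary.arm_label,
        p_ss=p_ss, p_sr=p_sr, p_sp=p_sp,
        p_rr=rnd(1.0 - p_rp, summary.rp_decimals), p_rp=p_rp,
        p_pp=rnd(1.0 - p_pd), p_pd=p_pd,
        rounding_mode=rounding_mode,
    )


@dataclass(frozen=True)
class SensitivityRange:
    """A best estimate with its one-way sensitivity bounds and distribution.

    Bounds are ``estimate*(1-fraction)`` and ``estimate*(1+fraction)``
    clamped to ``cap`` (``[0, 1]`` for probabilities and utilities, no
    upper cap for costs).
    """

    estimate: float
    lo: float
    hi: float
    fraction: float = DEFAULT_SA_FRACTION
    distribution: Literal["beta", "gamma"] = "beta"


def sa_range(
    estimate: float,
    fraction: float = DEFAULT_SA_FRACTION,
    cap: tuple[float, float | None] = (0.0, 1.0),
    distribution: Literal["beta", "gamma"] = "beta",
) -> SensitivityRange:
    """Symmetric +/-``fraction`` sensitivity range around ``estimate``, clamped."""
    if not 0.0 <= fraction < 1.0:
        raise InvalidParameterError(f"fraction must be in [0, 1), got {fraction}")
    if estimate < 0:
        raise InvalidParameterError(f"estimate must be >= 0, got {estimate}")
    cap_lo, cap_hi = cap
    lo = max(cap_lo, estimate * (1.0 - fraction))
    hi = estimate * (1.0 + fraction)
    if cap_hi is not None:
        hi = min(cap_hi, hi)
    return SensitivityRange(estimate=estimate, lo=lo, hi=hi,
                            fraction=fraction, distribution=distribution)


_FORMULAS = {
    "ss": "1 - sp - sr",
    "sr": "1 - exp(-RR/3)",
    "sp": "4 * rp",
    "rr": "1 - rp",
    "rp": "1 - exp(-0.75*ln2/DOR)",
    "pp": "1 - pd",
    "pd": "1 - exp(-0.75*ln2/(OS-TTP))",
}

_TRANSITION_NAMES = {
    "ss": "Stable -> Stable", "sr": "Stable -> Remission",
    "sp": "Stable -> Relapse", "rr": "Remission -> Remission",
    "rp": "Remission -> Relapse", "pp": "Relapse -> Relapse",
    "pd": "Relapse -> Death",
}


def parameter_table(
    summaries: list[ClinicalSummary] | None = None,
    fraction: float = DEFAULT_SA_FRACTION,
    rounding_mode: RoundingMode = "printed_precision",
) -> pd.DataFrame:
    """Derived probabilities plus SA ranges for each arm, as a tidy table.

    Mirrors the published parameter table: one row per transition with its
    formula, best estimate, SA bounds and distribution family.
    """
    if summaries is None:
        summaries = [ACTH_SUMMARY, TCH_SUMMARY]
    rows = []
    for summ in summaries:
        derived = build_arm_matrix(summ, rounding_mode=rounding_mode)
        for key, est in derived.as_dict().items():
            rng = sa_range(est, fraction=fraction, cap=(0.0, 1.0))
            rows.append({
                "arm": summ.arm_label,
                "transition": _TRANSITION_NAMES[key],
                "symbol": f"{summ.arm_label}_{key}",
                "formula": _FORMULAS[key],
                "estimate": est,
                "sa_lo": rng.lo,
                "sa_hi": rng.hi,
                "distribution": "beta",
            })
    return pd.DataFrame(rows)


def with_overrides(derived: DerivedProbabilities, **kw: float) -> DerivedProbabilities:
    """Return a copy with some probabilities replaced (no rebalancing)."""
    mapped = {f"p_{k}": v for k, v in kw.items()}
    return replace(derived, **mapped)
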