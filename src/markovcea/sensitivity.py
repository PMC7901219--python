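"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the paired model at each parameter's lower and
upper bound with everything else at its best estimate; the tornado
ordering ranks parameters by the absolute swing of the chosen output
(default: the net-monetary-benefit difference between the arms at a
willingness-to-pay of $20,000/QALY).

Probabilistic analysis (second-order Monte Carlo) assigns a beta
distribution to every probability and utility and a gamma distribution to
every cost, fitted by the method of moments treating the published
sensitivity range as a central 95% interval (sd = (hi - lo)/3.92).  Each
of the default 1000 draws re-evaluates the deterministic cohort model for
both arms; the per-draw incremental (cost, effect) pairs feed the
cost-effectiveness plane and the acceptability curves.

Row handling: only the exit probabilities (sr, sp, rp, pd) are sampled;
stay probabilities are their complements.  A sampled stable row whose
exits exceed 1 is rescaled proportionally onto the simplex and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .econ import DEFAULT_WTP_CEAC, nmb
from .engine import STATES, StrategyOutcome, evaluate
from .errors import InvalidSpreadError
from .model import CEModel
from .params import DEFAULT_SA_FRACTION, sa_range

#: Width of a central 95% interval in standard deviations.
CI95_WIDTH_SD = 3.92


# ---------------------------------------------------------------------------
# distribution fitting


def fit_beta(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments beta fit from a mean and a central 95% interval.

    sd = (hi - lo)/3.92; alpha = mean*(mean(1-mean)/sd^2 - 1), beta
    likewise.  Raises :class:`InvalidSpreadError` when the implied
    variance is not attainable by any beta distribution.
    """
    if not 0.0 < mean < 1.0:
        raise InvalidSpreadError(f"beta mean must be in (0, 1), got {mean}")
    if not (0.0 <= lo < hi <= 1.0):
        raise InvalidSpreadError(f"need 0 <= lo < hi <= 1, got ({lo}, {hi})")
    sd = (hi - lo) / CI95_WIDTH_SD
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InvalidSpreadError(
            f"implied variance {var:.3g} >= mean(1-mean) = "
            f"{mean * (1 - mean):.3g}; no beta distribution has this spread"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Method-of-moments gamma fit (shape, scale) from mean and 95% interval."""
    if not mean > 0:
        raise InvalidSpreadError(f"gamma mean must be > 0, got {mean}")
    if hi < lo:
        raise InvalidSpreadError(f"need lo <= hi, got ({lo}, {hi})")
    sd = (hi - lo) / CI95_WIDTH_SD
    if sd == 0:
        raise InvalidSpreadError("degenerate interval; use a point mass")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


@dataclass(frozen=True)
class SAParam:
    """One sensitivity parameter: name, best estimate, bounds, family."""

    name: str
    estimate: float
    lo: float
    hi: float
    family: Literal["beta", "gamma"]


class _Sampler:
    """Frozen sampling distribution for one parameter."""

    def __init__(self, param: SAParam):
        self.param = param
        if param.hi == param.lo or param.estimate == 0.0 or (
            param.family == "beta" and param.estimate >= 1.0
        ):
            self.kind = "point"
        elif param.family == "beta":
            self.kind = "beta"
            self.a, self.b = fit_beta(param.estimate, param.lo, param.hi)
        else:
            self.kind = "gamma"
            self.shape, self.scale = fit_gamma(param.estimate, param.lo, param.hi)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.param.estimate)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size)
        return rng.gamma(self.shape, self.scale, size)


# ---------------------------------------------------------------------------
# parameter sets

_EXIT_KEYS = ("sr", "sp", "rp", "pd")
_ALL_PROB_KEYS = ("ss", "sr", "sp", "rr", "rp", "pp", "pd")


def _prob_param(name: str, est: float, fraction: float) -> SAParam:
    rng_ = sa_range(est, fraction=fraction, cap=(0.0, 1.0))
    return SAParam(name=name, estimate=est, lo=rng_.lo, hi=rng_.hi, family="beta")


def _cost_param(name: str, est: float, fraction: float) -> SAParam:
    rng_ = sa_range(est, fraction=fraction, cap=(0.0, None), distribution="gamma")
    return SAParam(name=name, estimate=est, lo=rng_.lo, hi=rng_.hi, family="gamma")


def default_sa_params(
    model: CEModel,
    fraction: float = DEFAULT_SA_FRACTION,
    include: Sequence[str] = ("probabilities", "utilities", "costs"),
) -> list[SAParam]:
    """One-way parameter set: every transition probability (stay rows
    included, each over its own range), every non-death utility, every
    non-zero cost."""
    base = model.parameters()
    params: list[SAParam] = []
    if "probabilities" in include:
        for arm in model.arms:
            for key in _ALL_PROB_KEYS:
                name = f"{arm.label}_{key}"
                params.append(_prob_param(name, base[name], fraction))
    if "utilities" in include:
        for state in STATES:
            if state != "death":
                name = f"utility_{state}"
                params.append(_prob_param(name, base[name], fraction))
    if "costs" in include:
        for arm in model.arms:
            for state in STATES:
                if state != "death" and base[f"{arm.label}_cost_{state}"] > 0:
                    name = f"{arm.label}_cost_{state}"
                    params.append(_cost_param(name, base[name], fraction))
            params.append(_cost_param(f"{arm.label}_intervention_cost",
                                      base[f"{arm.label}_intervention_cost"],
                                      fraction))
    return params


def psa_params(
    model: CEModel,
    fraction: float = DEFAULT_SA_FRACTION,
    include: Sequence[str] = ("probabilities", "utilities", "costs"),
) -> list[SAParam]:
    """PSA parameter set: free exit probabilities only (stay probabilities
    are complements), plus utilities and costs."""
    params = default_sa_params(model, fraction=fraction, include=include)
    drop = {f"{arm.label}_{k}" for arm in model.arms for k in ("ss", "rr", "pp")}
    return [p for p in params if p.name not in drop]


# ---------------------------------------------------------------------------
# one-way / tornado


def nmb_difference(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> float:
    """NMB(a) - NMB(b): positive favours strategy a at this threshold."""
    return nmb(a, wtp) - nmb(b, wtp)


OutputFn = Callable[[StrategyOutcome, StrategyOutcome], float]


@dataclass(frozen=True)
class OneWayResult:
    param: SAParam
    output_lo: float
    output_hi: float

    @property
    def swing(self) -> float:
        return abs(self.output_hi - self.output_lo)


def one_way(
    model: CEModel,
    param: SAParam,
    wtp: float = DEFAULT_WTP_CEAC,
    output: OutputFn | None = None,
) -> OneWayResult:
    """Re-run the paired model at the parameter's bounds, all else fixed."""
    if output is None:
        output = lambda a, b: nmb_difference(a, b, wtp)
    a_lo, b_lo, _ = model.evaluate({param.name: param.lo})
    a_hi, b_hi, _ = model.evaluate({param.name: param.hi})
    return OneWayResult(param=param, output_lo=output(a_lo, b_lo),
                        output_hi=output(a_hi, b_hi))


def tornado(
    model: CEModel,
    params: Sequence[SAParam],
    wtp: float = DEFAULT_WTP_CEAC,
    output: OutputFn | None = None,
    cumulative_share: float | None = None,
) -> pd.DataFrame:
    """One-way swings for every parameter, widest first.

    Ties are broken by parameter name so the ordering is deterministic and
    invariant to input order.  ``cumulative_share`` truncates the list to
    the leading parameters that account for that share of the total swing.
    """
    if not params:
        raise ValueError("tornado requires at least one parameter")
    results = [one_way(model, p, wtp=wtp, output=output) for p in params]
    df = pd.DataFrame({
        "parameter": [r.param.name for r in results],
        "lo": [r.param.lo for r in results],
        "hi": [r.param.hi for r in results],
        "output_lo": [r.output_lo for r in results],
        "output_hi": [r.output_hi for r in results],
        "swing": [r.swing for r in results],
    })
    df = df.sort_values(["swing", "parameter"],
                        ascending=[False, True]).reset_index(drop=True)
    if cumulative_share is not None:
        total = df["swing"].sum()
        if total > 0:
            cum = df["swing"].cumsum() / total
            keep = int(np.searchsorted(cum.to_numpy(),
                                       cumulative_share - 1e-12) + 1)
            df = df.iloc[:keep].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Draw-level PSA output for the paired comparison."""

    draws: pd.DataFrame          # one row per draw: params, outcomes, deltas
    label_a: str
    label_b: str
    n_rescaled: int              # stable rows renormalised during sampling
    seed: int | None

    def interval(self, column: str, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval from the 2.5th/97.5th percentile ranks."""
        tail = (1.0 - level) / 2.0
        lo, hi = np.percentile(self.draws[column], [100 * tail, 100 * (1 - tail)])
        return float(lo), float(hi)


def run_psa(
    model: CEModel,
    params: Sequence[SAParam] | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
) -> PSAResult:
    """Second-order Monte Carlo: sample parameters, re-run both arms per draw."""
    if params is None:
        params = psa_params(model)
    rng = np.random.default_rng(seed)
    samplers = [_Sampler(p) for p in params]
    sampled = {s.param.name: s.sample(rng, n_sims) for s in samplers}

    records = []
    n_rescaled = 0
    for i in range(n_sims):
        overrides = {name: float(vals[i]) for name, vals in sampled.items()}
        spec_a = model.build_spec(model.arm_a.label, overrides, on_excess="rescale")
        spec_b = model.build_spec(model.arm_b.label, overrides, on_excess="rescale")
        for arm, spec in ((model.arm_a, spec_a), (model.arm_b, spec_b)):
            sr = overrides.get(f"{arm.label}_sr", arm.probs.p_sr)
            sp = overrides.get(f"{arm.label}_sp", arm.probs.p_sp)
            if sr + sp > 1.0:
                n_rescaled += 1
        out_a = evaluate(spec_a)
        out_b = evaluate(spec_b)
        rec = {"draw": i, **overrides,
               f"cost_{out_a.label}": out_a.cost,
               f"effect_{out_a.label}": out_a.effect,
               f"cost_{out_b.label}": out_b.cost,
               f"effect_{out_b.label}": out_b.effect,
               "delta_cost": out_a.cost - out_b.cost,
               "delta_effect": out_a.effect - out_b.effect}
        records.append(rec)
    return PSAResult(draws=pd.DataFrame(records),
                     label_a=model.arm_a.label, label_b=model.arm_b.label,
                     n_rescaled=n_rescaled, seed=seed)


def ceac(
    result: PSAResult,
    wtp_grid: Sequence[float],
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves for both strategies.

    At each willingness-to-pay the acceptability of a strategy is the
    fraction of draws in which it has the maximal NMB; exact ties are
    awarded to strategy a (the same <= convention as the WTP-ray rule), so
    the two fractions sum to 1 at every threshold.
    """
    draws = result.draws
    cost_a = draws[f"cost_{result.label_a}"].to_numpy()
    eff_a = draws[f"effect_{result.label_a}"].to_numpy()
    cost_b = draws[f"cost_{result.label_b}"].to_numpy()
    eff_b = draws[f"effect_{result.label_b}"].to_numpy()
    rows = []
    for wtp in wtp_grid:
        a_wins = (wtp * eff_a - cost_a) >= (wtp * eff_b - cost_b)
        p_a = float(a_wins.mean())
        rows.append({"wtp": wtp, "strategy": result.label_a, "probability": p_a})
        rows.append({"wtp": wtp, "strategy": result.label_b,
                     "probability": 1.0 - p_a})
    return pd.DataFrame(rows)


_QUADRANTS = {(1, 1): "I", (-1, 1): "II", (-1, -1): "III", (1, -1): "IV"}


def ce_plane(result: PSAResult, wtp: float = DEFAULT_WTP_CEAC) -> pd.DataFrame:
    """Label each PSA draw on the incremental cost-effectiveness plane.

    Quadrants follow the (delta_effect, delta_cost) sign convention:
    I more effective & costlier, II less effective & costlier, III less
    effective & cheaper, IV more effective & cheaper.  Axis points carry
    an ``on_axis`` flag and are binned with the positive half-plane.
    A draw is cost-effective for strategy a when delta_cost <= wtp *
    delta_effect (points on the ray count as cost-effective).
    """
    de = result.draws["delta_effect"].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    sign_e = np.where(de >= 0, 1, -1)
    sign_c = np.where(dc >= 0, 1, -1)
    quadrant = [_QUADRANTS[(int(se), int(sc))] for se, sc in zip(sign_e, sign_c)]
    out = result.draws[["draw", "delta_effect", "delta_cost"]].copy()
    out["quadrant"] = quadrant
    out["on_axis"] = (de == 0) | (dc == 0)
    out["cost_effective_a"] = dc <= wtp * de
    return out
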