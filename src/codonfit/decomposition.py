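"""Per-codon decomposition of allele-level fitness costs, and the study's
regression/correlation analyses.

Under a multiplicative model, a strain carrying N mutations each of cost
s_i has relative fitness

    omega = prod_i (1 - s_i)

and if all costs are equal, omega = (1 - s)^N, so the per-codon cost
implied by a measured total disadvantage s_total over N synonymous
substitutions is

    s = 1 - (1 - s_total)^(1/N).

The module also provides the s-versus-N regression (slope = per-codon
cost), the additivity comparison of half-gene alleles against the full
allele, plain OLS correlation for per-codon cost against codon-usage and
kinetic predictors, the selection-mutation-drift point prediction
s = 0.01 p for a protein comprising fraction p of total protein, and the
per-generation <-> per-hour conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .competition import SelectionResult


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class AdditivityResult:
    sum_of_parts: float
    whole: float
    difference: float
    p_value: float


def per_codon_s(total_s: float, n: int) -> float:
    """Equal-cost per-codon disadvantage implied by a total disadvantage."""
    if not 0 <= total_s < 1:
        raise ValueError("total_s must lie in [0, 1)")
    if n < 1:
        raise ValueError("N must be >= 1")
    return 1.0 - (1.0 - total_s) ** (1.0 / n)


def combine_fitness(per_codon_costs: list[float]) -> float:
    """Relative fitness omega of a strain carrying the listed costs."""
    omega = 1.0
    for s in per_codon_costs:
        if not 0 <= s < 1:
            raise ValueError("each per-codon cost must lie in [0, 1)")
        omega *= 1.0 - s
    return omega


def regress_s_vs_n(
    points: list[tuple[float, float]], include_origin: bool = True
) -> RegressionResult:
    """OLS of total disadvantage on substitution count N.

    ``include_origin`` prepends the wild-type point (0, 0), the default for
    allele series that share a wild-type reference. The slope estimates the
    per-codon cost.
    """
    pts = list(points)
    if include_origin:
        pts = [(0.0, 0.0)] + pts
    if len(pts) < 3:
        raise ValueError("need >= 3 points (after optional origin augmentation)")
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate N values: no spread on the x axis")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


# Backwards-friendly alias matching the N-first argument naming elsewhere.
regress_s_vs_N = regress_s_vs_n


def correlate(x: list[float], y: list[float]) -> RegressionResult:
    """OLS fit of y on x with r² and a two-sided slope p-value."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.size != ya.size:
        raise ValueError("x and y differ in length")
    if xa.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(xa) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(xa, ya)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def additivity_test(
    parts: list[SelectionResult], whole: SelectionResult
) -> AdditivityResult:
    """Welch-type test of (sum of part disadvantages) == (whole disadvantage).

    Uses the replicate-level samples carried by each SelectionResult; the
    variance of the sum is the sum of the parts' squared standard errors.
    """
    for r in [*parts, whole]:
        if r.samples is None or len(r.samples) < 2:
            raise ValueError(
                f"{r.allele or 'result'}: replicate-level samples required"
            )
    means = [float(np.mean(r.samples)) for r in parts]
    ses = [float(np.std(r.samples, ddof=1) / math.sqrt(len(r.samples))) for r in parts]
    dfs = [len(r.samples) - 1 for r in parts]
    sum_parts = sum(means)
    var_sum = sum(se**2 for se in ses)
    whole_mean = float(np.mean(whole.samples))
    whole_se = float(np.std(whole.samples, ddof=1) / math.sqrt(len(whole.samples)))
    diff = sum_parts - whole_mean
    se = math.sqrt(var_sum + whole_se**2)
    if se == 0:
        return AdditivityResult(sum_parts, whole_mean, diff, 1.0 if diff == 0 else 0.0)
    # Welch-Satterthwaite df over all contributing groups
    num = (var_sum + whole_se**2) ** 2
    den = sum(se_i**4 / df_i for se_i, df_i in zip(ses, dfs))
    den += whole_se**4 / (len(whole.samples) - 1)
    df = num / den
    p = 2 * stats.t.sf(abs(diff / se), df)
    return AdditivityResult(sum_parts, whole_mean, diff, float(p))


def bulmer_prediction(p: float) -> float:
    """Selection-mutation-drift prediction s = 0.01 p for one non-optimal
    codon in a protein comprising fraction p of total protein mass."""
    if not 0 <= p <= 1:
        raise ValueError("relative protein abundance p must lie in [0, 1]")
    return 0.01 * p


def per_generation_to_per_hour(s: float, doublings_per_hour: float) -> float:
    """Convert a per-generation cost to doublings per hour."""
    if not doublings_per_hour > 0:
        raise ValueError("doublings_per_hour must be positive")
    return s * doublings_per_hour


def per_hour_to_per_generation(s: float, doublings_per_hour: float) -> float:
    if not doublings_per_hour > 0:
        raise ValueError("doublings_per_hour must be positive")
    return s / doublings_per_hour
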