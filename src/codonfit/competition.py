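"""Selection coefficients from pairwise growth-competition trajectories.

Each replicate culture competes a focal strain against a fluorescently
marked reference; the marker ratio is read by flow cytometry every ten
generations over thirty generations.  The selection coefficient of one
replicate is the ordinary-least-squares slope of ln(ratio) against
generation.  Group-level processing then:

1. removes replicates whose s differs from the group median by more than a
   window (0.008 per generation by default) — such jumps indicate a
   secondary genetic change, not the fitness of the construct;
2. normalises every estimate to the mean control (wild-type) s of its dye
   batch, cancelling marker effects across dye swaps;
3. compares the test group against the control group with a two-tailed
   Welch t-test, reporting the mean difference as a positive selective
   disadvantage with a 95% confidence interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_OUTLIER_WINDOW = 0.008


@dataclass
class CompetitionTrajectory:
    strain: str
    dye: str
    replicate: int
    generations: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.generations.size != self.ratios.size:
            raise ValueError("generations and ratios differ in length")
        if self.generations.size < 2:
            raise ValueError(
                f"{self.strain}/{self.dye}/r{self.replicate}: need >= 2 observations"
            )
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")
        if np.any(self.ratios <= 0):
            raise ValueError(
                f"{self.strain}/{self.dye}/r{self.replicate}: ratios must be positive"
            )


@dataclass(frozen=True)
class SelectionEstimate:
    strain: str
    dye: str
    replicate: int
    s: float


@dataclass
class SelectionResult:
    """Per-allele selective disadvantage from a two-group comparison."""

    allele: str
    selective_disadvantage: float
    ci95: tuple[float, float]
    n_used: int
    p_value: float
    #: replicate-level disadvantages (control mean - test value), kept for
    #: downstream additivity comparisons.
    samples: np.ndarray = field(default_factory=lambda: np.array([]))


def estimate_s(traj: CompetitionTrajectory, method: str = "ols") -> SelectionEstimate:
    """Per-generation selection coefficient of one replicate.

    ``ols`` fits ln(ratio) on generation by least squares; ``endpoints``
    uses only the first and last observations, ln(R_T/R_0)/(T - 0).
    """
    logratio = np.log(traj.ratios)
    g = traj.generations
    if method == "ols":
        slope = np.polyfit(g, logratio, 1)[0]
    elif method == "endpoints":
        slope = (logratio[-1] - logratio[0]) / (g[-1] - g[0])
    else:
        raise ValueError(f"unknown estimator {method!r}")
    return SelectionEstimate(traj.strain, traj.dye, traj.replicate, float(slope))


def filter_outliers(
    estimates: list[SelectionEstimate], window: float = DEFAULT_OUTLIER_WINDOW
) -> tuple[list[SelectionEstimate], list[SelectionEstimate]]:
    """Single-pass median filter: drop estimates further than ``window`` from
    the group median (median taken on the raw input group)."""
    if not estimates:
        raise ValueError("no estimates to filter")
    med = float(np.median([e.s for e in estimates]))
    kept = [e for e in estimates if abs(e.s - med) <= window]
    removed = [e for e in estimates if abs(e.s - med) > window]
    return kept, removed


def normalize_to_reference(
    estimates: list[SelectionEstimate],
    control_estimates: list[SelectionEstimate],
) -> list[SelectionEstimate]:
    """Express every estimate relative to the mean control s of its dye batch.

    The control group's own batch mean maps to zero, so dye-specific marker
    effects cancel when groups are compared across the dye swap.
    """
    batches: dict[str, list[float]] = {}
    for e in control_estimates:
        batches.setdefault(e.dye, []).append(e.s)
    means = {dye: float(np.mean(vals)) for dye, vals in batches.items()}
    out = []
    for e in estimates:
        if e.dye not in means:
            raise ValueError(f"no control estimates for dye batch {e.dye!r}")
        out.append(SelectionEstimate(e.strain, e.dye, e.replicate, e.s - means[e.dye]))
    return out


def compare_groups(
    test: list[float] | list[SelectionEstimate],
    control: list[float] | list[SelectionEstimate],
    allele: str = "",
    equal_var: bool = False,
) -> SelectionResult:
    """Welch (default) two-tailed t comparison of normalised s values.

    The selective disadvantage is mean(control) - mean(test): positive when
    the test allele grows worse than the wild-type control.
    """
    t_vals = np.array([e.s if isinstance(e, SelectionEstimate) else e for e in test], float)
    c_vals = np.array([e.s if isinstance(e, SelectionEstimate) else e for e in control], float)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(np.mean(c_vals) - np.mean(t_vals))
    vt, vc = t_vals.var(ddof=1), c_vals.var(ddof=1)
    nt, nc = t_vals.size, c_vals.size
    if vt == 0 and vc == 0:
        warnings.warn("degenerate (zero) variance in both groups; CI collapsed")
        p = 1.0 if diff == 0 else 0.0
        return SelectionResult(allele, diff, (diff, diff), nt + nc, p,
                               samples=np.mean(c_vals) - t_vals)
    se = math.sqrt(vt / nt + vc / nc)
    if equal_var:
        df = nt + nc - 2
        sp2 = ((nt - 1) * vt + (nc - 1) * vc) / df
        se = math.sqrt(sp2 * (1 / nt + 1 / nc))
    else:
        df = (vt / nt + vc / nc) ** 2 / (
            (vt / nt) ** 2 / (nt - 1) + (vc / nc) ** 2 / (nc - 1)
        )
    tstat = diff / se
    p = 2 * stats.t.sf(abs(tstat), df)
    half = stats.t.ppf(0.975, df) * se
    return SelectionResult(
        allele=allele,
        selective_disadvantage=diff,
        ci95=(diff - half, diff + half),
        n_used=nt + nc,
        p_value=float(p),
        samples=np.mean(c_vals) - t_vals,
    )


def normality_check(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a group of selection coefficients."""
    arr = np.asarray([v.s if isinstance(v, SelectionEstimate) else v for v in values], float)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def read_trajectories(source) -> list[CompetitionTrajectory]:
    """Parse a trajectory table (TSV path or DataFrame) into trajectories.

    Expected columns: strain, dye, replicate, generation and either
    ``ratio`` or the pair ``count_focal``/``count_reference``.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    if "ratio" not in df.columns:
        if {"count_focal", "count_reference"} <= set(df.columns):
            df = df.assign(ratio=df["count_focal"] / df["count_reference"])
        else:
            raise ValueError("need a 'ratio' or 'count_focal'/'count_reference' columns")
    out = []
    for (strain, dye, rep), grp in df.groupby(["strain", "dye", "replicate"], sort=True):
        grp = grp.sort_values("generation")
        out.append(
            CompetitionTrajectory(
                strain=str(strain),
                dye=str(dye),
                replicate=int(rep),
                generations=grp["generation"].to_numpy(float),
                ratios=grp["ratio"].to_numpy(float),
            )
        )
    return out


def estimate_allele_disadvantage(
    trajectories: list[CompetitionTrajectory],
    allele: str,
    control: str,
    window: float = DEFAULT_OUTLIER_WINDOW,
    method: str = "ols",
) -> SelectionResult:
    """Full per-allele chain: slopes -> outlier filter -> dye normalisation
    -> Welch comparison against the control strain."""
    test_raw = [estimate_s(t, method) for t in trajectories if t.strain == allele]
    ctrl_raw = [estimate_s(t, method) for t in trajectories if t.strain == control]
    if not test_raw:
        raise ValueError(f"no trajectories for allele {allele!r}")
    if not ctrl_raw:
        raise ValueError(f"no trajectories for control {control!r}")
    test_kept, test_rm = filter_outliers(test_raw, window)
    ctrl_kept, ctrl_rm = filter_outliers(ctrl_raw, window)
    if test_rm or ctrl_rm:
        logger.info(
            "%s: removed %d test and %d control outlier replicates",
            allele, len(test_rm), len(ctrl_rm),
        )
    test_norm = normalize_to_reference(test_kept, ctrl_kept)
    ctrl_norm = normalize_to_reference(ctrl_kept, ctrl_kept)
    return compare_groups(test_norm, ctrl_norm, allele=allele)
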