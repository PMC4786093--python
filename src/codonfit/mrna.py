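"""Relative mRNA quantification and half-life estimation from qPCR tables.

Quantification follows the comparative-Ct (ΔΔCt) method with an assumed
amplification efficiency of 2.0 (configurable): the target Ct is referenced
against the mean Ct of one or more stable reference genes, and expressed
relative to a calibrator sample.  Half-lives come from a rifampicin
run-out: after transcription shut-off the target's relative quantity
decays log-linearly, and the half-life is -1/slope of log2(quantity)
against time in minutes.  A long-lived RNA (tmRNA) serves as the decay
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrSeries:
    """Long-format Ct table with columns sample, gene, timepoint_min, dilution, ct."""

    data: pd.DataFrame
    efficiency: float = 2.0

    REQUIRED = ("sample", "gene", "timepoint_min", "dilution", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table lacks columns: {missing}")
        if not np.isfinite(self.data["ct"].to_numpy(float)).all():
            raise ValueError("non-finite Ct value in table")
        if self.efficiency <= 1:
            raise ValueError("amplification efficiency must exceed 1")

    @classmethod
    def from_tsv(cls, path, efficiency: float = 2.0) -> "QpcrSeries":
        return cls(pd.read_csv(path, sep="\t"), efficiency=efficiency)

    def mean_ct(self, sample: str, gene: str, timepoint: float) -> float:
        """Dilution-corrected mean Ct of one gene in one sample/timepoint.

        A dilution d (e.g. 0.1) raises the observed Ct by log_E(1/d); the
        correction removes that shift before averaging across dilutions.
        """
        sel = self.data[
            (self.data["sample"] == sample)
            & (self.data["gene"] == gene)
            & (self.data["timepoint_min"] == timepoint)
        ]
        if sel.empty:
            raise ValueError(f"no Ct for {gene} in {sample} at t={timepoint}")
        base = math.log(self.efficiency)
        corrected = sel["ct"].to_numpy(float) + np.log(sel["dilution"].to_numpy(float)) / base
        return float(np.mean(corrected))


@dataclass
class HalfLifeResult:
    target: str
    half_life_min: float  # nan when not estimable
    slope: float
    estimable: bool


def relative_abundance(
    series: QpcrSeries,
    target: str,
    references: list[str],
    sample: str,
    calibrator: str,
    timepoint: float = 0.0,
) -> float:
    """ΔΔCt relative quantity of ``target`` in ``sample`` versus ``calibrator``."""
    if not references:
        raise ValueError("at least one reference gene required")

    def dct(smp: str) -> float:
        ref_mean = float(
            np.mean([series.mean_ct(smp, g, timepoint) for g in references])
        )
        return series.mean_ct(smp, target, timepoint) - ref_mean

    ddct = dct(sample) - dct(calibrator)
    return float(series.efficiency ** (-ddct))


def half_life(
    series: QpcrSeries,
    target: str,
    reference: str,
    sample: str,
    timepoints: list[float] | None = None,
) -> HalfLifeResult:
    """Half-life (minutes) from the decay of target relative to a stable RNA.

    Fits log2(relative quantity) against time by OLS; the series is "not
    estimable" when the fitted slope is non-negative (no decay).
    """
    if timepoints is None:
        timepoints = sorted(
            series.data.loc[series.data["sample"] == sample, "timepoint_min"].unique()
        )
    if len(timepoints) < 3:
        raise ValueError("need >= 3 timepoints for a decay fit")
    log2q = []
    for t in timepoints:
        dct = series.mean_ct(sample, target, t) - series.mean_ct(sample, reference, t)
        # relative quantity E^-dct, in log2 units
        log2q.append(-dct * math.log2(series.efficiency))
    res = stats.linregress(np.asarray(timepoints, float), np.asarray(log2q, float))
    slope = float(res.slope)
    if slope >= 0:
        return HalfLifeResult(target, math.nan, slope, estimable=False)
    return HalfLifeResult(target, -1.0 / slope, slope, estimable=True)
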