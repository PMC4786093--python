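"""End-to-end pipeline: design -> features -> fitness -> decomposition.

The umbrella stage consumes a YAML configuration naming the parent CDS,
the highly expressed reference gene set, the competition trajectory table
and optional ddG / tRNA tables, designs the requested synonymous alleles,
scores their sequence features, estimates per-allele selective
disadvantages, decomposes them per codon and reports the s-versus-N
regressions and predictor correlations.  The merged output table carries
one row per allele with the same quantities as the study's summary table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import competition, decomposition, features, io, kinetics
from .codon_usage import relative_adaptiveness
from .design import DesignSpec, design_allele
from .sequences import CodingSequence, to_dna, to_rna

logger = logging.getLogger(__name__)

MERGED_COLUMNS = [
    "allele", "N", "ddg", "hex_m4", "hex_m6", "log_wa", "delta_t",
    "s_total", "s_ci_low", "s_ci_high", "p_value", "s_per_codon",
]


@dataclass
class AlleleDesignConfig:
    name: str
    replacements: dict[str, str]
    source_filter: dict[str, str] = field(default_factory=dict)
    region: str | tuple[int, int] = "full"
    boundary: int | None = None


@dataclass
class PipelineConfig:
    parent_fasta: str
    reference_fasta: str
    trajectories: str
    designs: list[AlleleDesignConfig]
    out_dir: str = "."
    trna_table: str | None = None
    ddg_table: str | None = None
    control_strain: str = "tufA"
    outlier_window: float = competition.DEFAULT_OUTLIER_WINDOW
    protected_prefix: int = 40
    thresholds: tuple[float, float] = (-4.0, -6.0)
    include_origin: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        designs = [
            AlleleDesignConfig(
                name=d["name"],
                replacements=d["replacements"],
                source_filter=d.get("source_filter", {}),
                region=tuple(d["region"]) if isinstance(d.get("region"), list) else d.get("region", "full"),
                boundary=d.get("boundary"),
            )
            for d in raw.pop("designs")
        ]
        known = {f for f in cls.__dataclass_fields__}
        cfg = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "thresholds" in cfg:
            cfg["thresholds"] = tuple(cfg["thresholds"])
        return cls(designs=designs, **cfg)


@dataclass
class PipelineReport:
    merged: pd.DataFrame
    regressions: dict[str, decomposition.RegressionResult]
    correlations: dict[str, decomposition.RegressionResult]
    results: dict[str, competition.SelectionResult]


def _allele_predictors(
    allele, parent: CodingSequence, wa_table, trna
) -> tuple[float, float]:
    """Substitution-averaged log(wa) difference and translation-time increase."""
    if not allele.substitutions:
        return 0.0, 0.0
    log_was, dts = [], []
    for sub in allele.substitutions:
        syn, wt = to_dna(sub.new), to_dna(sub.original)
        lw = wa_table.log_wa.get(syn, math.nan) - wa_table.log_wa.get(wt, math.nan)
        log_was.append(lw)
        dts.append(trna.delta_t_trans(sub.new, sub.original).delta_t)
    return float(np.mean(log_was)), float(np.mean(dts))


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("[%s] running", name)

    stage("load")
    parent = io.read_fasta(config.parent_fasta)[0]
    reference_genes = io.read_fasta(config.reference_fasta)
    trna = (
        kinetics.TRNAAbundanceTable.from_tsv(config.trna_table)
        if config.trna_table
        else kinetics.TRNAAbundanceTable.default()
    )
    affinity = features.HexamerAffinityModel.default()
    trajectories = competition.read_trajectories(
        io.read_tsv(config.trajectories, required=("strain", "dye", "replicate", "generation"))
    )
    ddg_map: dict[str, float] = {}
    if config.ddg_table:
        ddg_map = {r.allele: r.ddg for r in features.load_ddg(config.ddg_table)}

    stage("codon_usage")
    wa_table = relative_adaptiveness(reference_genes, exclude_first=config.protected_prefix)

    stage("design")
    alleles = {}
    for d in config.designs:
        spec = DesignSpec(
            replacements=d.replacements,
            source_filter=d.source_filter,
            region=d.region,
            protected_prefix=config.protected_prefix,
            boundary=d.boundary,
        )
        alleles[d.name] = design_allele(parent, spec, id=d.name)

    stage("features")
    rows = []
    results: dict[str, competition.SelectionResult] = {}
    strains_in_traj = {t.strain for t in trajectories}
    for name, allele in sorted(alleles.items()):
        scan = features.scan_anti_sd(allele.seq, affinity, config.thresholds)
        log_wa, delta_t = _allele_predictors(allele, parent, wa_table, trna)
        row = {
            "allele": name,
            "N": allele.N,
            "ddg": ddg_map.get(name, math.nan),
            "hex_m4": scan.counts[config.thresholds[0]],
            "hex_m6": scan.counts[config.thresholds[1]],
            "log_wa": log_wa,
            "delta_t": delta_t,
        }
        if name in strains_in_traj:
            res = competition.estimate_allele_disadvantage(
                trajectories, name, config.control_strain, window=config.outlier_window
            )
            results[name] = res
            row.update(
                s_total=res.selective_disadvantage,
                s_ci_low=res.ci95[0],
                s_ci_high=res.ci95[1],
                p_value=res.p_value,
                s_per_codon=(
                    decomposition.per_codon_s(res.selective_disadvantage, allele.N)
                    if allele.N >= 1 and 0 <= res.selective_disadvantage < 1
                    else math.nan
                ),
            )
        else:
            logger.warning("no trajectories for allele %s; fitness columns empty", name)
            row.update(s_total=math.nan, s_ci_low=math.nan, s_ci_high=math.nan,
                       p_value=math.nan, s_per_codon=math.nan)
        rows.append(row)
    merged = pd.DataFrame(rows, columns=MERGED_COLUMNS)

    stage("decomposition")
    regressions: dict[str, decomposition.RegressionResult] = {}
    by_signature: dict[str, list[str]] = {}
    for d in config.designs:
        norm = DesignSpec(replacements=d.replacements).replacements
        sig = ",".join(f"{aa}->{to_rna(c)}" for aa, c in sorted(norm.items()))
        by_signature.setdefault(sig, []).append(d.name)
    for sig, names in sorted(by_signature.items()):
        pts = [
            (float(merged.loc[merged.allele == n, "N"].iloc[0]),
             float(merged.loc[merged.allele == n, "s_total"].iloc[0]))
            for n in names
        ]
        pts = [(n, s) for n, s in pts if not math.isnan(s)]
        if len({p[0] for p in pts}) >= 2:
            try:
                regressions[sig] = decomposition.regress_s_vs_n(
                    pts, include_origin=config.include_origin
                )
            except ValueError:
                pass

    correlations: dict[str, decomposition.RegressionResult] = {}
    valid = merged.dropna(subset=["s_per_codon"])
    for predictor in ("log_wa", "delta_t", "ddg", "hex_m4", "hex_m6"):
        sub = valid.dropna(subset=[predictor])
        if len(sub) >= 3 and sub[predictor].nunique() > 1:
            correlations[predictor] = decomposition.correlate(
                sub[predictor].tolist(), sub["s_per_codon"].tolist()
            )

    stage("write")
    io.write_tsv(merged, out_dir / "merged.tsv")
    _write_report(out_dir / "report.txt", merged, regressions, correlations)
    return PipelineReport(merged, regressions, correlations, results)


def _write_report(path, merged, regressions, correlations) -> None:
    lines = ["Synonymous-allele fitness pipeline report", ""]
    lines.append(f"{len(merged)} alleles analysed")
    lines.append("")
    lines.append("s-vs-N regressions (per-codon cost = slope):")
    for sig, r in regressions.items():
        lines.append(
            f"  {sig}: slope={r.slope:.3e} r2={r.r_squared:.3f} p={r.p_value:.3g}"
        )
    lines.append("")
    lines.append("per-codon s correlations:")
    for predictor, r in correlations.items():
        lines.append(
            f"  vs {predictor}: slope={r.slope:.3e} r2={r.r_squared:.3f} p={r.p_value:.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
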