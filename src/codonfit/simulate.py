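"""Synthetic inputs for every pipeline stage.

The generators emulate the study conditions end to end: a reference set of
highly expressed genes with strongly biased codon usage; serial-transfer
competition trajectories (ln-ratio observations every ten generations over
thirty, Gaussian measurement noise, occasional persistent outlier jumps
from secondary genetic changes, dye-swapped batches with an additive
marker effect); and rifampicin run-out qPCR Ct series with efficiency-2
amplification, stable reference genes and Gaussian Ct noise.

All randomness flows from ``SimulationConfig.seed`` through independent
per-generator streams, so identical configurations give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import FAMILIES, CodingSequence

#: Preferred codon per amino acid used for the default biased usage
#: (DNA alphabet; matches optima typical of enterobacterial highly
#: expressed genes, including the four families studied here).
OPTIMAL_CODONS: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTT",
}


def default_family_probs(bias: float = 0.75) -> dict[str, dict[str, float]]:
    """Codon-sampling probabilities per family: the preferred codon takes
    ``bias`` of the mass, the rest is shared uniformly."""
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            probs[aa] = {codons[0]: 1.0}
            continue
        rest = (1.0 - bias) / (len(codons) - 1)
        probs[aa] = {c: (bias if c == OPTIMAL_CODONS[aa] else rest) for c in codons}
    return probs


@dataclass
class SimulationConfig:
    """Defaults mirror the study conditions: twelve replicate cultures per
    dye batch with the dye swap on (24 effective replicates per group),
    ratios read at generations 0/10/20/30, per-observation ln-ratio noise
    0.025 (0.0025 x 10 per ten-generation interval), a 2% chance per
    replicate of a persistent 0.015-per-generation slope jump emulating a
    secondary genetic change, and an additive per-dye marker effect that
    normalisation must cancel."""

    seed: int = 0
    n_genes: int = 55
    gene_length: int = 300  # codons, incl. start, excl. stop
    family_probs: dict[str, dict[str, float]] = field(default_factory=default_family_probs)
    true_disadvantages: dict[str, float] = field(default_factory=dict)
    generations: tuple[int, ...] = (0, 10, 20, 30)
    sigma_lnratio: float = 0.025
    outlier_prob: float = 0.02
    outlier_jump: float = 0.015
    replicates: int = 12
    dye_swap: bool = True
    dye_effect: float = 0.001
    control_strain: str = "tufA"
    flow_events: int | None = None  # enable count-level binomial sampling
    sigma_ct: float = 0.1
    qpcr_timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    qpcr_dilutions: tuple[float, ...] = (1.0, 0.1, 0.01)

    def __post_init__(self) -> None:
        for aa, probs in self.family_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"family probabilities for {aa} sum to {total}, not 1")
        if self.sigma_lnratio < 0 or self.sigma_ct < 0:
            raise ValueError("noise sigma must be non-negative")
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, stream])


_STREAM_GENES, _STREAM_COMP, _STREAM_QPCR = 1, 2, 3


def make_biased_gene_set(config: SimulationConfig) -> list[CodingSequence]:
    """Reference-set stand-in: genes drawn codon-wise from the configured
    family probabilities (start ATG, terminal TAA, no internal stops)."""
    rng = config.rng(_STREAM_GENES)
    aas = sorted(config.family_probs)
    genes = []
    for g in range(config.n_genes):
        codons = ["ATG"]
        for _ in range(config.gene_length - 1):
            aa = aas[rng.integers(len(aas))]
            fam = config.family_probs[aa]
            members = sorted(fam)
            codons.append(members[rng.choice(len(members), p=[fam[c] for c in members])])
        codons.append("TAA")
        genes.append(CodingSequence(id=f"synth_{g + 1:03d}", seq="".join(codons)))
    return genes


def simulate_competitions(
    config: SimulationConfig,
    disadvantages: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Trajectory table for every strain (control included) in both dye batches.

    ln(ratio) at generation g is  -s_true*g + dye_effect(batch)*g + jump*g + eps
    with eps ~ N(0, sigma_lnratio) per observation.  Outlier replicates
    (probability ``outlier_prob``) carry a persistent slope jump of
    magnitude ``outlier_jump`` with random sign.  When ``flow_events`` is
    set, ratios are re-derived from binomial sampling of that many
    flow-cytometer events.
    """
    rng = config.rng(_STREAM_COMP)
    disadvantages = dict(disadvantages or config.true_disadvantages)
    disadvantages.setdefault(config.control_strain, 0.0)
    for strain, s in disadvantages.items():
        if not 0 <= s <= 0.05:
            raise ValueError(f"{strain}: true disadvantage {s} outside [0, 0.05]")
    dyes = ("YFP", "BFP") if config.dye_swap else ("YFP",)
    gens = np.asarray(config.generations, float)
    rows = []
    for strain in sorted(disadvantages):
        s_true = disadvantages[strain]
        for dye in dyes:
            dye_slope = config.dye_effect if dye == "YFP" else -config.dye_effect
            for rep in range(1, config.replicates + 1):
                jump = 0.0
                if rng.random() < config.outlier_prob:
                    jump = config.outlier_jump * (1 if rng.random() < 0.5 else -1)
                noise = rng.normal(0.0, config.sigma_lnratio, size=gens.size)
                if config.sigma_lnratio == 0:
                    noise = np.zeros_like(gens)
                lnratio = (-s_true + dye_slope + jump) * gens + noise
                ratio = np.exp(lnratio)
                if config.flow_events:
                    frac = ratio / (1.0 + ratio)
                    focal = rng.binomial(config.flow_events, frac)
                    focal = np.clip(focal, 1, config.flow_events - 1)
                    ratio = focal / (config.flow_events - focal)
                for g, r in zip(gens, ratio):
                    rows.append(
                        {
                            "strain": strain,
                            "dye": dye,
                            "replicate": rep,
                            "generation": int(g),
                            "ratio": r,
                            "outlier": bool(jump),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_qpcr(
    config: SimulationConfig,
    fold_changes: dict[str, float],
    half_lives: dict[str, float],
    target: str = "tuf",
    references: tuple[str, ...] = ("cysG", "hcaT", "idnT"),
    decay_reference: str = "tmRNA",
) -> pd.DataFrame:
    """Rifampicin run-out Ct table for each allele (sample).

    Reference genes are stable; the target's quantity decays 2-fold every
    half-life, i.e. its Ct rises by t / t_half cycles at efficiency 2.
    Dilution d raises every Ct by log2(1/d).  Gaussian Ct noise applies to
    every well.
    """
    rng = config.rng(_STREAM_QPCR)
    for allele, hl in half_lives.items():
        if not hl > 0:
            raise ValueError(f"{allele}: half-life must be positive")
    base_ct = {target: 16.0, decay_reference: 14.0, **{g: 20.0 for g in references}}
    rows = []
    for sample in sorted(fold_changes):
        fc, hl = fold_changes[sample], half_lives[sample]
        for t in config.qpcr_timepoints:
            for gene in (target, decay_reference, *references):
                ct = base_ct[gene]
                if gene == target:
                    ct -= np.log2(fc)
                    ct += t / hl
                for d in config.qpcr_dilutions:
                    noise = rng.normal(0.0, config.sigma_ct) if config.sigma_ct else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "gene": gene,
                            "timepoint_min": t,
                            "dilution": d,
                            "ct": ct + np.log2(1.0 / d) + noise,
                        }
                    )
    return pd.DataFrame(rows)
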