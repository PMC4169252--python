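"""Synthetic SILAC kinetic-degradome experiments with planted ground truth.

The generator emulates a three-channel (light/medium/heavy arginine) SILAC
experiment in which a proteome is incubated with a protease for 10, 30 and
60 min and N-terminal peptides are read out with two log2 channel ratios
(time point 2 vs 1 and 3 vs 2).

Kinetic model: a substrate pool S0 cleaved with first-order rate constant k
accumulates neo-N-terminus product N(t) = S0 * (1 - exp(-k t)), so the
expected log2 ratio between two time points is
log2[(1 - e^(-k t_late)) / (1 - e^(-k t_early))]. A fast substrate
(k >> 1/t_early) is fully cleaved before the first time point and its ratios
sit at 0 like a stable annotated N-terminus; a slow substrate is still
accumulating and its ratios approach the k -> 0 limit log2(t_late/t_early).
One rate parameter therefore realizes both the "efficient" and the
"bystander" regime.

Stable annotated N-termini draw their ratio pairs from the two null normals;
their non-zero means are a deliberate global shift so that the downstream
ratio correction has real work to do. Neo-N-termini get the kinetic
expectation plus the same per-axis shift plus additive Gaussian noise on the
log2 scale (equivalently multiplicative lognormal noise on the raw scale).

Everything is driven by one integer seed through a single generator
instance; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import (
    NTermMod,
    NTermPeptide,
    ProteinRecord,
    write_fasta,
    write_peptide_table,
)
from .sites import CleavageSite

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def expected_log2_ratio(k: float, t_early: float, t_late: float) -> float:
    """Expected log2 product ratio between two time points under first-order cleavage.

    log2[(1 - e^(-k t_late)) / (1 - e^(-k t_early))]; strictly decreasing in
    k, -> 0 as k -> inf and -> log2(t_late/t_early) as k -> 0.
    """
    if k <= 0 or t_early <= 0 or t_late <= t_early:
        raise ValueError("need k > 0 and 0 < t_early < t_late")
    # expm1 keeps the k -> 0 limit accurate
    return float(np.log2(-np.expm1(-k * t_late)) - np.log2(-np.expm1(-k * t_early)))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: 541 stable annotated N-termini, 9 efficiently
    and 28 slowly cleaved substrates, 10/30/60 min, null normals
    N(-0.003, 0.1451) and N(0.009, 0.1871), noise matched to the null scales."""

    seed: int = 0
    n_annotated: int = 541
    n_efficient: int = 9
    n_bystander: int = 28
    time_points: tuple[float, float, float] = (10.0, 30.0, 60.0)
    null_params: tuple[float, float, float, float] = (-0.003, 0.1451, 0.009, 0.1871)
    k_fast_range: tuple[float, float] = (0.5, 5.0)
    k_slow_range: tuple[float, float] = (0.001, 0.02)
    noise_sd: tuple[float, float] = (0.1451, 0.1871)
    protein_length_range: tuple[int, int] = (100, 600)
    motif_plant: str | None = "IEAD"

    def __post_init__(self) -> None:
        if min(self.n_annotated, self.n_efficient, self.n_bystander) < 0:
            raise ValueError("counts must be >= 0")
        t = self.time_points
        if not 0 < t[0] < t[1] < t[2]:
            raise ValueError("time points must be positive and strictly increasing")
        for rng_ in (self.k_fast_range, self.k_slow_range):
            if not 0 < rng_[0] <= rng_[1]:
                raise ValueError(f"rate range must be positive and ordered: {rng_}")
        if self.k_slow_range[1] >= self.k_fast_range[0]:
            raise ValueError("slow and fast rate ranges must not overlap")
        if min(self.noise_sd) < 0 or self.null_params[1] <= 0 or self.null_params[3] <= 0:
            raise ValueError("scales must be positive")
        lo, hi = self.protein_length_range
        if not 30 <= lo <= hi:
            raise ValueError("protein lengths must be >= 30 and ordered")
        # bystanders must be detectable: the smallest expected axis-a shift
        # (slowest separation is at the fastest slow rate) >= 5 x max noise sd
        min_shift = abs(expected_log2_ratio(self.k_slow_range[1], t[0], t[1]))
        if self.n_bystander and min_shift < 5.0 * max(self.noise_sd):
            raise ValueError(
                f"bystander/noise separation too small: min expected |log2 ratio| "
                f"{min_shift:.3f} < 5 x noise sd {5 * max(self.noise_sd):.3f}"
            )


@dataclass(frozen=True)
class GroundTruthRecord:
    protein_acc: str
    p1_pos: int
    k: float
    planted_class: str  # "efficient" | "bystander"

    @property
    def site(self) -> CleavageSite:
        return CleavageSite(self.protein_acc, self.p1_pos)


_AA_ARR = np.frombuffer(AA20.encode(), dtype="S1")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = _AA_ARR[rng.integers(0, len(AA20), size=length - 1)].tobytes().decode()
    return "M" + body


def simulate_proteome(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[CleavageSite]]:
    """Random protein database with one planted motif site per substrate protein.

    Returns the records (substrate proteins first, then one background
    protein per annotated N-terminus) and the planted cleavage sites
    (P1 = last motif residue; neo start positions never fall at 1-2).
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    n_sub = config.n_efficient + config.n_bystander
    records: list[ProteinRecord] = []
    planted: list[CleavageSite] = []
    for i in range(n_sub):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        acc = f"SUB{i + 1:04d}"
        p1 = int(rng.integers(5, length - 25))
        if config.motif_plant:
            seq = seq[: p1 - 4] + config.motif_plant + seq[p1:]
        records.append(ProteinRecord(acc, f"synthetic substrate protein {i + 1}", seq))
        planted.append(CleavageSite(acc, p1))
    for i in range(config.n_annotated):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteinRecord(
                f"BKG{i + 1:04d}",
                f"synthetic background protein {i + 1}",
                _random_protein(rng, length),
            )
        )
    return records, planted


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[NTermPeptide], list[GroundTruthRecord]]:
    """Full synthetic experiment: protein FASTA, peptide table and ground truth.

    Annotated N-termini start at position 1 or 2 (mixed acetyl /
    trideuteroacetyl) with ratio pairs from the null normals; neo-N-termini
    start at P1' = p1 + 1 with trideuteroacetyl and kinetic ratios. The
    peptide table round-trips through :mod:`kindeg.io` unchanged.
    """
    proteins, planted = simulate_proteome(config)
    rng = np.random.default_rng(config.seed + 1)
    mu_a, sd_a, mu_b, sd_b = config.null_params
    t1, t2, t3 = config.time_points
    by_acc = {p.accession: p for p in proteins}

    peptides: list[NTermPeptide] = []
    n_sub = config.n_efficient + config.n_bystander
    for i, rec in enumerate(proteins[n_sub:], start=1):
        start = int(rng.integers(1, 3))
        length = int(rng.integers(8, 26))
        mod = NTermMod.ACETYL if rng.random() < 0.8 else NTermMod.TRIDEUTEROACETYL
        peptides.append(
            NTermPeptide(
                peptide_id=f"ann{i:04d}",
                sequence=rec.sequence[start - 1 : start - 1 + length],
                protein_acc=rec.accession,
                start_pos=start,
                nterm_mod=mod,
                ratio_a=float(rng.normal(mu_a, sd_a)),
                ratio_b=float(rng.normal(mu_b, sd_b)),
            )
        )

    truth: list[GroundTruthRecord] = []
    classes = ["efficient"] * config.n_efficient + ["bystander"] * config.n_bystander
    for i, (site, cls) in enumerate(zip(planted, classes), start=1):
        if cls == "efficient":
            k = float(rng.uniform(*config.k_fast_range))
        else:
            k = float(rng.uniform(*config.k_slow_range))
        rec = by_acc[site.protein_acc]
        length = int(rng.integers(8, 26))
        neo_start = site.p1_pos + 1
        ra = expected_log2_ratio(k, t1, t2) + mu_a + float(rng.normal(0.0, config.noise_sd[0]))
        rb = expected_log2_ratio(k, t2, t3) + mu_b + float(rng.normal(0.0, config.noise_sd[1]))
        peptides.append(
            NTermPeptide(
                peptide_id=f"neo{i:04d}",
                sequence=rec.sequence[neo_start - 1 : neo_start - 1 + length],
                protein_acc=rec.accession,
                start_pos=neo_start,
                nterm_mod=NTermMod.TRIDEUTEROACETYL,
                ratio_a=ra,
                ratio_b=rb,
            )
        )
        truth.append(GroundTruthRecord(site.protein_acc, site.p1_pos, k, cls))

    return proteins, peptides, truth


def write_experiment(
    config: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write proteins.fasta, peptides.tsv, truth.tsv and config-echo.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, peptides, truth = simulate_experiment(config)
    paths = {
        "fasta": out / "proteins.fasta",
        "peptides": out / "peptides.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config-echo.yaml",
    }
    write_fasta(proteins, paths["fasta"])
    write_peptide_table(peptides, paths["peptides"])
    with paths["truth"].open("w") as fh:
        fh.write("protein_acc\tp1_pos\tk_per_min\tplanted_class\n")
        for t in truth:
            fh.write(f"{t.protein_acc}\t{t.p1_pos}\t{t.k:.10g}\t{t.planted_class}\n")
    paths["config"].write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return paths
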