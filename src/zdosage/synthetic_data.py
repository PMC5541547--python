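"""Negative-binomial RNA-seq simulator with known dosage ground truth.

The generator emulates the statistical shape of the study system — a
silkworm-like transcriptome of ~10 000 expressed genes of which ~450 are
Z-linked — without modelling any real gene: gene-wise baselines are
lognormal, counts are overdispersed negative binomial, technical replicates
are independent draws, and a small fraction of genes is silent per sex.
Dosage structure enters through three per-stage multipliers:

* ``z_dose_male`` / ``z_dose_female`` — the Z-gene expression factor per
  sex.  Equal values < 1 model a compensated Z expressed below autosomes in
  both sexes; a male excess models uncompensated early stages.
* ``male_global_bias`` — a genome-wide male multiplier, so autosomal M:F
  sits above 1 at uncompensated stages, as a global expression shift.

The implied truth: per-gene expected Z M:F is
``z_dose_male * male_global_bias / z_dose_female``, autosomal M:F is
``male_global_bias``, and the within-sample Z:A factor is ``z_dose_male``
(male) or ``z_dose_female`` (female), since the global bias cancels within
a sample.  A genome-wide bias is only observable when expression is
normalized against *fixed* library sizes; depth renormalization (FPKM on
column sums, TMM) removes it by construction.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, SampleMeta

__all__ = [
    "StageParams",
    "SimParams",
    "SimTruth",
    "SimulatedDataset",
    "default_gene_counts",
    "generate_dataset",
    "scenario_presets",
    "null_params",
    "write_fixture_files",
]

_GENES_PER_SCAFFOLD = 50


@dataclasses.dataclass(frozen=True)
class StageParams:
    """Per-stage dosage parameters."""

    name: str
    male_global_bias: float = 1.0
    z_dose_male: float = 1.0
    z_dose_female: float = 1.0

    @property
    def z_mf_truth(self) -> float:
        return self.z_dose_male * self.male_global_bias / self.z_dose_female

    @property
    def a_mf_truth(self) -> float:
        return self.male_global_bias


def default_gene_counts(n_z: int = 450, n_autosomal: int = 9600) -> dict[int, int]:
    """Gene counts per chromosome: chromosome 1 is Z, autosomes 2–28 share the rest."""
    counts = {1: n_z}
    base, rem = divmod(n_autosomal, 27)
    for i, chrom in enumerate(range(2, 29)):
        counts[chrom] = base + (1 if i < rem else 0)
    return counts


@dataclasses.dataclass
class SimParams:
    """Generator settings; the defaults describe an embryo-like sample.

    ``baseline_log2_mean``/``sd`` set the gene-wise lognormal expression
    baseline (log2 scale); ``dispersion`` is the negative-binomial size
    parameter (smaller = more overdispersed); ``silent_fraction`` is the
    probability a gene is off in one sex; ``unmapped_fraction`` places genes
    on scaffolds absent from the scaffold→chromosome map, exercising the
    unplaced-gene path.
    """

    stages: list[StageParams]
    n_genes_per_chromosome: dict[int, int] = dataclasses.field(
        default_factory=default_gene_counts
    )
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 10.0
    library_size: int = 10_000_000
    silent_fraction: float = 0.05
    n_technical_replicates: int = 2
    gene_length_log_mean: float = math.log(1500.0)
    gene_length_log_sd: float = 0.5
    unmapped_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage is required")
        if not 0 <= self.silent_fraction < 1:
            raise ValueError("silent_fraction must be in [0, 1)")
        if not 0 <= self.unmapped_fraction < 1:
            raise ValueError("unmapped_fraction must be in [0, 1)")
        for name, v in [
            ("dispersion", self.dispersion),
            ("library_size", self.library_size),
            ("n_technical_replicates", self.n_technical_replicates),
            ("baseline_log2_sd", self.baseline_log2_sd),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for s in self.stages:
            if min(s.male_global_bias, s.z_dose_male, s.z_dose_female) <= 0:
                raise ValueError(f"stage {s.name!r}: all dose factors must be positive")
        if any(n < 1 for n in self.n_genes_per_chromosome.values()):
            raise ValueError("every chromosome needs at least one gene")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated dataset, derived from its parameters."""

    z_mf: dict[str, float]  # stage -> expected per-gene Z M:F ratio
    a_mf: dict[str, float]  # stage -> expected per-gene autosomal M:F ratio
    za_factor_male: dict[str, float]  # stage -> within-sample Z:A factor, males
    za_factor_female: dict[str, float]
    gene_means: pd.DataFrame  # realized expected count per gene x sample


@dataclasses.dataclass
class SimulatedDataset:
    counts: ExpressionMatrix  # raw counts with gene lengths attached
    gene_chromosome: dict[str, int | str]  # gene -> chromosome (or "unplaced")
    gene_scaffold: dict[str, str]
    scaffold_map: dict[str, int]  # scaffold -> chromosome, unmapped scaffolds absent
    truth: SimTruth
    params: SimParams


def generate_dataset(params: SimParams) -> SimulatedDataset:
    """Draw one complete dataset (counts, linkage tables, ground truth).

    Counts are ``NB(mean, size=dispersion)`` with
    ``mean = library_size * baseline_share(g) * dose_factor(g, sex, stage)``
    where the baseline share is the gene's fragment weight
    (baseline × length) over the total baseline weight, so an unbiased
    sample totals ~``library_size`` fragments.  Technical replicates are
    independent draws.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    chroms = sorted(params.n_genes_per_chromosome)
    gene_ids: list[str] = []
    gene_chrom_true: list[int] = []
    for chrom in chroms:
        n = params.n_genes_per_chromosome[chrom]
        gene_ids += [f"SIMG{chrom:02d}{i:05d}" for i in range(n)]
        gene_chrom_true += [chrom] * n
    n_genes = len(gene_ids)
    chrom_arr = np.array(gene_chrom_true)
    is_z = chrom_arr == 1

    baseline = 2.0 ** rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_genes)
    lengths = np.maximum(
        100, np.round(rng.lognormal(params.gene_length_log_mean, params.gene_length_log_sd, n_genes))
    ).astype(int)
    weight = baseline * lengths
    share = weight / weight.sum()

    # silencing: a gene is off in a given sex (all stages and replicates)
    silent = {
        sex: rng.random(n_genes) < params.silent_fraction for sex in ("male", "female")
    }

    # scaffold layout: contiguous runs of genes share a scaffold; a fraction of
    # scaffolds is withheld from the map to create unplaced genes
    gene_scaffold: dict[str, str] = {}
    scaffold_map: dict[str, int] = {}
    scaf_idx = 0
    unmapped_scafs: set[str] = set()
    for chrom in chroms:
        ids = [g for g, c in zip(gene_ids, gene_chrom_true) if c == chrom]
        for start in range(0, len(ids), _GENES_PER_SCAFFOLD):
            scaf = f"nscaf{scaf_idx:04d}"
            scaf_idx += 1
            for g in ids[start : start + _GENES_PER_SCAFFOLD]:
                gene_scaffold[g] = scaf
            if rng.random() < params.unmapped_fraction:
                unmapped_scafs.add(scaf)
            else:
                scaffold_map[scaf] = chrom
    gene_chromosome: dict[str, int | str] = {
        g: (scaffold_map[s] if s in scaffold_map else "unplaced")
        for g, s in gene_scaffold.items()
    }

    cols: dict[str, np.ndarray] = {}
    metas: list[SampleMeta] = []
    mean_cols: dict[str, np.ndarray] = {}
    for stage in params.stages:
        for sex in ("male", "female"):
            factor = np.ones(n_genes)
            if sex == "male":
                factor *= stage.male_global_bias
                factor[is_z] *= stage.z_dose_male
            else:
                factor[is_z] *= stage.z_dose_female
            mean = params.library_size * share * factor
            mean[silent[sex]] = 0.0
            for rep in range(1, params.n_technical_replicates + 1):
                sid = f"{sex}_{stage.name}_r{rep}"
                with np.errstate(divide="ignore", invalid="ignore"):
                    p = params.dispersion / (params.dispersion + mean)
                draw = np.where(
                    mean > 0, rng.negative_binomial(params.dispersion, np.minimum(p, 1.0)), 0
                )
                cols[sid] = draw.astype(float)
                metas.append(SampleMeta(sid, sex, stage.name, rep))
                mean_cols[sid] = mean.copy()

    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    counts = ExpressionMatrix(
        values, "raw_counts", metas, pd.Series(lengths, index=values.index)
    )
    truth = SimTruth(
        z_mf={s.name: s.z_mf_truth for s in params.stages},
        a_mf={s.name: s.a_mf_truth for s in params.stages},
        za_factor_male={s.name: s.z_dose_male for s in params.stages},
        za_factor_female={s.name: s.z_dose_female for s in params.stages},
        gene_means=pd.DataFrame(mean_cols, index=values.index),
    )
    return SimulatedDataset(counts, gene_chromosome, gene_scaffold, scaffold_map, truth, params)


def scenario_presets(
    name: str,
    n_z: int = 450,
    n_autosomal: int = 5000,
    seed: int = 0,
) -> SimParams:
    """Named study-like scenarios.

    ``uncompensated_early``
        One early-embryo stage with Z M:F truth 1.5 riding on a global male
        bias of 1.35 (Z dose 0.50 male / 0.45 female).
    ``compensated_head``
        One head-like stage: Z and A M:F truth 1.0, Z:A factor 0.6 in both
        sexes.
    ``bombyx_like_timecourse``
        Four stages (78 h, 96 h, 120 h, head) with monotonically decreasing
        Z M:F truth 1.6 → 1.5 → 1.05 → 1.0, tracing the male-biased →
        compensated trajectory.
    """
    stages = {
        "uncompensated_early": [
            StageParams("early", male_global_bias=1.35, z_dose_male=0.50, z_dose_female=0.45),
        ],
        "compensated_head": [
            StageParams("head", male_global_bias=1.0, z_dose_male=0.6, z_dose_female=0.6),
        ],
        "bombyx_like_timecourse": [
            StageParams("78h", male_global_bias=1.35, z_dose_male=0.48, z_dose_female=0.405),
            StageParams("96h", male_global_bias=1.35, z_dose_male=0.50, z_dose_female=0.45),
            StageParams("120h", male_global_bias=1.0, z_dose_male=0.525, z_dose_female=0.50),
            StageParams("head", male_global_bias=1.0, z_dose_male=0.6, z_dose_female=0.6),
        ],
    }
    if name not in stages:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(stages)}")
    return SimParams(
        stages=stages[name],
        n_genes_per_chromosome=default_gene_counts(n_z=n_z, n_autosomal=n_autosomal),
        seed=seed,
    )


def null_params(n_z: int = 450, n_autosomal: int = 5000, seed: int = 0) -> SimParams:
    """A no-effect configuration: all dose factors 1, no silent genes."""
    return SimParams(
        stages=[StageParams("null")],
        n_genes_per_chromosome=default_gene_counts(n_z=n_z, n_autosomal=n_autosomal),
        silent_fraction=0.0,
        seed=seed,
    )


def write_fixture_files(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the readers consume.

    Produces ``counts.tsv`` (gene × sample raw counts), ``samples.tsv``
    (sample metadata), ``gene_lengths.tsv``, ``genes.gff3`` (gene features
    on their scaffolds) and ``scaffold_map.tsv`` (scaffold → chromosome,
    unmapped scaffolds absent), making end-to-end runs self-contained.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    counts_df = dataset.counts.values.astype(int)
    counts_df.index.name = "gene_id"
    paths["counts"] = out_dir / "counts.tsv"
    counts_df.to_csv(paths["counts"], sep="\t")

    meta = pd.DataFrame(
        [(s.sample_id, s.sex, s.stage, s.replicate) for s in dataset.counts.samples],
        columns=["sample_id", "sex", "stage", "replicate"],
    )
    paths["samples"] = out_dir / "samples.tsv"
    meta.to_csv(paths["samples"], sep="\t", index=False)

    lengths = dataset.counts.gene_lengths.rename("length").to_frame()
    lengths.index.name = "gene_id"
    paths["gene_lengths"] = out_dir / "gene_lengths.tsv"
    lengths.to_csv(paths["gene_lengths"], sep="\t")

    paths["gff"] = out_dir / "genes.gff3"
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        pos: dict[str, int] = {}
        for gene in dataset.counts.gene_ids:
            scaf = dataset.gene_scaffold[gene]
            start = pos.get(scaf, 1)
            length = int(dataset.counts.gene_lengths[gene])
            end = start + length - 1
            fh.write(
                f"{scaf}\tzdosage_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gene}\n"
            )
            pos[scaf] = end + 100
    paths["scaffold_map"] = out_dir / "scaffold_map.tsv"
    with open(paths["scaffold_map"], "w") as fh:
        for scaf, chrom in sorted(dataset.scaffold_map.items()):
            fh.write(f"{scaf}\t{chrom}\n")
    return paths
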