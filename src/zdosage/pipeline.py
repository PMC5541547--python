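"""End-to-end orchestration of the dosage analysis, plus the CLI.

The full run mirrors the analysis of a sexed RNA-seq time course:

1. read the expression table, sample metadata and gene → chromosome map;
2. derive FPKM from counts when needed and average technical replicates;
3. split genes into autosomal and Z-linked sets, dropping unplaced genes;
4. per sample — true-expression filter, Z:A summary, bootstrap CI,
   independent-quartile comparison of the Z-linked data;
5. per stage — genes expressed in both sexes, M:F ratio summary (FPKM
   path), the same under TMM normalization after the low-count filter
   (counts input only), and a paired-max quartile comparison;
6. export the Z-linked log2 profile matrix and write all tables plus a JSON
   manifest.

Each stage is also exposed as a CLI subcommand so each summary table can be
reproduced on its own: ``zdosage all --config run.yaml``.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from importlib import metadata as _im
from pathlib import Path
from typing import Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import binning, dosage_stats, expr_io, linkage, profile_export, quantify
from . import resampling, synthetic_data

__all__ = ["RunConfig", "run_dosage_analysis", "cli"]

logger = logging.getLogger(__name__)

ALL_STEPS = ("za", "bootstrap", "mf", "quartiles", "profile")


@dataclasses.dataclass
class RunConfig:
    """Settings of one analysis run (YAML-loadable)."""

    expression_table: str
    sample_metadata: str
    gff: str
    scaffold_map: str
    out_dir: str
    unit: str = "raw_counts"
    gene_lengths: str | None = None  # TSV gene_id<TAB>length; required for counts
    library_sizes: str | float = "from column sums"
    z_chromosome: int = 1
    min_count: int = 4
    logratio_trim: float = 0.30
    intensity_trim: float = 0.05
    tmm_reference: str = "auto"
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    cluster_k: int | None = None
    profile_floor: float = profile_export.DEFAULT_FLOOR

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    """Wrap a pipeline stage so failures carry the stage name."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("read")
def _load_inputs(config: RunConfig):
    lengths = None
    if config.gene_lengths:
        ldf = pd.read_csv(config.gene_lengths, sep="\t", index_col="gene_id")
        lengths = ldf.iloc[:, 0]
    matrix = expr_io.read_expression_table(
        config.expression_table, config.unit, config.sample_metadata, gene_lengths=lengths
    )
    gene_chrom = expr_io.read_gene_chromosome_map(config.gff, config.scaffold_map)
    return matrix, gene_chrom


@_stage("quantify")
def _to_fpkm(matrix: expr_io.ExpressionMatrix, config: RunConfig) -> expr_io.ExpressionMatrix:
    if matrix.unit == "fpkm":
        return matrix
    if isinstance(config.library_sizes, str):
        sizes = config.library_sizes
    else:
        sizes = {s: float(config.library_sizes) for s in matrix.sample_ids}
    return quantify.compute_fpkm(matrix, sizes)


def run_dosage_analysis(
    config: RunConfig, steps: Sequence[str] = ALL_STEPS
) -> dict:
    """Run the selected pipeline steps and write their result tables.

    Returns a dict with the in-memory results (``dosage``, ``bootstrap``,
    ``mf``, ``quartile`` row collections and the ``profile`` matrix).  On
    any stage failure the partially written output directory is removed and
    the stage-named error re-raised.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    try:
        return _run(config, steps, out_dir)
    except Exception:
        if created and out_dir.exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run(config: RunConfig, steps: Sequence[str], out_dir: Path) -> dict:
    matrix, gene_chrom = _load_inputs(config)
    fpkm = _to_fpkm(matrix, config)
    averaged = quantify.average_replicates(fpkm)
    a_sub, z_sub, dropped = linkage.assign_linkage(
        averaged, gene_chrom, config.z_chromosome
    )
    logger.info(
        "linkage: %d autosomal, %d Z-linked, %d unplaced genes dropped",
        len(a_sub.gene_ids), len(z_sub.gene_ids), len(dropped),
    )

    results: dict[str, list] = {"dosage": [], "bootstrap": [], "mf": [], "quartile": []}
    out: dict = dict(results)

    per_sample_a = quantify.filter_true_expression(a_sub, "per_sample")
    per_sample_z = quantify.filter_true_expression(z_sub, "per_sample")

    rng = np.random.default_rng(config.seed)
    boot_seeds = {
        sid: int(s) for sid, s in
        zip(averaged.sample_ids, rng.integers(0, 2**31 - 1, len(averaged.sample_ids)))
    }

    if "za" in steps or "bootstrap" in steps or "quartiles" in steps:
        for sid in averaged.sample_ids:
            a_vals = per_sample_a[sid].values[sid].to_numpy()
            z_vals = per_sample_z[sid].values[sid].to_numpy()
            logger.info(
                "true expression (%s): %d autosomal + %d Z-linked genes",
                sid, a_vals.size, z_vals.size,
            )
            if "za" in steps:
                summ = dosage_stats.za_summary(a_vals, z_vals, sid)
                results["dosage"].append(summ.as_row())
            if "bootstrap" in steps:
                boot = resampling.bootstrap_za_median(
                    a_vals, z_vals, config.n_boot, config.ci_level, boot_seeds[sid]
                )
                results["bootstrap"].append(boot.as_row(sample=sid))

    by_stage: dict[str, dict[str, str]] = {}
    for s in averaged.samples:
        if s.sex in ("male", "female"):
            by_stage.setdefault(s.stage, {})[s.sex] = s.sample_id

    if "quartiles" in steps:
        # independent binning of the per-sample Z-linked true-expression data
        for stage, sexes in by_stage.items():
            if set(sexes) != {"male", "female"}:
                continue
            zm = per_sample_z[sexes["male"]].values[sexes["male"]]
            zf = per_sample_z[sexes["female"]].values[sexes["female"]]
            bins_m = binning.independent_quartiles(zm.to_numpy(), list(zm.index))
            bins_f = binning.independent_quartiles(zf.to_numpy(), list(zf.index))
            report = binning.quartile_compare(
                bins_m, bins_f, zm.to_dict(), zf.to_dict(), "independent"
            )
            results["quartile"] += report.as_rows(label=stage)

    if "mf" in steps or "quartiles" in steps:
        both = quantify.filter_true_expression(averaged, "both_sexes")
        for stage, pair in both.items():
            male_col, female_col = pair.sample_ids
            m = pair.values[male_col].to_numpy()
            f = pair.values[female_col].to_numpy()
            ratios, _ = dosage_stats.mf_ratios(m, f)
            genes = pair.gene_ids
            z_mask = np.array([gene_chrom.get(g) == config.z_chromosome for g in genes])
            a_mask = np.array(
                [isinstance(gene_chrom.get(g), int) and gene_chrom[g] != config.z_chromosome
                 for g in genes]
            )
            if "mf" in steps and z_mask.any() and a_mask.any():
                summ = dosage_stats.mf_summary(
                    ratios[z_mask], ratios[a_mask], stage,
                    pairs_Z=(m[z_mask], f[z_mask]), pairs_A=(m[a_mask], f[a_mask]),
                )
                results["mf"].append(summ.as_row())
            if "quartiles" in steps and z_mask.sum() >= 4:
                z_genes = [g for g, zm_ in zip(genes, z_mask) if zm_]
                zm_vals = m[z_mask]
                zf_vals = f[z_mask]
                bins = binning.paired_max_quartiles(zm_vals, zf_vals, z_genes)
                report = binning.quartile_compare(
                    bins, bins, dict(zip(z_genes, zm_vals)), dict(zip(z_genes, zf_vals)),
                    "paired_max",
                )
                results["quartile"] += report.as_rows(label=f"{stage}_mf")

    if "mf" in steps and matrix.unit == "raw_counts":
        out["mf_tmm"] = _mf_tmm(matrix, gene_chrom, config)
        results["mf_tmm"] = [s.as_row() for s in out["mf_tmm"]]

    if "profile" in steps:
        profile = profile_export.z_profile_matrix(
            averaged, gene_chrom, config.z_chromosome, config.profile_floor
        )
        out["profile"] = profile
        out_dir.mkdir(parents=True, exist_ok=True)
        profile.index.name = "gene_id"
        profile.to_csv(out_dir / "z_profile.tsv", sep="\t", float_format="%.6f")
        if config.cluster_k:
            labels = profile_export.cluster_genes(profile, config.cluster_k)
            labels.to_csv(out_dir / "z_clusters.tsv", sep="\t", header=["cluster"])

    manifest = {
        "config": config.as_dict(),
        "seed": config.seed,
        "bootstrap_seeds": boot_seeds,
        "version": _version(),
        "n_genes": {
            "autosomal": len(a_sub.gene_ids),
            "z_linked": len(z_sub.gene_ids),
            "dropped_unplaced": len(dropped),
        },
    }
    expr_io.write_result_tables(results, out_dir, manifest=manifest)
    out.update(results)
    return out


@_stage("tmm")
def _mf_tmm(matrix, gene_chrom, config: RunConfig) -> list[dosage_stats.MFSummary]:
    """M:F summaries under TMM normalization, after the low-count filter.

    Per stage, the four libraries (two male and two female technical
    replicates) are filtered to genes with >= min_count reads in all four,
    TMM-scaled, replicate-averaged, and summarised exactly like the FPKM
    path.
    """
    summaries = []
    by_stage: dict[str, list] = {}
    for s in matrix.samples:
        if s.sex in ("male", "female"):
            by_stage.setdefault(s.stage, []).append(s)
    for stage, metas in sorted(by_stage.items()):
        ids = [s.sample_id for s in metas]
        if len(ids) != 4:
            logger.info("TMM path: stage %s has %d libraries, need 4; skipped", stage, len(ids))
            continue
        sub = matrix.subset_samples(ids)
        filtered = quantify.filter_low_counts(sub, ids, config.min_count)
        factors = quantify.tmm_factors(
            filtered, config.tmm_reference, config.logratio_trim, config.intensity_trim
        )
        norm = quantify.apply_tmm(filtered, factors)
        averaged = quantify.average_replicates(norm)
        both = quantify.filter_true_expression(averaged, "both_sexes")
        if stage not in both:
            continue
        pair = both[stage]
        male_col, female_col = pair.sample_ids
        m = pair.values[male_col].to_numpy()
        f = pair.values[female_col].to_numpy()
        ratios, _ = dosage_stats.mf_ratios(m, f)
        genes = pair.gene_ids
        z_mask = np.array([gene_chrom.get(g) == config.z_chromosome for g in genes])
        a_mask = np.array(
            [isinstance(gene_chrom.get(g), int) and gene_chrom[g] != config.z_chromosome
             for g in genes]
        )
        if z_mask.any() and a_mask.any():
            summaries.append(
                dosage_stats.mf_summary(
                    ratios[z_mask], ratios[a_mask], stage,
                    pairs_Z=(m[z_mask], f[z_mask]), pairs_A=(m[a_mask], f[a_mask]),
                )
            )
    return summaries


def _version() -> str:
    try:
        return _im.version("zdosage")
    except _im.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="INFO-level logging.")
def cli(verbose: bool) -> None:
    """Z-chromosome dosage compensation analysis from expression matrices."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _config_option(fn):
    return click.option(
        "--config", "config_path", required=True, type=click.Path(exists=True),
        help="YAML run configuration.",
    )(fn)


def _run_steps(config_path: str, steps: Sequence[str]) -> None:
    config = RunConfig.from_yaml(config_path)
    try:
        run_dosage_analysis(config, steps=steps)
    except RuntimeError as exc:
        raise click.ClickException(str(exc)) from exc


@cli.command("all")
@_config_option
def cmd_all(config_path: str) -> None:
    """Run the complete analysis (all tables)."""
    _run_steps(config_path, ALL_STEPS)


@cli.command("za")
@_config_option
def cmd_za(config_path: str) -> None:
    """Per-sample Z:A ratio summaries."""
    _run_steps(config_path, ("za",))


@cli.command("bootstrap")
@_config_option
def cmd_bootstrap(config_path: str) -> None:
    """Bootstrap CIs for the median Z:A ratio."""
    _run_steps(config_path, ("bootstrap",))


@cli.command("mf")
@_config_option
def cmd_mf(config_path: str) -> None:
    """Per-stage M:F ratio summaries (FPKM and TMM paths)."""
    _run_steps(config_path, ("mf",))


@cli.command("quartiles")
@_config_option
def cmd_quartiles(config_path: str) -> None:
    """Quartile-stratified male-vs-female comparisons."""
    _run_steps(config_path, ("quartiles",))


@cli.command("simulate")
@click.option("--preset", default="compensated_head",
              type=click.Choice(["uncompensated_early", "compensated_head",
                                 "bombyx_like_timecourse"]))
@click.option("--seed", default=0, type=int)
@click.option("--out-dir", required=True, type=click.Path())
def cmd_simulate(preset: str, seed: int, out_dir: str) -> None:
    """Write a synthetic dataset (counts, metadata, GFF3, scaffold map)."""
    params = synthetic_data.scenario_presets(preset, seed=seed)
    dataset = synthetic_data.generate_dataset(params)
    paths = synthetic_data.write_fixture_files(dataset, out_dir)
    for name, path in paths.items():
        click.echo(f"{name}\t{path}")


if __name__ == "__main__":  # pragma: no cover
    cli()
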