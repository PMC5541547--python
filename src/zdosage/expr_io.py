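"""Reading and writing the pipeline's external artifacts.

Expression tables are plain TSV with a ``gene_id`` column followed by one
numeric column per sample.  Sample metadata (sex, developmental stage,
technical-replicate index) lives in a separate TSV rather than being encoded
in column names.  Gene → chromosome assignment combines a GFF3 gene
annotation with a two-column scaffold → chromosome table, because silkworm
annotations place genes on scaffolds, not chromosomes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionMatrix",
    "read_sample_metadata",
    "read_expression_table",
    "read_scaffold_map",
    "read_gene_chromosome_map",
    "write_expression_table",
    "write_result_tables",
    "UNPLACED",
]

#: Label for genes whose scaffold is absent from the scaffold→chromosome map.
UNPLACED = "unplaced"

VALID_UNITS = ("raw_counts", "fpkm", "log2_fpkm")
VALID_SEXES = ("male", "female", "none")


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library (one matrix column)."""

    sample_id: str
    sex: str
    stage: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"sample {self.sample_id!r}: sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclasses.dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with a unit tag and sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    unit
        One of ``raw_counts``, ``fpkm`` or ``log2_fpkm``.
    samples
        One :class:`SampleMeta` per column, in column order.
    gene_lengths
        Optional per-gene transcript length in bp (required to derive FPKM).
    """

    values: pd.DataFrame
    unit: str
    samples: list[SampleMeta]
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(self.values.columns) != meta_ids:
            missing = set(self.values.columns) - set(meta_ids)
            if missing:
                raise ValueError(f"sample columns without metadata: {sorted(missing)}")
            raise ValueError("sample metadata order must match matrix columns")
        if self.unit in ("raw_counts", "fpkm"):
            vals = self.values.to_numpy()
            if (vals < 0).any():
                g, s = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative value at gene {idx[g]!r}, sample {self.values.columns[s]!r}"
                )
            if self.unit == "raw_counts" and not np.allclose(vals, np.round(vals)):
                g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise ValueError(
                    f"non-integer count {vals[g, s]} at gene {idx[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(idx)
            if self.gene_lengths.isna().any():
                gene = self.gene_lengths.index[self.gene_lengths.isna()][0]
                raise ValueError(f"missing gene length for {gene!r}")
            if (self.gene_lengths <= 0).any():
                gene = self.gene_lengths.index[self.gene_lengths <= 0][0]
                raise ValueError(f"non-positive gene length for {gene!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset preserving this matrix's gene order."""
        wanted = set(gene_ids)
        keep = [g for g in self.values.index if g in wanted]
        lengths = self.gene_lengths.loc[keep] if self.gene_lengths is not None else None
        return ExpressionMatrix(self.values.loc[keep], self.unit, list(self.samples), lengths)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        metas = [self.meta(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.unit, metas, self.gene_lengths
        )


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a sample metadata TSV with columns sample_id, sex, stage, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str, "stage": str})
    required = {"sample_id", "sex", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata file {path} must have columns {sorted(required)}")
    return [
        SampleMeta(r.sample_id, r.sex, r.stage, int(r.replicate))
        for r in df.itertuples(index=False)
    ]


def read_expression_table(
    path: str | Path,
    unit: str,
    metadata: Sequence[SampleMeta] | str | Path,
    gene_lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table into a validated :class:`ExpressionMatrix`.

    The file must have a ``gene_id`` header column followed by one numeric
    column per sample; ``metadata`` (a list of :class:`SampleMeta` or a path
    to a metadata TSV) must cover every sample column.  Row order is
    preserved and parsing uses the decimal point regardless of locale.
    """
    if not isinstance(metadata, (list, tuple)):
        metadata = read_sample_metadata(metadata)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'gene_id' column, got {list(df.columns)}")
    df = df.set_index("gene_id")
    by_id = {m.sample_id: m for m in metadata}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise ValueError(f"{path}: sample columns without metadata: {missing}")
    metas = [by_id[c] for c in df.columns]
    try:
        values = df.astype(float)
    except ValueError as exc:  # pragma: no cover - pandas message carries the cell
        raise ValueError(f"{path}: non-numeric value in expression table: {exc}") from exc
    return ExpressionMatrix(values, unit, metas, gene_lengths)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    fmt = "%d" if matrix.unit == "raw_counts" else "%.9g"
    out.to_csv(path, sep="\t", float_format=fmt)


# ---------------------------------------------------------------------------
# GFF3 + scaffold map → gene → chromosome assignment
# ---------------------------------------------------------------------------


def read_scaffold_map(path: str | Path) -> dict[str, int | str]:
    """Read a two-column TSV mapping scaffold id → chromosome number.

    Chromosome values parse as integers; anything non-numeric is kept as the
    literal label (e.g. ``unplaced``).
    """
    mapping: dict[str, int | str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: expected 2 tab-separated columns, got {line!r}")
            scaffold, chrom = fields[0], fields[1]
            if scaffold == "scaffold_id":  # optional header
                continue
            try:
                mapping[scaffold] = int(chrom)
            except ValueError:
                mapping[scaffold] = chrom
    if not mapping:
        raise ValueError(f"{path}: empty scaffold map")
    return mapping


def _iter_gff_genes(gff_path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (gene_id, scaffold) for each ``gene`` feature of a GFF3 file.

    Gene features are the per-locus unit (one record per gene after isoform
    merging); mRNA and exon children are ignored.  Coordinates are validated
    as 1-based inclusive integers but not otherwise used.
    """
    with open(gff_path) as fh:
        in_fasta = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                in_fasta = True
            if in_fasta or not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gff_path}: malformed GFF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(
                    f"{gff_path}: malformed GFF line {lineno}: non-integer coordinates"
                ) from None
            if start_i < 1 or end_i < start_i:
                raise ValueError(
                    f"{gff_path}: malformed GFF line {lineno}: bad coordinate range"
                )
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise ValueError(
                    f"{gff_path}: malformed GFF line {lineno}: gene feature without ID attribute"
                )
            yield gene_id, seqid


def read_gene_chromosome_map(
    gff_path: str | Path, scaffold_map_path: str | Path
) -> dict[str, int | str]:
    """Assign every GFF gene feature the chromosome of its scaffold.

    Genes on scaffolds absent from the map get the label ``"unplaced"`` (they
    are dropped later rather than erroring, so a partially anchored assembly
    still analyses cleanly).  The result covers every gene feature exactly
    once.
    """
    scaffold_map = read_scaffold_map(scaffold_map_path)
    mapping: dict[str, int | str] = {}
    for gene_id, scaffold in _iter_gff_genes(gff_path):
        mapping[gene_id] = scaffold_map.get(scaffold, UNPLACED)
    return mapping


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

#: Fixed column orders mirroring the per-sample and per-stage summary tables.
DOSAGE_COLUMNS = [
    "sample", "mean_A", "mean_Z", "mean_za", "median_A", "median_Z",
    "median_za", "n_A", "n_Z", "p_A_vs_Z",
]
BOOTSTRAP_COLUMNS = ["sample", "point", "ci_low", "ci_high", "n_boot", "ci_level", "seed"]
MF_COLUMNS = [
    "stage", "n_Z", "n_A", "median_mf_Z", "median_mf_A", "za_ratio_of_medians",
    "p_Z_MvsF", "p_A_MvsF", "p_AvsZ_dist",
]
QUARTILE_COLUMNS = [
    "label", "binning_mode", "quartile", "n_genes", "median_log2_male",
    "median_log2_female", "p_value",
]

_TABLE_SCHEMAS = {
    "dosage": DOSAGE_COLUMNS,
    "bootstrap": BOOTSTRAP_COLUMNS,
    "mf": MF_COLUMNS,
    "quartile": QUARTILE_COLUMNS,
}


def write_result_tables(
    results: Mapping[str, Sequence[Mapping]],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write one TSV per summary type plus a JSON run manifest.

    ``results`` maps a table name (``dosage``, ``bootstrap``, ``mf``,
    ``quartile``) to a list of row dicts.  Empty lists yield a header-only
    TSV.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    written: dict[str, Path] = {}
    for name, rows in results.items():
        cols = _TABLE_SCHEMAS.get(name)
        df = pd.DataFrame(list(rows))
        if cols is not None:
            df = df.reindex(columns=cols)
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written[name] = path
    if manifest is not None:
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written["manifest"] = mpath
    return written
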