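"""Split genes into autosomal (A) and Z-linked (Z) sets.

In *Bombyx mori* the Z chromosome is chromosome 1 and chromosomes 2–28 are
autosomes; the Z chromosome number is configurable so other ZW species can
be analysed.  Genes on unplaced scaffolds are dropped from all downstream
statistics.  The annotation carries no W chromosome; any unrecognised label
likewise falls into the dropped set.
"""

from __future__ import annotations

from typing import Mapping

from .expr_io import ExpressionMatrix, UNPLACED

__all__ = ["assign_linkage", "DEFAULT_Z_CHROMOSOME"]

DEFAULT_Z_CHROMOSOME = 1


def assign_linkage(
    matrix: ExpressionMatrix,
    gene_chromosome: Mapping[str, int | str],
    z_chromosome: int = DEFAULT_Z_CHROMOSOME,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Partition a matrix's genes into (A-submatrix, Z-submatrix, dropped ids).

    Genes on the configured Z chromosome go to Z, genes on any other
    numbered chromosome to A, and genes that are unplaced or absent from the
    mapping are dropped.  Gene order within each submatrix follows the input
    matrix.  Raises if no gene lands in either A or Z (a matrix/map
    mismatch).
    """
    a_genes: list[str] = []
    z_genes: list[str] = []
    dropped: list[str] = []
    for gene in matrix.gene_ids:
        chrom = gene_chromosome.get(gene, UNPLACED)
        if isinstance(chrom, int):
            (z_genes if chrom == z_chromosome else a_genes).append(gene)
        else:
            dropped.append(gene)
    if not a_genes and not z_genes:
        raise ValueError(
            "no gene of the expression matrix maps to any chromosome: "
            "matrix and gene->chromosome map do not match"
        )
    return matrix.subset_genes(a_genes), matrix.subset_genes(z_genes), dropped
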