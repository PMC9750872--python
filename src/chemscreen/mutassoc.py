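"""Somatic mutation vs drug-sensitivity association.

Filters a MAF-like variant table to putatively functional mutations
(non-coding, silent and in-frame insertions dropped; in-frame deletions and
frameshift indels kept; SNVs kept only with CADD Phred >= 15), collapses
them to a binary gene x cell-line matrix (multiple mutations of a gene in
one line count once), and tests each gene — and a combined Ras/Raf gene set
{KRAS, NRAS, HRAS, NF1, BRAF} — for association between mutation status and
IC50 with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import bh_fdr, rank_sum_p

logger = logging.getLogger(__name__)

RAS_RAF_GENES = ("KRAS", "NRAS", "HRAS", "NF1", "BRAF")

# canonical variant classes
MISSENSE = "missense"
NONSENSE = "nonsense"
NONSTOP = "nonstop"
SPLICE_SITE = "splice_site"
START_LOST = "start_lost"
SILENT = "silent"
NONCODING = "noncoding"
FRAMESHIFT_INDEL = "frameshift_indel"
INFRAME_INSERTION = "inframe_insertion"
INFRAME_DELETION = "inframe_deletion"

#: Canonical classes that are single-nucleotide variants and therefore
#: subject to the CADD Phred filter.
SNV_CLASSES = frozenset({MISSENSE, NONSENSE, NONSTOP, SPLICE_SITE, START_LOST})
#: Canonical classes always removed as non-functional.
DROPPED_CLASSES = frozenset({SILENT, NONCODING, INFRAME_INSERTION})
#: Indel classes retained unconditionally.
RETAINED_INDELS = frozenset({FRAMESHIFT_INDEL, INFRAME_DELETION})

#: Mapping from common MAF ``Variant_Classification`` labels to canonical
#: classes; extensible via the ``class_map`` argument of
#: :func:`filter_mutations`.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "missense_mutation": MISSENSE,
    "missense": MISSENSE,
    "nonsense_mutation": NONSENSE,
    "nonsense": NONSENSE,
    "nonstop_mutation": NONSTOP,
    "splice_site": SPLICE_SITE,
    "translation_start_site": START_LOST,
    "start_codon_snp": START_LOST,
    "silent": SILENT,
    "synonymous": SILENT,
    "3'utr": NONCODING,
    "5'utr": NONCODING,
    "3'flank": NONCODING,
    "5'flank": NONCODING,
    "intron": NONCODING,
    "igr": NONCODING,
    "rna": NONCODING,
    "lincrna": NONCODING,
    "noncoding": NONCODING,
    "frame_shift_del": FRAMESHIFT_INDEL,
    "frame_shift_ins": FRAMESHIFT_INDEL,
    "frameshift_indel": FRAMESHIFT_INDEL,
    "in_frame_ins": INFRAME_INSERTION,
    "inframe_insertion": INFRAME_INSERTION,
    "in_frame_del": INFRAME_DELETION,
    "inframe_deletion": INFRAME_DELETION,
}

MUTATION_COLUMNS = ["cell_line", "gene", "variant_class", "cadd_phred"]

#: Default mapping from MAF headers to the canonical mutation columns.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "Tumor_Sample_Barcode": "cell_line",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
    "CADD_Phred": "cadd_phred",
}


def read_mutation_table(
    path: str | Path, column_map: dict[str, str] | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read a MAF-like TSV/CSV into the canonical column layout.

    ``column_map`` maps source headers to ``cell_line / gene / variant_class /
    cadd_phred``; canonical headers and common MAF headers are recognized
    without it.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    tab = pd.read_csv(path, sep=sep, comment="#", low_memory=False)
    mapping = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    tab = tab.rename(columns=mapping)
    missing = [c for c in MUTATION_COLUMNS[:3] if c not in tab.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    if "cadd_phred" not in tab.columns:
        tab["cadd_phred"] = np.nan
    tab["cadd_phred"] = pd.to_numeric(tab["cadd_phred"], errors="coerce")
    return tab[MUTATION_COLUMNS].copy()


def filter_mutations(
    records: pd.DataFrame,
    cadd_min: float = 15.0,
    class_map: dict[str, str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Retain putatively functional mutations.

    Rules: drop non-coding, silent and in-frame insertions; retain frameshift
    indels and in-frame deletions; retain SNVs iff ``cadd_phred >= cadd_min``
    (SNVs without a CADD score are dropped with a warning). Unknown variant
    classes raise when ``strict`` else are dropped with a warning.
    Idempotent: re-filtering the retained records changes nothing.
    """
    mapping = dict(DEFAULT_CLASS_MAP)
    if class_map:
        mapping.update({k.lower(): v for k, v in class_map.items()})
    for canon in SNV_CLASSES | DROPPED_CLASSES | RETAINED_INDELS:
        mapping.setdefault(canon, canon)

    tab = records.copy()
    canon = tab["variant_class"].astype(str).str.lower().map(mapping)
    unknown = tab.loc[canon.isna(), "variant_class"].unique()
    if len(unknown):
        msg = f"unknown variant classes: {sorted(map(str, unknown))}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (dropped)", stacklevel=2)
    tab = tab.assign(_canon=canon).dropna(subset=["_canon"])

    is_snv = tab["_canon"].isin(SNV_CLASSES)
    no_cadd = is_snv & tab["cadd_phred"].isna()
    if no_cadd.any():
        warnings.warn(
            f"{int(no_cadd.sum())} SNV records without a CADD Phred score dropped",
            stacklevel=2,
        )
    keep = (
        tab["_canon"].isin(RETAINED_INDELS)
        | (is_snv & (tab["cadd_phred"] >= cadd_min))
    )
    out = tab.loc[keep].drop(columns="_canon").reset_index(drop=True)
    return out


def build_matrix(
    records: pd.DataFrame,
    cell_lines: list[str],
    on_unknown_line: str = "error",
) -> pd.DataFrame:
    """Binary gene x cell-line mutation matrix over a fixed cell-line universe.

    Entry 1 means the gene carries at least one retained mutation in that
    line (multiple mutations counted once by construction). Lines without
    retained records appear as all-zero columns. Records naming a line
    outside the universe raise, or are dropped under ``on_unknown_line="drop"``.
    """
    if not cell_lines:
        raise ValueError("cell_lines must be non-empty")
    cell_lines = list(dict.fromkeys(cell_lines))
    unknown = set(records["cell_line"]) - set(cell_lines)
    if unknown:
        if on_unknown_line == "drop":
            warnings.warn(f"dropping records from unknown cell lines: {sorted(unknown)}",
                          stacklevel=2)
            records = records.loc[records["cell_line"].isin(cell_lines)]
        else:
            raise ValueError(f"records name cell lines outside the universe: {sorted(unknown)}")
    genes = sorted(records["gene"].unique())
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=pd.Index(cell_lines, name="cell_line"), dtype=np.int8)
    for gene, line in records[["gene", "cell_line"]].itertuples(index=False):
        mat.at[gene, line] = 1
    return mat


@dataclass(frozen=True)
class AssociationResult:
    """One gene's (or gene set's) mutation vs IC50 rank-sum test."""

    label: str
    p_value: float  # NaN when untestable
    n_mutant: int
    n_wildtype: int
    median_ic50_mutant: float
    median_ic50_wildtype: float


def _associate(label: str, mutant_mask: np.ndarray, ic50: np.ndarray,
               min_group: int) -> AssociationResult:
    mut = ic50[mutant_mask]
    wt = ic50[~mutant_mask]
    med_mut = float(np.median(mut)) if mut.size else np.nan
    med_wt = float(np.median(wt)) if wt.size else np.nan
    if mut.size < min_group or wt.size < min_group:
        logger.info("%s: group sizes %d/%d below min_group=%d; p missing",
                    label, mut.size, wt.size, min_group)
        p = np.nan
    else:
        p = rank_sum_p(mut, wt)
    return AssociationResult(label, p, int(mut.size), int(wt.size), med_mut, med_wt)


def wilcoxon_association(
    matrix: pd.DataFrame, ic50: pd.Series, min_group: int = 2
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum association with IC50.

    ``ic50`` must cover every cell line of the matrix. Genes with fewer than
    ``min_group`` lines in either group get a missing p. Returns a frame
    sorted by p with group sizes, medians and a BH-FDR column (informational;
    the primary report is the raw p, as in standard practice for this test).
    """
    missing = matrix.columns.difference(ic50.index)
    if len(missing):
        raise ValueError(f"IC50 missing for cell lines: {sorted(missing)}")
    vals = ic50.loc[matrix.columns].to_numpy(dtype=float)
    results = [
        _associate(gene, matrix.loc[gene].to_numpy() == 1, vals, min_group)
        for gene in matrix.index
    ]
    columns = ["label", "p_value", "n_mutant", "n_wildtype",
               "median_ic50_mutant", "median_ic50_wildtype"]
    tab = pd.DataFrame([r.__dict__ for r in results], columns=columns)
    tab = tab.rename(columns={"label": "gene"})
    tab["bh_fdr"] = bh_fdr(tab["p_value"])
    return tab.sort_values("p_value", na_position="last", kind="mergesort").reset_index(drop=True)


def geneset_association(
    matrix: pd.DataFrame,
    ic50: pd.Series,
    genes: tuple[str, ...] = RAS_RAF_GENES,
    label: str | None = None,
    min_group: int = 2,
) -> AssociationResult:
    """Association test for a combined gene set: a line is mutant iff any
    member gene carries a retained mutation. Missing members warn; an empty
    effective set raises."""
    present = [g for g in genes if g in matrix.index]
    absent = [g for g in genes if g not in matrix.index]
    if absent:
        warnings.warn(f"gene-set members absent from matrix: {absent}", stacklevel=2)
    if not present:
        raise ValueError(f"no gene-set member present in the matrix: {genes}")
    missing = matrix.columns.difference(ic50.index)
    if len(missing):
        raise ValueError(f"IC50 missing for cell lines: {sorted(missing)}")
    mask = (matrix.loc[present] == 1).any(axis=0).to_numpy()
    vals = ic50.loc[matrix.columns].to_numpy(dtype=float)
    return _associate(label or "+".join(genes), mask, vals, min_group)
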