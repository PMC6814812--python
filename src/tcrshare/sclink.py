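"""Single-cell stage: QC, log-normalization, marker genes, clonotype linking.

This module consumes a gene×cell count matrix with per-cell cluster labels
and (optionally) per-cell TCR clonotype assignments — clustering and
embedding themselves are upstream concerns — and provides:

* the standard QC gate (minimum cells per gene, detected-gene bounds per
  cell, mitochondrial-fraction cap),
* library-size log-normalization ln(1 + c·sf/total),
* one-vs-rest Wilcoxon rank-sum marker detection with a min.pct
  expression-fraction gate and Benjamini–Hochberg FDR,
* cross-tabulation of clonotypes against clusters and a cross-strain
  shared-clonotype report at the amino-acid level.

Matrices are dense numpy int arrays (genes × cells); datasets at this
stage are a few hundred cells, so sparsity buys nothing.  ``to_anndata``
bridges to the AnnData ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .repcore import Clonotype, RepertoireSample, collapse_to_aa
from .repio import translate_cdr3

logger = logging.getLogger(__name__)


@dataclass
class ScDataset:
    """Gene×cell counts plus per-cell annotations (cluster, clonotype, strain)."""

    counts: np.ndarray  # genes x cells, non-negative integers
    gene_ids: list[str]
    barcodes: list[str]
    mito_genes: set[str] = field(default_factory=set)
    cluster_label: list[str] | None = None
    clonotype: list[str | None] | None = None  # per-cell CDR3 nt, None = unassigned
    strain: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(f"{n_genes} matrix rows vs {len(self.gene_ids)} gene ids")
        if n_cells != len(self.barcodes):
            raise ValueError(f"{n_cells} matrix cols vs {len(self.barcodes)} barcodes")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        for name, ann in (("cluster_label", self.cluster_label),
                          ("clonotype", self.clonotype)):
            if ann is not None and len(ann) != n_cells:
                raise ValueError(f"{name} length {len(ann)} != {n_cells} cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self):
        """Convert to an AnnData (cells × genes, annotations in .obs/.var)."""
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        if self.cluster_label is not None:
            obs["cluster"] = pd.Categorical(self.cluster_label)
        if self.clonotype is not None:
            obs["clonotype_nt"] = [c or "" for c in self.clonotype]
        obs["strain"] = self.strain
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        var["mito"] = [g in self.mito_genes for g in self.gene_ids]
        return ad.AnnData(X=self.counts.T.copy(), obs=obs, var=var)


@dataclass
class QcConfig:
    """Cell/gene quality gates.

    ``max_mito_fraction`` defaults to the printed pipeline value 0.05% (5e-4)
    of a cell's reads coming from mitochondrial genes; the conventional cap
    in this kind of pipeline is 5%, so the key is deliberately exposed.
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 2500
    max_mito_fraction: float = 0.0005

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be <= max_genes_per_cell")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


def _subset(data: ScDataset, gene_mask: np.ndarray, cell_mask: np.ndarray) -> ScDataset:
    return ScDataset(
        counts=data.counts[np.ix_(gene_mask, cell_mask)],
        gene_ids=[g for g, keep in zip(data.gene_ids, gene_mask) if keep],
        barcodes=[b for b, keep in zip(data.barcodes, cell_mask) if keep],
        mito_genes=data.mito_genes,
        cluster_label=(
            [c for c, keep in zip(data.cluster_label, cell_mask) if keep]
            if data.cluster_label is not None else None
        ),
        clonotype=(
            [c for c, keep in zip(data.clonotype, cell_mask) if keep]
            if data.clonotype is not None else None
        ),
        strain=data.strain,
    )


def qc_filter(data: ScDataset, cfg: QcConfig | None = None) -> ScDataset:
    """Apply the QC gates: gene filter first, then cell filters on the result.

    Genes detected (count > 0) in at least ``min_cells_per_gene`` cells are
    retained.  On the reduced matrix, cells are kept when their detected-gene
    count lies in [min_genes_per_cell, max_genes_per_cell] and their
    mitochondrial read fraction does not exceed ``max_mito_fraction``.
    Raises ``ValueError`` naming the responsible filter if no cell survives.
    """
    if cfg is None:
        cfg = QcConfig()
    if data.n_cells == 0 or data.n_genes == 0:
        raise ValueError("empty matrix")

    detected = data.counts > 0
    gene_mask = detected.sum(axis=1) >= cfg.min_cells_per_gene
    reduced = data.counts[gene_mask]
    kept_genes = [g for g, keep in zip(data.gene_ids, gene_mask) if keep]

    genes_per_cell = (reduced > 0).sum(axis=0)
    lo = genes_per_cell >= cfg.min_genes_per_cell
    hi = genes_per_cell <= cfg.max_genes_per_cell

    mito_rows = np.array([g in data.mito_genes for g in kept_genes])
    cell_totals = reduced.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            cell_totals > 0, reduced[mito_rows].sum(axis=0) / np.maximum(cell_totals, 1), 0.0
        )
    mito_ok = mito_frac <= cfg.max_mito_fraction

    cell_mask = lo & hi & mito_ok
    logger.info(
        "qc_filter: kept %d/%d genes; removed cells: %d low-gene, %d high-gene, "
        "%d high-mito; kept %d/%d cells",
        gene_mask.sum(), data.n_genes, (~lo).sum(), (~hi).sum(),
        (lo & hi & ~mito_ok).sum(), cell_mask.sum(), data.n_cells,
    )
    if not cell_mask.any():
        if not lo.any():
            culprit = "min_genes_per_cell"
        elif not (lo & hi).any():
            culprit = "max_genes_per_cell"
        else:
            culprit = "max_mito_fraction"
        raise ValueError(f"qc_filter removed every cell (filter: {culprit})")
    return _subset(data, gene_mask, cell_mask)


def log_normalize(data: ScDataset, scale_factor: float = 10_000) -> np.ndarray:
    """Library-size log-normalization: ln(1 + count·scale_factor/cell_total).

    Per cell, Σ_g expm1(value) equals ``scale_factor`` exactly, which makes
    the normalization depth-invariant: multiplying a cell's counts by a
    scalar leaves its normalized values unchanged.
    """
    totals = data.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [b for b, t in zip(data.barcodes, totals) if t == 0]
        raise ValueError(f"zero-total cell(s) {bad[:5]}; run qc_filter first")
    return np.log1p(data.counts * (scale_factor / totals))


@dataclass
class MarkerRecord:
    """One gene's one-vs-rest differential-expression result for one cluster."""

    gene_id: str
    group: str
    log2_fold_change: float
    p_value: float
    fdr: float
    pct_in_group: float
    pct_out_group: float


def find_markers(
    norm: np.ndarray,
    gene_ids: list[str],
    cluster_label: list[str],
    min_pct: float = 0.25,
) -> list[MarkerRecord]:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    A gene is eligible for a cluster when it is detected in at least
    ``min_pct`` of that cluster's cells or of the remaining cells (the
    boundary is inclusive: genes expressed in <25% on both sides are
    filtered out).  P-values come from the two-sided asymptotic rank-sum
    test with continuity correction on the normalized values;
    Benjamini–Hochberg FDR is applied across eligible genes within each
    cluster.  log2FC compares mean de-logged expression:
    log2((mean expm1 in + 1) / (mean expm1 out + 1)).

    Clusters with fewer than 3 cells are skipped with a warning.  Records
    are sorted by (group, fdr, −|log2FC|).
    """
    labels = np.asarray(cluster_label)
    groups = sorted(set(cluster_label))
    if len(groups) < 2:
        raise ValueError("find_markers requires at least 2 clusters")
    records: list[MarkerRecord] = []
    expm = np.expm1(norm)
    detected = norm > 0
    for group in groups:
        in_mask = labels == group
        if in_mask.sum() < 3:
            logger.warning("find_markers: cluster %r has < 3 cells; skipped", group)
            continue
        out_mask = ~in_mask
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, out_mask].mean(axis=1)
        eligible = (pct_in >= min_pct) | (pct_out >= min_pct)
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        pvals = np.empty(idx.size)
        for k, gi in enumerate(idx):
            x = norm[gi, in_mask]
            y = norm[gi, out_mask]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                pvals[k] = 1.0
                continue
            _, pvals[k] = mannwhitneyu(
                x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
            )
        fdr = multipletests(pvals, method="fdr_bh")[1]
        mean_in = expm[idx][:, in_mask].mean(axis=1)
        mean_out = expm[idx][:, out_mask].mean(axis=1)
        lfc = np.log2((mean_in + 1) / (mean_out + 1))
        for k, gi in enumerate(idx):
            records.append(
                MarkerRecord(
                    gene_id=gene_ids[gi],
                    group=group,
                    log2_fold_change=float(lfc[k]),
                    p_value=float(pvals[k]),
                    fdr=float(fdr[k]),
                    pct_in_group=float(pct_in[gi]),
                    pct_out_group=float(pct_out[gi]),
                )
            )
    records.sort(key=lambda r: (r.group, r.fdr, -abs(r.log2_fold_change)))
    return records


def markers_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# --- clonotype linking --------------------------------------------------------


def _cell_repertoire(data: ScDataset) -> RepertoireSample:
    """Cell-count repertoire of a dataset's clonotype annotation (1 cell = 1 count)."""
    if data.clonotype is None:
        raise ValueError(f"dataset {data.strain!r} has no clonotype annotation")
    counts: dict[Clonotype, int] = {}
    for nt in data.clonotype:
        if not nt:
            continue
        clone = Clonotype(cdr3_nt=nt, cdr3_aa=translate_cdr3(nt))
        counts[clone] = counts.get(clone, 0) + 1
    return RepertoireSample(sample_id=data.strain or "cells", counts=counts,
                            strain=data.strain)


@dataclass
class SharedClonotypeReport:
    """Cross-strain shared clonotypes at the amino-acid level.

    ``table`` has one row per shared aa clonotype: junction_aa, the number
    of distinct nucleotide variants across strains, and per-strain cell
    counts.  ``summary`` renders the headline totals as
    "N TCRs, M nucleotide sequences, K cells: k1 + k2".
    """

    table: pd.DataFrame
    n_shared_tcrs: int
    n_nt_variants: int
    cells_per_strain: dict[str, int]

    @property
    def summary(self) -> str:
        ks = " + ".join(str(v) for v in self.cells_per_strain.values())
        total = sum(self.cells_per_strain.values())
        return (
            f"{self.n_shared_tcrs} TCRs, {self.n_nt_variants} nucleotide sequences, "
            f"{total} cells: {ks}"
        )


def link_clonotypes(datasets: list[ScDataset]) -> SharedClonotypeReport:
    """Shared aa-level clonotypes across strain-labelled single-cell datasets.

    A clonotype counts as shared when its CDR3 amino-acid sequence appears in
    every dataset.  For each shared clonotype the report gives the number of
    distinct nucleotide sequences encoding it (pooled over strains) and the
    number of cells per strain expressing it.
    """
    if len(datasets) < 2:
        raise ValueError("link_clonotypes needs at least 2 datasets")
    reps = [_cell_repertoire(d) for d in datasets]
    collapsed = []
    variant_maps = []
    for rep in reps:
        aa_rep, variants = collapse_to_aa(rep)
        collapsed.append(aa_rep)
        variant_maps.append(variants)

    shared_keys = set(variant_maps[0])
    for vm in variant_maps[1:]:
        shared_keys &= set(vm)

    strains = [d.strain or f"dataset{i}" for i, d in enumerate(datasets)]
    rows = []
    total_variants = 0
    cells_per_strain = {s: 0 for s in strains}
    for key in sorted(shared_keys):
        aa = key[0]
        nt_variants = set()
        for vm in variant_maps:
            nt_variants |= vm[key]
        per_strain = {}
        for strain, rep in zip(strains, collapsed):
            n = 0
            for clone, c in rep.counts.items():
                if clone.key("aa") == key:
                    n = c
                    break
            per_strain[strain] = n
            cells_per_strain[strain] += n
        total_variants += len(nt_variants)
        rows.append(
            {"junction_aa": aa, "n_nt_variants": len(nt_variants),
             **{f"cells_{s}": per_strain[s] for s in strains}}
        )
    table = pd.DataFrame(
        rows, columns=["junction_aa", "n_nt_variants"] + [f"cells_{s}" for s in strains]
    )
    return SharedClonotypeReport(
        table=table,
        n_shared_tcrs=len(shared_keys),
        n_nt_variants=total_variants,
        cells_per_strain=cells_per_strain,
    )


def cluster_composition(data: ScDataset, use_aa: bool = True) -> pd.DataFrame:
    """Contingency table clonotype × cluster (cell counts).

    Row/column sums conserve the number of cells annotated with both a
    cluster and a clonotype.  ``use_aa`` keys rows by the translated CDR3.
    """
    if data.cluster_label is None or data.clonotype is None:
        raise ValueError("cluster_composition needs cluster and clonotype annotations")
    keys, clusters = [], []
    for nt, cl in zip(data.clonotype, data.cluster_label):
        if not nt:
            continue
        keys.append(translate_cdr3(nt) if use_aa else nt)
        clusters.append(cl)
    return pd.crosstab(
        pd.Series(keys, name="clonotype"), pd.Series(clusters, name="cluster")
    )


# --- MTX / CSV I/O ------------------------------------------------------------


def write_sc_dataset(data: ScDataset, outdir: str | Path) -> None:
    """Write matrix.mtx, features.tsv, barcodes.tsv and annotations.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(data.counts))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in data.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in data.barcodes))
    ann = pd.DataFrame({"barcode": data.barcodes})
    ann["cluster"] = data.cluster_label if data.cluster_label is not None else ""
    if data.clonotype is not None:
        ann["clonotype_nt"] = [c or "" for c in data.clonotype]
        ann["clonotype_aa"] = [translate_cdr3(c) if c else "" for c in data.clonotype]
    else:
        ann["clonotype_nt"] = ""
        ann["clonotype_aa"] = ""
    ann["strain"] = data.strain
    ann["mito_gene"] = ""
    ann.to_csv(outdir / "annotations.csv", index=False)
    (outdir / "mito_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(data.mito_genes))
    )


def read_sc_dataset(indir: str | Path) -> ScDataset:
    """Read a dataset written by :func:`write_sc_dataset`."""
    indir = Path(indir)
    counts = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense()).astype(int)
    gene_ids = (indir / "features.tsv").read_text().split()
    barcodes = (indir / "barcodes.tsv").read_text().split()
    ann = pd.read_csv(indir / "annotations.csv", dtype=str, keep_default_na=False)
    mito_path = indir / "mito_genes.txt"
    mito = set(mito_path.read_text().split()) if mito_path.exists() else set()
    cluster = ann["cluster"].tolist() if "cluster" in ann else None
    clono = (
        [c or None for c in ann["clonotype_nt"]] if "clonotype_nt" in ann else None
    )
    strain = ann["strain"].iloc[0] if "strain" in ann and len(ann) else ""
    return ScDataset(
        counts=counts, gene_ids=gene_ids, barcodes=barcodes, mito_genes=mito,
        cluster_label=cluster, clonotype=clono, strain=strain,
    )
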