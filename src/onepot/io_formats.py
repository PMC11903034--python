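"""On-disk formats and in-memory containers.

Expression data travels as a CellRanger-style triplet (``matrix.mtx``,
``barcodes.tsv``, ``features.tsv``); allelic counts as a pair of
Vartrix-style MatrixMarket files over cells x sites plus a site table;
the genetic map as a three-column TSV.  All on-disk coordinates are
1-based (VCF/TSV convention); in-memory arrays are 0-based.  Genomic
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("onepot")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _check_site_order(sites: pd.DataFrame) -> None:
    """Sites must come in contiguous chromosome blocks with strictly
    increasing positions; chromosome block order itself is free (roman
    numerals do not sort lexicographically)."""
    if sites.duplicated(["chrom", "pos"]).any():
        raise FormatError("duplicate sites")
    chroms = sites["chrom"].to_numpy()
    seen: set = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                raise FormatError(
                    f"chromosome {c} split into non-contiguous blocks")
            seen.add(c)
            prev = c
    for c in seen:
        pos = sites.loc[sites["chrom"] == c, "pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise FormatError(f"{c}: positions not strictly increasing")


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class GeneticMap:
    """Ordered genetic markers with physical (bp) and genetic (cM) positions.

    ``markers`` has columns ``chrom``, ``pos`` (bp, 1-based) and ``cM``;
    within each chromosome positions are strictly increasing and cM
    non-decreasing.
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "cM"}
        if not required.issubset(self.markers.columns):
            raise FormatError(f"genetic map needs columns {sorted(required)}")
        self.markers = self.markers.reset_index(drop=True)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            cm = sub["cM"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"{chrom}: bp positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"{chrom}: cM positions decreasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        sub = self.markers[self.markers["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        return sub

    def interpolate_cM(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Linearly interpolate genetic positions for bp coordinates.

        Positions outside the mapped range are clamped to the terminal cM.
        """
        sub = self.chrom_slice(chrom)
        return np.interp(np.asarray(pos, float), sub["pos"].to_numpy(float),
                         sub["cM"].to_numpy(float))


@dataclasses.dataclass
class ExpressionMatrix:
    """Sparse cell x transcript UMI counts with per-cell metadata.

    ``transcripts`` carries ``name``, ``chrom`` and ``pos``; ``cell_meta``
    is indexed like ``cells`` and carries at least ``batch`` and
    ``total_umis`` (always recomputed from the counts), optionally
    ``stage``, ``segregant`` and ``doublet``.
    """

    cells: np.ndarray
    transcripts: pd.DataFrame
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.transcripts)):
            raise FormatError("counts shape does not match cells x transcripts")
        if (self.counts.data < 0).any():
            raise FormatError("negative counts")
        self.transcripts = self.transcripts.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        self.cell_meta["total_umis"] = np.asarray(
            self.counts.sum(axis=1)).ravel().astype(int)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            cells=self.cells[idx],
            transcripts=self.transcripts,
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
        )


@dataclasses.dataclass
class AlleleCountMatrix:
    """Per-cell, per-site UMI counts supporting each parental allele.

    ``countsA[c, s]`` is the number of UMIs at site *s* in cell *c* that
    carry the parent-A allele (the quantity *r* of the genotyping HMM);
    the total informative depth is ``D = countsA + countsB``.  ``mask``
    marks sites usable for genotyping (sites failing the minor-allele
    frequency filter are masked but retained for imputation).
    """

    cells: np.ndarray
    sites: pd.DataFrame
    countsA: sp.csr_matrix
    countsB: sp.csr_matrix
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        self.countsA = sp.csr_matrix(self.countsA)
        self.countsB = sp.csr_matrix(self.countsB)
        if self.countsA.shape != self.countsB.shape:
            raise FormatError("allele count matrices differ in shape")
        if self.countsA.shape != (len(self.cells), len(self.sites)):
            raise FormatError("allele counts shape does not match cells x sites")
        if (self.countsA.data < 0).any() or (self.countsB.data < 0).any():
            raise FormatError("negative allelic counts")
        self.sites = self.sites.reset_index(drop=True)
        _check_site_order(self.sites)
        if self.mask is None:
            self.mask = np.ones(len(self.sites), bool)
        self.mask = np.asarray(self.mask, bool)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def depth(self) -> sp.csr_matrix:
        """Total informative read depth D per cell x site."""
        return (self.countsA + self.countsB).tocsr()

    def subset_cells(self, idx: np.ndarray) -> "AlleleCountMatrix":
        idx = np.asarray(idx)
        return AlleleCountMatrix(
            cells=self.cells[idx],
            sites=self.sites,
            countsA=self.countsA[idx],
            countsB=self.countsB[idx],
            mask=self.mask,
        )


# ---------------------------------------------------------------------------
# MatrixMarket triplet (expression)


def _read_mtx(path: Path) -> sp.coo_matrix:
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise FormatError(f"{path}: cannot parse MatrixMarket file ({exc})") from exc
    coo = sp.coo_matrix(mat)
    if coo.data.size and not np.allclose(coo.data, np.round(coo.data)):
        raise FormatError(f"{path}: non-integer entries")
    dup = pd.DataFrame({"r": coo.row, "c": coo.col}).duplicated().any()
    if dup:
        raise FormatError(f"{path}: duplicate coordinates")
    return coo


def read_umi_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a CellRanger-style triplet directory into an ExpressionMatrix.

    Expects ``matrix.mtx`` (cells x transcripts, coordinate integer),
    ``barcodes.tsv`` (one barcode per line) and ``features.tsv``
    (name, chrom, pos).  An optional ``cell_meta.tsv`` supplies batch and
    other per-cell columns; otherwise all cells get batch ``"b0"``.
    """
    path = Path(path)
    coo = _read_mtx(path / "matrix.mtx")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None,
                           names=["name", "chrom", "pos"])
    if coo.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"{path}: matrix is {coo.shape}, expected "
            f"{(len(barcodes), len(features))} from barcodes/features")
    meta_path = path / "cell_meta.tsv"
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t")
        if len(cell_meta) != len(barcodes):
            raise FormatError(f"{meta_path}: row count differs from barcodes")
    else:
        cell_meta = pd.DataFrame({"batch": np.repeat("b0", len(barcodes))})
    return ExpressionMatrix(cells=barcodes, transcripts=features,
                            counts=coo.tocsr().astype(np.int64),
                            cell_meta=cell_meta)


def write_umi_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), expr.counts.tocoo(),
                     field="integer")
    pd.Series(expr.cells).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    expr.transcripts[["name", "chrom", "pos"]].to_csv(
        path / "features.tsv", sep="\t", header=False, index=False)
    expr.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t", index=False)
    logger.info("wrote expression triplet to %s (%d cells x %d transcripts)",
                path, expr.n_cells, expr.n_transcripts)


# ---------------------------------------------------------------------------
# allele counts (Vartrix-style pair) + site table


def read_allele_counts(pathA: str | Path, pathB: str | Path,
                       sites_path: str | Path) -> AlleleCountMatrix:
    """Read parent-A/parent-B count matrices and the site table.

    The two matrices must share dimensions and cell ordering; sites.tsv
    carries ``chrom``, ``pos`` (1-based), ``alleleA``, ``alleleB``.
    """
    cooA = _read_mtx(Path(pathA))
    cooB = _read_mtx(Path(pathB))
    if cooA.shape != cooB.shape:
        raise FormatError(
            f"allele matrices differ in shape: {cooA.shape} vs {cooB.shape}")
    sites = pd.read_csv(sites_path, sep="\t")
    if len(sites) != cooA.shape[1]:
        raise FormatError(
            f"{sites_path}: {len(sites)} sites but matrices have "
            f"{cooA.shape[1]} columns")
    cells = np.array([f"cell{i}" for i in range(cooA.shape[0])])
    return AlleleCountMatrix(cells=cells, sites=sites,
                             countsA=cooA.tocsr().astype(np.int64),
                             countsB=cooB.tocsr().astype(np.int64))


def write_allele_counts(ac: AlleleCountMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "parentA.mtx"), ac.countsA.tocoo(), field="integer")
    scipy.io.mmwrite(str(path / "parentB.mtx"), ac.countsB.tocoo(), field="integer")
    ac.sites.to_csv(path / "sites.tsv", sep="\t", index=False)
    logger.info("wrote allele counts to %s (%d cells x %d sites)",
                path, ac.n_cells, ac.n_sites)


# ---------------------------------------------------------------------------
# VCF sites


def read_vcf_sites(path: str | Path, parentA: str | None = None,
                   parentB: str | None = None) -> pd.DataFrame:
    """Extract biallelic SNPs at which the two parents are informative.

    A site is retained only when both parents are homozygous for
    different alleles; multi-allelic records and indels are skipped with
    a logged count.  ``parentA``/``parentB`` name the two samples
    (default: first two samples in the file).
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot open VCF ({exc})") from exc
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise FormatError(f"{path}: need genotypes for two parents")
    ia = samples.index(parentA) if parentA else 0
    ib = samples.index(parentB) if parentB else 1
    rows = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes
        ga, gb = gts[ia][:2], gts[ib][:2]
        # informative: homozygous in both parents, for different alleles
        if ga[0] != ga[1] or gb[0] != gb[1] or ga[0] == gb[0]:
            continue
        alleles = [rec.REF, rec.ALT[0]]
        rows.append((rec.CHROM, rec.POS, alleles[ga[0]], alleles[gb[0]]))
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "alleleA", "alleleB"])


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a TSV genetic map with header ``chrom, pos, cM``."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "cM"}.issubset(df.columns):
        raise FormatError(f"{path}: header must contain chrom, pos, cM")
    if df.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicate (chrom, pos) rows")
    # sort positions within each chromosome, preserving the file's
    # chromosome block order (roman numerals do not sort lexically)
    order = pd.Categorical(df["chrom"],
                           categories=list(dict.fromkeys(df["chrom"])))
    sorted_df = (df.assign(_c=order).sort_values(["_c", "pos"], kind="stable")
                 .drop(columns="_c").reset_index(drop=True))
    if not sorted_df[["chrom", "pos"]].equals(
            df[["chrom", "pos"]].reset_index(drop=True)):
        logger.warning("%s: rows were not position-sorted; sorting", path)
    try:
        return GeneticMap(markers=sorted_df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.markers[["chrom", "pos", "cM"]].to_csv(path, sep="\t", index=False)
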