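"""Readers, writers and the shared tabular data model.

Internal coordinate convention is 1-based inclusive (GFF/VCF native); the
BED writer converts to 0-based half-open at write time only.  The minor
allele of every SNP is defined cohort-wise after any sample subsetting and
the orientation is recorded per SNP so downstream major-vs-minor
stratification is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AsvCountTable",
    "GenotypeMatrix",
    "GeneAnnotation",
    "FormatError",
    "REQUIRED_META_COLUMNS",
    "read_asv_table",
    "read_genotypes",
    "read_gff",
    "write_bed",
    "write_table",
    "read_table",
]

log = logging.getLogger(__name__)

#: design columns every sample row must carry
REQUIRED_META_COLUMNS = (
    "genotype",
    "treatment",
    "year",
    "block",
    "split_plot",
    "split_plot_block",
    "replicate",
)

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

TREATMENT_LEVELS = ("plusN", "minusN")


class FormatError(ValueError):
    """Raised when an input file violates its accepted dialect."""


@dataclass
class AsvCountTable:
    """Samples x ASVs integer counts with sample metadata and taxonomy.

    ``counts`` rows are samples, columns are ASV ids.  ``sample_meta`` is
    indexed by sample id and carries the split-plot field design columns;
    ``taxonomy`` is indexed by ASV id with ranks kingdom..species (missing
    ranks encoded as ``"Unknown"``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.DataFrame
    sequences: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in counts: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate ASV ids in counts: {dups}")
        missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise FormatError(f"sample metadata missing columns: {missing_cols}")
        if not self.counts.index.isin(self.sample_meta.index).all():
            orphans = self.counts.index[~self.counts.index.isin(self.sample_meta.index)]
            raise FormatError(f"samples without metadata: {orphans.tolist()[:10]}")
        na_rows = self.sample_meta.loc[
            self.counts.index, list(REQUIRED_META_COLUMNS)
        ].isna().any(axis=1)
        if na_rows.any():
            raise FormatError(
                f"design columns missing for samples: {na_rows.index[na_rows].tolist()[:10]}"
            )
        missing_tax = self.counts.columns[~self.counts.columns.isin(self.taxonomy.index)]
        if len(missing_tax):
            raise FormatError(f"ASVs without taxonomy rows: {missing_tax.tolist()[:10]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.mod(arr.astype(float), 1.0)
            bad = np.argwhere(frac != 0)
            if len(bad):
                i, j = bad[0]
                raise FormatError(
                    f"non-integer count at sample={self.counts.index[i]!r}, "
                    f"asv={self.counts.columns[j]!r}: {arr[i, j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts present")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AsvCountTable":
        idx = pd.Index(sample_ids)
        return AsvCountTable(
            counts=self.counts.loc[idx],
            sample_meta=self.sample_meta.loc[idx],
            taxonomy=self.taxonomy,
            sequences=self.sequences,
        )

    def subset_asvs(self, asv_ids: Sequence[str]) -> "AsvCountTable":
        idx = pd.Index(asv_ids)
        return AsvCountTable(
            counts=self.counts.loc[:, idx],
            sample_meta=self.sample_meta,
            taxonomy=self.taxonomy.loc[idx],
            sequences=None
            if self.sequences is None
            else {a: self.sequences[a] for a in idx if a in self.sequences},
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with a SNP map.

    ``dosage`` is float (np.nan marks missing calls) with values in
    {0, 1, 2}; ``snp_map`` has columns chrom, pos, allele_major,
    allele_minor, maf and is row-aligned with the dosage columns.
    """

    dosage: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: pd.Index

    def __post_init__(self) -> None:
        self.individual_ids = pd.Index(self.individual_ids)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_map)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_map)} SNPs"
            )
        self.snp_map = self.snp_map.reset_index(drop=True)
        for chrom, sub in self.snp_map.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"positions not strictly increasing on chrom {chrom}")
        maf = self.snp_map["maf"].to_numpy(float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise FormatError("maf outside (0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-site mean."""
        X = self.dosage.astype(float).copy()
        if np.isnan(X).any():
            means = np.nanmean(X, axis=0)
            nan_i, nan_j = np.nonzero(np.isnan(X))
            X[nan_i, nan_j] = means[nan_j]
        return X

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Subset and re-orient to the new cohort's minor allele."""
        idx = self.individual_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = [i for i, k in zip(ids, idx) if k < 0]
            raise FormatError(f"unknown individual ids: {missing[:10]}")
        X = self.dosage[idx]
        return _reorient_minor(X, self.snp_map, pd.Index(ids))

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, mask],
            snp_map=self.snp_map.loc[np.asarray(mask)].reset_index(drop=True),
            individual_ids=self.individual_ids,
        )


@dataclass
class GeneAnnotation:
    """Gene records with 1-based inclusive transcribed spans."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            raise FormatError(
                f"gene spans with start > end: {self.genes.loc[bad, 'gene_id'].tolist()[:5]}"
            )
        self.genes = self.genes.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_asv_table(counts_path, taxonomy_path, metadata_path) -> AsvCountTable:
    """Load a TSV trio (counts, taxonomy, sample metadata) into an AsvCountTable.

    Counts may be oriented samples-in-rows or ASVs-in-rows; the orientation
    is auto-detected from id overlap with the metadata and taxonomy tables.
    Samples present in counts but absent from metadata are dropped with a
    warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, comment="#", dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    for df, name in ((counts, "counts"), (taxonomy, "taxonomy"), (meta, "metadata")):
        if df.index.duplicated().any():
            raise FormatError(f"duplicate ids in {name} file")

    row_is_sample = counts.index.isin(meta.index).sum()
    col_is_sample = counts.columns.isin(meta.index).sum()
    if col_is_sample > row_is_sample:
        counts = counts.T
    dropped = counts.index[~counts.index.isin(meta.index)]
    if len(dropped):
        log.warning("dropping %d samples absent from metadata: %s",
                    len(dropped), dropped.tolist()[:5])
        counts = counts.loc[counts.index.isin(meta.index)]

    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")

    tax = taxonomy.reindex(columns=list(TAXONOMY_RANKS)).fillna("Unknown")
    return AsvCountTable(
        counts=counts, sample_meta=meta.loc[counts.index], taxonomy=tax
    )


def _reorient_minor(X: np.ndarray, snp_map: pd.DataFrame,
                    individual_ids: pd.Index) -> GenotypeMatrix:
    """Recompute allele frequencies on the cohort and flip to minor-allele dosage."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    flip = p > 0.5
    X = X.copy()
    X[:, flip] = 2.0 - X[:, flip]
    p = np.where(flip, 1.0 - p, p)
    sm = snp_map.copy().reset_index(drop=True)
    a_maj = sm["allele_major"].to_numpy().copy()
    a_min = sm["allele_minor"].to_numpy().copy()
    a_maj[flip], a_min[flip] = sm["allele_minor"].to_numpy()[flip], sm["allele_major"].to_numpy()[flip]
    sm["allele_major"], sm["allele_minor"] = a_maj, a_min
    sm["maf"] = p
    keep = (p > 0) & (p <= 0.5)
    return GenotypeMatrix(X[:, keep], sm.loc[keep], individual_ids)


def read_genotypes(path, format: str = "vcf", maf_min: float = 0.0,
                   impute_missing: bool = False) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from VCF or PLINK-style transposed text.

    Dosages are recoded to minor-allele counts with the minor allele defined
    from the loaded cohort; sites with maf < ``maf_min`` (or monomorphic) are
    removed.  Multiallelic records are skipped with a logged count.  Missing
    calls are mean-imputed only when ``impute_missing`` is set.
    """
    if format == "vcf":
        geno = _read_vcf(path)
    elif format == "plink_text":
        geno = _read_plink_text(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    keep = geno.snp_map["maf"].to_numpy() >= maf_min
    geno = geno.subset_snps(keep)
    if geno.n_snps == 0:
        raise FormatError(f"no polymorphic sites left after maf >= {maf_min} filter")
    if impute_missing:
        geno = GenotypeMatrix(geno.imputed(), geno.snp_map, geno.individual_ids)
    return geno


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = pd.Index(vcf.samples)
    rows, recs = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=missing
        g = np.asarray(v.gt_types, dtype=float)
        g[g == 3] = np.nan
        rows.append(g)
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_multi:
        log.warning("skipped %d multiallelic/non-SNP records", n_multi)
    if not rows:
        raise FormatError("no biallelic SNP records in VCF")
    X = np.vstack(rows).T  # individuals x snps, ALT-allele dosage
    sm = pd.DataFrame(recs, columns=["chrom", "pos", "allele_major", "allele_minor"])
    sm["maf"] = 0.25  # placeholder; recomputed cohort-wise below
    return _reorient_minor(X, sm, ids)


def _read_plink_text(path) -> GenotypeMatrix:
    """Transposed text: header 'snp chrom pos <id1> <id2> ...', one SNP per row."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    for col in ("snp", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"plink_text file missing column {col!r}")
    ids = pd.Index(df.columns[3:])
    X = df.iloc[:, 3:].to_numpy(float).T
    if np.nanmax(X) > 2 or np.nanmin(X) < 0:
        raise FormatError("plink_text dosages outside {0,1,2}")
    sm = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["pos"].astype(int),
        "allele_major": "A",
        "allele_minor": "B",
        "maf": 0.25,
    })
    return _reorient_minor(X, sm, ids)


def read_gff(path, chrom_aliases: Mapping[str, str] | None = None) -> GeneAnnotation:
    """Load gene-type features from a GFF3 file (1-based inclusive spans)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    recs = []
    for feat in db.features_of_type("gene"):
        chrom = feat.seqid
        if chrom_aliases and chrom in chrom_aliases:
            chrom = chrom_aliases[chrom]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        recs.append((gene_id, chrom, feat.start, feat.end, feat.strand))
    genes = pd.DataFrame(recs, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _header_comment(seed=None) -> str:
    from rhizoqg import __version__

    seed_part = f" seed={seed}" if seed is not None else ""
    return f"# rhizoqg v{__version__}{seed_part}\n"


def write_bed(mapls, path, seed=None) -> None:
    """Write MAPL regions as BED6 (0-based half-open).

    ``mapls`` is a DataFrame with chrom, start, end (internal 0-based
    half-open window coordinates), name, score columns, or an empty frame.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        if len(mapls) == 0:
            return
        for _, r in mapls.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r.get('name', '.')}\t{r.get('score', 0)}\t.\n"
            )


def write_table(df: pd.DataFrame, path, seed=None, index: bool = True) -> None:
    """Write a result table as TSV with a provenance header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g")


def read_table(path, index_col=0) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
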