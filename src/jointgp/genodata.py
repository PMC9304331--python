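"""Genotype and phenotype input handling.

Genotypes from genotyping-by-sequencing (GBS) experiments on polyploids are
represented as *allele proportions*: the fraction of reads carrying the
reference allele at a marker.  This continuous code in [0, 1] sidesteps
allele-dosage calling, which is unreliable at high ploidy.  The module reads
either a VCF with per-sample allelic depths (``FORMAT/AD``) or a pre-computed
numeric marker matrix (TSV, markers x individuals), applies the standard
depth / missingness / variance filters, mean-imputes what is left, and
min-max normalizes trait values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawGenotypeTable",
    "GenotypeMatrix",
    "TraitVector",
    "read_genotypes",
    "read_vcf",
    "read_genotype_tsv",
    "read_phenotypes",
    "encode_allele_proportions",
    "filter_and_impute",
    "minmax_normalize",
]

MISSING_SENTINEL = "NA"


@dataclass
class RawGenotypeTable:
    """Per-marker, per-individual read depths straight from a variant file.

    ``ref_depth`` and ``alt_depth`` are ``(n_markers, n_individuals)`` integer
    arrays; ``multiallelic`` flags records with more than one ALT allele,
    which are excluded from allele-proportion encoding.
    """

    markers: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    individuals: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    multiallelic: np.ndarray  # bool per marker

    def __post_init__(self) -> None:
        n_m, n_i = self.ref_depth.shape
        if self.alt_depth.shape != (n_m, n_i):
            raise ValueError("ref_depth and alt_depth shapes differ")
        if len(self.individuals) != n_i:
            raise ValueError("individual count does not match depth columns")
        if len(self.markers) != n_m:
            raise ValueError("marker count does not match depth rows")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of allele proportions.

    Missing entries are NaN; ``missing_mask`` exposes them as booleans.
    After :func:`filter_and_impute` the matrix is dense (no NaN).
    """

    values: np.ndarray  # (n_individuals, n_markers) float
    individuals: list[str]
    markers: list[str]
    marker_info: pd.DataFrame | None = None  # optional chrom/pos table

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n_i, n_m = self.values.shape
        if len(self.individuals) != n_i or len(self.markers) != n_m:
            raise ValueError("id lists inconsistent with value matrix shape")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("allele proportions must lie in [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        """Return a copy restricted to ``marker_ids`` (genotype-file order)."""
        wanted = set(marker_ids)
        unknown = wanted - set(self.markers)
        if unknown:
            raise KeyError(f"unknown marker ids: {sorted(unknown)[:5]} ...")
        idx = [j for j, m in enumerate(self.markers) if m in wanted]
        info = None
        if self.marker_info is not None:
            info = self.marker_info.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            self.values[:, idx].copy(),
            list(self.individuals),
            [self.markers[j] for j in idx],
            info,
        )

    def subset_individuals(self, individual_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.individuals)}
        idx = [pos[s] for s in individual_ids]
        return GenotypeMatrix(
            self.values[idx].copy(), list(individual_ids), list(self.markers), self.marker_info
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write as markers x individuals TSV (the on-disk convention)."""
        df = pd.DataFrame(self.values.T, index=self.markers, columns=self.individuals)
        df.to_csv(path, sep="\t", index_label="marker", na_rep=MISSING_SENTINEL)


@dataclass
class TraitVector:
    """Trait values (BLUPs or corrected phenotypes) for an ordered set of individuals."""

    individuals: list[str]
    values: np.ndarray
    name: str = "trait"
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.individuals) != self.values.size:
            raise ValueError("trait vector ids and values are inconsistent")

    @property
    def n(self) -> int:
        return self.values.size

    def normalize(self) -> "TraitVector":
        """Attach the min-max normalized values; returns self for chaining."""
        self.normalized = minmax_normalize(self.values)
        return self

    def align_to(self, individuals) -> "TraitVector":
        pos = {s: i for i, s in enumerate(self.individuals)}
        missing = [s for s in individuals if s not in pos]
        if missing:
            raise KeyError(f"individuals without phenotype: {missing[:5]} ...")
        idx = [pos[s] for s in individuals]
        out = TraitVector(list(individuals), self.values[idx], self.name)
        if self.normalized is not None:
            out.normalized = self.normalized[idx]
        return out


def read_vcf(path: str | os.PathLike) -> RawGenotypeTable:
    """Read a VCF 4.x with per-sample allelic depths into a depth table.

    Requires ``FORMAT/AD``.  Records with more than one ALT allele are kept
    but flagged multi-allelic; :func:`encode_allele_proportions` drops them.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, refs, alts = [], [], []
    multi = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"VCF record {var.CHROM}:{var.POS} lacks the FORMAT/AD field "
                "(per-sample allelic depths) required for allele-proportion encoding"
            )
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append(
            {
                "id": vid,
                "chrom": var.CHROM,
                "pos": var.POS,  # 1-based, as in the VCF
                "ref": var.REF,
                "alt": ",".join(var.ALT),
            }
        )
        refs.append(ad[:, 0])
        alts.append(ad[:, 1:].sum(axis=1))
        multi.append(len(var.ALT) > 1)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return RawGenotypeTable(
        markers=pd.DataFrame(rows),
        individuals=individuals,
        ref_depth=np.vstack(refs),
        alt_depth=np.vstack(alts),
        multiallelic=np.asarray(multi, dtype=bool),
    )


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a markers x individuals TSV of allele proportions.

    The first column holds marker ids, the header the individual ids, and
    ``NA`` marks missing values.  The returned matrix is transposed to the
    in-memory convention (individuals x markers).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_SENTINEL], keep_default_na=False)
    for col in df.columns:
        bad = df[col].apply(lambda x: isinstance(x, str))
        if bad.any():
            marker = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at marker {marker!r}, individual {col!r} "
                f"(only {MISSING_SENTINEL!r} marks missing data)"
            )
    values = df.to_numpy(dtype=float).T
    return GenotypeMatrix(values, [str(c) for c in df.columns], [str(m) for m in df.index])


def read_genotypes(path: str | os.PathLike) -> RawGenotypeTable | GenotypeMatrix:
    """Dispatch on file type: VCF -> depth table, TSV -> ready-made matrix."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_vcf(path)
    return read_genotype_tsv(path)


def read_phenotypes(path: str | os.PathLike, trait: str | None = None) -> dict[str, TraitVector]:
    """Read a phenotype CSV with an ``id`` column and one column per trait."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("phenotype CSV must have an 'id' column")
    ids = [str(s) for s in df["id"]]
    traits = [c for c in df.columns if c != "id"]
    if trait is not None:
        if trait not in traits:
            raise KeyError(f"trait {trait!r} not in {traits}")
        traits = [trait]
    return {t: TraitVector(ids, df[t].to_numpy(dtype=float), name=t) for t in traits}


def encode_allele_proportions(table: RawGenotypeTable, min_depth: int = 50) -> GenotypeMatrix:
    """Encode read depths as allele proportions.

    The proportion is ref_depth / (ref_depth + alt_depth).  Genotype calls
    whose total depth falls below ``min_depth`` (default 50 reads) become
    missing; multi-allelic records are excluded entirely.  Zero total depth
    is missing, never a division error.
    """
    total = table.ref_depth + table.alt_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, table.ref_depth / np.maximum(total, 1), np.nan)
    prop = np.where(total < min_depth, np.nan, prop)
    keep = ~table.multiallelic
    info = table.markers.loc[keep].reset_index(drop=True)
    return GenotypeMatrix(
        values=prop[keep].T,
        individuals=list(table.individuals),
        markers=list(info["id"]),
        marker_info=info,
    )


def filter_and_impute(
    g: GenotypeMatrix,
    max_missing: float = 0.25,
    drop_zero_variance: bool = True,
) -> GenotypeMatrix:
    """Apply the missingness filter and mean-impute the remainder.

    Markers missing in more than ``max_missing`` of individuals (default 25%)
    are removed; surviving missing entries are replaced by the per-marker mean
    over the observed individuals, which leaves each marker's mean unchanged.
    Zero-variance markers are dropped by default: they carry no information
    and degenerate several downstream statistics (RBF bandwidths, Pearson
    screens).
    """
    vals = g.values.copy()
    miss_frac = np.isnan(vals).mean(axis=0)
    keep = miss_frac <= max_missing
    all_missing = np.isnan(vals).all(axis=0)
    keep &= ~all_missing
    vals = vals[:, keep]
    col_means = np.nanmean(vals, axis=0) if vals.size else np.empty(0)
    nan_r, nan_c = np.nonzero(np.isnan(vals))
    vals[nan_r, nan_c] = col_means[nan_c]
    kept_idx = np.nonzero(keep)[0]
    if drop_zero_variance and vals.size:
        nonconst = vals.std(axis=0) > 0
        vals = vals[:, nonconst]
        kept_idx = kept_idx[nonconst]
    if vals.shape[1] == 0:
        raise ValueError("all markers removed by filtering; nothing to impute")
    info = None
    if g.marker_info is not None:
        info = g.marker_info.iloc[kept_idx].reset_index(drop=True)
    return GenotypeMatrix(
        vals, list(g.individuals), [g.markers[j] for j in kept_idx], info
    )


def minmax_normalize(v) -> np.ndarray:
    """Min-max normalize a vector: f(v) = (v - min v) / (max v - min v).

    Maps the range of ``v`` onto [0, 1]; order preserving and invariant to
    positive affine transforms.  Undefined (raises) for a constant vector.
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("trait vector contains non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined for a constant vector")
    return (v - lo) / (hi - lo)
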