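"""Genotype/phenotype containers, file I/O, quality control and phenotype correction.

Dosages count copies of allele2: 0 for A1A1, 1 for A1A2, 2 for A2A2, with a
single missing sentinel (:data:`MISSING`, -1).  Genotypes can be read from
plain or bgzipped VCF (via cyvcf2) or from a tabular dosage file (rows =
individuals, columns = markers, entries 0/1/2/NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

MISSING: int = -1

MARKER_COLUMNS = ["marker_id", "chromosome", "position", "allele1", "allele2"]


class ParseError(ValueError):
    """Raised when a genotype or phenotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers integer dosage matrix with marker metadata.

    Parameters
    ----------
    individual_ids : list of str
        Ordered, unique individual identifiers (length n).
    markers : pandas.DataFrame
        One row per marker with columns ``marker_id``, ``chromosome``,
        ``position`` (1-based bp), ``allele1``, ``allele2``.
    dosages : ndarray of int, shape (n, m)
        Copies of allele2 in {0, 1, 2}, or :data:`MISSING` (-1).
    """

    individual_ids: list
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        mids = self.markers["marker_id"]
        if mids.duplicated().any():
            dup = mids[mids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if (self.markers["position"] < 0).any():
            raise ValueError("negative marker position")
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.individual_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.markers)} markers"
            )
        ok = (self.dosages == MISSING) | ((self.dosages >= 0) & (self.dosages <= 2))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def subset_markers(self, mask_or_ids) -> "GenotypeMatrix":
        """Return a new matrix restricted to a boolean mask or list of marker ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {m: i for i, m in enumerate(self.markers["marker_id"])}
            idx = np.array([pos[m] for m in arr], dtype=int)
        return GenotypeMatrix(
            self.individual_ids,
            self.markers.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            self.markers.reset_index(drop=True),
            self.dosages[idx, :],
        )


@dataclass
class MafSummary:
    """Marker counts per MAF bin and their coefficient of variation."""

    bin_edges: np.ndarray
    counts: np.ndarray
    cv: float


# ---------------------------------------------------------------------------
# I/O


def _vcf_to_dosage(variant) -> np.ndarray:
    # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 with gts012), 3=unknown
    g = np.asarray(variant.gt_types, dtype=np.int16)
    g[g == 3] = MISSING
    return g


def read_vcf(path) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF of biallelic SNPs into dosages of ALT.

    Half-calls (e.g. ``./1``) and multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ParseError(
                f"multi-allelic record at {v.CHROM}:{v.POS} — split or drop it first"
            )
        gts = v.genotypes  # [[a, b, phased], ...]
        for (sample_id, gt) in zip(ids, gts):
            a, b = gt[0], gt[1]
            if (a < 0) != (b < 0):
                raise ParseError(f"half-call at {v.CHROM}:{v.POS} sample {sample_id}")
        rows.append(_vcf_to_dosage(v))
        meta.append(
            (v.ID or f"{v.CHROM}_{v.POS}", str(v.CHROM), int(v.POS), v.REF, v.ALT[0])
        )
    if not rows:
        raise ParseError(f"no variant records in {path}")
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    return GenotypeMatrix(ids, markers, np.array(rows, dtype=np.int16).T)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased minimal VCFv4.2 (GT only)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.individual_ids))
            + "\n"
        )
        for j, row in enumerate(g.markers.itertuples(index=False)):
            gts = "\t".join(code[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.marker_id}\t"
                f"{row.allele1}\t{row.allele2}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a tabular dosage file: first column individual id, header of marker ids."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected id column plus at least one marker column")
    ids = df.iloc[:, 0].tolist()
    marker_ids = list(df.columns[1:])
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid dosage {vals[i, j]!r} at line {i + 2}, marker {marker_ids[j]}"
        )
    dos = np.where(np.isnan(vals), MISSING, vals).astype(np.int16)
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chromosome": "0",
            "position": np.arange(1, len(marker_ids) + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(ids, markers, dos)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    out = pd.DataFrame(
        np.where(g.dosages == MISSING, np.nan, g.dosages),
        columns=g.markers["marker_id"],
    )
    out = out.astype("Int64")
    out.insert(0, "id", g.individual_ids)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from ``path`` as VCF or tabular dosage TSV.

    ``format`` is one of ``vcf``, ``tsv`` or ``auto`` (by extension).
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table (CSV/TSV with columns id, trait, sex, batch)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sex": str, "batch": str})
    missing = {"id", "trait", "sex", "batch"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing phenotype columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ParseError(f"{path}: duplicate individual ids")
    if not np.isfinite(df["trait"].to_numpy(dtype=float)).all():
        raise ParseError(f"{path}: non-finite trait values")
    return df


# ---------------------------------------------------------------------------
# Quality control


def compute_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker fraction of non-missing genotypes, in [0, 1]."""
    return (g.dosages != MISSING).mean(axis=0)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency; NaN where all genotypes are missing.

    Missing entries are excluded from the allele counts: with c non-missing
    calls carrying a total of s allele2 copies, p = s / (2c) and
    MAF = min(p, 1 - p).
    """
    obs = g.dosages != MISSING
    n_obs = obs.sum(axis=0)
    s = np.where(obs, g.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, s / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.70,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain markers with call rate > ``call_rate_min`` and MAF >= ``maf_min``.

    The call-rate comparison is strict and the MAF comparison inclusive,
    mirroring the usual "more than 70% called" / "MAF below 0.01 deleted"
    convention.  Returns the filtered matrix and a per-marker report with
    columns marker_id, call_rate, maf, kept, reason.
    """
    if not (0 <= call_rate_min <= 1 and 0 <= maf_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = compute_call_rate(g)
    maf = compute_maf(g)
    pass_cr = cr > call_rate_min
    pass_maf = ~np.isnan(maf) & (maf >= maf_min)
    kept = pass_cr & pass_maf
    reason = np.where(
        kept,
        "",
        np.where(
            ~pass_cr & ~pass_maf,
            "call_rate;maf",
            np.where(~pass_cr, "call_rate", "maf"),
        ),
    )
    report = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "call_rate": cr,
            "maf": maf,
            "kept": kept,
            "reason": reason,
        }
    )
    if not kept.any():
        warnings.warn("QC removed every marker", stacklevel=2)
    return g.subset_markers(kept), report


# ---------------------------------------------------------------------------
# Phenotype correction


def _sum_to_zero_design(levels: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: L-1 columns; last level coded -1."""
    cats = sorted(levels.unique())
    if len(cats) == 1:
        return np.zeros((len(levels), 0)), []
    cols = np.zeros((len(levels), len(cats) - 1))
    for j, c in enumerate(cats[:-1]):
        cols[:, j] = (levels == c).astype(float) - (levels == cats[-1]).astype(float)
    return cols, cats[:-1]


def correct_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Remove sex and batch fixed effects from the trait by least squares.

    Fits y = intercept + sex + batch by OLS with sum-to-zero effect coding
    and returns y_c = y - sex effect - batch effect.  The intercept is kept,
    so in balanced designs mean(y_c) = mean(y).

    Returns a DataFrame with columns ``id`` and ``yc``.
    """
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 individuals to correct phenotypes")
    y = phenotypes["trait"].to_numpy(dtype=float)
    Xs, _ = _sum_to_zero_design(phenotypes["sex"])
    Xb, _ = _sum_to_zero_design(phenotypes["batch"])
    X = np.column_stack([np.ones(len(y)), Xs, Xb])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "sex and batch are confounded (rank-deficient design); "
            "merge or drop aliased levels"
        )
    fit = sm.OLS(y, X).fit()
    fixed_part = X[:, 1:] @ fit.params[1:]
    return pd.DataFrame({"id": phenotypes["id"], "yc": y - fixed_part})


# ---------------------------------------------------------------------------
# MAF spectrum


def maf_distribution(
    g: GenotypeMatrix, bin_width: float = 0.05, maf_floor: float = 0.0
) -> MafSummary:
    """Bin polymorphic-marker MAF and compute the coefficient of variation.

    Bins are half-open ``[floor, floor+w), ...`` with the final bin closed at
    0.5.  cv is the sample standard deviation of the bin counts divided by
    their mean — a uniformity measure of the MAF spectrum.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    maf = compute_maf(g)
    maf = maf[~np.isnan(maf) & (maf > 0) & (maf >= maf_floor)]
    if maf.size == 0:
        raise ValueError("no polymorphic marker to summarize")
    edges = np.arange(maf_floor, 0.5 + bin_width, bin_width)
    edges[-1] = 0.5
    counts, _ = np.histogram(maf, bins=edges)
    mean = counts.mean()
    sd = counts.std(ddof=1) if len(counts) > 1 else 0.0
    cv = float(sd / mean) if mean > 0 else 0.0
    return MafSummary(bin_edges=edges, counts=counts, cv=cv)
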