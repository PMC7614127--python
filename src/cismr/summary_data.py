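"""Domain types, file I/O and harmonization for two-sample summary-data cis-MR.

A cis-MR analysis works from three ingredients: marginal SNP-exposure
association statistics, marginal SNP-outcome association statistics (from a
different, non-overlapping sample), and a reference panel from which pairwise
genotype correlations (LD) are estimated.  This module defines the containers
for those ingredients, readers/writers for the plain-text exchange formats,
and the harmonization step that puts all three on a common variant list and
allele coding and builds the IVW weighting matrix

    Omega_ij = se_Yi * se_Yj * rho_ij ,

i.e. ``diag(se_y) @ R @ diag(se_y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SummaryStats",
    "LDReference",
    "HarmonizedDataset",
    "ParseReport",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "ld_from_genotypes",
    "harmonize",
]

_ALLELES = frozenset("ACGTN")  # N marks an unknown coding (allele-free LD files)
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

REQUIRED_COLUMNS = ("snp", "ea", "nea", "eaf", "beta", "se", "pval")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with its effect-allele coding and frequency."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float

    def __post_init__(self):
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise ValueError(
                f"{self.snp_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele != "N":
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie in (0,1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC

    def flipped(self) -> "VariantRecord":
        """The same variant coded on the opposite allele."""
        return VariantRecord(
            self.snp_id, self.chrom, self.pos,
            self.other_allele, self.effect_allele, 1.0 - self.eaf,
        )


@dataclass
class ParseReport:
    """Per-line issues found while reading a summary-statistics file."""

    rejected: list = field(default_factory=list)  # (line_number, snp_id, reason)

    def add(self, line: int, snp_id: str, reason: str) -> None:
        self.rejected.append((line, snp_id, reason))


@dataclass
class SummaryStats:
    """Marginal association statistics for one gene region.

    Either side (exposure ``*_x`` / outcome ``*_y``) may be ``None`` when the
    object holds a single GWAS; :func:`harmonize` merges two one-sided
    objects into a complete dataset.
    """

    variants: list
    beta_x: np.ndarray | None = None
    se_x: np.ndarray | None = None
    p_x: np.ndarray | None = None
    beta_y: np.ndarray | None = None
    se_y: np.ndarray | None = None
    n_x: float | None = None
    n_y: float | None = None
    parse_report: ParseReport | None = None

    def __post_init__(self):
        p = len(self.variants)
        seen = set()
        for v in self.variants:
            if v.snp_id in seen:
                raise ValueError(f"duplicate snp_id {v.snp_id!r} within region")
            seen.add(v.snp_id)
        for name in ("beta_x", "se_x", "p_x", "beta_y", "se_y"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != (p,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({p},)")
        for name in ("se_x", "se_y"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.p_x is not None and (np.any(self.p_x <= 0) or np.any(self.p_x > 1)):
            raise ValueError("p_x must lie in (0, 1]")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list:
        return [v.snp_id for v in self.variants]

    @property
    def eaf(self) -> np.ndarray:
        return np.array([v.eaf for v in self.variants])

    def subset(self, idx) -> "SummaryStats":
        idx = np.asarray(idx)
        pick = lambda a: None if a is None else a[idx]
        return SummaryStats(
            variants=[self.variants[i] for i in idx],
            beta_x=pick(self.beta_x), se_x=pick(self.se_x), p_x=pick(self.p_x),
            beta_y=pick(self.beta_y), se_y=pick(self.se_y),
            n_x=self.n_x, n_y=self.n_y,
        )


@dataclass
class LDReference:
    """Reference-panel correlation matrix aligned to a variant list."""

    variants: list
    corr: np.ndarray
    n_ref: int | None = None

    def __post_init__(self):
        p = len(self.variants)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (p, p):
            raise ValueError(f"corr has shape {self.corr.shape}, expected ({p},{p})")
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("corr must be symmetric")
        if np.any(np.abs(self.corr) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.min(np.linalg.eigvalsh((self.corr + self.corr.T) / 2)) < -1e-8:
            raise ValueError("corr is not positive semi-definite within tolerance")

    @property
    def snp_ids(self) -> list:
        return [v.snp_id for v in self.variants]

    def subset(self, idx) -> "LDReference":
        idx = np.asarray(idx)
        return LDReference(
            variants=[self.variants[i] for i in idx],
            corr=self.corr[np.ix_(idx, idx)],
            n_ref=self.n_ref,
        )


@dataclass
class HarmonizedDataset:
    """Exposure + outcome statistics and LD on one variant list/order.

    ``omega`` is the correlated-IVW weighting matrix
    ``diag(se_y) @ corr @ diag(se_y)``.
    """

    stats: SummaryStats
    ld: LDReference
    omega: np.ndarray
    dropped: list = field(default_factory=list)  # (snp_id, reason)

    def __post_init__(self):
        if self.stats.snp_ids != self.ld.snp_ids:
            raise ValueError("stats and ld must cover identical variants in order")
        self.omega = np.asarray(self.omega, dtype=float)

    @property
    def n_variants(self) -> int:
        return self.stats.n_variants

    def subset(self, idx) -> "HarmonizedDataset":
        idx = np.asarray(idx)
        return HarmonizedDataset(
            stats=self.stats.subset(idx),
            ld=self.ld.subset(idx),
            omega=self.omega[np.ix_(idx, idx)],
        )

    def subset_by_id(self, snp_ids) -> "HarmonizedDataset":
        pos = {s: i for i, s in enumerate(self.stats.snp_ids)}
        return self.subset([pos[s] for s in snp_ids])


def read_summary_stats(path, role: str = "exposure") -> SummaryStats:
    """Read a tab-separated GWAS summary-statistics file.

    The header must contain at least ``snp ea nea eaf beta se pval``
    (``chr``, ``pos``, ``n`` optional; extra columns ignored).  Rows with an
    out-of-range frequency, non-positive standard error or out-of-range
    p-value are rejected and listed in the returned object's
    ``parse_report``; a non-numeric beta/se is a hard error.
    """
    if role not in ("exposure", "outcome"):
        raise ValueError(f"role must be 'exposure' or 'outcome', got {role!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")

    report = ParseReport()
    variants, rows = [], []
    n_col = pd.to_numeric(df["n"], errors="coerce") if "n" in df.columns else None
    n_value = None
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        snp = str(row["snp"])
        try:
            beta = float(row["beta"])
            se = float(row["se"])
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric beta/se at line {line} of {path}"
            ) from None
        eaf = pd.to_numeric(row["eaf"], errors="coerce")
        pval = pd.to_numeric(row["pval"], errors="coerce")
        if not np.isfinite(eaf) or not 0 < eaf < 1:
            report.add(line, snp, f"eaf out of range: {row['eaf']}")
            continue
        if se <= 0:
            report.add(line, snp, f"non-positive se: {se}")
            continue
        if not np.isfinite(pval) or not 0 < pval <= 1:
            report.add(line, snp, f"pval out of range: {row['pval']}")
            continue
        ea, nea = str(row["ea"]).upper(), str(row["nea"]).upper()
        try:
            rec = VariantRecord(
                snp_id=snp,
                chrom=str(row.get("chr", "NA")),
                pos=int(row["pos"]) if "pos" in df.columns else 0,
                effect_allele=ea, other_allele=nea, eaf=float(eaf),
            )
        except ValueError as exc:
            report.add(line, snp, str(exc))
            continue
        variants.append(rec)
        rows.append((beta, se, float(pval)))
        if n_col is not None and np.isfinite(n_col.iloc[i]):
            n_value = float(n_col.iloc[i])

    if not variants:
        raise ValueError(f"no valid rows in {path}")
    beta, se, pval = map(np.array, zip(*rows))
    if role == "exposure":
        return SummaryStats(variants, beta_x=beta, se_x=se, p_x=pval,
                            n_x=n_value, parse_report=report)
    return SummaryStats(variants, beta_y=beta, se_y=se,
                        n_y=n_value, parse_report=report)


def write_summary_stats(stats: SummaryStats, path, role: str = "exposure") -> None:
    """Write one side of a :class:`SummaryStats` to TSV at full precision."""
    if role == "exposure":
        beta, se, pval, n = stats.beta_x, stats.se_x, stats.p_x, stats.n_x
    else:
        beta, se = stats.beta_y, stats.se_y
        pval, n = None, stats.n_y
    if beta is None:
        raise ValueError(f"no {role} statistics to write")
    df = pd.DataFrame({
        "snp": stats.snp_ids,
        "chr": [v.chrom for v in stats.variants],
        "pos": [v.pos for v in stats.variants],
        "ea": [v.effect_allele for v in stats.variants],
        "nea": [v.other_allele for v in stats.variants],
        "eaf": stats.eaf,
        "beta": beta,
        "se": se,
        "pval": pval if pval is not None else 1.0,
    })
    if n is not None:
        df["n"] = n
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _generic_variants(snp_ids) -> list:
    # LD matrix files carry no allele information; mark the coding unknown
    return [VariantRecord(s, "NA", 0, "N", "N", 0.5) for s in snp_ids]


def read_ld_matrix(path) -> LDReference:
    """Read an LD correlation matrix.

    Two dialects: a square whitespace-delimited matrix whose header row lists
    the SNP ids, or a long format with three columns ``id1 id2 r``.
    Asymmetries up to 1e-6 are averaged away; anything larger is an error, as
    is a diagonal entry off unity by more than 1e-6.
    """
    with open(path) as fh:
        first = fh.readline().split()
        second = fh.readline().split()
    is_long = len(first) == 3 and len(second) in (0, 3)
    if is_long:
        try:
            float(first[2])
        except ValueError:
            is_long = False  # header row of a 3x3 square matrix
    if is_long:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["id1", "id2", "r"])
        ids = list(dict.fromkeys(list(df["id1"]) + list(df["id2"])))
        pos = {s: i for i, s in enumerate(ids)}
        corr = np.eye(len(ids))
        for id1, id2, r in df.itertuples(index=False):
            corr[pos[id1], pos[id2]] = r
            corr[pos[id2], pos[id1]] = r
        return LDReference(_generic_variants(ids), corr)

    df = pd.read_csv(path, sep=r"\s+")
    ids = list(df.columns)
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"LD matrix is not square: {mat.shape[0]} rows x {mat.shape[1]} columns"
        )
    asym = np.max(np.abs(mat - mat.T))
    if asym > 1e-6:
        raise ValueError(f"LD matrix asymmetric by {asym:.3g} (> 1e-6)")
    mat = (mat + mat.T) / 2
    diag_err = np.max(np.abs(np.diag(mat) - 1))
    if diag_err > 1e-6:
        raise ValueError(f"LD matrix diagonal deviates from 1 by {diag_err:.3g}")
    np.fill_diagonal(mat, 1.0)
    return LDReference(_generic_variants(ids), mat)


def write_ld_matrix(ld: LDReference, path) -> None:
    pd.DataFrame(ld.corr, columns=ld.snp_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def ld_from_genotypes(dosages, variants, n_ref: int | None = None) -> LDReference:
    """Pearson correlations of dosage columns (one column per variant)."""
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("dosage matrix must be n x P with n >= 2")
    if dosages.shape[1] != len(variants):
        raise ValueError("dosage columns must match the variant list")
    sd = dosages.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            vid = variants[j].snp_id if hasattr(variants[j], "snp_id") else variants[j]
            raise ValueError(f"constant dosage column for variant {vid}")
    corr = np.corrcoef(dosages, rowvar=False)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return LDReference(list(variants), corr,
                       n_ref=n_ref if n_ref is not None else dosages.shape[0])


def _match_alleles(ref: VariantRecord, other: VariantRecord):
    """Return 'same', 'swap' or None for the coding relation of two records."""
    if "N" in (other.effect_allele, other.other_allele):
        return "same"  # allele-free source (e.g. a bare LD matrix): trust it
    if (other.effect_allele, other.other_allele) == (ref.effect_allele, ref.other_allele):
        return "same"
    if (other.effect_allele, other.other_allele) == (ref.other_allele, ref.effect_allele):
        return "swap"
    return None


def harmonize(exposure: SummaryStats, outcome: SummaryStats, ld: LDReference,
              drop_palindromic: bool = False) -> HarmonizedDataset:
    """Align exposure, outcome and LD on common variants and allele coding.

    Variant order follows the exposure file.  An outcome record coded on the
    exposure's other allele has its beta sign-flipped; an LD-panel record
    coded on the other allele has its correlation row/column sign-flipped.
    Allele pairs that neither match nor swap are dropped with reason
    ``allele_mismatch``; A/T and C/G variants are dropped when
    ``drop_palindromic`` is set.
    """
    out_pos = {v.snp_id: i for i, v in enumerate(outcome.variants)}
    ld_pos = {v.snp_id: i for i, v in enumerate(ld.variants)}
    dropped = []
    keep_e, keep_o, keep_l, flip_y, flip_ld = [], [], [], [], []
    for i, v in enumerate(exposure.variants):
        if v.snp_id not in out_pos or v.snp_id not in ld_pos:
            dropped.append((v.snp_id, "not_shared"))
            continue
        if drop_palindromic and v.is_palindromic:
            dropped.append((v.snp_id, "palindromic"))
            continue
        j, k = out_pos[v.snp_id], ld_pos[v.snp_id]
        rel_o = _match_alleles(v, outcome.variants[j])
        rel_l = _match_alleles(v, ld.variants[k])
        if rel_o is None or rel_l is None:
            dropped.append((v.snp_id, "allele_mismatch"))
            continue
        keep_e.append(i)
        keep_o.append(j)
        keep_l.append(k)
        flip_y.append(rel_o == "swap")
        flip_ld.append(rel_l == "swap")
    if not keep_e:
        raise ValueError("no variants shared between exposure, outcome and LD")

    keep_e = np.asarray(keep_e)
    stats_x = exposure.subset(keep_e)
    beta_y = outcome.beta_y[np.asarray(keep_o)].copy()
    se_y = outcome.se_y[np.asarray(keep_o)].copy()
    beta_y[np.asarray(flip_y)] *= -1

    ld_sub = ld.subset(np.asarray(keep_l))
    corr = ld_sub.corr.copy()
    sign = np.where(np.asarray(flip_ld), -1.0, 1.0)
    corr = corr * np.outer(sign, sign)
    ld_aligned = LDReference(list(stats_x.variants), corr, n_ref=ld.n_ref)

    merged = SummaryStats(
        variants=list(stats_x.variants),
        beta_x=stats_x.beta_x, se_x=stats_x.se_x, p_x=stats_x.p_x,
        beta_y=beta_y, se_y=se_y,
        n_x=exposure.n_x, n_y=outcome.n_y,
    )
    omega = corr * np.outer(se_y, se_y)
    return HarmonizedDataset(stats=merged, ld=ld_aligned, omega=omega,
                             dropped=dropped)
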