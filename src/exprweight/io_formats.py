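"""Readers/writers for the standard formats the pipeline touches.

Genotypes come from VCF 4.x (via cyvcf2), gene definitions from BED4
(0-based half-open), expression from a wide TSV (first column sample id,
remaining columns probes), phenotypes from a long TSV
(individual/visit/measurement/value).  Coordinates are converted explicitly
when joining: VCF positions are 1-based, BED intervals 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x variants ALT-allele counts with per-variant metadata.

    ``counts`` is a float matrix with values in {0, 1, 2} and NaN for
    missing calls.  ``variants`` is a DataFrame with columns
    ``chrom, pos, ref, alt, maf, monomorphic, n_missing`` (pos 1-based).
    MAF is the minor-allele frequency computed from non-missing calls in
    the analysed sample set: ``min(alt_freq, 1 - alt_freq)``.
    """

    samples: list[str]
    counts: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        obs = self.counts[np.isfinite(self.counts)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype counts must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def analysis_counts(self) -> np.ndarray:
        """Counts with missing calls imputed as the variant mean (2 x ALT freq).

        Mean imputation preserves the allele frequency; imputed variants are
        flagged through ``variants['n_missing']``.
        """
        out = self.counts.copy()
        nan_mask = ~np.isfinite(out)
        if nan_mask.any():
            col_mean = np.nanmean(np.where(nan_mask, np.nan, out), axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            idx = np.nonzero(nan_mask)
            out[idx] = col_mean[idx[1]]
        return out

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        missing = [s for s in sample_ids if s not in set(self.samples)]
        if missing:
            raise KeyError(f"samples not present in genotype matrix: {missing}")
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        sub = GenotypeMatrix.__new__(GenotypeMatrix)
        sub.samples = list(sample_ids)
        sub.counts = self.counts[rows]
        sub.variants = self.variants.copy()
        _annotate_frequencies(sub)
        return sub


@dataclass
class GeneEntry:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    variant_indices: list[int] = field(default_factory=list)


@dataclass
class GeneTable:
    """Gene id -> interval -> member variant column indices (sorted)."""

    entries: dict[str, GeneEntry]

    def __post_init__(self) -> None:
        for gene, e in self.entries.items():
            idx = list(e.variant_indices)
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"variant indices for {gene} not strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())


@dataclass
class PhenotypeTable:
    """Long-format records of (individual, visit, measurement, value)."""

    records: pd.DataFrame

    REQUIRED = ("individual", "visit", "measurement", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        keys = self.records[["individual", "visit", "measurement"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (individual, visit, measurement) key: {dup}")

    @property
    def measurements(self) -> list[str]:
        return sorted(self.records["measurement"].unique())


@dataclass
class ExpressionMatrix:
    """Samples x probes real-valued expression values (NaN = missing)."""

    samples: list[str]
    probes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.probes)):
            raise ValueError("expression values shape mismatch")
        if self.probes and np.isnan(self.values).all(axis=0).any():
            bad = [p for p, m in zip(self.probes, np.isnan(self.values).all(axis=0)) if m]
            raise ValueError(f"probes with all-missing values: {bad}")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not present in expression matrix: {missing}")
        rows = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), list(self.probes), self.values[rows])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _annotate_frequencies(geno: GenotypeMatrix) -> None:
    """(Re)compute maf / monomorphic / n_missing columns from counts."""
    counts = geno.counts
    with np.errstate(invalid="ignore"):
        n_obs = np.isfinite(counts).sum(axis=0)
        alt_freq = np.where(n_obs > 0, np.nansum(counts, axis=0) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    geno.variants = geno.variants.assign(
        maf=maf,
        monomorphic=(maf == 0.0),
        n_missing=(len(geno.samples) - n_obs),
    )


def read_vcf_genotypes(
    path: str,
    samples: list[str] | None = None,
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix` of ALT-allele counts.

    Multiallelic records are rejected by default; with
    ``split_multiallelic=True`` each ALT allele becomes its own column with
    counts of that allele.  MAF is computed from non-missing calls.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc

    if samples is not None:
        available = set(vcf.samples)
        absent = [s for s in samples if s not in available]
        if absent:
            raise KeyError(f"requested samples absent from VCF: {absent}")
        vcf = VCF(path, gts012=True, samples=samples)

    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    for i, var in enumerate(vcf):
        if var.ALT is None or len(var.ALT) == 0:
            continue
        if len(var.ALT) > 1:
            if not split_multiallelic:
                raise ValueError(
                    f"multiallelic record at {var.CHROM}:{var.POS} "
                    f"(VCF data line {i + 1}); re-run with split_multiallelic=True"
                )
            gts = np.array([g[:2] for g in var.genotypes], dtype=float)
            called = np.array([g[0] >= 0 and g[1] >= 0 for g in var.genotypes])
            for alt_index, alt in enumerate(var.ALT, start=1):
                col = (gts == alt_index).sum(axis=1).astype(float)
                col[~called] = np.nan
                cols.append(col)
                meta.append((var.CHROM, var.POS, var.REF, alt))
        else:
            col = np.asarray(var.gt_types, dtype=float)
            col[col == 3] = np.nan  # gts012: 3 == unknown
            cols.append(col)
            meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))

    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    counts = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    geno = GenotypeMatrix(sample_ids, counts, variants)
    _annotate_frequencies(geno)
    return geno


def read_gene_annotation(path: str, geno: GenotypeMatrix) -> GeneTable:
    """Read a BED4 file and join gene intervals to variants of ``geno``.

    BED intervals are 0-based half-open; a variant at 1-based position
    ``pos`` belongs to gene [start, end) when ``start <= pos - 1 < end``.
    Unsorted input is accepted and sorted internally; duplicate gene names
    are rejected.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if bed.shape[1] < 4:
        raise ValueError(f"BED file {path!r} needs >= 4 columns (chrom start end name)")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "name"]
    dup = bed["name"][bed["name"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene names in BED: {sorted(dup.unique())}")
    bed = bed.sort_values(["chrom", "start"]).reset_index(drop=True)

    # group variant 0-based positions by chromosome for a sorted lookup
    var = geno.variants
    entries: dict[str, GeneEntry] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in var.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        by_chrom[str(chrom)] = (pos0[order], sub.index.to_numpy()[order])

    for row in bed.itertuples(index=False):
        chrom, start, end, name = str(row.chrom), int(row.start), int(row.end), str(row.name)
        if chrom in by_chrom:
            pos0, idx = by_chrom[chrom]
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            members = sorted(int(j) for j in idx[lo:hi])
        else:
            members = []
        entries[name] = GeneEntry(chrom, start, end, members)
    return GeneTable(entries)


def read_expression(path: str) -> ExpressionMatrix:
    """Read a wide TSV: first column sample id, remaining columns probes."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"expression TSV {path!r} needs a sample column and >= 1 probe")
    samples = df.iloc[:, 0].astype(str).tolist()
    probes = list(df.columns[1:])
    return ExpressionMatrix(samples, probes, df.iloc[:, 1:].to_numpy(dtype=float))


def read_phenotype(path: str) -> PhenotypeTable:
    """Read a long TSV with columns individual, visit, measurement, value."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "measurement": str})
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# summaries / writers
# ---------------------------------------------------------------------------


def average_visits(pheno: PhenotypeTable, measurement: str) -> pd.Series:
    """Per-individual arithmetic mean over available visits.

    Individuals with no non-missing value for the measurement are dropped
    with a warning; the mean uses available visits only.
    """
    df = pheno.records
    if df.empty:
        raise ValueError("phenotype table is empty")
    sub = df[df["measurement"] == measurement]
    if sub.empty:
        raise ValueError(f"measurement {measurement!r} not present in phenotype table")
    means = sub.groupby("individual", sort=False)["value"].mean()
    dropped = means[means.isna()].index.tolist()
    if dropped:
        logger.warning(
            "dropping %d individuals with no %s value: %s",
            len(dropped), measurement, dropped[:10],
        )
        means = means.dropna()
    return means


def write_results(results: list, path: str, display_3dp: bool = False) -> None:
    """Write per-gene results as TSV.

    Columns are gene, chrom, n_rare_variants followed by
    ``<pheno>_raw_p, <pheno>_weight, <pheno>_adjusted_p`` per phenotype.
    Floats use 6 significant digits by default; ``display_3dp`` switches to
    a fixed 3-decimal display.
    """
    rows = []
    phenos: list[str] = []
    for r in results:
        row = {"gene": r.gene, "chrom": r.chrom, "n_rare_variants": r.k}
        for ph, vals in r.per_phenotype.items():
            if ph not in phenos:
                phenos.append(ph)
            row[f"{ph}_raw_p"] = vals["raw_p"]
            row[f"{ph}_weight"] = vals["weight"]
            row[f"{ph}_adjusted_p"] = vals["adjusted_p"]
        rows.append(row)
    columns = ["gene", "chrom", "n_rare_variants"]
    for ph in phenos:
        columns += [f"{ph}_raw_p", f"{ph}_weight", f"{ph}_adjusted_p"]
    df = pd.DataFrame(rows, columns=columns)
    fmt = "%.3f" if display_3dp else "%.6g"
    df.to_csv(path, sep="\t", index=False, float_format=fmt)


def read_results(path: str) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
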