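"""Core data model: genotype matrices, variant records, allele frequencies.

Conventions used throughout the package:

* Genomic coordinates are 1-based inclusive (GRCh37 convention; VCF agrees).
* Dosages count copies of the ALT allele and live in ``{0, 1, 2}``;
  missing genotypes are ``NaN`` in a float array.
* The minor allele frequency (MAF) of a site is computed from non-missing
  allele counts only; missing genotypes are excluded, not imputed.
* "Common" variants have sample MAF >= 10% (boundary inclusive); everything
  below is "low-frequency".
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMMON_MAF_THRESHOLD = 0.10

__all__ = [
    "COMMON_MAF_THRESHOLD",
    "VariantRecord",
    "GenotypeMatrix",
    "FrequencyClass",
    "read_vcf",
    "compute_maf",
    "classify_frequency",
    "locus_length",
    "summarize_variants",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed
    percentage tables), unlike banker's rounding of the builtin."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass
class VariantRecord:
    """One biallelic variant with its annotations.

    ``feature_location`` uses free-text labels such as ``"exon 10"``,
    ``"intron 6"``, ``"upstream"``, ``"5'UTR"``, ``"3'UTR"``,
    ``"downstream"``. ``exon_distance_bp`` is the distance (bp) into the
    intron from the nearest exon boundary and must be present iff the
    variant is intronic. ``ref_panel_afs`` maps reference-panel names
    (e.g. ``"1000g_all"``, ``"1000g_eur"``, ``"evs"``) to alternate-allele
    frequencies; an absent panel means the variant is not annotated there.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dbsnp_id: str | None = None
    is_indel: bool = False
    hgvs_c: str | None = None
    gene: str | None = None
    feature_location: str | None = None
    exon_distance_bp: int | None = None
    ref_panel_afs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.is_intronic and self.exon_distance_bp is None:
            raise ValueError(
                f"{self.variant_id}: intronic variant needs exon_distance_bp"
            )
        if not self.is_intronic and self.exon_distance_bp is not None:
            raise ValueError(
                f"{self.variant_id}: exon_distance_bp only applies to intronic variants"
            )

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_intronic(self) -> bool:
        return self.feature_location is not None and self.feature_location.lower().startswith(
            "intron"
        )

    @property
    def is_exonic(self) -> bool:
        return self.feature_location is not None and self.feature_location.lower().startswith(
            "exon"
        )


class GenotypeMatrix:
    """Individuals x variants dosage matrix.

    Parameters
    ----------
    dosages:
        Array of shape ``(n_individuals, n_variants)`` with entries in
        ``{0, 1, 2}`` and ``NaN`` for missing genotypes.
    individual_ids, variant_ids:
        Row and column labels.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        individual_ids: list[str],
        variant_ids: list[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, m = dosages.shape
        if len(individual_ids) != n:
            raise ValueError(f"{len(individual_ids)} individual ids for {n} rows")
        if len(variant_ids) != m:
            raise ValueError(f"{len(variant_ids)} variant ids for {m} columns")
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = dosages[~valid]
            raise ValueError(f"dosages must be 0/1/2/NaN; found {bad[:5]}")
        if m and np.isnan(dosages).all(axis=0).any():
            raise ValueError("every variant needs at least one non-missing genotype")
        self.dosages = dosages
        self.individual_ids = list(individual_ids)
        self.variant_ids = list(variant_ids)
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
        self._iidx = {s: i for i, s in enumerate(self.individual_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._vidx[variant_id]]

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._vidx[v] for v in variant_ids]
        return GenotypeMatrix(
            self.dosages[:, idx], self.individual_ids, list(variant_ids)
        )

    def subset_individuals(self, individual_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._iidx[s] for s in individual_ids]
        return GenotypeMatrix(
            self.dosages[idx, :], list(individual_ids), self.variant_ids
        )

    def mafs(self) -> np.ndarray:
        return np.array([compute_maf(self.dosages[:, j]) for j in range(self.n_variants)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_variants} variants)"


@dataclass(frozen=True)
class FrequencyClass:
    maf: float
    frequency_class: str  # "common" | "low_frequency"
    threshold: float = COMMON_MAF_THRESHOLD

    @property
    def is_common(self) -> bool:
        return self.frequency_class == "common"


def compute_maf(dosages: np.ndarray) -> float:
    """Sample minor allele frequency from a dosage vector.

    ``min(f, 1 - f)`` with ``f`` the ALT-allele frequency among non-missing
    genotypes. Raises if every genotype is missing.
    """
    d = np.asarray(dosages, dtype=float)
    mask = ~np.isnan(d)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    f = float(d[mask].sum()) / (2 * n)
    return min(f, 1.0 - f)


def classify_frequency(maf: float, threshold: float = COMMON_MAF_THRESHOLD) -> FrequencyClass:
    """Classify a site as common (MAF >= threshold) or low-frequency."""
    if not 0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    cls = "common" if maf >= threshold else "low_frequency"
    return FrequencyClass(maf=maf, frequency_class=cls, threshold=threshold)


def locus_length(start_bp: int, end_bp: int) -> int:
    """Length in bp of a 1-based inclusive interval."""
    if start_bp > end_bp:
        raise ValueError(f"start_bp {start_bp} > end_bp {end_bp}")
    return end_bp - start_bp + 1


def summarize_variants(
    variants: list[VariantRecord],
    loci: list[tuple[str, str, int, int]],
    rare_panel_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-locus descriptive summary of a variant list.

    ``loci`` is a list of ``(name, chrom, start_bp, end_bp)``. Reported per
    locus: totals, indels, exonic variants, variants lacking a dbSNP id, and
    variants whose every supplied reference-panel AF exceeds
    ``rare_panel_threshold`` (i.e. panel AF > 1% by default). Percentages are
    rounded half-up to one decimal; an empty locus reports NaN percentages.
    A variant falling in no locus is an error.
    """

    def locus_of(v: VariantRecord) -> str:
        for name, chrom, start, end in loci:
            if v.chrom == chrom and start <= v.pos <= end:
                return name
        raise ValueError(f"variant {v.variant_id} is outside every locus")

    rows = []
    by_locus: dict[str, list[VariantRecord]] = {name: [] for name, *_ in loci}
    for v in variants:
        by_locus[locus_of(v)].append(v)

    for name, chrom, start, end in loci:
        vs = by_locus[name]
        total = len(vs)
        n_indel = sum(v.is_indel for v in vs)
        n_exonic = sum(v.is_exonic for v in vs)
        n_no_dbsnp = sum(v.dbsnp_id is None for v in vs)
        n_panel_common = sum(
            bool(v.ref_panel_afs)
            and all(af > rare_panel_threshold for af in v.ref_panel_afs.values())
            for v in vs
        )

        def pct(k: int) -> float:
            return round_half_up(100.0 * k / total, 1) if total else float("nan")

        rows.append(
            {
                "locus": name,
                "chrom": chrom,
                "start_bp": start,
                "end_bp": end,
                "length_bp": locus_length(start, end),
                "n_variants": total,
                "n_indels": n_indel,
                "pct_indels": pct(n_indel),
                "n_exonic": n_exonic,
                "pct_exonic": pct(n_exonic),
                "n_not_in_dbsnp": n_no_dbsnp,
                "pct_not_in_dbsnp": pct(n_no_dbsnp),
                "n_panel_af_gt_1pct": n_panel_common,
                "pct_panel_af_gt_1pct": pct(n_panel_common),
            }
        )
    return pd.DataFrame(rows)


def read_vcf(path: str) -> tuple[GenotypeMatrix, list[VariantRecord], int]:
    """Load biallelic records from a VCF into a dosage matrix.

    Multiallelic records are skipped (their count is the third return
    value). Positions are kept 1-based as in the file. Genotype dosages
    count ALT alleles; any genotype containing a missing allele is NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        rec = VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=ref,
            alt=alt,
            dbsnp_id=v.ID if v.ID not in (None, ".", "") else None,
            is_indel=len(ref) != len(alt),
        )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = v.gt_types
        col = np.full(len(samples), np.nan)
        col[gt == 0] = 0.0
        col[gt == 1] = 1.0
        col[gt == 3] = 2.0
        records.append(rec)
        columns.append(col)
    vcf.close()
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(dosages, samples, [r.variant_id for r in records])
    return gm, records, n_multiallelic
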