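"""Polygenic score construction from GWAS weight tables and genotype panels.

A score is a per-sample weighted sum of effect-allele dosages.  Weight
records are joined to panel variants by id; strand-ambiguous records
(complementary allele pairs) are removed, records whose effect allele is the
panel reference allele are counted on the complementary dosage ``2 - x``,
and irreconcilable allele pairs are dropped.  No p-value threshold is ever
applied.  Raw scores are the weighted *sum* over matched variants; the
standardized score is the raw score centered and scaled to unit sample SD.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GwasWeightRecord",
    "GenotypePanel",
    "MatchedWeights",
    "MatchReport",
    "ScoreVector",
    "match_variants",
    "compute_scores",
    "read_weights",
    "read_panel",
    "is_strand_ambiguous",
    "standardize",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: column layout of the weights TSV dialect
WEIGHT_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


def is_strand_ambiguous(allele1: str, allele2: str) -> bool:
    """True if the allele pair is complementary (A/T or C/G)."""
    return COMPLEMENT.get(allele1) == allele2


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample SD (ddof=1); error on zero variance."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("cannot standardize: zero variance")
    return (values - values.mean()) / sd


@dataclasses.dataclass(frozen=True)
class GwasWeightRecord:
    """One row of a GWAS summary-statistic weight table."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float | None = None
    pval: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(
                f"invalid effect allele {self.effect_allele!r} for {self.variant_id}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"invalid other allele {self.other_allele!r} for {self.variant_id}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"identical alleles for {self.variant_id}")
        if self.pval is not None and not 0.0 <= self.pval <= 1.0:
            raise ValueError(f"p-value out of [0,1] for {self.variant_id}")

    @property
    def ambiguous(self) -> bool:
        return is_strand_ambiguous(self.effect_allele, self.other_allele)


@dataclasses.dataclass
class GenotypePanel:
    """Samples x variants alt-allele dosage matrix with variant metadata.

    Dosages are 0/1/2 alt-allele counts stored as float with NaN for
    missing genotypes.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.variant_ids = list(self.variant_ids)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in panel")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing genotypes."""
        observed = ~np.isnan(self.dosages)
        counts = observed.sum(axis=0)
        total = np.where(observed, self.dosages, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(counts > 0, total / (2.0 * counts), np.nan)
        return freq


@dataclasses.dataclass(frozen=True)
class MatchedWeights:
    """Weights resolved against a panel: variant column index, effect size and
    whether the dosage must be complemented (effect allele == panel ref)."""

    variant_index: np.ndarray
    beta: np.ndarray
    flipped: np.ndarray

    def __len__(self) -> int:
        return len(self.variant_index)


@dataclasses.dataclass(frozen=True)
class MatchReport:
    n_input_weights: int
    n_matched: int
    n_ambiguous_removed: int
    n_allele_mismatch: int
    n_unmatched_id: int
    n_flipped: int

    def __post_init__(self) -> None:
        total = (
            self.n_matched
            + self.n_ambiguous_removed
            + self.n_allele_mismatch
            + self.n_unmatched_id
        )
        if total != self.n_input_weights:
            raise ValueError("match report categories do not sum to input count")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ScoreVector:
    """Per-sample raw and standardized polygenic scores."""

    sample_ids: list[str]
    raw: np.ndarray
    std: np.ndarray
    n_variants_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.sample_ids,
                "raw_score": self.raw,
                "std_score": self.std,
            }
        )


def match_variants(
    panel: GenotypePanel, weights: list[GwasWeightRecord]
) -> tuple[MatchedWeights, MatchReport]:
    """Join weight records to panel variants and resolve allele orientation.

    Strand-ambiguous records are removed unconditionally.  For the rest,
    effect allele == panel alt uses the dosage as is; effect allele == panel
    ref (with other allele == panel alt) uses the complementary dosage and is
    counted as a flip; any other allele combination is a mismatch.
    """
    seen: set[str] = set()
    for rec in weights:
        if rec.variant_id in seen:
            raise ValueError(f"duplicate variant id in weights: {rec.variant_id}")
        seen.add(rec.variant_id)

    col = {vid: j for j, vid in enumerate(panel.variant_ids)}
    idx: list[int] = []
    beta: list[float] = []
    flipped: list[bool] = []
    n_ambiguous = n_unmatched = n_mismatch = 0
    for rec in weights:
        if rec.ambiguous:
            n_ambiguous += 1
            continue
        j = col.get(rec.variant_id)
        if j is None:
            n_unmatched += 1
            continue
        ref, alt = panel.ref[j], panel.alt[j]
        if rec.effect_allele == alt and rec.other_allele == ref:
            idx.append(j)
            beta.append(rec.beta)
            flipped.append(False)
        elif rec.effect_allele == ref and rec.other_allele == alt:
            idx.append(j)
            beta.append(rec.beta)
            flipped.append(True)
        else:
            n_mismatch += 1

    matched = MatchedWeights(
        variant_index=np.asarray(idx, dtype=int),
        beta=np.asarray(beta, dtype=float),
        flipped=np.asarray(flipped, dtype=bool),
    )
    report = MatchReport(
        n_input_weights=len(weights),
        n_matched=len(idx),
        n_ambiguous_removed=n_ambiguous,
        n_allele_mismatch=n_mismatch,
        n_unmatched_id=n_unmatched,
        n_flipped=int(sum(flipped)),
    )
    return matched, report


def compute_scores(panel: GenotypePanel, matched: MatchedWeights) -> ScoreVector:
    """Weighted sum of orientation-corrected dosages, plus standardization.

    Missing dosages are imputed with the variant's mean observed dosage
    before weighting, so scores are defined for every sample.
    """
    if len(matched) == 0:
        raise ValueError("no matched weights: cannot compute scores")
    dosages = panel.dosages[:, matched.variant_index].copy()
    dosages[:, matched.flipped] = 2.0 - dosages[:, matched.flipped]
    missing = np.isnan(dosages)
    if missing.any():
        n_obs = (~missing).sum(axis=0)
        if (n_obs == 0).any():
            j = int(np.argmax(n_obs == 0))
            vid = panel.variant_ids[matched.variant_index[j]]
            raise ValueError(f"variant {vid} has no observed genotypes")
        col_mean = np.where(missing, 0.0, dosages).sum(axis=0) / n_obs
        dosages = np.where(missing, col_mean[None, :], dosages)
    raw = dosages @ matched.beta
    std = standardize(raw)
    return ScoreVector(
        sample_ids=list(panel.sample_ids),
        raw=raw,
        std=std,
        n_variants_used=len(matched),
    )


def read_weights(path: str | Path) -> list[GwasWeightRecord]:
    """Parse a tab-delimited weight table (columns ``snp effect_allele
    other_allele beta`` with optional ``se``/``pval``; ``NA`` = missing)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"snp": str, "effect_allele": str, "other_allele": str},
        na_values=["NA"],
        keep_default_na=True,
        float_precision="round_trip",
    )
    required = ("snp", "effect_allele", "other_allele", "beta")
    for name in required:
        if name not in df.columns:
            raise ValueError(f"{path}: missing required column {name!r}")
    records: list[GwasWeightRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        try:
            se = getattr(row, "se", None)
            pval = getattr(row, "pval", None)
            records.append(
                GwasWeightRecord(
                    variant_id=str(row.snp),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    beta=float(row.beta),
                    se=None if se is None or pd.isna(se) else float(se),
                    pval=None if pval is None or pd.isna(pval) else float(pval),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return records


def read_panel(path: str | Path) -> GenotypePanel:
    """Read a biallelic-SNP VCF (GT genotypes) into a GenotypePanel."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}, record {i} ({rec.ID or rec.POS}): not biallelic"
            )
        r, a = rec.REF, rec.ALT[0]
        if r not in VALID_ALLELES or a not in VALID_ALLELES:
            raise ValueError(
                f"{path}, record {i} ({rec.ID or rec.POS}): non-SNP alleles {r}/{a}"
            )
        variant_ids.append(rec.ID if rec.ID else f"var{i}")
        ref.append(r)
        alt.append(a)
        pos.append(rec.POS)
        gt = np.asarray(rec.genotypes, dtype=int)[:, :2]
        dose = np.where((gt < 0).any(axis=1), np.nan, (gt == 1).sum(axis=1))
        rows.append(dose.astype(float))
    dosages = (
        np.column_stack(rows)
        if rows
        else np.empty((len(sample_ids), 0), dtype=float)
    )
    return GenotypePanel(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        ref=np.asarray(ref, dtype="U1"),
        alt=np.asarray(alt, dtype="U1"),
        dosages=dosages,
        pos=np.asarray(pos, dtype=int),
    )
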