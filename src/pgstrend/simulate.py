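"""Synthetic cohort generator: genotype panels, noisy GWAS weights, and
wave-long phenotype tables with known ground-truth penetrance trends.

The generator stands in for restricted survey genotype data.  It draws
biallelic SNP dosages under Hardy-Weinberg (optionally with two
Balding-Nichols subpopulations), true per-variant effects, noisy "published"
weights (a configurable fraction emitted with strand-ambiguous allele pairs
to exercise the matching filter), and per-person latent traits whose
polygenic effect varies linearly with birth year.  Phenotype tables are
wave-long with spousal household clustering and an optional
phenotype-dependent mortality-selection step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .scoring import COMPLEMENT, GenotypePanel, GwasWeightRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_phenotypes",
    "apply_mortality_selection",
    "write_fixture",
    "write_vcf",
    "write_weights",
]

#: observation year used to compute ages for mortality selection
OBSERVATION_YEAR = 2012

#: ordered (ref, alt) pairs that are NOT strand-ambiguous
_NON_AMBIGUOUS_PAIRS = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if a != r and COMPLEMENT[r] != a
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: wave-long phenotype CSV column order
WAVE_COLUMNS = (
    "person_id",
    "household_id",
    "birth_year",
    "wave",
    "educ",
    "bmi",
    "height",
    "heart",
    "cesd",
)


@dataclasses.dataclass
class SimConfig:
    """Knobs for the synthetic cohort.

    ``beta0``/``beta1`` are the baseline polygenic effect and its per-year
    slope (the ground truth for the interaction model); ``gamma`` is a
    secular birth-year main effect.  ``spouse_fraction`` pairs that share of
    samples into 2-person households, with within-couple true-score
    correlation ``spouse_score_corr``.  ``mortality_slope`` drives
    phenotype-dependent exclusion that thins older cohorts selectively.
    """

    n_samples: int = 500
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    weight_scale: float = 0.1
    weight_noise_sd: float = 0.0
    ambiguous_fraction: float = 0.1
    birth_year_range: tuple[int, int] = (1919, 1955)
    alpha: float = 0.0
    beta0: float = 0.5
    beta1: float = 0.0
    gamma: float = 0.0
    noise_sd: float = 1.0
    wave_noise_sd: float = 0.0
    height_base: float = 170.0
    bmi_base: float = 27.0
    household_noise_sd: float = 0.0
    spouse_fraction: float = 0.0
    spouse_score_corr: float = 0.0
    mortality_slope: float = 0.0
    n_waves: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1)")
        if self.n_subpops not in (1, 2):
            raise ValueError("n_subpops must be 1 or 2")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        ylo, yhi = self.birth_year_range
        if not ylo < yhi:
            raise ValueError("birth_year_range min must be < max")
        for name in (
            "weight_scale",
            "weight_noise_sd",
            "noise_sd",
            "wave_noise_sd",
            "household_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.spouse_fraction <= 1.0:
            raise ValueError("spouse_fraction must be in [0, 1]")
        if not 0.0 <= self.spouse_score_corr <= 1.0:
            raise ValueError("spouse_score_corr must be in [0, 1]")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must be in [0, 1]")
        if self.mortality_slope < 0:
            raise ValueError("mortality_slope must be >= 0")
        if self.n_waves <= 0:
            raise ValueError("n_waves must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        kwargs = dict(data)
        for key in ("maf_range", "birth_year_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class GroundTruth:
    """What the simulator knows: true weights/scores and trend parameters."""

    true_weights: np.ndarray
    true_scores: np.ndarray
    beta0: float
    beta1: float
    gamma: float
    subpop: np.ndarray | None = None
    generating_freq: np.ndarray | None = None  # (n_subpops, n_variants)

    def standardized_scores(self) -> np.ndarray:
        sd = self.true_scores.std(ddof=1)
        if sd == 0.0:
            return np.zeros_like(self.true_scores)
        return (self.true_scores - self.true_scores.mean()) / sd


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypePanel, list[GwasWeightRecord], GroundTruth]:
    """Draw a genotype panel, its published weight file, and the truth.

    Allele frequencies are uniform over ``maf_range``; with two
    subpopulations, per-subpopulation frequencies follow a Balding-Nichols
    beta draw around the ancestral frequency with divergence ``fst``.
    Published weights are the true effects plus estimation noise; effect
    allele is the panel alt allele.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.n_variants, config.n_samples

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    subpop = np.arange(n) % config.n_subpops
    if config.n_subpops == 2 and config.fst > 0:
        shape = (1.0 - config.fst) / config.fst
        sub_p = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(2, m))
        sub_p = np.clip(sub_p, 1e-6, 1.0 - 1e-6)
    else:
        sub_p = np.tile(p_anc, (config.n_subpops, 1))
    dosages = rng.binomial(2, sub_p[subpop, :]).astype(float)

    amb = rng.random(m) < config.ambiguous_fraction
    amb_choice = rng.integers(0, len(_AMBIGUOUS_PAIRS), size=m)
    pair_choice = rng.integers(0, len(_NON_AMBIGUOUS_PAIRS), size=m)
    ref = np.empty(m, dtype="U1")
    alt = np.empty(m, dtype="U1")
    for j in range(m):
        r, a = (
            _AMBIGUOUS_PAIRS[amb_choice[j]]
            if amb[j]
            else _NON_AMBIGUOUS_PAIRS[pair_choice[j]]
        )
        ref[j], alt[j] = r, a

    true_w = rng.normal(0.0, config.weight_scale, size=m)
    if config.weight_noise_sd > 0:
        pub_w = true_w + rng.normal(0.0, config.weight_noise_sd, size=m)
    else:
        pub_w = true_w.copy()

    variant_ids = [f"snp{j:06d}" for j in range(m)]
    weights = []
    for j in range(m):
        se = config.weight_noise_sd if config.weight_noise_sd > 0 else None
        pval = None
        if se:
            from scipy.stats import norm

            pval = float(2.0 * norm.sf(abs(pub_w[j]) / se))
        weights.append(
            GwasWeightRecord(
                variant_id=variant_ids[j],
                effect_allele=str(alt[j]),
                other_allele=str(ref[j]),
                beta=float(pub_w[j]),
                se=se,
                pval=pval,
            )
        )

    panel = GenotypePanel(
        sample_ids=[f"P{i:05d}" for i in range(n)],
        variant_ids=variant_ids,
        ref=ref,
        alt=alt,
        dosages=dosages,
        pos=np.arange(1, m + 1),
    )
    truth = GroundTruth(
        true_weights=true_w,
        true_scores=dosages @ true_w,
        beta0=config.beta0,
        beta1=config.beta1,
        gamma=config.gamma,
        subpop=subpop,
        generating_freq=sub_p,
    )
    return panel, weights, truth


def _assign_households(
    z: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Household index per sample; couples matched to induce the configured
    within-couple score correlation (sqrt-rho noisy-rank matching)."""
    n = len(z)
    hh = np.full(n, -1, dtype=int)
    n_paired = int(config.spouse_fraction * n) // 2 * 2
    perm = rng.permutation(n)
    paired = perm[:n_paired]
    if n_paired > 0 and config.spouse_score_corr > 0:
        a = np.sqrt(config.spouse_score_corr)
        v = a * z[paired] + np.sqrt(1.0 - a * a) * rng.standard_normal(n_paired)
        paired = paired[np.argsort(v, kind="stable")]
    next_id = 0
    for k in range(0, n_paired, 2):
        hh[paired[k]] = hh[paired[k + 1]] = next_id
        next_id += 1
    for i in range(n):
        if hh[i] < 0:
            hh[i] = next_id
            next_id += 1
    return hh


def simulate_phenotypes(
    panel: GenotypePanel, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Wave-long phenotype table driven by the latent trait
    ``y = alpha + gamma*c + (beta0 + beta1*c) * S_std + eps``.

    ``height`` and ``bmi`` carry the latent trait plus a baseline offset and
    wave noise, ``heart`` is a liability-threshold binary
    with ~40% lifetime prevalence by construction, and ``cesd`` is a
    right-skewed transform of the latent.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = panel.n_samples
    ylo, yhi = config.birth_year_range
    birth_year = rng.integers(ylo, yhi + 1, size=n)
    c = birth_year - (ylo + yhi) / 2.0

    z = truth.standardized_scores()
    hh = _assign_households(z, config, rng)
    hh_noise = (
        rng.normal(0.0, config.household_noise_sd, size=hh.max() + 1)[hh]
        if config.household_noise_sd > 0
        else np.zeros(n)
    )
    eps = (
        rng.normal(0.0, config.noise_sd, size=n)
        if config.noise_sd > 0
        else np.zeros(n)
    )
    y = config.alpha + config.gamma * c + (config.beta0 + config.beta1 * c) * z
    y = y + hh_noise + eps

    # liability threshold at the empirical 60% quantile: ~40% ever-affected
    threshold = np.quantile(y, 0.6)
    affected = y > threshold
    onset = rng.integers(1, config.n_waves + 1, size=n)
    educ = np.maximum(13.0 + y, 0.0)

    frames = []
    for wave in range(1, config.n_waves + 1):
        if config.wave_noise_sd > 0:
            height = config.height_base + y + rng.normal(
                0.0, config.wave_noise_sd, size=n
            )
            bmi = config.bmi_base + y + rng.normal(
                0.0, config.wave_noise_sd, size=n
            )
            cesd_lat = 0.5 * y + rng.normal(0.0, config.wave_noise_sd, size=n)
        else:
            height = config.height_base + y
            bmi = config.bmi_base + y
            cesd_lat = 0.5 * y
        frames.append(
            pd.DataFrame(
                {
                    "person_id": panel.sample_ids,
                    "household_id": [f"H{h:05d}" for h in hh],
                    "birth_year": birth_year,
                    "wave": wave,
                    "educ": educ,
                    "bmi": bmi,
                    "height": height,
                    "heart": (affected & (onset <= wave)).astype(int),
                    "cesd": np.maximum(np.exp(cesd_lat) - 1.0, 0.0),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["person_id", "wave"], kind="stable").reset_index(
        drop=True
    )


def apply_mortality_selection(
    table: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Thin the cohort with phenotype-dependent retention.

    Each person is kept with probability
    ``expit(-mortality_slope * (bmi_mean - cohort mean) * age_decades)``
    where age is relative to the fixed observation year, so selection
    against high-phenotype individuals strengthens in older cohorts.
    """
    if config.mortality_slope == 0:
        return table.copy()
    rng = np.random.default_rng(
        [config.seed, 13] if seed is None else seed
    )
    persons = table.groupby("person_id", sort=False).agg(
        pheno=("bmi", "mean"), birth_year=("birth_year", "first")
    )
    decades = (OBSERVATION_YEAR - persons["birth_year"].to_numpy()) / 10.0
    centered = persons["pheno"].to_numpy() - persons["pheno"].to_numpy().mean()
    p_keep = expit(-config.mortality_slope * centered * decades)
    kept = persons.index[rng.random(len(persons)) < p_keep]
    out = table[table["person_id"].isin(set(kept))]
    return out.reset_index(drop=True)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF v4.2 with GT genotypes."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        pos = (
            panel.pos
            if panel.pos is not None
            else np.arange(1, panel.n_variants + 1)
        )
        for j in range(panel.n_variants):
            calls = "\t".join(
                "./." if np.isnan(d) else gt_map[d] for d in panel.dosages[:, j]
            )
            fh.write(
                f"1\t{int(pos[j])}\t{panel.variant_ids[j]}\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


def write_weights(weights: list[GwasWeightRecord], path: str | Path) -> None:
    """Write weight records as the tab-delimited dialect read_weights expects."""
    df = pd.DataFrame(
        {
            "snp": [w.variant_id for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "other_allele": [w.other_allele for w in weights],
            "beta": [repr(w.beta) for w in weights],
            "se": [("NA" if w.se is None else repr(w.se)) for w in weights],
            "pval": [("NA" if w.pval is None else repr(w.pval)) for w in weights],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_fixture(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Simulate a full fixture and write it as plain-text files.

    Emits ``genotypes.vcf``, ``weights.tsv``, ``phenotypes.csv`` (wave-long,
    after any mortality selection) and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, weights, truth = simulate_panel(config)
    table = simulate_phenotypes(panel, truth, config)
    if config.mortality_slope > 0:
        table = apply_mortality_selection(table, config)
    paths = {
        "vcf": out / "genotypes.vcf",
        "weights": out / "weights.tsv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "ground_truth.json",
    }
    write_vcf(panel, paths["vcf"])
    write_weights(weights, paths["weights"])
    table.to_csv(paths["phenotypes"], index=False, columns=list(WAVE_COLUMNS))
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "alpha": config.alpha,
                "beta0": truth.beta0,
                "beta1": truth.beta1,
                "gamma": truth.gamma,
                "seed": config.seed,
                "n_samples": config.n_samples,
                "n_variants": config.n_variants,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
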