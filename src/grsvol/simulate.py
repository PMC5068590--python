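"""Synthetic cross-disorder data with known genetic architecture.

Generates the three inputs the pipeline consumes, with ground truth held
fixed by seed:

* LD-blocked genotype dosages (AR(1) latent-Gaussian haplotypes thresholded
  at per-variant allele-frequency quantiles);
* four coupled summary-statistics sets — combined cases of disorders A and B
  versus controls, A-versus-B case-only, and each disorder versus controls —
  built from shared plus disorder-specific causal effects with
  frequency-dependent estimation noise;
* ROI volumes carrying a designed incremental-R2 genetic signal on top of
  sex/ICV(/age) covariate effects.

Per-variant true standardized effects: b_A = b_shared + b_Aspec and
b_B = b_shared + b_Bspec over disjoint causal sets.  The combined set's true
effect is (b_A + b_B)/2 and the case-only contrast's is (b_A - b_B)/2.
Training estimates add Normal(0, se^2) noise with
se = 1/sqrt(2 * n_train_eff * f(1-f)); P-values come from the Wald statistic
and the OR column is exp(b_hat).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .io import GenotypeMatrix, PhenotypeTable, SummaryStats, SS_FIELDS

__all__ = [
    "ArchitectureSpec",
    "PhenoSpec",
    "TRAINING_SETS",
    "sim_variants",
    "true_effects",
    "sim_genotypes",
    "sim_sumstats",
    "sim_phenotypes",
    "sim_covariates",
    "genetic_values",
]

#: the four coupled training sets, in report order
TRAINING_SETS = ("SCZ&BD", "SCZvsBD", "SCZ", "BD")

_BP_SPACING = 5000  # base pairs between adjacent simulated variants

# seeded substream tags so adding one generator never perturbs another
_STREAM_VARIANTS = 11
_STREAM_EFFECTS = 23
_STREAM_GENOTYPES = 37
_STREAM_SUMSTATS = 53
_STREAM_PHENO = 71
_STREAM_COVARS = 89

# unambiguous (non A/T, non C/G) allele pairs for simulated variants
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Variant panel, LD structure and causal architecture of the simulation."""

    m: int = 5000
    block_size: int = 50
    rho: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_shared: int = 30
    n_causal_a: int = 30
    n_causal_b: int = 30
    effect_sd: float = 0.1
    n_train_eff: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.block_size < 1:
            raise ValidationError("m and block_size must be positive")
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0.01, 0.5]")
        if self.n_causal_shared + self.n_causal_a + self.n_causal_b > self.m:
            raise ValidationError("causal counts exceed variant count")
        if self.effect_sd < 0 or self.n_train_eff <= 0:
            raise ValidationError("effect_sd must be >= 0 and n_train_eff > 0")


@dataclass(frozen=True)
class PhenoSpec:
    """One simulated ROI volume with a designed genetic increment.

    ``coupling`` selects which causal component drives the volume: "shared",
    "a-specific", "b-specific" or "null".  ``target_delta_r2`` is the designed
    increment in variance explained when the genetic value is added after the
    covariates (i.e. on the full-variance scale the regression reports);
    ``negative`` flips the coupling sign (default on — risk associates with
    smaller volume).  Demographics default to the target
    cohort: 71.4% female, age Normal(24.77, 6.86^2).
    """

    roi: str = "globus_pallidus"
    coupling: str = "shared"
    target_delta_r2: float = 0.02
    negative: bool = True
    intercept: float = 1700.0
    beta_sex: float = -120.0
    beta_icv: float = 6e-4
    beta_age: float = 0.0
    noise_sd: float = 150.0
    female_fraction: float = 0.714
    age_mean: float = 24.77
    age_sd: float = 6.86
    icv_mean: float = 1.5e6
    icv_sd: float = 1.3e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling not in ("shared", "a-specific", "b-specific", "null"):
            raise ValidationError(f"unknown coupling {self.coupling!r}")
        if not 0 <= self.target_delta_r2 < 1:
            raise ValidationError("target_delta_r2 must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *map(int, extra)]))


def sim_variants(arch: ArchitectureSpec) -> pd.DataFrame:
    """Deterministic variant panel: ids, positions, alleles and target MAFs."""
    rng = _rng(arch.seed, _STREAM_VARIANTS)
    lo, hi = arch.maf_range
    maf = rng.uniform(lo, hi, size=arch.m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=arch.m)
    alleles = np.array(_ALLELE_PAIRS)[pair_idx]
    return pd.DataFrame(
        {
            "variant_id": [f"snp{j:06d}" for j in range(arch.m)],
            "chrom": "1",
            "pos": 1 + np.arange(arch.m) * _BP_SPACING,
            "allele_a": alleles[:, 0],
            "allele_b": alleles[:, 1],
            "maf": maf,
        }
    )


@dataclass(frozen=True)
class EffectSet:
    """True standardized per-variant effects and causal index sets."""

    b_shared: np.ndarray
    b_a_spec: np.ndarray
    b_b_spec: np.ndarray
    idx_shared: np.ndarray
    idx_a: np.ndarray
    idx_b: np.ndarray

    @property
    def b_a(self) -> np.ndarray:
        return self.b_shared + self.b_a_spec

    @property
    def b_b(self) -> np.ndarray:
        return self.b_shared + self.b_b_spec

    def true_effect(self, training_set: str) -> np.ndarray:
        if training_set == "SCZ&BD":
            return (self.b_a + self.b_b) / 2.0
        if training_set == "SCZvsBD":
            return (self.b_a - self.b_b) / 2.0
        if training_set == "SCZ":
            return self.b_a
        if training_set == "BD":
            return self.b_b
        raise ValueError(f"unknown training set {training_set!r}")


def true_effects(arch: ArchitectureSpec) -> EffectSet:
    """Draw disjoint shared/A-specific/B-specific causal sets and effects."""
    rng = _rng(arch.seed, _STREAM_EFFECTS)
    perm = rng.permutation(arch.m)
    ks, ka, kb = arch.n_causal_shared, arch.n_causal_a, arch.n_causal_b
    idx_shared = np.sort(perm[:ks])
    idx_a = np.sort(perm[ks:ks + ka])
    idx_b = np.sort(perm[ks + ka:ks + ka + kb])
    b_shared = np.zeros(arch.m)
    b_a_spec = np.zeros(arch.m)
    b_b_spec = np.zeros(arch.m)
    b_shared[idx_shared] = rng.normal(0.0, arch.effect_sd, size=ks)
    b_a_spec[idx_a] = rng.normal(0.0, arch.effect_sd, size=ka)
    b_b_spec[idx_b] = rng.normal(0.0, arch.effect_sd, size=kb)
    return EffectSet(b_shared, b_a_spec, b_b_spec, idx_shared, idx_a, idx_b)


def sim_genotypes(n: int, arch: ArchitectureSpec, seed: int | None = None) -> GenotypeMatrix:
    """LD-blocked dosages for n samples.

    Each haplotype is a latent AR(1) Gaussian with parameter rho inside
    blocks of ``block_size`` adjacent variants (independent across blocks),
    thresholded at the (1 - maf) quantile; the dosage is the sum of two
    independent haplotypes.
    """
    if n < 2:
        raise ValidationError("need n >= 2 samples")
    variants = sim_variants(arch)
    rng = _rng(arch.seed if seed is None else seed, _STREAM_GENOTYPES, n)
    m, bs, rho = arch.m, arch.block_size, arch.rho
    z = rng.standard_normal((2 * n, m))
    if rho > 0:
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if j % bs:  # same block as j-1
                z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    thresh = norm.ppf(1.0 - variants["maf"].to_numpy())
    hap = (z > thresh).astype(float)
    dosages = hap[0::2] + hap[1::2]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants.drop(columns="maf"), dosages)


def sim_sumstats(
    arch: ArchitectureSpec,
    gm_train: GenotypeMatrix | None = None,
) -> dict[str, SummaryStats]:
    """Four coupled summary-statistics sets keyed by training-set name.

    Estimation noise uses per-variant standard errors from the target allele
    frequency (the designed MAF, or empirical frequencies of ``gm_train``
    when given).  Effect alleles are oriented to allele_b, so the output is
    already harmonized to matrices drawn from the same architecture.
    """
    variants = sim_variants(arch)
    effects = true_effects(arch)
    if gm_train is not None:
        from .io import allele_frequencies

        f = allele_frequencies(gm_train)
        if len(f) != arch.m:
            raise ValidationError("gm_train does not match the architecture's panel")
    else:
        f = variants["maf"].to_numpy()
    het = 2.0 * f * (1.0 - f)
    ok = het > 0
    if not ok.all():
        import warnings

        warnings.warn(f"skipping {int((~ok).sum())} degenerate-frequency variants")
    se = np.full(arch.m, np.nan)
    se[ok] = 1.0 / np.sqrt(2.0 * arch.n_train_eff * het[ok])

    out: dict[str, SummaryStats] = {}
    for si, ts in enumerate(TRAINING_SETS):
        rng = _rng(arch.seed, _STREAM_SUMSTATS, si)
        b_true = effects.true_effect(ts)
        b_hat = b_true + se * rng.standard_normal(arch.m)
        with np.errstate(invalid="ignore"):
            pvals = 2.0 * norm.sf(np.abs(b_hat / se))
        pvals = np.clip(pvals, 1e-300, 1.0)
        tab = pd.DataFrame(
            {
                "variant_id": variants["variant_id"],
                "chrom": variants["chrom"],
                "pos": variants["pos"],
                "effect_allele": variants["allele_b"],
                "other_allele": variants["allele_a"],
                "weight": b_hat,
                "pvalue": pvals,
            }
        )[SS_FIELDS]
        tab = tab.loc[ok].reset_index(drop=True)
        out[ts] = SummaryStats(tab)
    return out


def sim_covariates(n: int, pheno: PhenoSpec, seed: int | None = None) -> pd.DataFrame:
    """Sex (1=female), age and ICV draws shared by every ROI of a cohort."""
    rng = _rng(pheno.seed if seed is None else seed, _STREAM_COVARS, n)
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, pheno.female_fraction, size=n).astype(float),
            "age": rng.normal(pheno.age_mean, pheno.age_sd, size=n),
            "icv": rng.normal(pheno.icv_mean, pheno.icv_sd, size=n),
        }
    )


def genetic_values(gm: GenotypeMatrix, arch: ArchitectureSpec, coupling: str) -> np.ndarray:
    """True causal score G_i = sum_j b_j * dosage_ij over the coupled causal set."""
    effects = true_effects(arch)
    if coupling == "null":
        return np.zeros(gm.n_samples)
    if coupling == "shared":
        idx, b = effects.idx_shared, effects.b_shared
    elif coupling == "a-specific":
        idx, b = effects.idx_a, effects.b_a_spec
    elif coupling == "b-specific":
        idx, b = effects.idx_b, effects.b_b_spec
    else:
        raise ValueError(f"unknown coupling {coupling!r}")
    return gm.dosages[:, idx] @ b[idx]


def sim_phenotypes(
    gm: GenotypeMatrix,
    arch: ArchitectureSpec,
    pheno: PhenoSpec | Mapping[str, PhenoSpec],
    covariates: pd.DataFrame | None = None,
) -> PhenotypeTable:
    """ROI volumes with covariate effects and a designed genetic increment.

    The genetic value is scaled so that its share of the total volume
    variance equals ``target_delta_r2``.  Passing
    a mapping of ROI name -> PhenoSpec produces one cohort with shared
    covariates (drawn from the first spec unless ``covariates`` is supplied).
    """
    specs: dict[str, PhenoSpec]
    if isinstance(pheno, PhenoSpec):
        specs = {pheno.roi: pheno}
    else:
        specs = {roi: (sp if sp.roi == roi else replace(sp, roi=roi)) for roi, sp in pheno.items()}
    first = next(iter(specs.values()))
    n = gm.n_samples
    if covariates is None:
        covariates = sim_covariates(n, first)
    table = covariates.copy()
    table.index = pd.Index(gm.sample_ids, name="sample_id")

    for roi, sp in specs.items():
        rng = _rng(sp.seed, _STREAM_PHENO, zlib.crc32(roi.encode()))
        g = genetic_values(gm, arch, sp.coupling)
        base = (
            sp.beta_sex * table["sex"].to_numpy()
            + sp.beta_icv * table["icv"].to_numpy()
            + sp.beta_age * table["age"].to_numpy()
            + rng.normal(0.0, sp.noise_sd, size=n)
        )
        g_sd = g.std()
        if sp.target_delta_r2 > 0 and g_sd > 0:
            # delta-R2 is measured against total volume variance, so scale the
            # genetic value against everything else (covariates + noise):
            # Var(cG) / (Var(cG) + Var(base)) = target
            c = np.sqrt(sp.target_delta_r2 / (1.0 - sp.target_delta_r2)) * base.std() / g_sd
        else:
            c = 0.0
        sign = -1.0 if sp.negative else 1.0
        table[roi] = sp.intercept + base + sign * c * (g - g.mean())
    return PhenotypeTable(table, list(specs))
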