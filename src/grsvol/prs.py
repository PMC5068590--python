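"""Per-sample genetic risk scores at a ladder of P-value thresholds.

A variant contributes to the score at threshold t when its training P-value is
strictly below t; its contribution is weight (log OR) times the dosage of the
effect allele, with missing dosages mean-imputed from the target cohort at
scoring time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GenotypeMatrix, SummaryStats, allele_frequencies

__all__ = ["ThresholdSet", "ScoreProfile", "score", "standardize_scores", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = (1e-5, 1e-4, 0.01, 0.1, 0.3, 0.5)


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing P-value ceilings in (0, 1]."""

    values: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        v = self.values
        if not v:
            raise ValidationError("empty threshold set")
        if any(not 0 < t <= 1 for t in v):
            raise ValidationError("thresholds must be in (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValidationError("thresholds must be strictly increasing")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ScoreProfile:
    """Per-sample scores, one column per threshold.

    ``scores`` is a DataFrame indexed by sample_id with one float column per
    threshold (column labels are the thresholds); ``n_variants[t]`` counts the
    variants contributing at threshold t.
    """

    scores: pd.DataFrame
    n_variants: dict[float, int]

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise ValidationError("non-finite score")
        counts = [self.n_variants[t] for t in self.scores.columns]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValidationError("n_variants must be non-decreasing in threshold")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def thresholds(self) -> list[float]:
        return list(self.scores.columns)


def score(
    gm: GenotypeMatrix,
    ss: SummaryStats,
    thresholds: ThresholdSet | None = None,
    mode: str = "sum",
) -> ScoreProfile:
    """Score every sample at every threshold.

    ``ss`` must already be harmonized to ``gm`` (weights oriented to allele_b)
    and restricted to clump index variants; every variant must be present in
    ``gm``.  mode="sum" (default) accumulates weight x dosage; mode="average"
    divides each sample's sum by its number of non-missing contributing
    variants.
    """
    thresholds = thresholds or ThresholdSet()
    if mode not in ("sum", "average"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    col_of = gm.column_index()
    t = ss.table
    absent = ~t["variant_id"].isin(col_of.index)
    if absent.any():
        raise ValidationError(
            f"score variants absent from genotypes: {t.loc[absent, 'variant_id'].tolist()[:5]}"
        )
    cols = col_of[t["variant_id"]].to_numpy()
    w = t["weight"].to_numpy(float)
    p = t["pvalue"].to_numpy(float)

    D = gm.dosages[:, cols]
    miss = np.isnan(D)
    freq = allele_frequencies(gm)[cols]
    D_imp = np.where(miss, 2.0 * freq, D)
    if np.isnan(D_imp).any():
        raise ValidationError("variant with no non-missing dosages cannot be imputed")

    out = {}
    n_variants = {}
    for thr in thresholds:
        sel = p < thr
        k = int(sel.sum())
        n_variants[thr] = k
        if k == 0:
            warnings.warn(f"no variants pass threshold {thr}; score set to 0")
            out[thr] = np.zeros(gm.n_samples)
            continue
        s = D_imp[:, sel] @ w[sel]
        if mode == "average":
            denom = (~miss[:, sel]).sum(axis=1).astype(float)
            denom[denom == 0] = k  # all-missing sample: fall back to variant count
            s = s / denom
        out[thr] = s
    frame = pd.DataFrame(out, index=pd.Index(gm.sample_ids, name="sample_id"))
    return ScoreProfile(frame, n_variants)


def standardize_scores(sp: ScoreProfile) -> ScoreProfile:
    """Z-score each threshold's column across samples (ddof=1)."""
    if len(sp.scores) < 2:
        raise ValidationError("standardization requires at least 2 samples")
    z = sp.scores.copy()
    for thr in z.columns:
        v = z[thr].to_numpy(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"zero score variance at threshold {thr}")
        z[thr] = (v - v.mean()) / sd
    return ScoreProfile(z, dict(sp.n_variants))
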