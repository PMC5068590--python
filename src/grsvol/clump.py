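"""Greedy P-value-ordered LD clumping against target-cohort genotypes.

Variants are visited in ascending P order; each not-yet-removed variant
becomes an index, and every other unassigned variant on the same chromosome
within the base-pair window whose dosage r-squared with the index exceeds the
threshold is removed and recorded against that index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedLDError, ValidationError
from .io import GenotypeMatrix, SummaryStats

__all__ = ["ClumpParams", "ClumpResult", "pairwise_r2", "clump"]


@dataclass(frozen=True)
class ClumpParams:
    """r2_threshold and window follow the PLINK --clump convention.

    The window is two-sided: variants within +/- window_kb of the index are
    candidates for removal.  ``p1`` caps the P-value of variants entering the
    clumping pass at all.
    """

    r2_threshold: float = 0.25
    window_kb: float = 500.0
    p1: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValidationError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValidationError("window_kb must be positive")
        if not 0 < self.p1 <= 1:
            raise ValidationError("p1 must be in (0, 1]")


@dataclass
class ClumpResult:
    index_variants: list[str]
    clumped_by: dict[str, str] = field(default_factory=dict)
    index_pvalues: dict[str, float] = field(default_factory=dict)

    def report_frame(self) -> pd.DataFrame:
        """One row per index: variant, P, comma-joined clump members."""
        members: dict[str, list[str]] = {v: [] for v in self.index_variants}
        for removed, index in self.clumped_by.items():
            members[index].append(removed)
        return pd.DataFrame(
            {
                "index_variant": self.index_variants,
                "p": [self.index_pvalues[v] for v in self.index_variants],
                "n_members": [len(members[v]) for v in self.index_variants],
                "members": [",".join(sorted(members[v])) or "." for v in self.index_variants],
            }
        )


def pairwise_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples."""
    x, y = gm.dosages[:, i], gm.dosages[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise UndefinedLDError(f"fewer than 2 overlapping samples for variants {i}, {j}")
    x, y = x[ok], y[ok]
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = xc @ xc, yc @ yc
    if vx == 0 or vy == 0:
        raise UndefinedLDError(f"zero dosage variance for variant pair {i}, {j}")
    r = (xc @ yc) / np.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def clump(ss: SummaryStats, gm: GenotypeMatrix, params: ClumpParams | None = None) -> ClumpResult:
    """Greedy LD clumping of ``ss`` (harmonized to ``gm``) in the target cohort.

    Ties in P are broken by (chrom, pos) so the result is a deterministic
    function of the data, independent of input row order.  Variants with
    undefined LD against an index (zero variance) are treated as r2 = 0 with
    a warning.
    """
    params = params or ClumpParams()
    t = ss.table
    if t.empty:
        return ClumpResult([], {}, {})
    if t["pos"].isna().any():
        raise ValidationError("clumping requires positions for every variant")
    t = t[t["pvalue"] <= params.p1]
    col_of = gm.column_index()
    missing = ~t["variant_id"].isin(col_of.index)
    if missing.any():
        raise ValidationError(
            f"variants absent from genotypes: {t.loc[missing, 'variant_id'].tolist()[:5]}"
        )
    order = t.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    window_bp = params.window_kb * 1000.0
    D = gm.dosages
    no_missing = not np.isnan(D).any()
    if no_missing:
        # standardized dosage cache for fast vectorized r2 against each index
        mu = D.mean(axis=0)
        sd = D.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (D - mu) / sd
        Z = np.where(np.isfinite(Z), Z, 0.0)  # zero-variance columns -> r2 0
        zero_var = sd == 0
        n = D.shape[0]

    vids = order["variant_id"].to_numpy()
    chroms = order["chrom"].to_numpy()
    poss = order["pos"].to_numpy(float)
    pvals = order["pvalue"].to_numpy(float)
    cols = col_of[vids].to_numpy()
    m = len(order)

    # for moderate panels, one Gram product beats per-index slicing
    use_gram = no_missing and m <= 3000 and D.shape[0] * m * m <= 6e9
    if use_gram:
        Zs = Z[:, cols]
        R2 = (Zs.T @ Zs / n) ** 2

    assigned = np.zeros(m, dtype=bool)  # removed as a clump member
    is_index = np.zeros(m, dtype=bool)
    index_variants: list[str] = []
    clumped_by: dict[str, str] = {}
    index_pvalues: dict[str, float] = {}

    for k in range(m):
        if assigned[k]:
            continue
        is_index[k] = True
        index_variants.append(vids[k])
        index_pvalues[vids[k]] = float(pvals[k])
        cand = (
            ~assigned
            & ~is_index
            & (chroms == chroms[k])
            & (np.abs(poss - poss[k]) <= window_bp)
        )
        cand_idx = np.nonzero(cand)[0]
        if cand_idx.size == 0:
            continue
        if use_gram:
            # zero-variance columns were zeroed in Z, giving r2 = 0
            hit = cand_idx[R2[k, cand_idx] > params.r2_threshold]
        elif no_missing:
            ck = cols[k]
            if zero_var[ck]:
                warnings.warn(f"zero variance for index {vids[k]}; treating r2 as 0")
                continue
            r = (Z[:, cols[cand_idx]].T @ Z[:, ck]) / n
            r2 = r * r
            cz = zero_var[cols[cand_idx]]
            if cz.any():
                warnings.warn("zero-variance variants encountered; treating r2 as 0")
            hit = cand_idx[(r2 > params.r2_threshold) & ~cz]
        else:
            hit = []
            for j in cand_idx:
                try:
                    r2 = pairwise_r2(gm, int(cols[k]), int(cols[j]))
                except UndefinedLDError:
                    warnings.warn(
                        f"undefined LD between {vids[k]} and {vids[j]}; treating r2 as 0"
                    )
                    continue
                if r2 > params.r2_threshold:
                    hit.append(j)
            hit = np.asarray(hit, dtype=int)
        assigned[hit] = True
        for j in hit:
            clumped_by[vids[j]] = vids[k]

    return ClumpResult(index_variants, clumped_by, index_pvalues)
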