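"""Efficiency-corrected relative expression (ΔΔCt) and desk-scale statistics.

Relative expression of a target gene, normalised to a reference transcript
(rp49 in the mosquito experiments) and expressed against a calibrator
condition, uses the efficiency-corrected (Pfaffl) form of the comparative
ΔΔCt method:

    ratio = E_target^(−ΔCt_target) / E_ref^(−ΔCt_ref)

with ΔCt = mean Ct(condition) − mean Ct(calibrator) per gene and E the
amplification efficiency in fold-per-cycle (E = 2 is perfect doubling, and
the ratio then reduces to the classical 2^(−ΔΔCt)).  Standard errors are
propagated from the replicate ΔCt spread by the delta method.  Replicates
are aggregated by the arithmetic mean of Ct (the geometric-mean equivalent
on the expression scale); no outlier handling is applied.

Egg-laying assays are normalised to eggs per female per cage, and group
comparisons use one-way ANOVA or the pooled-variance Student t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct", "efficiency"]


@dataclass(frozen=True)
class ExpressionRatio:
    gene: str
    condition: str
    calibrator: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if self.ratio <= 0 or self.se < 0 or not np.isfinite(self.ratio):
            raise ContractError("ratio must be positive and finite, se nonnegative")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _validate_ct(df: pd.DataFrame) -> None:
    if not np.all(np.isfinite(df["ct"])) or (df["ct"] <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    bad = df[(df["efficiency"] < 1.0) | (df["efficiency"] > 2.0)]
    if len(bad):
        raise ValidationError(
            f"amplification efficiency outside [1, 2] for {sorted(bad.gene.unique())}"
        )


def _gene_stats(df: pd.DataFrame, gene: str, condition: str):
    sub = df[(df.gene == gene) & (df.condition == condition)]
    if sub.empty:
        raise ContractError(f"no Ct measurements for {gene} in {condition!r}")
    cts = sub.ct.to_numpy(float)
    sem2 = cts.var(ddof=1) / len(cts) if len(cts) > 1 else 0.0
    eff = sub.efficiency.to_numpy(float)
    if not np.allclose(eff, eff[0]):
        raise ValidationError(f"inconsistent efficiencies for {gene}")
    return float(cts.mean()), float(sem2), float(eff[0])


def relative_expression(ct: pd.DataFrame, target_gene: str, condition: str,
                        calibrator: str, reference_gene: str = "rp49",
                        mode: str = "pfaffl") -> ExpressionRatio:
    """Efficiency-corrected relative expression of one gene in one condition.

    ``mode="pfaffl"`` uses each gene's own efficiency; ``mode="classic"``
    fixes both at 2 (the plain comparative 2^(−ΔΔCt) form).
    """
    if mode not in ("pfaffl", "classic"):
        raise ContractError(f"unknown mode {mode!r}")
    _validate_ct(ct)
    if calibrator not in set(ct.condition):
        raise ContractError(f"calibrator condition {calibrator!r} not in table")

    mt_c, vt_c, et = _gene_stats(ct, target_gene, condition)
    mt_0, vt_0, _ = _gene_stats(ct, target_gene, calibrator)
    mr_c, vr_c, er = _gene_stats(ct, reference_gene, condition)
    mr_0, vr_0, _ = _gene_stats(ct, reference_gene, calibrator)
    if mode == "classic":
        et = er = 2.0

    dct_t = mt_c - mt_0
    dct_r = mr_c - mr_0
    ratio = et ** (-dct_t) / er ** (-dct_r)
    # delta method on log ratio: Var(ln R) = (ln Et)^2 Var(dCt_t) + (ln Er)^2 Var(dCt_r)
    var_ln = np.log(et) ** 2 * (vt_c + vt_0) + np.log(er) ** 2 * (vr_c + vr_0)
    se = float(ratio * np.sqrt(var_ln))
    return ExpressionRatio(gene=target_gene, condition=condition,
                           calibrator=calibrator, ratio=float(ratio), se=se)


def expression_table(ct: pd.DataFrame, calibrator: str,
                     reference_gene: str = "rp49",
                     mode: str = "pfaffl") -> pd.DataFrame:
    """Ratios for every (target gene, condition) pair in a Ct table."""
    genes = [g for g in ct.gene.unique() if g != reference_gene]
    conditions = list(ct.condition.unique())
    rows = []
    for g in genes:
        for c in conditions:
            r = relative_expression(ct, g, c, calibrator,
                                    reference_gene=reference_gene, mode=mode)
            rows.append({"gene": g, "condition": c, "calibrator": calibrator,
                         "ratio": r.ratio, "se": r.se})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# egg counts

def normalize_egg_counts(eggs: float, females: int) -> float:
    """Eggs laid per female in one cage."""
    if females < 1:
        raise ContractError("a cage must contain at least one female")
    if eggs < 0:
        raise ValidationError("egg count cannot be negative")
    return eggs / females


def eggs_per_female_table(cages: pd.DataFrame) -> pd.DataFrame:
    out = cages.copy()
    out["eggs_per_female"] = [
        normalize_egg_counts(e, f) for e, f in zip(cages.eggs, cages.females)
    ]
    return out


# --------------------------------------------------------------------------
# significance tests

def _check_groups(groups, min_n=2):
    if len(groups) < 2:
        raise ContractError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if len(g) < min_n:
            raise ContractError(f"each group needs n >= {min_n}")
    return arrs


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical between/within mean-square F with (k−1, N−k) df."""
    arrs = _check_groups(groups)
    grand = np.concatenate(arrs)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance Student t, two-sided p."""
    a, b = _check_groups([a, b])
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
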