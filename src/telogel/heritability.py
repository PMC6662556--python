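"""Mid-parent/offspring heritability of telomere length.

Under the infinitesimal model, the slope of offspring phenotype on the
mid-parent value (the mean of the two parents' trait values) estimates
narrow-sense heritability h2.  The cross-fostering design decouples genetic
and rearing environments, so the chick-level model controls for the brood
manipulation as a fixed effect and absorbs shared-environment and paternity
structure with random intercepts for natal box, rearing box and genetic
father:

    chick_tl ~ midparent_tl + treatment + (1|natal) + (1|rearing) + (1|father)

fitted by REML; h2 is the mid-parent slope, tested with an F statistic whose
denominator degrees of freedom use the Satterthwaite approximation.  A
brood-level variant averages chick scores within each genetic pair and
regresses the brood mean on the mid-parent value by ordinary least squares.

Only chicks with both genetic parents known and a telomere score (i.e. alive
at day 12) enter either model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import LMMFit, fit_lmm

logger = logging.getLogger(__name__)

RANDOM_FACTORS = ["natal_box", "rearing_box", "genetic_father_id"]


@dataclass
class HeritabilityFit:
    """A mid-parent regression fit; ``h2`` is the mid-parent slope."""

    h2: float
    se: float
    f_stat: float
    df_denominator: float
    p_value: float
    n: int
    level: str
    random_variances: dict[str, float] = field(default_factory=dict)
    conf_int: tuple[float, float] = (np.nan, np.nan)
    lmm: LMMFit | None = field(repr=False, default=None)

    def summary(self) -> str:
        lo, hi = self.conf_int
        lines = [
            f"Mid-parent/offspring heritability ({self.level} level)",
            f"  h2 (slope) = {self.h2:.3f} +/- {self.se:.3f}  95% CI [{lo:.3f}, {hi:.3f}]",
            f"  F({1}, {self.df_denominator:.2f}) = {self.f_stat:.2f}, p = {self.p_value:.2g}",
            f"  n = {self.n}",
        ]
        if self.random_variances:
            vs = ", ".join(f"{k}={v:.4f}" for k, v in self.random_variances.items())
            lines.append(f"  random-intercept variances: {vs}")
        return "\n".join(lines)


def _heritability_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Complete-case subset for the mid-parent models."""
    needed = [
        "tl_score",
        "maternal_tl",
        "paternal_tl",
        "genetic_mother_id",
        "genetic_father_id",
    ]
    df = records.dropna(subset=[c for c in needed if c in records.columns]).copy()
    if "survived_day12" in df.columns:
        df = df[df["survived_day12"].astype(bool)]
    df["midparent_tl"] = 0.5 * (df["maternal_tl"] + df["paternal_tl"])
    return df


def midparent_heritability(
    records: pd.DataFrame, include_treatment: bool = True
) -> HeritabilityFit:
    """Chick-level heritability by mixed-effects mid-parent regression."""
    df = _heritability_frame(records)
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete chick records, got {len(df)}")
    if float(df["midparent_tl"].std()) == 0.0:
        raise ValueError("no variance in mid-parent telomere score")
    X = pd.DataFrame({"Intercept": 1.0, "midparent_tl": df["midparent_tl"]})
    if include_treatment and df["treatment"].nunique() > 1:
        X["treatment_enlarged"] = (df["treatment"] == "enlarged").astype(float)
    fit = fit_lmm(
        df["tl_score"], X, data=df, random_factors=RANDOM_FACTORS, method="REML"
    )
    f, df2, p = fit.f_test("midparent_tl")
    return HeritabilityFit(
        h2=float(fit.params["midparent_tl"]),
        se=float(fit.bse["midparent_tl"]),
        f_stat=f,
        df_denominator=df2,
        p_value=p,
        n=fit.n,
        level="chick",
        random_variances={**fit.vcomp, "residual": fit.scale},
        conf_int=fit.conf_int("midparent_tl"),
        lmm=fit,
    )


def brood_level_heritability(records: pd.DataFrame) -> HeritabilityFit:
    """Brood-level variant: mean chick score per genetic pair on mid-parent value."""
    df = _heritability_frame(records)
    grouped = (
        df.groupby(["genetic_mother_id", "genetic_father_id"], sort=True)
        .agg(brood_tl=("tl_score", "mean"), midparent_tl=("midparent_tl", "first"),
             n_chicks=("tl_score", "size"))
        .reset_index()
    )
    empty = int((grouped["n_chicks"] == 0).sum())
    if empty:
        logger.info("dropped %d broods with no scored offspring", empty)
        grouped = grouped[grouped["n_chicks"] > 0]
    if len(grouped) < 3:
        raise ValueError(f"need >= 3 broods, got {len(grouped)}")
    X = sm.add_constant(grouped["midparent_tl"])
    ols = sm.OLS(grouped["brood_tl"], X).fit()
    slope = float(ols.params["midparent_tl"])
    se = float(ols.bse["midparent_tl"])
    df2 = float(ols.df_resid)
    f = (slope / se) ** 2
    ci = ols.conf_int().loc["midparent_tl"]
    return HeritabilityFit(
        h2=slope,
        se=se,
        f_stat=f,
        df_denominator=df2,
        p_value=float(stats.f.sf(f, 1, df2)),
        n=len(grouped),
        level="brood",
        conf_int=(float(ci[0]), float(ci[1])),
    )
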