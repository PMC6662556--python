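"""Determinants of chick telomere length: AICc all-subsets multimodel inference.

The main analysis asks which of several candidate predictors (brood
manipulation, parental telomere scores, parental minimum ages, chick sex,
chick size, within-brood mass rank, and sex interactions) best explain chick
telomere length, while natal box, rearing box and genetic father stay in
every model as random intercepts.  The procedure:

1. ``enumerate_candidates`` fits, by maximum likelihood on one shared
   complete-case dataset, every subset of the fixed terms that respects
   marginality (an interaction only with both main effects present).
2. ``aicc`` scores each fit with the small-sample Akaike criterion
   AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), where k counts fixed-effect
   coefficients plus the three random-intercept variances and the residual
   variance.
3. ``retain_and_weight`` keeps the models within a configurable dAICc of the
   best (2 by convention) and renormalizes exp(-d/2) into Akaike weights.
4. ``average_models`` produces full and conditional weighted-average
   coefficients with unconditional standard errors, and
   ``relative_importance`` sums weights over the models containing each term.

Supporting analyses for the brood-size manipulation itself: a repeated
measures growth model (measurement x group interaction), a binomial GLMM for
fledging with a likelihood-ratio test, the day-0 Welch comparison, the
morphometric size PC1, VIF diagnostics and within-brood mass ranks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMFit, fit_binomial_glmm, likelihood_ratio_test
from .lmm import LMMFit, fit_lmm

logger = logging.getLogger(__name__)

#: Fixed-effect terms of the full model and the data column each one reads.
TERM_COLUMNS: dict[str, str] = {
    "experimental_group": "treatment",
    "maternal_tl": "maternal_tl",
    "paternal_tl": "paternal_tl",
    "maternal_age": "maternal_min_age",
    "paternal_age": "paternal_min_age",
    "chick_sex": "sex",
    "chick_size_day12": "size_day12",
    "mass_rank": "mass_rank",
}

MAIN_TERMS: tuple[str, ...] = tuple(TERM_COLUMNS)
SEX_INTERACTIONS: tuple[str, ...] = tuple(
    f"chick_sex:{t}" for t in MAIN_TERMS if t != "chick_sex"
)
RANDOM_FACTORS = ["natal_box", "rearing_box", "genetic_father_id"]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (random structure is fixed)."""

    fixed_terms: frozenset
    response: str = "tl_score"

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise ValueError(
                        f"marginality violated: {t} requires both {a} and {b}"
                    )

    def sorted_terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.fixed_terms))


@dataclass
class CandidateFit:
    """One fitted candidate model with its AICc bookkeeping."""

    spec: ModelSpec
    loglik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)

    def term_label(self) -> str:
        return " + ".join(self.spec.sorted_terms()) or "(intercept only)"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas) -> np.ndarray:
    """Renormalized exp(-delta/2) over a retained candidate set."""
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def prepare_model_frame(records: pd.DataFrame, terms=MAIN_TERMS) -> pd.DataFrame:
    """Complete-case analysis frame for the requested terms.

    Derives ``size_day12`` (morphometric PC1 of day-12 mass, head-plus-bill
    and wing) and ``mass_rank`` (within rearing brood, heaviest = 1) when
    absent, then filters once to complete cases so every candidate model
    shares the same n, as AICc comparability requires.
    """
    df = records.copy()
    if "survived_day12" in df.columns:
        df = df[df["survived_day12"].astype(bool)]
    if "size_day12" not in df.columns and "chick_size_day12" in [t.split(":")[-1] for t in terms]:
        morpho = df[["mass_day12", "head_bill_day12", "wing_day12"]].dropna()
        scores, _ = morphometric_size_pc1(
            morpho["mass_day12"], morpho["head_bill_day12"], morpho["wing_day12"]
        )
        df.loc[morpho.index, "size_day12"] = scores
    if "mass_rank" not in df.columns and "mass_rank" in terms:
        df["mass_rank"] = mass_rank(df)
    cols = {TERM_COLUMNS[t] for t in terms if ":" not in t}
    needed = ["tl_score", *cols, *RANDOM_FACTORS]
    before = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    logger.info("complete cases: %d of %d rows retained", len(df), before)
    return df


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design with an explicit intercept.

    Binary codings: ``experimental_group`` is 1 for enlarged broods,
    ``chick_sex`` is 1 for males.
    """
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0

    def column(term: str) -> np.ndarray:
        col = TERM_COLUMNS[term]
        if term == "experimental_group":
            return (data[col] == "enlarged").to_numpy(dtype=float)
        if term == "chick_sex":
            return (data[col] == "M").to_numpy(dtype=float)
        return data[col].to_numpy(dtype=float)

    for t in sorted(spec.fixed_terms):
        if ":" in t:
            a, b = t.split(":")
            X[t] = column(a) * column(b)
        else:
            X[t] = column(t)
    return X


def fit_candidate(
    spec: ModelSpec, data: pd.DataFrame, method: str = "ML"
) -> CandidateFit:
    """Fit one candidate by (restricted) maximum likelihood and score it."""
    X = design_matrix(spec, data)
    fit = fit_lmm(
        data[spec.response], X, data=data, random_factors=RANDOM_FACTORS, method=method
    )
    return CandidateFit(
        spec=spec,
        loglik=fit.loglik,
        k=fit.k_params,
        n=fit.n,
        aicc=aicc(fit.loglik, fit.k_params, fit.n),
        coefficients={
            t: (float(fit.params[t]), float(fit.bse[t])) for t in X.columns
        },
    )


def enumerate_specs(
    main_terms=MAIN_TERMS, interactions=SEX_INTERACTIONS
) -> list[ModelSpec]:
    """All marginality-respecting subsets of the fixed terms."""
    specs = []
    mains = list(main_terms)
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            present = set(subset)
            eligible = [
                i
                for i in interactions
                if all(part in present for part in i.split(":"))
            ]
            for ri in range(len(eligible) + 1):
                for isub in itertools.combinations(eligible, ri):
                    specs.append(ModelSpec(frozenset(present | set(isub))))
    return specs


def enumerate_candidates(
    data: pd.DataFrame,
    main_terms=MAIN_TERMS,
    interactions=SEX_INTERACTIONS,
    method: str = "ML",
) -> list[CandidateFit]:
    """Fit every candidate on the identical complete-case dataset.

    Failed fits are excluded with a log entry.  The result is ordered by
    AICc, then fewer terms, then lexicographic term set, and ``delta_aicc``
    is filled relative to the best model of the whole set.
    """
    frame = prepare_model_frame(data, tuple(main_terms))
    fits = []
    for spec in enumerate_specs(main_terms, interactions):
        try:
            fits.append(fit_candidate(spec, frame, method))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("candidate %s failed: %s", sorted(spec.fixed_terms), exc)
    fits.sort(key=lambda c: (c.aicc, len(c.spec.fixed_terms), c.spec.sorted_terms()))
    best = fits[0].aicc
    for c in fits:
        c.delta_aicc = c.aicc - best
    return fits


def retain_and_weight(
    candidates: list[CandidateFit], delta_cut: float = 2.0
) -> list[CandidateFit]:
    """Keep models within ``delta_cut`` of the best AICc; renormalize weights."""
    if not candidates:
        raise ValueError("no candidates to retain")
    best = min(c.aicc for c in candidates)
    retained = []
    for c in candidates:
        c.delta_aicc = c.aicc - best
        if c.delta_aicc <= delta_cut:
            retained.append(c)
    retained.sort(key=lambda c: (c.aicc, len(c.spec.fixed_terms), c.spec.sorted_terms()))
    w = akaike_weights([c.delta_aicc for c in retained])
    for c, wi in zip(retained, w):
        c.weight = float(wi)
    return retained


def _adjust_se(se: float, n: int, k: int) -> float:
    """Small-sample adjustment: scale by the t/normal 97.5% quantile ratio."""
    df = max(n - k, 1)
    return se * stats.t.ppf(0.975, df) / stats.norm.ppf(0.975)


def average_models(retained: list[CandidateFit]) -> pd.DataFrame:
    """Full and conditional model-averaged coefficients.

    Full averages set a term's coefficient to zero in models that omit it;
    conditional averages renormalize over the containing models only.  The
    unconditional SE is sum_i w_i sqrt(se_i^2 + (b_i - bbar)^2); the adjusted
    variant applies the small-sample t correction to each se_i first.  z and
    two-sided normal p-values are reported against the adjusted SE.
    """
    if not retained:
        raise ValueError("no retained models to average")
    weights = np.array([c.weight for c in retained])
    if np.any(np.isnan(weights)):
        raise ValueError("retained models carry no weights; run retain_and_weight")
    terms: list[str] = []
    for c in retained:
        for t in c.coefficients:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        present = np.array([t in c.coefficients for c in retained])
        betas = np.array([c.coefficients.get(t, (0.0, 0.0))[0] for c in retained])
        ses = np.array([c.coefficients.get(t, (0.0, 0.0))[1] for c in retained])
        adj = np.array(
            [
                _adjust_se(se, c.n, c.k) if p else 0.0
                for se, c, p in zip(ses, retained, present)
            ]
        )
        full_b = float(weights @ betas)
        full_se = float(weights @ np.sqrt(ses**2 + (betas - full_b) ** 2))
        full_adj = float(weights @ np.sqrt(adj**2 + (betas - full_b) ** 2))
        wc = weights[present] / weights[present].sum()
        cond_b = float(wc @ betas[present])
        cond_se = float(wc @ np.sqrt(ses[present] ** 2 + (betas[present] - cond_b) ** 2))
        cond_adj = float(wc @ np.sqrt(adj[present] ** 2 + (betas[present] - cond_b) ** 2))
        z_full = full_b / full_adj if full_adj > 0 else np.nan
        z_cond = cond_b / cond_adj if cond_adj > 0 else np.nan
        rows.append(
            {
                "term": t,
                "full_estimate": full_b,
                "full_se": full_se,
                "full_adjusted_se": full_adj,
                "full_z": z_full,
                "full_p": 2 * stats.norm.sf(abs(z_full)) if np.isfinite(z_full) else np.nan,
                "conditional_estimate": cond_b,
                "conditional_se": cond_se,
                "conditional_adjusted_se": cond_adj,
                "conditional_z": z_cond,
                "conditional_p": 2 * stats.norm.sf(abs(z_cond)) if np.isfinite(z_cond) else np.nan,
                "importance": float(weights[present].sum()),
                "n_containing_models": int(present.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def relative_importance(retained: list[CandidateFit]) -> pd.DataFrame:
    """Sum of Akaike weights over the models containing each fixed term."""
    if not retained:
        raise ValueError("no retained models")
    weights = np.array([c.weight for c in retained])
    terms: list[str] = []
    for c in retained:
        for t in c.spec.sorted_terms():
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        present = np.array([t in c.spec.fixed_terms for c in retained])
        rows.append(
            {
                "term": t,
                "importance": float(weights[present].sum()),
                "n_containing_models": int(present.sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    return out.sort_values("importance", ascending=False)


def candidate_table(candidates: list[CandidateFit]) -> pd.DataFrame:
    """Candidate summary in the conventional layout (terms, df, logLik, AICc, dAICc, weight)."""
    return pd.DataFrame(
        {
            "component_terms": [c.term_label() for c in candidates],
            "df": [c.k for c in candidates],
            "logLik": [c.loglik for c in candidates],
            "AICc": [c.aicc for c in candidates],
            "delta_AICc": [c.delta_aicc for c in candidates],
            "weight": [c.weight for c in candidates],
        }
    )


# ---------------------------------------------------------------------------
# treatment-effect models and diagnostics


def morphometric_size_pc1(mass, head_bill, wing) -> tuple[np.ndarray, float]:
    """PC1 of the three morphometrics (covariance mode), larger chicks higher.

    Returns per-row scores and the fraction of variance PC1 explains.
    """
    M = np.column_stack(
        [np.asarray(mass, float), np.asarray(head_bill, float), np.asarray(wing, float)]
    )
    if np.any(np.isnan(M)):
        raise ValueError("morphometric columns must be complete")
    if np.any(M.std(axis=0) == 0):
        raise ValueError("constant morphometric column")
    centered = M - M.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    v1 = evecs[:, 0]
    if v1[0] < 0:  # mass loading positive: big chicks score high
        v1 = -v1
    return centered @ v1, float(evals[0] / evals.sum())


def growth_model(records: pd.DataFrame) -> dict:
    """Treatment effect on growth: size ~ measurement x group, repeated measures.

    Builds a long table of the four measurements (days 0/4/8/12), scores size
    as the pooled morphometric PC1, and fits an LMM with the measurement-by-
    group interaction as fixed effects and chick id, natal box and rearing
    box as random intercepts.  Reports per-measurement group contrasts and a
    likelihood-ratio p-value (ML) for the interaction.
    """
    ages = (0, 4, 8, 12)
    long_rows = []
    for _, r in records.iterrows():
        for m, age in enumerate(ages):
            vals = (r.get(f"mass_day{age}"), r.get(f"head_bill_day{age}"), r.get(f"wing_day{age}"))
            if any(pd.isna(v) for v in vals):
                continue
            long_rows.append(
                {
                    "chick_id": r["chick_id"],
                    "natal_box": r["natal_box"],
                    "rearing_box": r["rearing_box"],
                    "enlarged": 1.0 if r["treatment"] == "enlarged" else 0.0,
                    "measurement": m,
                    "mass": vals[0],
                    "head_bill": vals[1],
                    "wing": vals[2],
                }
            )
    long = pd.DataFrame(long_rows)
    scores, explained = morphometric_size_pc1(long["mass"], long["head_bill"], long["wing"])
    long["size"] = scores

    def design(with_interaction: bool) -> pd.DataFrame:
        X = pd.DataFrame(index=long.index)
        X["Intercept"] = 1.0
        for m in (1, 2, 3):
            X[f"measurement_{m}"] = (long["measurement"] == m).astype(float)
        X["enlarged"] = long["enlarged"]
        if with_interaction:
            for m in (1, 2, 3):
                X[f"measurement_{m}:enlarged"] = X[f"measurement_{m}"] * X["enlarged"]
        return X

    factors = ["chick_id", "natal_box", "rearing_box"]
    full = fit_lmm(long["size"], design(True), data=long, random_factors=factors, method="ML")
    reduced = fit_lmm(long["size"], design(False), data=long, random_factors=factors, method="ML")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p_int = float(stats.chi2.sf(chi2, 3))
    contrasts = {}
    for m in range(4):
        est = float(full.params["enlarged"])
        if m > 0:
            est += float(full.params[f"measurement_{m}:enlarged"])
        contrasts[f"measurement_{m}"] = est
    return {
        "fit": full,
        "size_pc1_explained": explained,
        "group_contrast_by_measurement": contrasts,
        "interaction_chi2": chi2,
        "interaction_p": p_int,
        "n_measurements": len(long),
    }


def fledging_model(records: pd.DataFrame) -> dict:
    """Fledging probability: binomial GLMM, treatment effect tested by LRT."""
    df = records.dropna(subset=["fledged"]).copy()
    y = df["fledged"].astype(float)
    X_full = pd.DataFrame(
        {
            "Intercept": 1.0,
            "treatment_enlarged": (df["treatment"] == "enlarged").astype(float),
        },
        index=df.index,
    )
    X_red = X_full[["Intercept"]]
    factors = ["natal_box", "rearing_box"]
    full = fit_binomial_glmm(y, X_full, data=df, random_factors=factors)
    reduced = fit_binomial_glmm(y, X_red, data=df, random_factors=factors)
    chi2, dof, p = likelihood_ratio_test(full, reduced)
    return {
        "fit": full,
        "coefficient": float(full.params["treatment_enlarged"]),
        "se": float(full.bse["treatment_enlarged"]),
        "lrt_chi2": chi2,
        "lrt_df": dof,
        "lrt_p": p,
        "n": full.n,
    }


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per non-intercept column: 1/(1 - R2_j)."""
    cols = [c for c in design.columns if c.lower() != "intercept"]
    X = design[cols].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(cols):
        others = np.column_stack(
            [np.ones(len(X)), np.delete(X, j, axis=1)]
        )
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    if np.isinf(s).any():
        logger.warning("aliased column(s) with infinite VIF: %s", list(s[np.isinf(s)].index))
    return s


def mass_rank(records: pd.DataFrame, mass_col: str = "mass_day12") -> pd.Series:
    """Within-rearing-brood rank of day-12 mass; heaviest = 1, ties averaged."""
    return records.groupby("rearing_box")[mass_col].rank(
        ascending=False, method="average"
    )
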