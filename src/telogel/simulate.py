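"""Synthetic gels and synthetic cross-fostered populations with known truth.

Two generators make every downstream stage testable against ground truth:

``render_gel``
    Paints a TRF gel image from known telomere-length mixtures: ladder lanes
    as bands at the inverse migration map of the rung sizes, sample lanes as
    smears whose per-row intensity is proportional to the true molecule
    count at that row's fragment size, plus blur, background and noise.
    Analytic metrics of the generating mixture accompany the image, so the
    densitometry/metrics pipeline has exact targets to recover.

``simulate_population``
    Emulates a paired brood-size-manipulation experiment with reciprocal
    cross-fostering: nests are paired and matched on hatch date, brood size
    and female age; one nest per pair is enlarged by adding donor chicks
    from non-experimental nests; half of each brood (rounded down) is swapped
    between the paired nests.  Telomere-length scores follow the
    infinitesimal model - offspring breeding value = mid-parent mean plus a
    segregation deviation of variance sigma2_additive/2 - with natal-box,
    rearing-box, treatment and residual effects on top, so the mid-parent
    regression slope targets a configurable heritability exactly.

Both generators draw from a single seeded RNG stream and are byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

from .densitometry import DEFAULT_WINDOW_KB, GelImage, LaneSpec
from .metrics import TLMetricSet

#: Visible rungs of a 1-kb extension ladder between the outermost markers (kb).
DEFAULT_LADDER_KB: tuple[float, ...] = (
    1.636, 2.036, 3.054, 4.072, 5.09, 6.108, 7.126, 8.144, 9.162, 10.18,
    11.198, 12.216, 15.004, 17.057, 19.397, 22.621, 24.776, 29.95, 33.5, 40.0,
)

#: Default migration map: strictly decreasing cubic, ~44 kb at the top row,
#: ~1.4 kb at row 500 (its derivative is -((A - B r)^2 + g), negative by
#: construction, with separation widest near the well as on a real gel).
DEFAULT_MIGRATION_COEFFS: tuple[float, float, float, float] = (
    44.0,
    -0.19638894009216592,
    0.00029905990783410136,
    -1.5336405529953918e-07,
)


@dataclass
class GelSimConfig:
    """Geometry, optics and noise of a simulated gel."""

    image_height_px: int = 520
    image_width_px: int = 280
    migration_coeffs: tuple[float, float, float, float] = DEFAULT_MIGRATION_COEFFS
    ladder_sizes_kb: tuple[float, ...] = DEFAULT_LADDER_KB
    lane_centers_px: tuple[int, ...] = tuple(range(14, 274, 20))
    lane_width_px: int = 12
    ladder_lane_indices: tuple[int, ...] | None = None
    ladder_band_intensity: float = 2500.0
    ladder_band_sd_px: float = 1.3
    background_level: float = 40.0
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    blur_sd_px: float = 0.0
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.noise_sd < 0 or self.blur_sd_px < 0:
            raise ValueError("background, noise and blur parameters must be >= 0")
        if self.ladder_lane_indices is None:
            n = len(self.lane_centers_px)
            self.ladder_lane_indices = (0, n // 2, n - 1)
        centers = np.asarray(self.lane_centers_px)
        if np.any(np.diff(np.sort(centers)) < self.lane_width_px):
            raise ValueError("lane regions overlap")
        rows = np.arange(self.image_height_px, dtype=float)
        kb = self.kb_at(rows)
        if not (np.all(np.diff(kb) < 0) or np.all(np.diff(kb) > 0)):
            raise ValueError("migration map is not monotone over the image")

    def kb_at(self, row):
        c0, c1, c2, c3 = self.migration_coeffs
        r = np.asarray(row, dtype=float)
        return c0 + c1 * r + c2 * r**2 + c3 * r**3

    def dkb_drow(self, row):
        _, c1, c2, c3 = self.migration_coeffs
        r = np.asarray(row, dtype=float)
        return c1 + 2 * c2 * r + 3 * c3 * r**2

    def row_of_kb(self, kb: float) -> float:
        rows = np.arange(self.image_height_px, dtype=float)
        vals = self.kb_at(rows)
        order = np.argsort(vals)
        return float(np.interp(kb, vals[order], rows[order]))

    def below_marker_row(self, margin_px: int = 6) -> int:
        """A row just below the lowest size marker, for background estimation."""
        return min(
            int(round(self.row_of_kb(self.window_kb[0]))) + margin_px,
            self.image_height_px - 1,
        )

    def sample_lane_indices(self) -> list[int]:
        return [
            i
            for i in range(len(self.lane_centers_px))
            if i not in self.ladder_lane_indices
        ]

    def lane_layout(self, sample_ids: list[str], gel_id: str = "gel") -> list[LaneSpec]:
        """LaneSpec list matching this geometry for the densitometry stage."""
        lanes = []
        sample_iter = iter(sample_ids)
        for i, c in enumerate(self.lane_centers_px):
            if i in self.ladder_lane_indices:
                lanes.append(
                    LaneSpec(f"ladder_{i}", int(c), self.lane_width_px, "ladder", gel_id)
                )
            else:
                try:
                    sid = next(sample_iter)
                except StopIteration:
                    break
                lanes.append(LaneSpec(sid, int(c), self.lane_width_px, "sample", gel_id))
        return lanes


@dataclass
class TrueTLSpec:
    """Ground-truth telomere-length mixture for one simulated individual.

    ``components`` are (mixture_weight, mean_kb, sd_kb) triples; the family
    of each component is lognormal by default (smears are right-skewed on
    the kb scale), with a plain normal alternative.
    """

    individual_id: str
    components: list[tuple[float, float, float]]
    total_intensity: float = 1.0e5
    family: str = "lognormal"

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components], dtype=float)
        if not math.isclose(w.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.family not in ("lognormal", "normal"):
            raise ValueError("family must be 'lognormal' or 'normal'")

    def _dists(self):
        out = []
        for w, m, s in self.components:
            if self.family == "lognormal":
                sig2 = math.log1p((s / m) ** 2)
                mu = math.log(m) - sig2 / 2
                out.append((w, stats.lognorm(s=math.sqrt(sig2), scale=math.exp(mu))))
            else:
                out.append((w, stats.norm(loc=m, scale=s)))
        return out

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * d.pdf(x) for w, d in self._dists())

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(w * d.cdf(x) for w, d in self._dists())

    def quantile(self, q: float) -> float:
        lo = min(d.ppf(1e-9) for _, d in self._dists())
        hi = max(d.ppf(1 - 1e-9) for _, d in self._dists())
        return float(optimize.brentq(lambda x: self.cdf(x) - q, lo, hi, xtol=1e-10))

    def moments(self) -> tuple[float, float, float, float]:
        """Mean, variance, skew and non-excess kurtosis of the mixture."""
        raw = np.zeros(4)
        for w, d in self._dists():
            raw += w * np.array([d.moment(k) for k in range(1, 5)])
        m1, m2, m3, m4 = raw
        mu = m1
        var = m2 - mu**2
        c3 = m3 - 3 * mu * m2 + 2 * mu**3
        c4 = m4 - 4 * mu * m3 + 6 * mu**2 * m2 - 3 * mu**4
        return float(mu), float(var), float(c3 / var**1.5), float(c4 / var**2)

    def true_metric_set(self) -> TLMetricSet:
        mu, _, skew, kurt = self.moments()
        dec = {f"p{q}": self.quantile(q / 100) for q in range(10, 100, 10)}
        return TLMetricSet(
            individual_id=self.individual_id,
            mean_kb=mu,
            skew=skew,
            kurtosis=kurt,
            **dec,
        )

    def support_range(self, eps: float = 1e-5) -> tuple[float, float]:
        return (
            min(d.ppf(eps) for _, d in self._dists()),
            max(d.ppf(1 - eps) for _, d in self._dists()),
        )


def render_gel(
    config: GelSimConfig, specs: list[TrueTLSpec]
) -> tuple[GelImage, pd.DataFrame]:
    """Render a gel image plus a ground-truth metric table.

    Per-row expected smear intensity is the mixture density in kb times
    |d(kb)/d(row)| (change of variables), so that row intensity is
    proportional to the molecule count migrating to that row.  The image is
    then blurred, offset by the background and corrupted by Gaussian noise
    clipped at zero.
    """
    sample_idx = config.sample_lane_indices()
    if len(specs) > len(sample_idx):
        raise ValueError(
            f"{len(specs)} samples but only {len(sample_idx)} sample lanes"
        )
    lo, hi = config.window_kb
    for sp in specs:
        s_lo, s_hi = sp.support_range()
        if s_lo < lo or s_hi > hi:
            raise ValueError(
                f"{sp.individual_id}: mixture support [{s_lo:.2f}, {s_hi:.2f}] kb "
                f"outside analysis window [{lo}, {hi}]"
            )
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height_px, config.image_width_px
    rows = np.arange(H, dtype=float)
    kb = config.kb_at(rows)
    jac = np.abs(config.dkb_drow(rows))
    signal = np.zeros((H, W))

    def paint(center: int, trace: np.ndarray) -> None:
        half = config.lane_width_px // 2
        c0 = center - half
        signal[:, c0 : c0 + config.lane_width_px] += trace[:, None]

    for i in config.ladder_lane_indices:
        trace = np.zeros(H)
        for size in config.ladder_sizes_kb:
            r0 = config.row_of_kb(size)
            trace += config.ladder_band_intensity * np.exp(
                -0.5 * ((rows - r0) / config.ladder_band_sd_px) ** 2
            )
        paint(config.lane_centers_px[i], trace)

    truth_rows = []
    for sp, lane_i in zip(specs, sample_idx):
        trace = sp.total_intensity * sp.pdf(kb) * jac
        paint(config.lane_centers_px[lane_i], trace)
        truth_rows.append(sp.true_metric_set().as_row())

    if config.blur_sd_px > 0:
        signal = gaussian_filter(signal, config.blur_sd_px)
    image = signal + config.background_level + config.background_gradient * rows[:, None]
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)
    truth = pd.DataFrame(truth_rows).set_index("individual_id") if truth_rows else pd.DataFrame()
    return GelImage(image, bit_depth=16, provenance=f"synthetic seed={config.seed}"), truth


@dataclass
class PopulationSimConfig:
    """True parameters of the simulated cross-fostering experiment.

    Variance components are on the telomere-score scale; the implied
    narrow-sense heritability is sigma2_additive / (sigma2_additive +
    sigma2_natal_box + sigma2_rearing_box + sigma2_residual).  Defaults give
    the realized design of the field study being emulated: paired broods of
    about 5 chicks, enlargement by 3 donor chicks, and a high heritability.
    """

    n_pairs: int = 39
    control_brood_mean: float = 5.07
    brood_sd: float = 0.67
    enlargement_add: int = 3
    sigma2_additive: float = 0.8
    sigma2_natal_box: float = 0.03
    sigma2_rearing_box: float = 0.05
    sigma2_residual: float = 0.12
    treatment_effect_tl: float = -0.3
    treatment_effect_growth: float = -0.8
    fledging_logit_base: float = 2.5
    fledging_logit_treatment: float = -1.5
    fledging_box_sd: float = 0.7
    mu_tl: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name in (
            "sigma2_additive",
            "sigma2_natal_box",
            "sigma2_rearing_box",
            "sigma2_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("implied heritability outside [0, 1]")
        if self.enlargement_add < 0:
            raise ValueError("enlargement_add must be >= 0")

    @property
    def sigma2_env(self) -> float:
        return self.sigma2_natal_box + self.sigma2_rearing_box + self.sigma2_residual

    @property
    def h2(self) -> float:
        tot = self.sigma2_additive + self.sigma2_env
        return self.sigma2_additive / tot if tot > 0 else 0.0

    def metadata(self) -> dict:
        return asdict(self)


def simulate_population(config: PopulationSimConfig) -> pd.DataFrame:
    """Simulate one breeding season of the paired brood-manipulation design.

    Returns one row per chick reared in an experimental nest, with pedigree,
    treatment, telomere scores (chick and parents), morphometrics at days
    0/4/8/12 and survival outcomes.  Chicks that die before day 12 carry no
    telomere score or day-12 morphometrics (the assay needs intact DNA from
    a day-12 blood sample).
    """
    rng = np.random.default_rng(config.seed)
    sA = math.sqrt(config.sigma2_additive)
    sE = math.sqrt(config.sigma2_env)
    records: list[dict] = []

    def make_parents(box: str, female_min_age: int | None = None):
        """Breeding values and phenotypes for the resident pair of a box."""
        bv_m, bv_f = rng.normal(0.0, sA, size=2)
        tl_m, tl_f = config.mu_tl + np.array([bv_m, bv_f]) + rng.normal(0.0, sE, size=2)
        age_m = (
            female_min_age
            if female_min_age is not None
            else 2 + int(rng.poisson(1.2))
        )
        age_f = 1 + int(rng.poisson(1.2))
        return {
            "mother_id": f"F_{box}",
            "father_id": f"M_{box}",
            "bv_mother": bv_m,
            "bv_father": bv_f,
            "maternal_tl": float(tl_m),
            "paternal_tl": float(tl_f),
            "maternal_min_age": age_m,
            "paternal_min_age": age_f,
        }

    def make_chick(parents: dict, natal_box: str, chick_id: str) -> dict:
        bv = 0.5 * (parents["bv_mother"] + parents["bv_father"]) + rng.normal(
            0.0, math.sqrt(config.sigma2_additive / 2)
        )
        return {
            "chick_id": chick_id,
            "natal_box": natal_box,
            "genetic_mother_id": parents["mother_id"],
            "genetic_father_id": parents["father_id"],
            "maternal_tl": parents["maternal_tl"],
            "paternal_tl": parents["paternal_tl"],
            "maternal_min_age": parents["maternal_min_age"],
            "paternal_min_age": parents["paternal_min_age"],
            "_bv": bv,
        }

    natal_effects: dict[str, float] = {}
    rearing_effects: dict[str, float] = {}
    fledging_effects: dict[str, float] = {}

    def box_effect(store: dict, box: str, sd: float) -> float:
        if box not in store:
            store[box] = float(rng.normal(0.0, sd))
        return store[box]

    for p in range(config.n_pairs):
        pair_id = f"pair{p:03d}"
        hatch_date = int(rng.integers(130, 160))
        female_age = 2 + int(rng.poisson(1.2))
        brood_size = max(1, int(round(rng.normal(config.control_brood_mean, config.brood_sd))))
        control_box = f"box_{pair_id}_C"
        enlarged_box = f"box_{pair_id}_E"
        donor_box = f"box_{pair_id}_D"
        par_c = make_parents(control_box, female_age)
        par_e = make_parents(enlarged_box, female_age)
        par_d = make_parents(donor_box)

        brood_c = [
            make_chick(par_c, control_box, f"{pair_id}_C{i}") for i in range(brood_size)
        ]
        brood_e = [
            make_chick(par_e, enlarged_box, f"{pair_id}_E{i}") for i in range(brood_size)
        ]
        # reciprocal transfer of half of each brood (rounded down), at random
        k = brood_size // 2
        swap_c = rng.choice(brood_size, size=k, replace=False)
        swap_e = rng.choice(brood_size, size=k, replace=False)
        for chick in brood_c + brood_e:
            chick["rearing_box"] = chick["natal_box"]
        for i in swap_c:
            brood_c[i]["rearing_box"] = enlarged_box
        for i in swap_e:
            brood_e[i]["rearing_box"] = control_box
        donors = [
            make_chick(par_d, donor_box, f"{pair_id}_D{i}")
            for i in range(config.enlargement_add)
        ]
        for chick in donors:
            chick["rearing_box"] = enlarged_box

        chicks = brood_c + brood_e + donors
        for chick in chicks:
            chick["pair_id"] = pair_id
            chick["hatch_date"] = hatch_date
            chick["treatment"] = (
                "enlarged" if chick["rearing_box"] == enlarged_box else "control"
            )
        records.extend(chicks)

    df = pd.DataFrame(records)
    n = len(df)
    enlarged = (df["treatment"] == "enlarged").to_numpy()

    # sexes 1:1 within each rearing brood
    sex = np.empty(n, dtype=object)
    for _, idx in df.groupby("rearing_box").indices.items():
        labels = np.array(["M", "F"] * (len(idx) // 2 + 1))[: len(idx)]
        sex[idx] = labels[rng.permutation(len(idx))]
    df["sex"] = sex

    natal_eff = np.array(
        [
            box_effect(natal_effects, b, math.sqrt(config.sigma2_natal_box))
            for b in df["natal_box"]
        ]
    )
    rear_eff = np.array(
        [
            box_effect(rearing_effects, b, math.sqrt(config.sigma2_rearing_box))
            for b in df["rearing_box"]
        ]
    )
    tl = (
        config.mu_tl
        + df["_bv"].to_numpy()
        + natal_eff
        + rear_eff
        + config.treatment_effect_tl * enlarged
        + rng.normal(0.0, math.sqrt(config.sigma2_residual), size=n)
    )

    # fledging: binomial with a rearing-box random intercept
    fledge_eff = np.array(
        [
            box_effect(fledging_effects, b, config.fledging_box_sd)
            for b in df["rearing_box"]
        ]
    )
    eta = config.fledging_logit_base + config.fledging_logit_treatment * enlarged + fledge_eff
    fledged = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    died_early = (~fledged) & (rng.random(n) < 0.5)
    survived = ~died_early
    df["fledged"] = fledged
    df["survived_day12"] = survived

    # growth: a per-chick quality offset shifts three collinear morphometrics
    # at every age; enlargement depresses growth more with each measurement
    quality = rng.normal(0.0, 1.0, size=n)
    for m, age in enumerate((0, 4, 8, 12)):
        deficit = config.treatment_effect_growth * m * enlarged
        frac = age / 12.0
        df[f"mass_day{age}"] = (
            1.8 + 18.0 * frac + 1.5 * quality + deficit + rng.normal(0.0, 0.4, size=n)
        )
        df[f"head_bill_day{age}"] = (
            10.0 + 18.0 * frac + 1.2 * quality + 0.6 * deficit
            + rng.normal(0.0, 0.35, size=n)
        )
        df[f"wing_day{age}"] = (
            5.0 + 45.0 * frac + 3.5 * quality + 1.5 * deficit
            + rng.normal(0.0, 0.9, size=n)
        )

    df["tl_score"] = np.where(survived, tl, np.nan)
    for col in ("mass_day12", "head_bill_day12", "wing_day12"):
        df.loc[~survived, col] = np.nan
    df = df.drop(columns=["_bv"])
    front = [
        "chick_id", "pair_id", "sex", "treatment", "natal_box", "rearing_box",
        "genetic_mother_id", "genetic_father_id", "tl_score",
        "maternal_tl", "paternal_tl", "maternal_min_age", "paternal_min_age",
        "hatch_date", "fledged", "survived_day12",
    ]
    return df[front + [c for c in df.columns if c not in front]].reset_index(drop=True)


def specs_from_scores(
    ids,
    scores,
    seed: int = 0,
    mean_center_kb: float = 10.0,
    mean_scale_kb: float = 1.0,
    spread_kb: float = 2.0,
) -> list[TrueTLSpec]:
    """Map latent telomere scores to plausible gel mixtures.

    Each individual's score shifts the location of a two-component lognormal
    smear; useful to exercise the full image pipeline on a simulated cohort.
    The smear center is clamped to 5.5-16 kb so that even extreme scores
    keep the mixture support inside the 1.636-40 kb analysis window.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for cid, score in zip(ids, scores):
        center = float(np.clip(mean_center_kb + mean_scale_kb * float(score), 5.5, 16.0))
        w = 0.6 + 0.1 * rng.random()
        specs.append(
            TrueTLSpec(
                individual_id=str(cid),
                components=[
                    (w, center, spread_kb),
                    (1 - w, center * 1.15, spread_kb * 1.2),
                ],
                total_intensity=8e4 * (0.8 + 0.4 * rng.random()),
            )
        )
    return specs


def specs_from_population(table: pd.DataFrame, seed: int = 0, **kwargs) -> list[TrueTLSpec]:
    """Gel mixtures for every scored chick of a simulated population table."""
    sub = table.dropna(subset=["tl_score"])
    return specs_from_scores(sub["chick_id"], sub["tl_score"], seed=seed, **kwargs)
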