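"""Formats, configuration, run logging and the end-to-end pipeline.

File conventions: phenotype/pedigree tables are UTF-8 comma-separated CSV
with "." decimal points (Unicode minus signs are normalized to ASCII on
read); per-individual telomere distributions are two-column CSV (kb, weight);
calibrations and PCA results are JSON; gel images are 16-bit TIFF or PNG;
run configuration is YAML.  Every pipeline output directory carries a
metadata JSON echoing the configuration and seed so runs can be reproduced
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .densitometry import (
    DEFAULT_WINDOW_KB,
    GelImage,
    LadderCalibration,
    LaneSpec,
    TLDistribution,
    quantify_gel,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "chick_id",
    "sex",
    "natal_box",
    "rearing_box",
    "genetic_mother_id",
    "genetic_father_id",
    "treatment",
)
SEX_VALUES = {"M", "F"}
TREATMENT_VALUES = {"control", "enlarged"}


@dataclass
class RunLog:
    """Structured, timestamped record of what a run read, excluded and warned about."""

    entries: list[dict] = field(default_factory=list)

    def add(self, event: str, **details) -> None:
        entry = {
            "time": datetime.now(timezone.utc).isoformat(),
            "event": event,
            **details,
        }
        self.entries.append(entry)
        logger.info("%s %s", event, details)

    def excluded_total(self) -> int:
        return sum(e.get("n_excluded", 0) for e in self.entries)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2))


def validate_phenotype_table(df: pd.DataFrame) -> tuple[pd.DataFrame, RunLog]:
    """Type and validate an in-memory phenotype table; log exclusions.

    Rows with unknown paternity (missing genetic father) are flagged, not
    dropped: downstream model subsets exclude them and the log accounts for
    every excluded row.
    """
    log = RunLog()
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    for col in ("chick_id", "natal_box", "rearing_box"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"malformed row(s) {list(bad)}: empty {col}")
    badsex = set(df["sex"].dropna()) - SEX_VALUES
    if badsex:
        raise ValueError(f"invalid sex value(s): {sorted(badsex)} (expected M/F)")
    badtr = set(df["treatment"].dropna()) - TREATMENT_VALUES
    if badtr:
        raise ValueError(
            f"invalid treatment value(s): {sorted(badtr)} (expected control/enlarged)"
        )
    log.add("records_read", n=len(df))
    unknown_father = df["genetic_father_id"].isna()
    if unknown_father.any():
        log.add(
            "unknown_paternity",
            n_excluded=int(unknown_father.sum()),
            note="excluded from heritability and determinant models",
        )
    if "survived_day12" in df.columns:
        dead = ~df["survived_day12"].astype(bool)
        if dead.any():
            log.add(
                "died_before_day12",
                n_excluded=int(dead.sum()),
                note="no telomere score measured",
            )
    return df, log


def read_phenotype_table(path) -> tuple[pd.DataFrame, RunLog]:
    """Read and validate a phenotype/pedigree CSV."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    # normalize Unicode minus to ASCII in any object column that holds numbers
    for col in df.columns:
        if df[col].dtype == object:
            cleaned = df[col].astype(str).str.replace("−", "-", regex=False)
            converted = pd.to_numeric(cleaned, errors="coerce")
            if converted.notna().sum() == df[col].notna().sum():
                df[col] = converted.where(df[col].notna())
            else:
                df[col] = df[col]
    return validate_phenotype_table(df)


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def heritability_subset(df: pd.DataFrame, log: RunLog | None = None) -> pd.DataFrame:
    """Rows usable for the mid-parent models: both parents known, chick scored."""
    needed = ["tl_score", "maternal_tl", "paternal_tl", "genetic_mother_id", "genetic_father_id"]
    out = df.dropna(subset=[c for c in needed if c in df.columns])
    if "survived_day12" in out.columns:
        out = out[out["survived_day12"].astype(bool)]
    if log is not None:
        log.add("heritability_subset", n=len(out), n_excluded=len(df) - len(out))
    return out


# ---------------------------------------------------------------------------
# distributions / calibration / metrics


def write_distribution(dist: TLDistribution, path) -> None:
    pd.DataFrame({"kb": dist.positions_kb, "weight": dist.weights}).to_csv(
        path, index=False
    )


def read_distribution(path, individual_id: str | None = None,
                      window_kb=DEFAULT_WINDOW_KB) -> TLDistribution:
    df = pd.read_csv(path)
    return TLDistribution(
        individual_id=individual_id or Path(path).stem,
        positions_kb=df["kb"].to_numpy(),
        weights=df["weight"].to_numpy(),
        window_kb=window_kb,
    )


def write_calibration(cal: LadderCalibration, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "coeffs": list(cal.coeffs),
                "window_kb": list(cal.window_kb),
                "fit_rmse_kb": cal.fit_rmse_kb,
                "source_peaks": cal.source_peaks,
            },
            indent=2,
        )
    )


def read_calibration(path) -> LadderCalibration:
    d = json.loads(Path(path).read_text())
    return LadderCalibration(
        coeffs=np.array(d["coeffs"]),
        window_kb=tuple(d["window_kb"]),
        fit_rmse_kb=d["fit_rmse_kb"],
        source_peaks=[tuple(p) for p in d["source_peaks"]],
    )


# ---------------------------------------------------------------------------
# gel images


def write_gel_image(image: GelImage, path) -> None:
    """Write as 16-bit grayscale TIFF or PNG depending on the suffix."""
    arr = np.clip(image.pixels, 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_gel_image(path) -> GelImage:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise ValueError(f"cannot read gel image {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse RGB scans
        arr = arr.mean(axis=2)
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return GelImage(arr.astype(float), bit_depth=bit_depth, provenance=str(path))


def read_lane_layout(path) -> tuple[list[LaneSpec], dict]:
    """Lane layout YAML: gel_id, ladder sizes, below-marker row, per-lane specs."""
    cfg = yaml.safe_load(Path(path).read_text())
    lanes = [
        LaneSpec(
            lane_id=str(ln["lane_id"]),
            center_col_px=int(ln["center_col_px"]),
            width_px=int(ln.get("width_px", cfg.get("lane_width_px", 12))),
            kind=ln.get("kind", "sample"),
            gel_id=str(cfg.get("gel_id", "")),
        )
        for ln in cfg["lanes"]
    ]
    meta = {
        "gel_id": cfg.get("gel_id", ""),
        "ladder_sizes_kb": [float(v) for v in cfg["ladder_sizes_kb"]],
        "below_marker_row": int(cfg["below_marker_row"]),
        "window_kb": tuple(cfg.get("window_kb", DEFAULT_WINDOW_KB)),
    }
    return lanes, meta


# ---------------------------------------------------------------------------
# run configuration and the chained pipeline


@dataclass
class RunConfig:
    """Parameters of a full synthetic-to-report pipeline run."""

    seed: int = 0
    n_pairs: int = 8
    window_kb: tuple[float, float] = DEFAULT_WINDOW_KB
    delta_cut: float = 2.0
    pca_mode: str = "covariance"
    noise_sd: float = 3.0
    blur_sd_px: float = 1.0
    h2_true: float = 0.8

    def __post_init__(self) -> None:
        if self.pca_mode not in ("covariance", "correlation"):
            raise ValueError("pca_mode must be 'covariance' or 'correlation'")
        if self.delta_cut < 0:
            raise ValueError("delta_cut must be >= 0")
        if not self.window_kb[0] < self.window_kb[1]:
            raise ValueError("window low must be below window high")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["window_kb"] = list(self.window_kb)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "window_kb" in d:
            d["window_kb"] = tuple(d["window_kb"])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Synthetic cohort -> gels -> quantification -> TL scores -> h2 + dredge.

    Simulates a cross-fostered population, renders every scored chick and
    parent onto gels, quantifies the gels back into distribution metrics,
    scores individuals with PC1, then runs the heritability and
    determinant analyses on the measured (not the latent) scores.  Writes
    all artifacts under ``out_dir`` and returns the key results.
    """
    from . import heritability, inference, metrics as tlm, simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    env_total = 0.2
    sA = config.h2_true * (env_total / (1 - config.h2_true)) if config.h2_true < 1 else 1.0
    pop_cfg = simulate.PopulationSimConfig(
        n_pairs=config.n_pairs,
        sigma2_additive=sA,
        sigma2_natal_box=0.03 / 0.2 * env_total,
        sigma2_rearing_box=0.05 / 0.2 * env_total,
        sigma2_residual=0.12 / 0.2 * env_total,
        seed=config.seed,
    )
    table = simulate.simulate_population(pop_cfg)
    write_phenotype_table(table, out / "population.csv")
    log.add("population_simulated", n_chicks=len(table))

    # gel rendering for every scored individual: chicks and parents
    chicks = table.dropna(subset=["tl_score"])
    parents = (
        table.groupby("genetic_father_id")
        .first()
        .reset_index()[["genetic_father_id", "genetic_mother_id", "maternal_tl", "paternal_tl"]]
    )
    ids = list(chicks["chick_id"])
    scores = list(chicks["tl_score"])
    for _, r in parents.iterrows():
        ids += [r["genetic_mother_id"], r["genetic_father_id"]]
        scores += [r["maternal_tl"], r["paternal_tl"]]

    gel_cfg = simulate.GelSimConfig(
        noise_sd=config.noise_sd,
        blur_sd_px=config.blur_sd_px,
        window_kb=config.window_kb,
        seed=config.seed,
    )
    per_gel = len(gel_cfg.sample_lane_indices())
    measured = {}
    gel_dir = out / "gels"
    gel_dir.mkdir(exist_ok=True)
    for g in range(0, len(ids), per_gel):
        batch_ids = ids[g : g + per_gel]
        batch_scores = scores[g : g + per_gel]
        specs = simulate.specs_from_scores(
            batch_ids, batch_scores, seed=config.seed + 1000 + g
        )
        cfg_g = dataclasses.replace(gel_cfg, seed=config.seed + g)
        image, _truth = simulate.render_gel(cfg_g, specs)
        write_gel_image(image, gel_dir / f"gel_{g // per_gel:03d}.tif")
        lanes = cfg_g.lane_layout(batch_ids, gel_id=f"gel_{g // per_gel:03d}")
        cal, dists = quantify_gel(
            image, lanes, cfg_g.ladder_sizes_kb, cfg_g.below_marker_row(),
            window_kb=config.window_kb,
        )
        for lane_id, dist in dists.items():
            measured[lane_id] = tlm.compute_metric_set(dist)
    log.add("gels_quantified", n_individuals=len(measured))

    mtable = tlm.metrics_table(list(measured.values()))
    mtable.to_csv(out / "metrics.csv")
    pca = tlm.pca_scores(mtable, mode=config.pca_mode)
    pc1 = pca.pc1_scores()

    analysis = table.copy()
    analysis["tl_score"] = analysis["chick_id"].map(pc1)
    analysis["maternal_tl"] = analysis["genetic_mother_id"].map(pc1)
    analysis["paternal_tl"] = analysis["genetic_father_id"].map(pc1)
    write_phenotype_table(analysis, out / "analysis_table.csv")

    h2 = heritability.midparent_heritability(analysis)
    candidates = inference.enumerate_candidates(
        analysis,
        main_terms=("experimental_group", "maternal_tl", "paternal_tl", "chick_size_day12"),
        interactions=(),
    )
    retained = inference.retain_and_weight(candidates, config.delta_cut)
    averaged = inference.average_models(retained)
    importance = inference.relative_importance(retained)

    inference.candidate_table(retained).to_csv(out / "candidates.csv", index=False)
    averaged.to_csv(out / "averaged_coefficients.csv")
    importance.to_csv(out / "importance.csv")
    (out / "h2.json").write_text(
        json.dumps(
            {
                "h2": h2.h2, "se": h2.se, "f": h2.f_stat,
                "df_denominator": h2.df_denominator, "p": h2.p_value, "n": h2.n,
            },
            indent=2,
        )
    )
    meta = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "pc1_explained": float(pca.explained_fraction[0]),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=list))
    log.to_json(out / "run_log.json")
    return {
        "h2": h2,
        "retained": retained,
        "averaged": averaged,
        "importance": importance,
        "pca_explained": float(pca.explained_fraction[0]),
        "out_dir": out,
    }
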