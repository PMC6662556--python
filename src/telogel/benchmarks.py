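"""Published benchmark values for a tree swallow cross-fostering dataset.

A field study of Tree Swallows (brood-size manipulation with reciprocal
cross-fostering, telomere scores from TRF gels) published the per-model
summaries of its AICc analysis: the 12 candidate models within dAICc < 2 of
the best, with their term sets, parameter counts and log-likelihoods at
n = 119 complete cases.  Those printed summaries are inputs against which
this package's AICc, Akaike-weight and relative-importance arithmetic can be
recomputed end to end without access to the raw data (the raw data live in a
public archive; the loader below adapts such a table if a local copy is
available).
"""

from __future__ import annotations

import pandas as pd

from . import io as tio

#: Complete-case sample size shared by all candidate models.
BENCHMARK_N: int = 119

#: The 12 retained candidate models: fixed-term set, parameter count (fixed
#: coefficients + 3 random-intercept variances + residual), log-likelihood.
BENCHMARK_CANDIDATES: tuple[tuple[tuple[str, ...], int, float], ...] = (
    (("maternal_tl", "chick_size_day12"), 7, -298.25),
    (("experimental_group", "paternal_tl", "maternal_tl"), 8, -297.26),
    (("paternal_tl", "maternal_tl"), 7, -298.46),
    (("paternal_tl", "maternal_tl", "chick_size_day12"), 8, -297.31),
    (("experimental_group", "maternal_tl"), 7, -298.73),
    (("paternal_age", "maternal_tl", "chick_size_day12"), 8, -297.61),
    (("maternal_tl",), 6, -300.11),
    (("experimental_group", "maternal_tl", "chick_size_day12"), 8, -297.83),
    (("maternal_tl", "mass_rank", "chick_size_day12"), 8, -297.89),
    (("experimental_group", "paternal_age", "maternal_tl"), 8, -297.95),
    (("experimental_group", "paternal_tl", "maternal_tl", "chick_size_day12"), 9, -296.82),
    (("maternal_age", "maternal_tl", "chick_size_day12"), 8, -298.05),
)

#: AICc, dAICc and Akaike weight as printed for the same 12 models.
BENCHMARK_PRINTED: tuple[tuple[float, float, float], ...] = (
    (611.5, 0.0, 0.14),
    (611.83, 0.32, 0.12),
    (611.93, 0.43, 0.11),
    (611.93, 0.43, 0.11),
    (612.47, 0.97, 0.08),
    (612.53, 1.03, 0.08),
    (612.97, 1.46, 0.07),
    (612.97, 1.46, 0.07),
    (613.09, 1.58, 0.06),
    (613.22, 1.71, 0.06),
    (613.3, 1.79, 0.06),
    (613.41, 1.91, 0.05),
)

#: Other published point estimates useful as recomputation anchors.
BENCHMARK_ESTIMATES: dict[str, float] = {
    "h2_chick_level": 0.81,      # mid-parent slope, n = 122
    "h2_brood_level": 0.78,      # brood-mean slope, n = 37
    "full_average_maternal_tl": 0.57,
    "fledging_glmm_coefficient": -4.89,
    "control_brood_mean": 5.07,
    "enlarged_brood_mean": 8.05,
}


def benchmark_candidate_table() -> pd.DataFrame:
    """The retained candidate set as a DataFrame (one row per model)."""
    rows = []
    for (terms, k, ll), (aicc_p, delta_p, w_p) in zip(
        BENCHMARK_CANDIDATES, BENCHMARK_PRINTED
    ):
        rows.append(
            {
                "terms": terms,
                "k": k,
                "loglik": ll,
                "n": BENCHMARK_N,
                "aicc_printed": aicc_p,
                "delta_printed": delta_p,
                "weight_printed": w_p,
            }
        )
    return pd.DataFrame(rows)


def load_benchmark_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Adapt a locally downloaded benchmark CSV to the canonical schema.

    ``column_map`` renames the file's columns to this package's phenotype
    schema (see :mod:`telogel.io`); the core pipeline never depends on the
    external file's layout.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    table, _ = tio.validate_phenotype_table(df)
    return table
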