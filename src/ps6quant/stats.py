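"""Group statistics: Mann–Whitney U, log activation ratios, region report.

Each learning group is compared against the control group per brain region
with a two-sided Mann–Whitney U test on the per-animal pooled stained-area
fractions.  The per-region effect size is the activation log-ratio
``log10(mean_group / mean_control)``.  Significance is reported at
uncorrected p < alpha (one star per region, as in the source analysis); a
Benjamini–Hochberg option exists but is off by default.

The U statistic uses the pair-count convention with half-credit for ties:
``U_x = #{(i, j): x_i > y_j} + 0.5 * #{x_i = y_j}``.  For pooled sample
sizes up to 20 without ties the two-sided p-value is exact — the
probability, over all C(n1+n2, n1) equally likely group labelings, of a U
at least as far from its null mean as observed.  Ties or larger samples
fall back to the normal approximation with tie-corrected variance and a
0.5 continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .regions import CONTROL_GROUP

__all__ = [
    "UTestResult",
    "mann_whitney_u",
    "group_means",
    "activation_log_ratio",
    "ActivationReport",
    "build_report",
    "error_calibration",
]

EXACT_MAX_N = 20  # largest pooled sample size for the exact null distribution


@dataclass(frozen=True)
class UTestResult:
    U_x: float
    U_y: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    tie_correction_applied: bool


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts of n1-subsets of ranks 1..n1+n2 by U.

    Subset-sum dynamic program over the pooled ranks; index u holds the
    number of labelings with U_x == u.  Total mass is C(n1+n2, n1).
    """
    n = n1 + n2
    max_sum = n1 * n2 + n1 * (n1 + 1) // 2
    # f[j, s] = number of j-subsets of {1..i} with rank sum s, i ascending
    f = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    f[0, 0] = 1
    for i in range(1, n + 1):
        for j in range(min(i, n1), 0, -1):
            f[j, i:] += f[j - 1, :-i]
    offset = n1 * (n1 + 1) // 2  # U = rank_sum - offset
    return f[n1, offset:offset + n1 * n2 + 1].astype(float)


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    # compare |2U - n1*n2| so everything stays integral for tie-free data
    d_obs = abs(2 * u - n1 * n2)
    us = np.arange(n1 * n2 + 1)
    extreme = np.abs(2 * us - n1 * n2) >= d_obs - 1e-9
    return float(counts[extreme].sum() / total)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann–Whitney U test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_x = float(r1 - n1 * (n1 + 1) / 2)
    u_y = float(n1 * n2 - u_x)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(u_x, n1, n2)
        return UTestResult(u_x, u_y, p, "exact", False)

    n = n1 + n2
    mu = n1 * n2 / 2
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return UTestResult(u_x, u_y, 1.0, "normal_approx", has_ties)
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2 * float(norm.sf(max(z, 0.0))))
    return UTestResult(u_x, u_y, p, "normal_approx", has_ties)


def mann_whitney_u_bruteforce(x: Sequence[float], y: Sequence[float]) -> float:
    """Independent oracle: two-sided p by explicit labeling enumeration.

    Enumerates every C(n1+n2, n1) assignment of the pooled values to the
    first sample and counts assignments with |U - n1*n2/2| at least as
    large as observed.  Exponential; for cross-checks at small n only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        diff = a[:, None] - b[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    d_obs = abs(u_stat(x, y) - n1 * n2 / 2)
    idx = np.arange(n1 + n2)
    extreme = total = 0
    for combo in itertools.combinations(idx, n1):
        sel = np.zeros(n1 + n2, dtype=bool)
        sel[list(combo)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - n1 * n2 / 2) >= d_obs - 1e-9:
            extreme += 1
    return extreme / total


def group_means(table: Mapping[tuple[str, str], Sequence[float]] | pd.DataFrame,
                ) -> pd.DataFrame:
    """Arithmetic mean of per-animal pooled fractions per (group, region)."""
    if isinstance(table, pd.DataFrame):
        if table.empty:
            raise ValueError("empty measurement table")
        out = (table.groupby(["group", "region"], sort=False)["fraction"]
               .agg(n="size", mean="mean").reset_index())
        return out
    rows = []
    for (g, r), vals in table.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty cell for {(g, r)}")
        rows.append({"group": g, "region": r, "n": vals.size,
                     "mean": float(vals.mean())})
    return pd.DataFrame(rows, columns=["group", "region", "n", "mean"])


def activation_log_ratio(group_mean: float, control_mean: float,
                         base: float = 10.0) -> float:
    """log_base(group_mean / control_mean); errors on non-positive means."""
    if group_mean <= 0 or control_mean <= 0:
        raise ValueError("activation log-ratio requires strictly positive "
                         f"means, got {group_mean} / {control_mean}")
    return math.log(group_mean / control_mean, base)


REPORT_COLUMNS = ["region", "group", "n", "n_control", "mean", "mean_control",
                  "U", "p", "method", "log10_ratio", "significant"]


@dataclass
class ActivationReport:
    """Per (learning group, region) comparison table against control."""

    frame: pd.DataFrame
    alpha: float
    log_base: float
    control_group: str

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=1)


def build_report(measurements: pd.DataFrame, control_group: str = CONTROL_GROUP,
                 alpha: float = 0.05, log_base: float = 10.0,
                 correction: str | None = None) -> ActivationReport:
    """Assemble the per-region activation report from pooled measurements.

    ``measurements`` must carry one row per animal x region with columns
    ``animal_id, group, region, fraction`` (the quantify contract).  Each
    learning group is tested against control per region; p-values are
    uncorrected unless ``correction="bh"`` (Benjamini–Hochberg across the
    report, applied to the significance flag only).
    """
    groups = list(pd.unique(measurements["group"]))
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} missing from data")
    regions = list(pd.unique(measurements["region"]))
    learning = [g for g in groups if g != control_group]

    rows = []
    for g in learning:
        for region in regions:
            x = measurements.query("group == @g and region == @region")[
                "fraction"].to_numpy()
            y = measurements.query("group == @control_group and region == @region")[
                "fraction"].to_numpy()
            if x.size == 0 or y.size == 0:
                raise ValueError(f"no measurements for {(g, region)} vs control")
            res = mann_whitney_u(x, y)
            rows.append({
                "region": region, "group": g, "n": x.size, "n_control": y.size,
                "mean": float(x.mean()), "mean_control": float(y.mean()),
                "U": res.U_x, "p": res.p_value, "method": res.method,
                "log10_ratio": activation_log_ratio(float(x.mean()),
                                                    float(y.mean()), log_base),
                "significant": bool(res.p_value < alpha),
            })
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        rej, p_adj, _, _ = multipletests(frame["p"], alpha=alpha, method="fdr_bh")
        frame["p_adjusted"] = p_adj
        frame["significant"] = rej
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return ActivationReport(frame=frame, alpha=alpha, log_base=log_base,
                            control_group=control_group)


@dataclass(frozen=True)
class CalibrationResult:
    rate: float
    n_rejections: int
    n_reps: int
    effect_multiplier: float
    alpha: float


def error_calibration(n1: int, n2: int, alpha: float = 0.05,
                      n_reps: int = 1000, effect_multiplier: float = 1.0,
                      seed: int = 0, field_spec=None,
                      rois_per_animal: int = 2) -> CalibrationResult:
    """Monte-Carlo type-I error (multiplier 1.0) or power of the pipeline.

    Each replicate generates a fresh single-region two-group cohort
    (``n1`` treated vs ``n2`` control animals) through the image
    generator, quantifies every ROI with the default threshold rule, pools
    per animal and applies the two-sided U test at ``alpha``.  Returns the
    rejection fraction.  Simulation fields default to a reduced 96x96 px
    frame with 2 ROIs per animal, keeping replicates cheap while exercising
    the full image path.
    """
    from .quantify import measure_records
    from .synthetic import CohortSpec, StainFieldSpec, generate_cohort

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable rate")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    if field_spec is None:
        field_spec = StainFieldSpec(image_shape=(96, 96))
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_reps)]
    rejections = 0
    for rep_seed in rep_seeds:
        spec = CohortSpec(
            regions=("ROI",), groups=("control", "treated"),
            n_per_group={"control": n2, "treated": n1},
            rois_per_region=rois_per_animal,
            activation_multiplier={("treated", "ROI"): effect_multiplier},
            base_field=field_spec, seed=rep_seed)
        cohort = generate_cohort(spec)
        _, pooled = measure_records(cohort.records)
        x = pooled.loc[pooled["group"] == "treated", "fraction"].to_numpy()
        y = pooled.loc[pooled["group"] == "control", "fraction"].to_numpy()
        if mann_whitney_u(x, y).p_value < alpha:
            rejections += 1
    return CalibrationResult(rate=rejections / n_reps, n_rejections=rejections,
                             n_reps=n_reps, effect_multiplier=effect_multiplier,
                             alpha=alpha)
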