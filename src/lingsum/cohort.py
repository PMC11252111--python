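"""Synthetic ET + Bayley cohort generator.

No child-level data from the original study are available, so this module
generates cohorts carrying the statistical structure the summarization
pipeline is meant to detect: an ASD group (n=61, ages ~34.9 months) whose
visual attention favours animation videos over social-interaction (SI) videos,
a TD group (n=72, ages ~32.9 months) with the opposite preference, a
within-child attention budget that induces the negative cross-AOI trade-off
(high animation dwell implies low SI dwell), Bayley composites on the standard
100/15 scale (ASD shifted down 1.5 SD) with positive within-child correlation,
and subscale age-equivalents tied to the matching composite so that low
composites translate into "behind by age" differences.

All durations are truncated log-normal (non-negative, right-skewed; animation
dwell spans roughly the 590-13051 ms range observed in the study), counts are
Poisson, and every draw is routed through a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "generate_cohort", "degrade_cohort",
           "ET_FEATURES", "BAYLEY_COMPOSITES", "BAYLEY_AGE_EQUIVALENTS"]

AOIS = ("si", "anim")
ET_FEATURES = (
    "net_dwell_ms", "dwell_ms", "glance_duration_ms", "diversion_duration_ms",
    "first_fixation_duration_ms", "fixation_count", "fixation_time_ms",
    "entry_time_ms", "revisit", "glances_count", "average_fixation_duration_ms",
)
BAYLEY_COMPOSITES = ("cognitive_composite", "language_composite",
                     "motor_composite")
BAYLEY_AGE_EQUIVALENTS = ("cognitive_age_months", "receptive_communication_months",
                          "expressive_communication_months", "fine_motor_months",
                          "gross_motor_months")
# which composite drives each age-equivalent subscale
_SUBSCALE_COMPOSITE = {
    "cognitive_age_months": "cognitive_composite",
    "receptive_communication_months": "language_composite",
    "expressive_communication_months": "language_composite",
    "fine_motor_months": "motor_composite",
    "gross_motor_months": "motor_composite",
}


@dataclass(frozen=True)
class GroupParams:
    """Per-group generator parameters."""

    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    anim_share_mean: float  # mean fraction of the attention budget on animation
    share_concentration: float = 8.0
    bayley_mean: float = 100.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the study cohort: 61 ASD children (ages 28-36, mean 34.85)
    preferring animation, 72 TD children (ages 26-36, mean 32.90) preferring
    SI, trade-off strength rho in [-1, 0], Bayley composite correlation r in
    [0, 1], ASD composites shifted down 1.5 SD.
    """

    n_asd: int = 61
    n_td: int = 72
    seed: int = 0
    rho: float = -0.8
    bayley_corr: float = 0.6
    bayley_sd: float = 15.0
    asd_bayley_shift_sd: float = -1.5
    budget_median_ms: float = 9000.0
    # age_mean/age_sd parameterise the latent normal before truncation to
    # age_range; these defaults realise observed means of 34.85 (ASD) and
    # 32.90 (TD) months after truncation
    asd: GroupParams = field(default_factory=lambda: GroupParams(
        35.53, 1.2, (28.0, 36.0), anim_share_mean=0.78,
        share_concentration=16.0))
    td: GroupParams = field(default_factory=lambda: GroupParams(
        33.57, 2.4, (26.0, 36.0), anim_share_mean=0.25,
        share_concentration=16.0))
    planted_associations: tuple = ()
    # each: (group, pre_column, pre_label, summ_column, summ_label, strength)

    def __post_init__(self) -> None:
        if self.n_asd < 0 or self.n_td < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not (-1.0 <= self.rho <= 0.0):
            raise ValueError("rho must lie in [-1, 0]")
        if not (0.0 <= self.bayley_corr <= 1.0):
            raise ValueError("bayley_corr must lie in [0, 1]")
        if self.budget_median_ms <= 0:
            raise ValueError("budget must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # redraw out-of-range values
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _generate_group(rng: np.random.Generator, spec: CohortSpec,
                    params: GroupParams, group: str, n: int,
                    start_id: int) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame()
    age = _truncated_normal(rng, params.age_mean, params.age_sd,
                            *params.age_range, n)

    # attention budget and animation share: anim = share * budget,
    # si = (1 - share) * budget; the shared budget induces the cross-AOI
    # trade-off, with |rho| shrinking budget variability so the share term
    # (negatively coupled between AOIs) dominates
    budget_sigma = max(0.4 * (1.0 - abs(spec.rho)), 0.05)
    budget = spec.budget_median_ms * np.exp(rng.normal(0.0, budget_sigma, n))
    budget = np.clip(budget, 1200.0, 26000.0)
    kappa = params.share_concentration
    m = params.anim_share_mean
    share = rng.beta(m * kappa, (1.0 - m) * kappa, n)
    share = np.clip(share, 0.02, 0.98)

    cols: dict[str, np.ndarray] = {
        "child_id": np.array([f"c{start_id + i:03d}" for i in range(n)]),
        "group": np.repeat(group, n),
        "chron_age_months": np.round(age, 1),
    }
    for aoi in AOIS:
        s = share if aoi == "anim" else 1.0 - share
        dwell = s * budget * np.exp(rng.normal(0.0, 0.08, n))
        dwell = np.clip(dwell, 100.0, None)
        net = dwell * rng.uniform(0.65, 0.92, n)
        fix_time = net * rng.uniform(0.85, 1.0, n)
        fix_count = np.maximum(rng.poisson(fix_time / 280.0), 1)
        cols[f"{aoi}_dwell_ms"] = np.round(dwell, 1)
        cols[f"{aoi}_net_dwell_ms"] = np.round(net, 1)
        cols[f"{aoi}_fixation_time_ms"] = np.round(fix_time, 1)
        cols[f"{aoi}_fixation_count"] = fix_count
        cols[f"{aoi}_average_fixation_duration_ms"] = np.round(
            fix_time / fix_count, 1)
        cols[f"{aoi}_glance_duration_ms"] = np.round(
            dwell * rng.uniform(0.05, 0.18, n), 1)
        cols[f"{aoi}_diversion_duration_ms"] = np.round(
            dwell * rng.uniform(0.05, 0.20, n), 1)
        cols[f"{aoi}_first_fixation_duration_ms"] = np.round(
            np.clip(300.0 * np.exp(rng.normal(0.0, 0.4, n)), 50.0, 2000.0), 1)
        # preferred AOI is entered earlier
        cols[f"{aoi}_entry_time_ms"] = np.round(
            np.clip((400.0 + 3000.0 * (1.0 - s))
                    * np.exp(rng.normal(0.0, 0.3, n)), 30.0, 15000.0), 1)
        cols[f"{aoi}_revisit"] = rng.poisson(2.0 + 5.0 * s, n)
        cols[f"{aoi}_glances_count"] = (
            cols[f"{aoi}_revisit"] + rng.poisson(2.0, n))

    # Bayley composites: correlated trivariate normal on the 100/15 scale
    shift = spec.asd_bayley_shift_sd * spec.bayley_sd if group == "ASD" else 0.0
    r = spec.bayley_corr
    cov = spec.bayley_sd ** 2 * (np.full((3, 3), r) + (1 - r) * np.eye(3))
    comps = rng.multivariate_normal(
        np.repeat(params.bayley_mean + shift, 3), cov, size=n)
    comps = np.clip(np.round(comps), 40, 160)
    for j, name in enumerate(BAYLEY_COMPOSITES):
        cols[name] = comps[:, j]

    # age-equivalents: chronological age shifted by the matching composite
    # (4 months per population SD) plus subscale noise
    for name, comp in _SUBSCALE_COMPOSITE.items():
        offset = (cols[comp] - 100.0) / spec.bayley_sd * 4.0
        ae = age + offset + rng.normal(0.0, 1.5, n)
        cols[name] = np.round(np.clip(ae, 1.0, None), 1)

    return pd.DataFrame(cols)


def _label_bounds(values: np.ndarray, label: str) -> tuple[float, float]:
    """Value range standing for a linguistic label, via within-group quantiles."""
    three = {"low": (0.0, 1 / 3), "medium": (1 / 3, 2 / 3), "high": (2 / 3, 1.0)}
    five = {"far behind": (0.0, 0.2), "behind": (0.2, 0.4), "equal": (0.4, 0.6),
            "ahead": (0.6, 0.8), "far ahead": (0.8, 1.0)}
    qlo, qhi = (three | five)[label]
    return (float(np.quantile(values, qlo)), float(np.quantile(values, qhi)))


def _plant_associations(df: pd.DataFrame, spec: CohortSpec,
                        rng: np.random.Generator) -> pd.DataFrame:
    for group, pre_col, pre_label, summ_col, summ_label, strength in \
            spec.planted_associations:
        if not (0.0 <= strength <= 1.0):
            raise ValueError("association strength must lie in [0, 1]")
        sub = df.index[df["group"] == group]
        if len(sub) == 0:
            continue
        pre_vals = df.loc[sub, pre_col].to_numpy(dtype=float)
        lo, hi = _label_bounds(pre_vals, pre_label)
        hit = sub[(pre_vals >= lo) & (pre_vals <= hi)]
        summ_vals = df.loc[sub, summ_col].to_numpy(dtype=float)
        tlo, thi = _label_bounds(summ_vals, summ_label)
        integral = pd.api.types.is_integer_dtype(df[summ_col])
        for i in hit:
            if rng.random() < strength:
                v = rng.uniform(tlo, thi)
                df.loc[i, summ_col] = int(round(v)) if integral else v
    return df


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a cohort table; identical spec and seed give identical output."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = [
        _generate_group(rng, spec, spec.asd, "ASD", spec.n_asd, 0),
        _generate_group(rng, spec, spec.td, "TD", spec.n_td, spec.n_asd),
    ]
    df = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    if spec.planted_associations:
        df = _plant_associations(df, spec, rng)
    return df


def degrade_cohort(df: pd.DataFrame, missing_bayley_fraction: float,
                   seed: int = 0) -> pd.DataFrame:
    """Blank the Bayley block for a seeded random subset of children.

    Emulates children who completed the eye-tracking session but not the
    Bayley assessment; downstream summarization excludes them.
    """
    if not (0.0 <= missing_bayley_fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    out = df.copy()
    n_missing = int(round(missing_bayley_fraction * len(out)))
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(out), size=n_missing, replace=False)
    bayley_cols = list(BAYLEY_COMPOSITES) + list(BAYLEY_AGE_EQUIVALENTS)
    out.loc[out.index[rows], bayley_cols] = np.nan
    return out
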