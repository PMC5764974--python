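"""Synthetic fingerprint and toxicity data with the structure the analysis assumes.

The default scenario emulates the study regime: 21 batch fingerprints over
10 common peaks with high batch-to-batch cosine similarity (> 0.9), two
planted toxic peaks (9 and 10, minor constituents by area), and per-animal
serum ALT/AST responses whose group means span roughly 3800-17000 U/L (ALT)
above control baselines of 32 / 83 U/L.  Peak areas are per-peak base levels
times lognormal batch factors; enzyme group means are baseline plus a linear
contribution of the toxic-peak areas; animals vary lognormally around the
group mean with a fixed coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equivalence import ToxicityGroup
from .fingerprint import Chromatogram, CommonPeakTable
from .io import ToxicityTable

__all__ = [
    "ScenarioConfig",
    "generate_fingerprints",
    "generate_chromatograms",
    "generate_toxicity",
    "generate_control_group",
    "generate_equivalence_groups",
    "calibration_points",
    "ground_truth",
]

# Default per-peak base area levels (arbitrary detector units).  Peaks 9 and
# 10 are deliberately minor constituents: small relative area, large
# toxicological leverage, mirroring diterpenoid-lactone markers hidden in a
# flavonoid-dominated fingerprint.
_BASE_AREAS = (18.0, 14.0, 12.0, 16.0, 10.0, 9.0, 7.0, 6.0, 1.5, 2.0)

# Consensus retention times (min) for the ten common peaks.
_COMMON_RTS = (12.4, 13.2, 17.5, 19.7, 22.8, 24.2, 33.5, 34.6, 43.7, 44.5)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition parameters for the synthetic default scenario."""

    n_samples: int = 21
    n_peaks: int = 10
    toxic_peaks: tuple[int, ...] = (9, 10)
    # U/L of group-mean enzyme per unit area, keyed like toxic_peaks: ALT
    # effects then AST effects (balanced so both markers carry comparable
    # toxicological weight, peak 10 slightly stronger).
    alt_effects: tuple[float, ...] = (2400.0, 1850.0)
    ast_effects: tuple[float, ...] = (1200.0, 950.0)
    baseline_alt: float = 32.0
    baseline_ast: float = 83.0
    noise_cv: float = 0.30
    animals_per_group: int = 10
    # Batch structure: matrix peaks share a batch-strength factor plus small
    # idiosyncratic variation (keeping fingerprint similarity high), while
    # the minor toxic peaks vary several-fold around a shared biosynthetic
    # factor (corr toxic_corr), driving the toxicity spread.
    area_lognormal_sigma: float = 0.05
    toxic_area_sigma: float = 0.50
    batch_sigma: float = 0.12
    toxic_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.toxic_peaks) <= set(range(1, self.n_peaks + 1)):
            raise ValueError("toxic_peaks must be peak ids in 1..n_peaks")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if len(self.alt_effects) != len(self.toxic_peaks) or len(
            self.ast_effects
        ) != len(self.toxic_peaks):
            raise ValueError("one ALT and one AST effect size per toxic peak")
        if not 0 <= self.toxic_corr < 1:
            raise ValueError("toxic_corr must be in [0, 1)")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def _base_areas(c: ScenarioConfig) -> np.ndarray:
    base = np.array(_BASE_AREAS, dtype=float)
    if c.n_peaks <= base.size:
        return base[: c.n_peaks]
    extra = np.full(c.n_peaks - base.size, 5.0)
    return np.concatenate([base, extra])


def generate_fingerprints(c: ScenarioConfig) -> CommonPeakTable:
    """Common-peak table: base level x lognormal(0, sigma) batch factors."""
    rng = np.random.default_rng(c.seed)
    base = _base_areas(c)
    n, p = c.n_samples, c.n_peaks
    tox = [q - 1 for q in c.toxic_peaks]
    sigmas = np.full(p, c.area_lognormal_sigma)
    sigmas[tox] = c.toxic_area_sigma
    z = rng.standard_normal((n, p))
    # the toxic (biosynthetically related) peaks co-vary around a shared
    # pathway factor; the matrix peaks ride the batch-strength factor instead
    g = rng.standard_normal((n, 1))
    z[:, tox] = math.sqrt(c.toxic_corr) * g + math.sqrt(1.0 - c.toxic_corr) * z[:, tox]
    batch_mask = np.ones(p)
    batch_mask[tox] = 0.0
    batch = np.exp(c.batch_sigma * rng.standard_normal((n, 1)))
    factors = batch**batch_mask * np.exp(sigmas * z)
    rts = np.array(_COMMON_RTS[: c.n_peaks])
    if rts.size < c.n_peaks:
        rts = np.concatenate([rts, 45.0 + np.arange(c.n_peaks - rts.size)])
    return CommonPeakTable(
        sample_ids=[f"S{i + 1:02d}" for i in range(c.n_samples)],
        peak_ids=list(range(1, c.n_peaks + 1)),
        areas=base * factors,
        rts=rts,
    )


def generate_chromatograms(
    c: ScenarioConfig, n_minor: int = 3, minor_fraction: float = 0.12
) -> list[Chromatogram]:
    """Peak lists with the common peaks plus sample-specific minor peaks.

    Minor peaks carry about ``minor_fraction`` of each sample's total area at
    sample-specific retention times, so the common peaks keep > 80% of the
    overall area and minor peaks never form complete cross-sample groups.
    """
    table = generate_fingerprints(c)
    rng = np.random.default_rng(c.seed + 1)
    # rt windows well clear of every consensus rt, so minor peaks never fold
    # into a common-peak group at the default 0.5 min tolerance
    windows = [2.0, 26.5, 36.5, 48.0, 55.0][:n_minor]
    chroms = []
    for i, sid in enumerate(table.sample_ids):
        rts = table.rts + rng.uniform(-0.05, 0.05, size=table.n_peaks)
        peaks = list(zip(rts, table.areas[i]))
        total = table.areas[i].sum()
        minor_total = total * minor_fraction / (1 - minor_fraction)
        shares = rng.dirichlet(np.ones(n_minor)) * minor_total
        # each minor peak is present in only some samples, so minor groups
        # are never complete across samples
        for k, w in enumerate(windows):
            if rng.random() < 0.7:
                peaks.append((float(w + rng.uniform(0.0, 2.0)), float(shares[k])))
        peaks.sort()
        chroms.append(Chromatogram(sample_id=sid, peaks=peaks))
    return chroms


def _mean_responses(table: CommonPeakTable, c: ScenarioConfig) -> pd.DataFrame:
    idx = [table.peak_ids.index(p) for p in c.toxic_peaks]
    toxic_areas = table.areas[:, idx]
    alt = c.baseline_alt + toxic_areas @ np.array(c.alt_effects)
    ast = c.baseline_ast + toxic_areas @ np.array(c.ast_effects)
    return pd.DataFrame(
        {"sample_id": table.sample_ids, "alt_mean": alt, "ast_mean": ast}
    )


def _lognormal_around(rng, mean: float, cv: float, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log(1.0 + cv**2))
    # mean-preserving lognormal: E[exp(mu + sigma Z)] = mean
    mu = math.log(mean) - 0.5 * sigma**2
    return np.exp(mu + sigma * rng.standard_normal(n))


def generate_toxicity(table: CommonPeakTable, c: ScenarioConfig) -> ToxicityTable:
    """Per-animal ALT/AST values, lognormal around the per-sample means."""
    missing = set(c.toxic_peaks) - set(table.peak_ids)
    if missing:
        raise ValueError(f"toxic peaks {sorted(missing)} not in the table")
    rng = np.random.default_rng(c.seed + 2)
    means = _mean_responses(table, c)
    rows = []
    for rec in means.itertuples(index=False):
        alt = _lognormal_around(rng, rec.alt_mean, c.noise_cv, c.animals_per_group)
        ast = _lognormal_around(rng, rec.ast_mean, c.noise_cv, c.animals_per_group)
        for a in range(c.animals_per_group):
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "animal": a + 1,
                    "alt": alt[a],
                    "ast": ast[a],
                }
            )
    return ToxicityTable(pd.DataFrame(rows))


def generate_control_group(c: ScenarioConfig, cv: float = 0.19) -> pd.DataFrame:
    """Vehicle-control animals around the baseline ALT/AST levels."""
    rng = np.random.default_rng(c.seed + 3)
    alt = _lognormal_around(rng, c.baseline_alt, cv, c.animals_per_group)
    ast = _lognormal_around(rng, c.baseline_ast, cv, c.animals_per_group)
    return pd.DataFrame(
        {
            "sample_id": "control",
            "animal": np.arange(1, c.animals_per_group + 1),
            "alt": alt,
            "ast": ast,
        }
    )


def generate_equivalence_groups(
    geo_mean_ratio: float,
    cv: float,
    n: int,
    seed: int = 0,
    original_geo_mean: float = 8000.0,
    labels: tuple[str, str] = ("candidate", "original"),
) -> tuple[ToxicityGroup, ToxicityGroup]:
    """Two lognormal groups with a prescribed population geometric-mean ratio."""
    if geo_mean_ratio <= 0 or cv <= 0:
        raise ValueError("ratio and cv must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    cand = (original_geo_mean * geo_mean_ratio) * np.exp(
        sigma * rng.standard_normal(n)
    )
    orig = original_geo_mean * np.exp(sigma * rng.standard_normal(n))
    return ToxicityGroup(labels[0], cand), ToxicityGroup(labels[1], orig)


def calibration_points(
    slope: float,
    intercept: float,
    r2: float,
    conc_range: tuple[float, float],
    n: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic calibration standards that refit to the given line exactly.

    Concentrations are spread over ``conc_range``; responses sit on the line
    plus a residual vector orthogonal to the design (so OLS recovers slope
    and intercept exactly) whose norm is set so the refitted coefficient of
    determination equals ``r2``.  Deterministic; stands in for undeposited
    raw calibration standards.
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    x = np.linspace(conc_range[0], conc_range[1], n)
    line = slope * x + intercept
    if r2 == 1.0:
        return x, line
    raw = np.array([(-1.0) ** k for k in range(n)])
    X = np.column_stack([np.ones(n), x])
    resid = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0]
    resid /= np.linalg.norm(resid)
    ss_reg = float(((line - line.mean()) ** 2).sum())
    ss_res = ss_reg * (1.0 - r2) / r2
    return x, line + resid * math.sqrt(ss_res)


def ground_truth(c: ScenarioConfig) -> dict:
    """Planted structure of a scenario, for provenance files."""
    return {
        "toxic_peaks": list(c.toxic_peaks),
        "alt_effects": list(c.alt_effects),
        "ast_effects": list(c.ast_effects),
        "baseline_alt": c.baseline_alt,
        "baseline_ast": c.baseline_ast,
        "noise_cv": c.noise_cv,
        "area_lognormal_sigma": c.area_lognormal_sigma,
        "toxic_area_sigma": c.toxic_area_sigma,
        "batch_sigma": c.batch_sigma,
        "toxic_corr": c.toxic_corr,
        "seed": c.seed,
    }
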