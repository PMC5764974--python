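"""Common-peak table construction and Pharmacopoeia-style similarity analysis.

Batch fingerprints are reduced to a samples x common-peaks area matrix: a
"common peak" is a retention-time group that contains exactly one peak from
every sample.  The reference fingerprint is the per-peak median across
samples and batch-to-batch consistency is measured with the cosine
(congruence) coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "CommonPeakTable",
    "SimilarityReport",
    "match_common_peaks",
    "reference_fingerprint",
    "similarity",
    "similarity_report",
    "read_peak_list_csv",
    "write_peak_list_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class Chromatogram:
    """A single sample's peak list: (retention time [min], area) pairs."""

    sample_id: str
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"{self.sample_id}: retention times must strictly increase")
        if any(area < 0 for _, area in self.peaks):
            raise ValueError(f"{self.sample_id}: peak areas must be >= 0")


@dataclass
class CommonPeakTable:
    """Samples x common-peaks area matrix with consensus retention times."""

    sample_ids: list[str]
    peak_ids: list[int]
    areas: np.ndarray  # shape (n_samples, n_peaks)
    rts: np.ndarray  # shape (n_peaks,), consensus rt per peak (min)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.rts = np.asarray(self.rts, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ValueError("areas shape does not match sample_ids x peak_ids")
        if np.any(self.areas < 0):
            raise ValueError("areas must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, columns=[f"peak_{p}" for p in self.peak_ids])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CommonPeakTable":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ValueError("common-peak CSV must have a sample_id column")
        peak_cols = [c for c in df.columns if c.startswith("peak_")]
        peak_ids = [int(c.removeprefix("peak_")) for c in peak_cols]
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            peak_ids=peak_ids,
            areas=df[peak_cols].to_numpy(dtype=float),
            rts=np.full(len(peak_ids), np.nan),
        )


def match_common_peaks(
    chroms: Sequence[Chromatogram], rt_tol: float = 0.5
) -> CommonPeakTable:
    """Group peaks across samples by retention time and keep complete groups.

    Peaks from all samples are pooled, sorted by rt and grouped greedily: a
    peak joins the current group while its rt is within ``rt_tol`` of the
    group's most recent member.  Only groups with exactly one peak from every
    sample become common peaks; groups with two peaks from one sample (an rt
    collision) are rejected with a logged reason.  Consensus rt is the median
    of member rts.
    """
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromatograms")
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    pooled = sorted(
        (rt, area, c.sample_id) for c in chroms for rt, area in c.peaks
    )
    groups: list[list[tuple[float, float, str]]] = []
    for rec in pooled:
        if groups and rec[0] - groups[-1][-1][0] <= rt_tol:
            groups[-1].append(rec)
        else:
            groups.append([rec])

    sample_ids = [c.sample_id for c in chroms]
    kept: list[tuple[float, dict[str, float]]] = []
    for g in groups:
        seen: dict[str, float] = {}
        collision = False
        for rt, area, sid in g:
            if sid in seen:
                collision = True
            seen[sid] = area
        med_rt = float(np.median([rt for rt, _, _ in g]))
        if collision:
            logger.info("rt group at %.3f min rejected: rt collision within a sample", med_rt)
            continue
        if len(seen) != len(sample_ids):
            continue  # not present in every sample -> not a common peak
        kept.append((med_rt, seen))

    kept.sort(key=lambda k: k[0])
    areas = np.array(
        [[areas_by_sample[sid] for _, areas_by_sample in kept] for sid in sample_ids]
    ).reshape(len(sample_ids), len(kept))
    return CommonPeakTable(
        sample_ids=sample_ids,
        peak_ids=list(range(1, len(kept) + 1)),
        areas=areas,
        rts=np.array([rt for rt, _ in kept]),
    )


def reference_fingerprint(t: CommonPeakTable) -> np.ndarray:
    """Median reference fingerprint: per-peak median area across samples."""
    if t.n_samples == 0 or t.n_peaks == 0:
        raise ValueError("common-peak table is empty")
    return np.median(t.areas, axis=0)


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine (congruence) coefficient between two fingerprint vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size == 0:
        raise ValueError("vectors must be 1-D, non-empty and of equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class SimilarityReport:
    """Per-sample similarity against the median reference + pairwise matrix."""

    reference: np.ndarray
    per_sample: dict[str, float]
    pairwise: pd.DataFrame = field(repr=False)

    def summary(self) -> dict[str, float]:
        vals = np.array(list(self.per_sample.values()))
        return {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
        }


def similarity_report(t: CommonPeakTable) -> SimilarityReport:
    """Similarity of every sample against the median reference fingerprint."""
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    ref = reference_fingerprint(t)
    per_sample = {
        sid: similarity(t.areas[i], ref) for i, sid in enumerate(t.sample_ids)
    }
    n = t.n_samples
    pw = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pw[i, j] = pw[j, i] = similarity(t.areas[i], t.areas[j])
    pairwise = pd.DataFrame(pw, index=t.sample_ids, columns=t.sample_ids)
    return SimilarityReport(reference=ref, per_sample=per_sample, pairwise=pairwise)


def read_peak_list_csv(path) -> list[Chromatogram]:
    """Read a long-format peak list (sample_id, rt_min, area) into chromatograms."""
    df = pd.read_csv(path)
    required = {"sample_id", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak-list CSV must have columns {sorted(required)}")
    chroms = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("rt_min")
        chroms.append(
            Chromatogram(
                sample_id=str(sid),
                peaks=list(zip(grp["rt_min"].astype(float), grp["area"].astype(float))),
            )
        )
    return chroms


def write_peak_list_csv(chroms: Sequence[Chromatogram], path) -> None:
    rows = [
        {"sample_id": c.sample_id, "rt_min": rt, "area": area}
        for c in chroms
        for rt, area in c.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
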