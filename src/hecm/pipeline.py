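"""End-to-end orchestration of the marker-screening strategy.

The pipeline runs fingerprint similarity, PLS-VIP screening, BP-ANN-MIV
screening and column clustering on a common-peak table plus per-animal
toxicity data, combines the screens into a final marker selection, and
optionally tests hepatotoxic equivalence of candidate marker mixtures
against whole extracts.  The final selection rule is conservative: a peak
is a marker when its VIP exceeds the threshold AND it sits within the top-k
MIV ranks, with k the size of the VIP selection; cluster co-membership with
the ALT/AST endpoints is reported as supporting evidence, not a gate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import yaml

from . import __version__
from .bpann import miv as _miv
from .bpann import rank_variables, train_bpann
from .clustering import cluster_heatmap
from .equivalence import ToxicityGroup, equivalence_ci, equivalence_decision
from .fingerprint import CommonPeakTable, similarity_report
from .io import ToxicityTable, read_toxicity_csv
from .pls import fit_pls, screen_by_vip, vip

__all__ = ["PipelineConfig", "HECMReport", "run_pipeline", "validate_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the screening strategy, with study defaults."""

    rt_tol: float = 0.5  # min, common-peak grouping tolerance
    vip_threshold: float = 1.0
    n_components: "int | None" = None  # None -> LOO-CV choice
    hidden: int = 3
    epochs: int = 5000
    lr: float = 0.05
    momentum: float = 0.0
    miv_delta: float = 0.10
    miv_rank_by: str = "signed"
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    alpha: float = 0.10
    limits: tuple[float, float] = (0.70, 1.43)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "limits" in raw:
            raw["limits"] = tuple(raw["limits"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class HECMReport:
    """Serializable record of every stage's outputs plus provenance."""

    similarity: dict
    vip: dict
    miv: dict
    cluster: dict
    selected_markers: list[int]
    equivalence: "dict | None"
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "HECMReport":
        d = json.loads(text)
        d["selected_markers"] = [int(p) for p in d["selected_markers"]]
        return cls(**d)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def _check_node(node: Any, schema: dict, path: str, errors: list[str]) -> None:
    t = schema.get("type")
    if t is not None:
        allowed = t if isinstance(t, list) else [t]
        pytypes_list: list[type] = []
        for name in allowed:
            t_entry = _TYPES[name]
            pytypes_list.extend(t_entry if isinstance(t_entry, tuple) else [t_entry])
        pytypes = tuple(pytypes_list)
        if not isinstance(node, pytypes):
            errors.append(f"{path}: expected {allowed}, got {type(node).__name__}")
            return
    if isinstance(node, dict):
        for req in schema.get("required", []):
            if req not in node:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check_node(node[key], sub, f"{path}.{key}", errors)


def validate_report(report: "HECMReport | dict") -> list[str]:
    """Structural validation against the packaged report schema.

    Returns a list of violations (empty when the report conforms).
    """
    d = report.to_dict() if isinstance(report, HECMReport) else report
    schema = json.loads(
        resources.files("hecm.data").joinpath("report_schema.json").read_text()
    )
    errors: list[str] = []
    _check_node(d, schema, "report", errors)
    return errors


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(
    table: "CommonPeakTable | str",
    toxicity: "ToxicityTable | str",
    config: "PipelineConfig | None" = None,
    equivalence_groups: "dict[str, tuple[ToxicityGroup, ToxicityGroup]] | None" = None,
) -> HECMReport:
    """Run fingerprint -> PLS-VIP -> BP-ANN-MIV -> clustering -> selection.

    ``table`` and ``toxicity`` may be loaded objects or CSV paths.  When
    ``equivalence_groups`` maps an enzyme label to a (candidate, original)
    pair of per-animal groups, the equivalence stage is run per enzyme.
    """
    config = config or PipelineConfig()
    if isinstance(table, str):
        table = CommonPeakTable.from_csv(table)
    if isinstance(toxicity, str):
        toxicity = read_toxicity_csv(toxicity)

    tox_ids = set(toxicity.sample_ids)
    tab_ids = set(table.sample_ids)
    if tox_ids != tab_ids:
        raise ValueError(
            "sample ids differ between tables: "
            f"only in peak table {sorted(tab_ids - tox_ids)}, "
            f"only in toxicity table {sorted(tox_ids - tab_ids)}"
        )

    with _stage("fingerprint"):
        sim = similarity_report(table)

    means = toxicity.group_means().loc[table.sample_ids]
    X = table.areas
    Y = means[["alt_mean", "ast_mean"]].to_numpy()
    ids = table.peak_ids

    with _stage("plsr_vip"):
        model = fit_pls(X, Y, n_components=config.n_components)
        vres = vip(model, peak_ids=ids, threshold=config.vip_threshold)
        vip_selected = screen_by_vip(vres)

    with _stage("bpann_miv"):
        ann = train_bpann(
            X,
            Y,
            hidden=config.hidden,
            epochs=config.epochs,
            lr=config.lr,
            momentum=config.momentum,
            seed=config.seed,
        )
        mres = _miv(ann, X, delta=config.miv_delta, peak_ids=ids)

    with _stage("clustering"):
        col_ids = [f"peak_{p}" for p in ids] + ["ALT", "AST"]
        H = cluster_heatmap(
            np.column_stack([X, Y]),
            row_ids=table.sample_ids,
            col_ids=col_ids,
            metric=config.cluster_metric,
            linkage=config.cluster_linkage,
        )
        order = H.ordered_col_ids()
        # peaks adjacent to the ALT/AST block in the leaf order, as
        # supporting (non-gating) evidence
        endpoint_pos = [order.index("ALT"), order.index("AST")]
        near = set()
        for pos in endpoint_pos:
            for q in (pos - 1, pos + 1):
                if 0 <= q < len(order) and order[q].startswith("peak_"):
                    near.add(int(order[q].removeprefix("peak_")))

    with _stage("selection"):
        k = len(vip_selected)
        miv_top = rank_variables(mres, k, by=config.miv_rank_by) if k else []
        selected = sorted(set(vip_selected) & set(miv_top))

    equivalence_out = None
    if equivalence_groups:
        with _stage("equivalence"):
            equivalence_out = {}
            for enzyme, (cand, orig) in equivalence_groups.items():
                res = equivalence_ci(
                    cand, orig, alpha=config.alpha, limits=config.limits
                )
                ok, text = equivalence_decision(res)
                equivalence_out[enzyme] = {
                    "ci": list(res.ratio_ci),
                    "ratio": res.ratio,
                    "sigma_w": res.sigma_w,
                    "df": res.df,
                    "equivalent": ok,
                    "report": text,
                }

    report = HECMReport(
        similarity={
            "summary": sim.summary(),
            "per_sample": {k: float(v) for k, v in sim.per_sample.items()},
        },
        vip={
            "values": {str(p): float(v) for p, v in zip(ids, vres.vip)},
            "threshold": config.vip_threshold,
            "selected": [int(p) for p in vip_selected],
            "r_squared": vres.r_squared,
            "adjusted_r_squared": vres.adjusted_r_squared,
            "n_components": model.n_components,
        },
        miv={
            "values": {str(p): float(v) for p, v in zip(ids, mres.miv)},
            "iv": {str(p): float(v) for p, v in zip(ids, mres.iv)},
            "ranking_signed": [int(p) for p in mres.ranking_signed],
            "ranking_abs": [int(p) for p in mres.ranking_abs],
            "final_mse": float(ann.mse_trace[-1]),
        },
        cluster={
            "col_order": order,
            "row_order": H.ordered_row_ids(),
            "markers_near_endpoints": sorted(near),
        },
        selected_markers=[int(p) for p in selected],
        equivalence=equivalence_out,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    bad = validate_report(report)
    if bad:  # defensive: the schema and builder must stay in sync
        raise StageError("report", ValueError("; ".join(bad)))
    return report
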