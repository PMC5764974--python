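"""Per-animal toxicity tables and their delimited-text round trips."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ToxicityTable", "read_toxicity_csv"]


@dataclass
class ToxicityTable:
    """Per-animal serum ALT/AST activities (U/L) grouped by extract sample.

    ``data`` is a long-format frame with columns sample_id, animal, alt, ast.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "animal", "alt", "ast"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"toxicity table needs columns {sorted(required)}")
        if (self.data[["alt", "ast"]] <= 0).any().any():
            raise ValueError("enzyme activities must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"].astype(str)))

    def group_means(self) -> pd.DataFrame:
        """Per-sample mean ALT and AST, in first-appearance sample order."""
        g = (
            self.data.assign(sample_id=self.data["sample_id"].astype(str))
            .groupby("sample_id", sort=False)[["alt", "ast"]]
            .mean()
            .rename(columns={"alt": "alt_mean", "ast": "ast_mean"})
        )
        return g.loc[self.sample_ids]

    def group_values(self, sample_id: str, enzyme: str) -> np.ndarray:
        sel = self.data["sample_id"].astype(str) == str(sample_id)
        return self.data.loc[sel, enzyme].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_toxicity_csv(path) -> ToxicityTable:
    """Read per-animal toxicity data.

    Accepts either wide per-animal rows (sample_id, animal, alt, ast) or the
    long group/enzyme layout (group, enzyme, value_U_per_L), which is pivoted.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"sample_id", "animal", "alt", "ast"}.issubset(cols):
        return ToxicityTable(df)
    if {"group", "enzyme", "value_U_per_L"}.issubset(cols):
        df = df.copy()
        df["animal"] = df.groupby(["group", "enzyme"]).cumcount() + 1
        wide = df.pivot_table(
            index=["group", "animal"], columns="enzyme", values="value_U_per_L"
        ).reset_index()
        wide.columns.name = None
        wide = wide.rename(
            columns={"group": "sample_id", "ALT": "alt", "AST": "ast"}
        )
        return ToxicityTable(wide)
    raise ValueError(
        "toxicity CSV must have columns (sample_id, animal, alt, ast) "
        "or (group, enzyme, value_U_per_L)"
    )
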