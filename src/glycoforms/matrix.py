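"""Shared quantitative containers: the feature-by-sample intensity matrix and
the sample design that annotates its columns."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SampleDesign", "IntensityMatrix"]


@dataclass
class SampleDesign:
    """Per-channel annotation of a multiplexed experiment.

    ``table`` is indexed by channel label (one row per reporter column of the
    matrix) and carries at least a ``condition`` column; ``replicate``,
    ``tissue``, ``time`` and ``treatment`` are recognized by downstream
    presets when present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate channel labels in design: {dupes}")
        if "condition" not in self.table.columns:
            raise ValueError("sample design requires a 'condition' column")

    @property
    def channels(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read(cls, path) -> "SampleDesign":
        """Read a tab-separated design table whose first column is the channel."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="channel")


@dataclass
class IntensityMatrix:
    """Features x samples intensities with design annotation.

    ``values`` rows are feature ids, columns are sample/channel labels and
    must match the design index.  ``scale`` tags the interpretation of the
    numbers: ``raw`` (non-negative intensities), ``log2``, or ``normalized``
    (calibrated log-like scale).  Missing values are NaN.
    """

    values: pd.DataFrame
    design: SampleDesign
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.channels:
            raise ValueError(
                "matrix columns do not match design channels: "
                f"{list(self.values.columns)} vs {self.design.channels}"
            )
        if self.scale not in ("raw", "log2", "normalized"):
            raise ValueError(f"unknown scale tag {self.scale!r}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def complete_cases(self) -> "IntensityMatrix":
        """Restrict to features quantified (finite, and >0 on raw scale) in
        every sample — the requirement for differential analysis."""
        v = self.values
        ok = np.isfinite(v).all(axis=1)
        if self.scale == "raw":
            ok &= (v > 0).all(axis=1)
        return replace(self, values=v.loc[ok])

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def read(cls, path, design: SampleDesign, scale: str = "raw") -> "IntensityMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, design=design, scale=scale)
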