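"""Validation-assay arithmetic: Livak qPCR quantification and hormone ratios.

Relative expression by the 2^-ddCt (Livak) method: per condition, the
target gene's mean Ct is normalized against the mean Ct of one or more
reference genes (dCt); the dCt of a calibrator condition is subtracted
(ddCt); relative expression is 2**(-ddCt).  Replicate Ct values are
averaged on the Ct scale first, and multiple reference genes are combined
by the arithmetic mean of their Cts (equivalently the geometric mean of
their linear quantities).

Hormone ratios are plain elementwise time-series division, e.g. ABA/GA3
content per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CtTable", "ddct", "ddct_table", "HormoneSeries", "hormone_ratio"]


@dataclass
class CtTable:
    """Long-format qPCR Ct measurements.

    ``data`` columns: gene, condition, replicate, ct.  ``references`` are
    the internal reference genes (must be measured in every condition);
    ``calibrator`` is the baseline condition (e.g. "0h").
    """

    data: pd.DataFrame
    references: list[str]
    calibrator: str

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if not self.references:
            raise ValueError("at least one reference gene is required")
        conditions = set(self.data["condition"])
        if self.calibrator not in conditions:
            raise ValueError(f"calibrator condition {self.calibrator!r} not measured")
        for ref in self.references:
            ref_conds = set(self.data.loc[self.data["gene"] == ref, "condition"])
            absent = conditions - ref_conds
            if absent:
                raise ValueError(
                    f"reference gene {ref!r} not measured in condition(s) "
                    f"{sorted(absent)}"
                )

    @classmethod
    def from_tsv(
        cls, path: str | Path, references: Sequence[str], calibrator: str
    ) -> "CtTable":
        return cls(
            data=pd.read_csv(path, sep="\t"),
            references=list(references),
            calibrator=calibrator,
        )

    def mean_ct(self, gene: str, condition: str) -> float:
        sel = self.data[
            (self.data["gene"] == gene) & (self.data["condition"] == condition)
        ]
        if sel.empty:
            raise ValueError(f"gene {gene!r} not measured in condition {condition!r}")
        return float(sel["ct"].mean())


def ddct(ct: CtTable, target: str, condition: str) -> float:
    """Relative expression 2^-ddCt of ``target`` in ``condition`` vs the
    calibrator.

    dCt = mean Ct(target) - mean over references of mean Ct(reference),
    per condition; ddCt = dCt(condition) - dCt(calibrator).  The
    calibrator against itself is exactly 1.
    """

    def dct(cond: str) -> float:
        ref_ct = float(
            np.mean([ct.mean_ct(ref, cond) for ref in ct.references])
        )
        return ct.mean_ct(target, cond) - ref_ct

    ddct_value = dct(condition) - dct(ct.calibrator)
    return float(2.0 ** (-ddct_value))


def ddct_table(ct: CtTable, targets: Sequence[str] | None = None) -> pd.DataFrame:
    """2^-ddCt for every (target, condition) pair in the table."""
    if targets is None:
        targets = [
            g for g in ct.data["gene"].unique() if g not in ct.references
        ]
    conditions = list(ct.data["condition"].unique())
    rows = [
        {
            "gene": t,
            "condition": c,
            "relative_expression": ddct(ct, t, c),
        }
        for t in targets
        for c in conditions
        if not ct.data[(ct.data["gene"] == t) & (ct.data["condition"] == c)].empty
    ]
    return pd.DataFrame(rows)


@dataclass
class HormoneSeries:
    """Hormone content (e.g. ng per g fresh weight) on a shared time grid."""

    times: list
    content: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in self.content.items():
            series = np.asarray(series, dtype=float)
            if series.shape != (len(self.times),):
                raise ValueError(
                    f"hormone {name!r} series length does not match time grid"
                )
            if (series < 0).any():
                raise ValueError(f"hormone {name!r} has negative content")
            self.content[name] = series

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HormoneSeries":
        df = pd.read_csv(path, sep="\t")
        required = {"hormone", "time", "content"}
        if missing := required - set(df.columns):
            raise ValueError(f"hormone table missing columns: {sorted(missing)}")
        times = list(dict.fromkeys(df["time"]))
        content = {}
        for hormone, sub in df.groupby("hormone", sort=False):
            indexed = sub.set_index("time")["content"]
            if set(indexed.index) != set(times):
                raise ValueError(
                    f"hormone {hormone!r} not measured on the shared time grid"
                )
            content[hormone] = indexed.loc[times].to_numpy(dtype=float)
        return cls(times=times, content=content)


def hormone_ratio(
    series: HormoneSeries, numerator: str, denominator: str
) -> np.ndarray:
    """Elementwise numerator/denominator content ratio per time point."""
    for h in (numerator, denominator):
        if h not in series.content:
            raise KeyError(f"hormone {h!r} not in series")
    den = series.content[denominator]
    zero = np.flatnonzero(den == 0)
    if zero.size:
        raise ValueError(
            f"zero {denominator!r} content at time {series.times[zero[0]]!r}"
        )
    return series.content[numerator] / den
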