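"""Fluorescence-quenching screen for small-molecule / protein binding.

Each candidate component is measured against four plate controls:
A = lysis buffer alone, B = buffer + ligand, C = protein solution,
D = protein + ligand.  If ligand and protein did not interact, the
mixture D would fluoresce additively, FD = FB + FC - FA (the buffer
background FA is counted twice in FB + FC).  The activity percentage
measures the quenched fraction of that additive expectation:

    AP = (FB + FC - FA - FD) / (FB + FC - 2 FA) * 100

AP is 0 for perfect additivity (no interaction) and 100 when the
mixture is quenched all the way down to the buffer-only expectation
(FD = FA).  Activity percentages are Z-scored across components and
the top-k components are selected as active quality-marker candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("A", "B", "C", "D")


class AssayInvalidError(ValueError):
    """The additive fluorescence expectation is non-positive."""


@dataclass
class FluorescenceReadings:
    """Triplicate plate readings for one component, groups A-D."""

    component_id: str
    replicates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.replicates = {
            g: np.asarray(v, dtype=float) for g, v in self.replicates.items()
        }
        missing = [g for g in GROUPS if g not in self.replicates]
        if missing:
            raise ValueError(f"missing control group(s): {missing}")
        for g, v in self.replicates.items():
            if (v < 0).any():
                raise ValueError(f"negative intensity in group {g}")

    def mean(self, group: str) -> float:
        return float(self.replicates[group].mean())

    @property
    def FA(self) -> float:
        return self.mean("A")

    @property
    def FB(self) -> float:
        return self.mean("B")

    @property
    def FC(self) -> float:
        return self.mean("C")

    @property
    def FD(self) -> float:
        return self.mean("D")


def activity_percentage(
    readings: FluorescenceReadings | tuple[float, float, float, float],
) -> float:
    """AP = (FB + FC - FA - FD) / (FB + FC - 2 FA) * 100.

    Negative values (fluorescence enhancement) and values above 100
    (over-quench) are reported as-is; Z-scoring downstream relies on
    the raw scale.
    """
    if isinstance(readings, FluorescenceReadings):
        fa, fb, fc, fd = readings.FA, readings.FB, readings.FC, readings.FD
    else:
        fa, fb, fc, fd = map(float, readings)
    denom = fb + fc - 2.0 * fa
    if denom <= 0:
        raise AssayInvalidError(
            f"additive expectation FB+FC-2FA = {denom:.4g} is not positive"
        )
    return (fb + fc - fa - fd) / denom * 100.0


def replicate_activity(readings: FluorescenceReadings) -> tuple[np.ndarray, float]:
    """Replicate-wise APs (paired by replicate position) and their sample sd."""
    reps = readings.replicates
    n = min(len(reps[g]) for g in GROUPS)
    aps = np.array(
        [
            activity_percentage(
                (reps["A"][i], reps["B"][i], reps["C"][i], reps["D"][i])
            )
            for i in range(n)
        ]
    )
    sd = float(aps.std(ddof=1)) if n > 1 else float("nan")
    return aps, sd


def z_normalize(values) -> np.ndarray:
    """(x - mean) / sd with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("Z-normalization needs at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("Z-normalization undefined for zero spread")
    return (v - v.mean()) / sd


def screen(
    readings: list[FluorescenceReadings], top_k: int = 3
) -> pd.DataFrame:
    """Full screen: AP per component, Z-score, rank, top-k selection.

    Ranks descend in Z-score (equivalently in AP); ties are broken
    alphabetically by component id so the selection is deterministic.
    """
    if top_k > len(readings):
        raise ValueError(f"top_k={top_k} exceeds {len(readings)} components")
    ids = [r.component_id for r in readings]
    ap = np.array([activity_percentage(r) for r in readings])
    z = z_normalize(ap)
    df = pd.DataFrame({"activity_pct": ap, "z_score": z},
                      index=pd.Index(ids, name="component"))
    df = df.sort_values(["z_score", "component"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= top_k
    return df.loc[ids]  # restore input order


def select_active(results: pd.DataFrame, k: int | None = None) -> list[str]:
    """Component ids selected by the screen, ordered by rank."""
    df = results.sort_values("rank")
    if k is None:
        return list(df.index[df["selected"]])
    if k > len(df):
        raise ValueError(f"k={k} exceeds {len(df)} components")
    return list(df.index[:k])
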