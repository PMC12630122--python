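"""HPLC fingerprint construction for multi-batch herbal material.

Workflow: integrate peaks per batch, warp retention times onto a common
scale (multi-point calibration), match peaks across batches within a
retention-time window, keep only peaks present in every batch ("common
peaks"), build a median reference fingerprint, and score each batch by
the cosine congruence of its common-peak area vector with the reference.
Relative retention times and relative areas are expressed against a
designated reference peak S (by convention the dominant, most stable
peak; gentiopicroside in the motivating assay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class Chromatogram:
    """A single detector trace: time in minutes, intensity in mAU."""

    time: np.ndarray
    intensity: np.ndarray
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_min": self.time, "intensity_mau": self.intensity}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, batch_id: str = "") -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["intensity_mau"].to_numpy(), batch_id)


@dataclass
class CommonPeakMatrix:
    """Batches x common-peaks areas and retention times.

    ``areas`` and ``rts`` are DataFrames indexed by batch with one column
    per common peak (columns ordered by consensus retention time).
    ``reference_peak`` names the column designated as reference peak S.
    """

    areas: pd.DataFrame
    rts: pd.DataFrame
    reference_peak: object | None = None

    @property
    def n_batches(self) -> int:
        return len(self.areas)

    @property
    def n_peaks(self) -> int:
        return self.areas.shape[1]


@dataclass
class ReferenceFingerprint:
    """Per-peak median retention time and area across batches."""

    rt: pd.Series
    area: pd.Series


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 1.0,
    min_prominence: float = 1.0,
) -> pd.DataFrame:
    """Locate local maxima and integrate each between flanking minima.

    Returns a peak table with columns ``rt`` (min), ``area`` (mAU*min,
    trapezoidal), ``height`` (mAU) and ``batch_id``.  A flat or empty
    signal yields an empty table.
    """
    if min_height < 0 or min_prominence < 0:
        raise ValueError("thresholds must be non-negative")
    y = chrom.intensity
    t = chrom.time
    if y.size < 3:
        return _empty_peak_table(chrom.batch_id)
    idx, _ = find_peaks(y, height=min_height, prominence=min_prominence)
    if idx.size == 0:
        return _empty_peak_table(chrom.batch_id)
    # integration bounds: the signal minimum between adjacent peaks
    bounds = np.empty(idx.size + 1, dtype=int)
    bounds[0], bounds[-1] = 0, y.size - 1
    for k in range(idx.size - 1):
        lo, hi = idx[k], idx[k + 1]
        bounds[k + 1] = lo + int(np.argmin(y[lo : hi + 1]))
    rows = []
    for k, i in enumerate(idx):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(y[lo : hi + 1], t[lo : hi + 1]))
        rows.append((float(t[i]), area, float(y[i])))
    out = pd.DataFrame(rows, columns=["rt", "area", "height"])
    out["batch_id"] = chrom.batch_id
    return out


def _empty_peak_table(batch_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rt": pd.Series(dtype=float),
            "area": pd.Series(dtype=float),
            "height": pd.Series(dtype=float),
            "batch_id": pd.Series(dtype=object),
        }
    )


def calibrate_rts(
    tables: dict[str, pd.DataFrame],
    n_anchors: int = 8,
    window: float = 0.30,
    n_iter: int = 2,
) -> dict[str, pd.DataFrame]:
    """Multi-point retention-time calibration onto a consensus scale.

    Run-to-run drift (flow/gradient variation) stretches whole
    chromatograms coherently, so late peaks can drift by far more than
    the matching window.  Calibration proceeds in two steps, mirroring
    manual practice:

    1. scale correction — candidate run-wide scale factors are formed
       from RT ratios between the batch's and the consensus batch's
       few largest peaks, and the candidate that pairs the most
       consensus anchors (smallest residual on ties) wins; this is
       robust to a secondary peak occasionally outgrowing the dominant
       one;
    2. multi-point refinement — the ``n_anchors`` largest consensus
       peaks are paired to each rescaled run by nearest-neighbour
       within ``window`` minutes (affine refit per iteration), and the
       run is warped piecewise-linearly through the matched anchors.

    Falls back to the scale-only correction when fewer than 3 anchors
    pair up; returns inputs unchanged for fewer than 2 batches.
    """
    if len(tables) < 2:
        return {k: v.copy() for k, v in tables.items()}
    # consensus batch: the one whose peak count equals the median count
    counts = {k: len(v) for k, v in tables.items()}
    med = int(np.median(sorted(counts.values())))
    ref_key = min(counts, key=lambda k: (abs(counts[k] - med), k))
    ref = tables[ref_key]
    if ref.empty:
        return {k: v.copy() for k, v in tables.items()}
    anchors = (
        ref.sort_values("area", ascending=False)
        .head(n_anchors)["rt"]
        .sort_values()
        .to_numpy()
    )
    ref_top_rts = (
        ref.sort_values("area", ascending=False).head(5)["rt"].to_numpy()
    )
    out = {}
    for key, tab in tables.items():
        tab = tab.copy()
        rts = tab["rt"].to_numpy(dtype=float)
        if rts.size == 0:
            out[key] = tab
            continue
        areas = tab["area"].to_numpy(dtype=float)
        top_rts = rts[np.argsort(-areas)[:5]]
        scale = _best_scale(rts, top_rts, ref_top_rts, anchors, window)
        warped = rts * scale
        pairs = _pair_nearest(warped, anchors, window)
        for _ in range(n_iter - 1):
            if len(pairs) < 3:
                break
            src = rts[[i for i, _ in pairs]]
            dst = anchors[[j for _, j in pairs]]
            a, b = np.polyfit(src, dst, 1)
            warped = a * rts + b
            pairs = _pair_nearest(warped, anchors, window / 2.0)
        if len(pairs) >= 3:
            src = rts[[i for i, _ in pairs]]
            dst = anchors[[j for _, j in pairs]]
            order = np.argsort(src)
            tab["rt"] = _piecewise_warp(rts, src[order], dst[order])
        else:
            tab["rt"] = warped
        out[key] = tab
    return out


def _piecewise_warp(rts: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Piecewise-linear warp through anchor pairs.  Outside the anchor
    span the affine fit through all pairs is extrapolated: drift is
    dominated by a run-wide stretch, and np.interp's clamping would
    collapse distinct outer RTs onto a single value."""
    w = np.interp(rts, src, dst)
    a, b = np.polyfit(src, dst, 1)
    outside = (rts < src[0]) | (rts > src[-1])
    w[outside] = a * rts[outside] + b
    return w


def _best_scale(
    rts: np.ndarray,
    top_rts: np.ndarray,
    ref_top_rts: np.ndarray,
    anchors: np.ndarray,
    window: float,
    max_drift: float = 0.15,
) -> float:
    """Pick the run-wide RT scale factor among cross-ratio candidates of
    the largest peaks that aligns the most anchors (ties: smaller median
    residual, then scale closest to 1)."""
    cands = {1.0}
    for a in ref_top_rts:
        for b in top_rts:
            if b > 0 and abs(a / b - 1.0) <= max_drift:
                cands.add(a / b)
    best = (-1, np.inf, np.inf, 1.0)
    for s in sorted(cands):
        pairs = _pair_nearest(rts * s, anchors, window)
        if not pairs:
            continue
        resid = float(
            np.median([abs(rts[i] * s - anchors[j]) for i, j in pairs])
        )
        key = (-len(pairs), resid, abs(s - 1.0), s)
        if key < (-best[0], best[1], best[2], best[3]):
            best = (len(pairs), resid, abs(s - 1.0), s)
    return best[3]


def _pair_nearest(rts: np.ndarray, anchors: np.ndarray, window: float):
    """Greedy mutual nearest-neighbour pairing within a window."""
    pairs = []
    used = set()
    for j, a in enumerate(anchors):
        if rts.size == 0:
            break
        d = np.abs(rts - a)
        order = np.argsort(d)
        for i in order:
            if d[i] > window:
                break
            if i not in used:
                used.add(i)
                pairs.append((int(i), j))
                break
    return pairs


def match_common_peaks(
    tables: dict[str, pd.DataFrame],
    window: float = 0.10,
    calibrate: bool = True,
) -> CommonPeakMatrix:
    """Match peaks across batches; keep those present in every batch.

    Greedy centroid-seeded clustering: candidate seeds are taken in
    descending area order (ties by smaller RT); each seed claims the
    nearest unassigned peak of every batch within ``window`` minutes of
    the running centroid.  Clusters holding exactly one peak from every
    batch are the common peaks, reported in retention-time order.
    """
    if len(tables) < 2:
        raise ValueError("need at least two batches to match common peaks")
    if calibrate:
        tables = calibrate_rts(tables)
    batches = sorted(tables)
    nb = len(batches)
    rt_arr = [tables[b]["rt"].to_numpy(dtype=float) for b in batches]
    area_arr = [tables[b]["area"].to_numpy(dtype=float) for b in batches]
    free = [np.ones(a.size, dtype=bool) for a in rt_arr]
    pool = sorted(
        (
            (-area_arr[bi][i], rt_arr[bi][i], bi, i)
            for bi in range(nb)
            for i in range(rt_arr[bi].size)
        )
    )
    clusters: list[list[int]] = []  # per cluster: peak index per batch
    for _, seed_rt, seed_b, seed_i in pool:
        if not free[seed_b][seed_i]:
            continue
        members: list[tuple[int, int]] = []
        member_rts: list[float] = []
        centroid = seed_rt
        for bb in range(nb):
            rts_b = rt_arr[bb]
            mask = free[bb]
            if not mask.any():
                continue
            d = np.where(mask, np.abs(rts_b - centroid), np.inf)
            i = int(np.argmin(d))
            if d[i] <= window:
                members.append((bb, i))
                member_rts.append(rts_b[i])
                centroid = float(np.median(member_rts))
        if len(members) == nb:
            for bb, i in members:
                free[bb][i] = False
            clusters.append([i for _, i in sorted(members)])
        else:
            free[seed_b][seed_i] = False  # seed exhausted; never retried
    if not clusters:
        warnings.warn("no common peaks found", stacklevel=2)
        empty = pd.DataFrame(index=pd.Index(batches, name="batch"))
        return CommonPeakMatrix(areas=empty, rts=empty.copy())
    med_rt = [
        float(np.median([rt_arr[bi][m[bi]] for bi in range(nb)])) for m in clusters
    ]
    order = np.argsort(med_rt)
    idx = pd.Index(batches, name="batch")
    areas = pd.DataFrame(
        {
            rank: [area_arr[bi][clusters[ci][bi]] for bi in range(nb)]
            for rank, ci in enumerate(order, start=1)
        },
        index=idx,
    )
    rts = pd.DataFrame(
        {
            rank: [rt_arr[bi][clusters[ci][bi]] for bi in range(nb)]
            for rank, ci in enumerate(order, start=1)
        },
        index=idx,
    )
    return CommonPeakMatrix(areas=areas, rts=rts)


def build_reference(matrix: CommonPeakMatrix) -> ReferenceFingerprint:
    """Median reference fingerprint over batches (lower median for even
    counts, so the reference is always an observed value)."""
    if matrix.n_peaks == 0:
        raise ValueError("empty common-peak matrix")
    return ReferenceFingerprint(
        rt=matrix.rts.apply(_lower_median),
        area=matrix.areas.apply(_lower_median),
    )


def _lower_median(col: pd.Series) -> float:
    v = np.sort(col.to_numpy(dtype=float))
    return float(v[(len(v) - 1) // 2])


def similarity(sample_areas, reference_areas, metric: str = "cosine") -> float:
    """Congruence between a batch's common-peak areas and the reference.

    ``cosine`` (default) is the congruence coefficient; ``correlation``
    is the Pearson correlation of the two area vectors.
    """
    x = np.asarray(sample_areas, dtype=float)
    r = np.asarray(reference_areas, dtype=float)
    if x.shape != r.shape:
        raise ValueError("vectors must have equal length")
    if not np.any(x) or not np.any(r):
        raise ValueError("similarity undefined for a zero vector")
    if metric == "cosine":
        val = float(x @ r / (np.linalg.norm(x) * np.linalg.norm(r)))
    elif metric == "correlation":
        val = float(np.corrcoef(x, r)[0, 1])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return round(val, 3)


def similarity_report(
    matrix: CommonPeakMatrix,
    reference: ReferenceFingerprint | None = None,
    metric: str = "cosine",
) -> pd.Series:
    """Similarity of every batch against the median reference."""
    if reference is None:
        reference = build_reference(matrix)
    return matrix.areas.apply(
        lambda row: similarity(row, reference.area, metric=metric), axis=1
    ).rename("similarity")


def select_reference_peak(matrix: CommonPeakMatrix) -> object:
    """Auto-select reference peak S: the common peak with the largest
    median area (the stable, dominant peak)."""
    if matrix.n_peaks == 0:
        raise ValueError("empty common-peak matrix")
    return matrix.areas.median(axis=0).idxmax()


def relative_metrics(
    matrix: CommonPeakMatrix, reference_peak=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative RT and relative area of every peak against peak S,
    batch-wise (each cell divided by that batch's S value)."""
    s = reference_peak if reference_peak is not None else (
        matrix.reference_peak
        if matrix.reference_peak is not None
        else select_reference_peak(matrix)
    )
    if s not in matrix.areas.columns:
        raise KeyError(f"reference peak {s!r} is not a common peak")
    if (matrix.areas[s] == 0).any():
        raise ValueError("reference peak has zero area in some batch")
    matrix.reference_peak = s
    rel_rt = matrix.rts.div(matrix.rts[s], axis=0)
    rel_area = matrix.areas.div(matrix.areas[s], axis=0)
    return rel_rt, rel_area


def rsd(values) -> float:
    """Relative standard deviation in percent: sample sd (n-1) / mean * 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(v.std(ddof=1) / m * 100.0)


def validation_rsds(matrix: CommonPeakMatrix) -> pd.DataFrame:
    """Per-common-peak RSDs of relative RT and relative area, the
    fingerprint method-validation statistics."""
    rel_rt, rel_area = relative_metrics(matrix)
    s = matrix.reference_peak
    cols = [c for c in rel_rt.columns if c != s]
    return pd.DataFrame(
        {
            "rt_rsd_pct": [rsd(rel_rt[c]) for c in cols],
            "area_rsd_pct": [rsd(rel_area[c]) for c in cols],
        },
        index=pd.Index(cols, name="peak"),
    )
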