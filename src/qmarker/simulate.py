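"""Synthetic instrument data with the statistical structure of a
multi-batch herbal fingerprinting study.

No raw chromatograms are deposited for the motivating study, so the
test bed is simulated: Gaussian-peak chromatograms whose retention-time
scatter and (lognormal) area scatter match the validation bands reported
for real 44-batch data (relative-RT RSDs of 0.635-3.917 % and
relative-area RSDs of 19.439-144.854 %), four-control fluorescence
plates with a configurable true quench fraction, and two-group content
tables emulating the wild vs. cultivated contrast.

Retention-time scatter is realised as a coherent per-batch scale factor
(gradient/flow drift shifts a whole run together) plus a small
incoherent per-peak jitter; the coherent part is what multi-point RT
calibration removes before window matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import FluorescenceReadings
from .fingerprint import Chromatogram

DEFAULT_SEED = 20251106

#: 25 Gaussian peak templates (rt min, sigma min, area mAU*min) spread over
#: a 5-75 min gradient.  Template 13 plays the dominant reference-peak role
#: (gentiopicroside-like: roughly 10x every other area); templates 8, 10,
#: 11 and 15 are the other identified marker peaks.
DEFAULT_TEMPLATES: tuple[tuple[float, float, float], ...] = tuple(
    (rt, 0.08, area)
    for rt, area in [
        (5.2, 12.0), (7.9, 18.0), (10.4, 45.0), (13.1, 20.0), (15.8, 60.0),
        (18.5, 15.0), (21.3, 30.0), (24.0, 70.0), (26.8, 25.0), (29.5, 65.0),
        (32.2, 90.0), (35.0, 28.0), (37.7, 2000.0), (40.5, 19.0), (43.2, 75.0),
        (46.0, 23.0), (48.7, 40.0), (51.5, 17.0), (54.2, 50.0), (57.0, 26.0),
        (59.7, 35.0), (62.5, 62.0), (65.2, 21.0), (68.0, 31.0), (70.7, 14.0),
    ]
)


@dataclass
class SimulationConfig:
    """The stated world for the synthetic study.

    Defaults mirror the motivating study's scale: 44 batches, 25 common
    peaks, RT RSD centred at 2 % (inside the reported 0.635-3.917 %
    band), per-peak area RSDs spanning the reported 19.439-144.854 %
    band, triplicate plates, and a roughly 1.75x content advantage for
    the high-quality (wild-type) group, the middle of the reported
    1.5-2x contrast.
    """

    n_batches: int = 44
    peak_templates: tuple = DEFAULT_TEMPLATES
    rt_jitter_rsd_pct: float = 2.0
    rt_incoherent_sd_min: float = 0.01
    area_rsd_pct_range: tuple[float, float] = (19.439, 144.854)
    baseline_drift: float = 0.0          # mAU per min
    noise_sd: float = 0.2                # mAU
    time_step: float = 0.005             # min
    time_pad: float = 2.0                # min beyond outermost peaks
    quench_fractions: tuple[float, ...] = (0.8, 0.7, 0.6, 0.2, 0.1)
    plate_noise_pct: float = 5.0
    n_replicates: int = 3
    group_effect: float = 1.75
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")
        if any(s <= 0 for _, s, _ in self.peak_templates):
            raise ValueError("peak sigmas must be positive")
        if not all(0.0 <= q <= 1.0 for q in self.quench_fractions):
            raise ValueError("quench fractions must lie in [0, 1]")
        if self.group_effect <= 0:
            raise ValueError("group_effect must be positive")
        rts = sorted(rt for rt, _, _ in self.peak_templates)
        sigs = {rt: s for rt, s, _ in self.peak_templates}
        for a, b in zip(rts, rts[1:]):
            if b - a < 3.0 * max(sigs[a], sigs[b]):
                warnings.warn(
                    f"templates at {a} and {b} min are closer than 3 sigma; "
                    "peaks may merge",
                    stacklevel=2,
                )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _area_rsds(config: SimulationConfig) -> np.ndarray:
    """Per-template area RSDs: the largest peak gets the low end of the
    band (the dominant peak is the stable one), ascending as templates
    get smaller."""
    areas = np.array([a for _, _, a in config.peak_templates])
    lo, hi = config.area_rsd_pct_range
    ladder = np.linspace(lo, hi, len(areas))
    rsds = np.empty_like(ladder)
    rsds[np.argsort(-areas)] = ladder
    return rsds


def generate_chromatograms(
    config: SimulationConfig | None = None,
) -> dict[str, Chromatogram]:
    """Simulate one chromatogram per batch on a common time grid.

    Peak areas vary lognormally around the template area (mean-
    preserving), retention times get a coherent per-batch scale factor
    drawn with sd = rt_jitter_rsd_pct/100 plus incoherent N(0,
    rt_incoherent_sd_min) jitter, and the trace gains linear baseline
    drift plus white noise.  Bit-reproducible for a fixed config.
    """
    config = config or SimulationConfig()
    rng = config.rng()
    templates = list(config.peak_templates)
    rts = np.array([t[0] for t in templates])
    sigmas = np.array([t[1] for t in templates])
    areas = np.array([t[2] for t in templates])
    rsds = _area_rsds(config)
    t0 = max(rts.min() - config.time_pad, 0.0)
    t1 = (rts.max() + config.time_pad) * (1.0 + 4.0 * config.rt_jitter_rsd_pct / 100.0)
    grid = np.arange(t0, t1 + config.time_step, config.time_step)
    out: dict[str, Chromatogram] = {}
    for b in range(config.n_batches):
        batch = f"S{b + 1}"
        scale = rng.normal(1.0, config.rt_jitter_rsd_pct / 100.0)
        peak_rts = scale * rts + rng.normal(0.0, config.rt_incoherent_sd_min, rts.size)
        sd_log = np.sqrt(np.log1p((rsds / 100.0) ** 2))
        peak_areas = areas * np.exp(
            rng.normal(0.0, 1.0, areas.size) * sd_log - sd_log ** 2 / 2.0
        )
        y = np.zeros_like(grid)
        for mu, sig, ar in zip(peak_rts, sigmas, peak_areas):
            y += ar / (sig * np.sqrt(2.0 * np.pi)) * np.exp(
                -0.5 * ((grid - mu) / sig) ** 2
            )
        y += config.baseline_drift * (grid - grid[0])
        if config.noise_sd > 0:
            y += rng.normal(0.0, config.noise_sd, grid.size)
        out[batch] = Chromatogram(grid.copy(), y, batch_id=batch)
    return out


def true_peak_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth template table (rt, sigma, area) for recovery checks."""
    return pd.DataFrame(
        list(config.peak_templates), columns=["rt", "sigma", "area"]
    )


def generate_fluorescence_assay(
    quench_fractions=None,
    config: SimulationConfig | None = None,
) -> list[FluorescenceReadings]:
    """Simulate four-control plates, one component per quench fraction.

    FD is placed so the noiseless activity percentage equals the quench
    fraction times 100:  FD = FB + FC - FA - q * (FB + FC - 2 FA).
    Multiplicative Gaussian noise (sd = plate_noise_pct %) is applied
    per replicate.
    """
    config = config or SimulationConfig()
    if quench_fractions is None:
        quench_fractions = config.quench_fractions
    if not all(0.0 <= q <= 1.0 for q in quench_fractions):
        raise ValueError("quench fractions must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    fa, ligand, protein = 100.0, 500.0, 2000.0
    readings = []
    for i, q in enumerate(quench_fractions):
        fb = fa + ligand
        fc = protein
        fd = fb + fc - fa - q * (fb + fc - 2.0 * fa)
        reps = {}
        for g, level in zip("ABCD", (fa, fb, fc, fd)):
            noise = rng.normal(
                1.0, config.plate_noise_pct / 100.0, config.n_replicates
            )
            reps[g] = np.clip(level * noise, 0.0, None)
        readings.append(
            FluorescenceReadings(component_id=f"C{i + 1}", replicates=reps)
        )
    return readings


#: per-analyte (mean mg/g, lognormal CV) for the low-quality group,
#: loosely matching the cultivated-batch content scale of the study
CONTENT_PRIORS = {
    "swertiamarin": (3.3, 0.25),
    "gentiopicroside": (34.0, 0.15),
    "sweroside": (0.35, 0.35),
}


def generate_content_table(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group lognormal content table with known quality labels.

    The first half of the batches forms the "high" group whose contents
    are multiplied by ``group_effect``.  Returns (contents, labels) with
    labels in {"high", "low"}.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_batches
    n_high = n // 2
    labels = pd.Series(
        ["high"] * n_high + ["low"] * (n - n_high),
        index=[f"S{i + 1}" for i in range(n)],
        name="group",
    )
    cols = {}
    for analyte, (mean, cv) in CONTENT_PRIORS.items():
        sd_log = np.sqrt(np.log1p(cv ** 2))
        base = mean * np.exp(rng.normal(0.0, 1.0, n) * sd_log - sd_log ** 2 / 2.0)
        base[:n_high] *= config.group_effect
        cols[analyte] = base
    contents = pd.DataFrame(cols, index=labels.index)
    contents.index.name = "batch"
    return contents, labels
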