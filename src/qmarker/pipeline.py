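"""End-to-end orchestration: simulate -> fingerprint -> screen ->
quantify -> evaluate, with a reproducible run manifest.

The stages are the library modules; this layer only wires them together
under a single config, writes per-stage CSV outputs into a run
directory, and records a manifest (config hash, input checksums, stage
timings, warnings) that fully determines the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import binding, chemometrics, datasets, fingerprint, quality, quantify
from .simulate import (
    SimulationConfig,
    generate_chromatograms,
    generate_content_table,
    generate_fluorescence_assay,
)

__version__ = "0.1.0"

STAGES = ("fingerprint", "screen", "binding", "quantify", "evaluate")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = STAGES
    workdir: str | Path = "qmarker_run"
    matching_window: float = 0.10
    similarity_metric: str = "cosine"
    vip_threshold: float = 1.0
    top_k: int = 3
    prep_mass: float = 0.5
    prep_volume: float = 20.0
    topsis_variant: str = "normalized"
    linkage: str = "average"
    n_grades: int = 3
    seed: int = 20251106
    simulation: SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["workdir"] = str(self.workdir)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    contents: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> dict:
    """Execute the enabled stages in order and return the result bundle.

    When ``contents`` is None the synthetic generators provide every
    input (sized by ``config.simulation``); pass the packaged study
    table (``datasets.load_contents()``) for the fixture-only path.
    """
    outdir = Path(config.workdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or SimulationConfig(seed=config.seed)
    results: dict = {}
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    if not config.stages:
        warnings.warn("no stages enabled; writing empty report", stacklevel=2)
        manifest["warnings"].append("no stages enabled")
        _write_manifest(outdir, manifest)
        return {"manifest": manifest}

    for stage in config.stages:
        if stage not in STAGES:
            raise StageError(stage, ValueError("unknown stage"))
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                if stage == "fingerprint":
                    _stage_fingerprint(config, sim, results, outdir)
                elif stage == "screen":
                    _stage_screen(config, results, labels, outdir)
                elif stage == "binding":
                    _stage_binding(config, sim, results, outdir)
                elif stage == "quantify":
                    _stage_quantify(config, sim, results, contents, outdir)
                elif stage == "evaluate":
                    _stage_evaluate(config, results, contents, outdir)
            except StageError:
                raise
            except Exception as exc:  # tag failures with the stage name
                raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 4),
            "warnings": [str(w.message) for w in caught],
        }
    results["manifest"] = manifest
    _write_manifest(outdir, manifest)
    return results


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_fingerprint(config, sim, results, outdir) -> None:
    chroms = generate_chromatograms(sim)
    tables = {
        b: fingerprint.detect_peaks(c, min_height=2.0, min_prominence=2.0)
        for b, c in chroms.items()
    }
    matrix = fingerprint.match_common_peaks(tables, window=config.matching_window)
    ref = fingerprint.build_reference(matrix)
    sims = fingerprint.similarity_report(matrix, ref, metric=config.similarity_metric)
    rel_rt, rel_area = fingerprint.relative_metrics(matrix)
    results.update(
        common_peaks=matrix, reference=ref, similarities=sims,
        relative_rt=rel_rt, relative_area=rel_area,
    )
    matrix.areas.to_csv(outdir / "common_peak_areas.csv")
    sims.to_csv(outdir / "similarity.csv")
    pd.DataFrame({"rt": ref.rt, "area": ref.area}).to_csv(
        outdir / "reference_fingerprint.csv", index_label="peak"
    )


def _stage_screen(config, results, labels, outdir) -> None:
    matrix = results.get("common_peaks")
    if matrix is None:
        raise ValueError("screen stage needs the fingerprint stage first")
    if labels is None:  # synthetic default: first half vs second half
        n = matrix.n_batches
        labels = pd.Series(
            ["A"] * (n // 2) + ["B"] * (n - n // 2), index=matrix.areas.index
        )
    std = chemometrics.standardize(matrix.areas)
    pca_res = chemometrics.pca(std)
    opls = chemometrics.opls_da(std, labels.loc[matrix.areas.index])
    vips = chemometrics.vip(opls)
    markers = chemometrics.select_markers(vips, config.vip_threshold)
    results.update(pca=pca_res, oplsda=opls, vip=vips, markers=markers)
    vips.to_csv(outdir / "vip.csv")
    pd.DataFrame(
        {
            "eigenvalue": pca_res.eigenvalues,
            "variance_pct": pca_res.variance_pct,
            "cumulative_pct": pca_res.cumulative_pct,
        }
    ).to_csv(outdir / "pca_eigenvalues.csv", index_label="component")


def _stage_binding(config, sim, results, outdir) -> None:
    readings = generate_fluorescence_assay(config=sim)
    screen_df = binding.screen(readings, top_k=config.top_k)
    results["binding"] = screen_df
    results["active_components"] = binding.select_active(screen_df)
    screen_df.to_csv(outdir / "binding_screen.csv")


def _stage_quantify(config, sim, results, contents, outdir) -> None:
    prep = quantify.SamplePrep(mass=config.prep_mass, volume=config.prep_volume)
    curves_df = datasets.load_calibration_curves()
    curves = {
        a: quantify.CalibrationCurve(analyte=a, slope=r.slope, intercept=r.intercept)
        for a, r in curves_df.iterrows()
    }
    if contents is None:
        contents, labels = generate_content_table(sim)
        results["content_labels"] = labels
    results["contents"] = contents
    results["prep"] = prep
    results["calibration_curves"] = curves
    contents.to_csv(outdir / "contents_mg_per_g.csv")


def _stage_evaluate(config, results, contents, outdir) -> None:
    if contents is None:
        contents = results.get("contents")
    if contents is None:
        contents, labels = generate_content_table(
            config.simulation or SimulationConfig(seed=config.seed)
        )
        results["content_labels"] = labels
    top = quality.evaluate_topsis(contents, variant=config.topsis_variant)
    comp = quality.composite_score(contents)
    grades = quality.hca_grade(
        contents, k=config.n_grades, method=config.linkage,
        order_by=top.closeness,
    )
    report = quality.quality_report(top, comp, grades)
    results.update(topsis=top, composite=comp, grades=grades, report=report)
    report.to_csv(outdir / "quality_report.csv")


def make_demo(seed: int = 20251106, workdir: str | Path = "qmarker_demo") -> Path:
    """Write a self-contained synthetic dataset sized like the study:
    44 chromatograms (25 peaks each), 5 component plate-reading sets,
    3 calibration-point sets, and a content table."""
    out = Path(workdir)
    (out / "chromatograms").mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(seed=seed)
    for b, c in generate_chromatograms(sim).items():
        c.to_csv(out / "chromatograms" / f"{b}.csv")
    rows = []
    for r in generate_fluorescence_assay(config=sim):
        for g, reps in r.replicates.items():
            for i, v in enumerate(reps, start=1):
                rows.append((r.component_id, g, i, v))
    pd.DataFrame(rows, columns=["component", "group", "replicate", "intensity"]).to_csv(
        out / "plate_readings.csv", index=False
    )
    rng = sim.rng()
    cal_rows = []
    for a, r in datasets.load_calibration_curves().iterrows():
        for conc in (0.05, 0.1, 0.25, 0.5, 1.0):
            area = r.slope * conc + r.intercept
            cal_rows.append((a, conc, area * (1 + rng.normal(0, 0.002))))
    pd.DataFrame(cal_rows, columns=["analyte", "conc_mg_ml", "area_mau"]).to_csv(
        out / "calibration_points.csv", index=False
    )
    contents, labels = generate_content_table(sim)
    contents.assign(group=labels).to_csv(out / "contents.csv")
    (out / "README.txt").write_text(
        f"Synthetic demo workspace (seed={seed}).\n"
        "chromatograms/: 44 two-column traces (time_min, intensity_mau)\n"
        "plate_readings.csv: fluorescence controls A-D, 5 components x 3 reps\n"
        "calibration_points.csv: 3 analytes x 5 levels\n"
        "contents.csv: synthetic two-group content table (mg/g)\n"
    )
    return out
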