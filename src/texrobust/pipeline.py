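"""End-to-end pipeline: cohort -> ROIs -> features -> similarity -> robustness.

One :class:`PipelineConfig` drives the whole analysis; in synthetic mode the
run is bit-identical under a fixed configuration.  Outputs are plain CSV/JSON
files in the configured output directory:

* ``features_3d.csv`` / ``features_2d.csv`` / ``features_circles.csv`` —
  one row per lesion x reader x ROI type x mode;
* ``similarity_3d.csv`` / ``similarity_2d.csv`` + ``similarity_summary.json``;
* ``robustness.csv`` — per-feature MRC/ICC/band/robust for both modes;
* ``size_agreement.csv`` — size-vs-agreement correlations;
* ``circular_comparison.csv`` — inter-reader vs circular-ROI variability;
* ``exclusions.json`` and ``run_manifest.json`` — provenance and per-stage
  counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DomainError
from .features import FeatureVector, extract_features
from .io import read_cohort_manifest, read_labelmap, read_volume, write_cohort
from .roi import (largest_axial_cross_section, max_inscribed_circle_roi,
                  min_enclosing_circle_roi)
from .similarity import cohort_similarity
from .stats import (ICC_ROBUST_THRESHOLD, MRC_ROBUST_THRESHOLD_PCT,
                    PairedFeatureTable, circular_roi_comparison,
                    robustness_table, size_agreement_analysis, spearman_rho,
                    wilcoxon_signed_rank)
from .synthetic import (DEFAULT_READER1, DEFAULT_READER2, DEFAULT_SPACING,
                        ReaderPerturbationSpec, SyntheticCohort,
                        apply_exclusion_criteria, generate_cohort,
                        largest_axial_diameter)
from .texture import DiscretizationConfig


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (exactly one input mode)."""

    input_mode: str = "synthetic"            # {"synthetic", "labelmap-directory"}
    output_dir: str = "texrobust_output"
    # synthetic mode
    n_lesions: int = 70
    master_seed: int = 0
    n_patients: int = 17
    population_ranges: dict = field(default_factory=dict)
    spacing: tuple = DEFAULT_SPACING
    reader1: ReaderPerturbationSpec = DEFAULT_READER1
    reader2: ReaderPerturbationSpec = DEFAULT_READER2
    # labelmap mode
    manifest_path: str = ""
    # analysis
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    do_3d: bool = True
    do_2d: bool = True
    do_circles: bool = True
    icc_robust: float = ICC_ROBUST_THRESHOLD
    mrc_robust_pct: float = MRC_ROBUST_THRESHOLD_PCT
    min_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "labelmap-directory"):
            raise DomainError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "labelmap-directory" and not self.manifest_path:
            raise DomainError("labelmap-directory mode needs manifest_path")
        if min(self.icc_robust, self.mrc_robust_pct, self.min_diameter_mm) <= 0:
            raise DomainError("thresholds must be positive")
        if isinstance(self.reader1, dict):
            self.reader1 = ReaderPerturbationSpec(**self.reader1)
        if isinstance(self.reader2, dict):
            self.reader2 = ReaderPerturbationSpec(**self.reader2)
        if isinstance(self.discretization, dict):
            self.discretization = DiscretizationConfig(**self.discretization)
        self.spacing = tuple(self.spacing)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _load_labelmap_cohort(config: PipelineConfig) -> tuple[SyntheticCohort, list[dict]]:
    """Ingest a cohort from a NIfTI labelmap directory manifest.

    Lesions with unreadable or missing files are logged and skipped; the run
    aborts only if no lesion survives.
    """
    manifest = read_cohort_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    errors: list[dict] = []
    volumes, truths, r1s, r2s, specs, ids = [], [], [], [], [], []
    spacing = tuple(manifest.get("spacing", config.spacing))
    for entry in manifest["lesions"]:
        lid = entry["lesion_id"]
        try:
            vol = read_volume(base / entry["files"]["volume"])
            r1 = read_labelmap(base / entry["files"]["reader1"], vol,
                               reader_id="R1")
            r2 = read_labelmap(base / entry["files"]["reader2"], vol,
                               reader_id="R2")
        except Exception as exc:  # per-file failures are collected, not fatal
            errors.append({"lesion_id": lid, "error": str(exc)})
            continue
        volumes.append(vol)
        truths.append(r1)                     # no ground truth in clinical mode
        r1s.append(r1)
        r2s.append(r2)
        ids.append(lid)
    if not volumes:
        raise DomainError("no lesion could be loaded from the manifest")
    from .synthetic import LesionSpec
    specs = [LesionSpec(center=(0, 0, 0), target_diameter=1.0)] * len(volumes)
    cohort = SyntheticCohort(volumes=volumes, truth_masks=truths,
                             reader1_masks=r1s, reader2_masks=r2s,
                             lesion_specs=specs, master_seed=-1,
                             spacing=spacing, lesion_ids=ids)
    return cohort, errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of in-memory results (DataFrames and summaries) mirroring
    the files written to ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    load_errors: list[dict] = []

    if config.input_mode == "synthetic":
        cohort = generate_cohort(
            config.n_lesions, config.master_seed,
            population_ranges=config.population_ranges or None,
            spacing=config.spacing,
            reader1=config.reader1, reader2=config.reader2,
        )
    else:
        cohort, load_errors = _load_labelmap_cohort(config)
    counts["lesions_in"] = len(cohort)

    # exclusion rule: lesions too small for texture analysis (measured on the
    # reader-1 mask, as a human reader would measure with a calliper)
    retained, exclusion_log = apply_exclusion_criteria(
        cohort.reader1_masks, cohort.spacing, config.min_diameter_mm
    )
    counts["lesions_retained"] = len(retained)
    ids = [cohort.lesion_ids[i] for i in retained]
    patient_ids = [f"patient{(i % config.n_patients):02d}" for i in retained]

    dconf = config.discretization
    results: dict = {"config": config, "lesion_ids": ids,
                     "exclusions": exclusion_log, "load_errors": load_errors}

    feature_rows: dict[str, list[dict]] = {"3d": [], "2d": [], "circles": []}
    vecs: dict[str, list[FeatureVector]] = {
        "r1_3d": [], "r2_3d": [], "r1_2d": [], "r2_2d": [],
    }
    masks_2d = {"r1": [], "r2": []}

    for pos, i in enumerate(retained):
        lid = ids[pos]
        vol = cohort.volumes[i]
        r1, r2 = cohort.reader1_masks[i], cohort.reader2_masks[i]
        if config.do_3d:
            for key, mask in (("r1_3d", r1), ("r2_3d", r2)):
                fv = extract_features(vol, mask, dconf, mode="3D", lesion_id=lid)
                vecs[key].append(fv)
                feature_rows["3d"].append(fv.to_dict())
        if config.do_2d or config.do_circles:
            c1 = largest_axial_cross_section(r1)
            c2 = largest_axial_cross_section(r2)
            masks_2d["r1"].append(c1)
            masks_2d["r2"].append(c2)
            if config.do_2d:
                for key, mask in (("r1_2d", c1), ("r2_2d", c2)):
                    fv = extract_features(vol, mask, dconf, mode="2D", lesion_id=lid)
                    vecs[key].append(fv)
                    feature_rows["2d"].append(fv.to_dict())

    for mode_key, fname in (("3d", "features_3d.csv"), ("2d", "features_2d.csv")):
        if feature_rows[mode_key]:
            pd.DataFrame(feature_rows[mode_key]).to_csv(outdir / fname, index=False)

    # ---- similarity ----------------------------------------------------
    similarity_summaries = {}
    sim_results = {}
    for mode, enabled in (("3D", config.do_3d), ("2D", config.do_2d)):
        if not enabled:
            continue
        r1_masks = [cohort.reader1_masks[i] for i in retained]
        r2_masks = [cohort.reader2_masks[i] for i in retained]
        res, summary = cohort_similarity(r1_masks, r2_masks, mode=mode,
                                         lesion_ids=ids)
        sim_results[mode] = res
        similarity_summaries[mode] = summary
        df = pd.DataFrame([{"lesion_id": r.lesion_id, "mode": r.roi_mode,
                            "dice": r.dice,
                            "avg_hausdorff_mm": r.avg_hausdorff}
                           for r in res])
        df.to_csv(outdir / f"similarity_{mode.lower()}.csv", index=False)

    stats_summary: dict = {"similarity": similarity_summaries}
    if config.do_3d and config.do_2d:
        dc3 = [r.dice for r in sim_results["3D"]]
        dc2 = [r.dice for r in sim_results["2D"]]
        hd3 = [r.avg_hausdorff for r in sim_results["3D"]]
        hd2 = [r.avg_hausdorff for r in sim_results["2D"]]
        stats_summary["wilcoxon_dice_2d_vs_3d"] = wilcoxon_signed_rank(dc2, dc3)
        stats_summary["wilcoxon_hd_2d_vs_3d"] = wilcoxon_signed_rank(hd2, hd3)
    for mode in sim_results:
        dcs = [r.dice for r in sim_results[mode]]
        hds = [r.avg_hausdorff for r in sim_results[mode]]
        if len(dcs) >= 3:
            rho = spearman_rho(dcs, hds)
        else:
            rho = {"rho": float("nan"), "p_value": float("nan"), "n": len(dcs)}
        stats_summary[f"spearman_dc_vs_hd_{mode.lower()}"] = rho
    (outdir / "similarity_summary.json").write_text(
        json.dumps(stats_summary, indent=2, default=float))
    results["stats_summary"] = stats_summary

    # ---- robustness -----------------------------------------------------
    rob_parts = []
    for mode, key1, key2 in (("2D", "r1_2d", "r2_2d"), ("3D", "r1_3d", "r2_3d")):
        if not vecs[key1]:
            continue
        table = PairedFeatureTable.from_vectors(vecs[key1], vecs[key2],
                                                roi_mode=mode)
        rt = robustness_table(table, icc_threshold=config.icc_robust,
                              mrc_threshold_pct=config.mrc_robust_pct)
        rt = rt.rename(columns={c: f"{c}_{mode.lower()}" for c in
                                ("mrc_pct", "n_valid_mrc", "icc",
                                 "n_valid_icc", "band", "robust")})
        rob_parts.append(rt)
        results[f"robustness_{mode.lower()}"] = rt
    if rob_parts:
        merged = rob_parts[0]
        for part in rob_parts[1:]:
            merged = merged.join(part.drop(columns=["family"]))
        merged.to_csv(outdir / "robustness.csv")
        results["robustness"] = merged

    # ---- size vs agreement ---------------------------------------------
    size_frames = []
    for mode in (sim_results if len(retained) >= 3 else {}):
        key = "r1_3d" if mode == "3D" else "r1_2d"
        if not vecs[key]:
            continue
        r1_masks = [cohort.reader1_masks[i] for i in retained]
        axial = np.array([largest_axial_diameter(m) for m in r1_masks])
        max3d = np.array([fv["Max3DDiameter"] for fv in vecs["r1_3d" if vecs["r1_3d"] else key]])
        if mode == "3D":
            bulk = np.array([fv["Volume"] for fv in vecs[key]])  # cm^3
            bulk_name = "volume_cm3"
        else:
            sx, sy, _ = cohort.spacing
            bulk = np.array([fv["NumberOfVoxels"] * sx * sy / 100.0
                             for fv in vecs[key]])               # cm^2
            bulk_name = "area_cm2"
        frame = size_agreement_analysis(
            {"manual_axial_diameter_mm": axial,
             "max_3d_diameter_mm": max3d,
             bulk_name: bulk},
            np.array([r.dice for r in sim_results[mode]]),
            np.array([r.avg_hausdorff for r in sim_results[mode]]),
        )
        frame.insert(0, "roi_mode", mode)
        size_frames.append(frame)
    if size_frames:
        size_df = pd.concat(size_frames, ignore_index=True)
        size_df.to_csv(outdir / "size_agreement.csv", index=False)
        results["size_agreement"] = size_df

    # ---- circular-ROI comparison on main lesions -----------------------
    if config.do_circles and masks_2d["r1"]:
        volumes_3d = np.array([cohort.reader1_masks[i].n_voxels
                               for i in retained], dtype=float)
        main_idx: dict[str, int] = {}
        for pos, pid in enumerate(patient_ids):
            if pid not in main_idx or volumes_3d[pos] > volumes_3d[main_idx[pid]]:
                main_idx[pid] = pos              # main lesion = largest volume
        circle_rows = []
        quads = {"r1": [], "enc": [], "ins": [], "r2": []}
        for pid, pos in sorted(main_idx.items()):
            i = retained[pos]
            lid = ids[pos]
            vol = cohort.volumes[i]
            c1 = masks_2d["r1"][pos]
            c2 = masks_2d["r2"][pos]
            enc = min_enclosing_circle_roi(c1)
            ins = max_inscribed_circle_roi(c1)
            extracted = {}
            for key, mask in (("r1", c1), ("enc", enc), ("ins", ins), ("r2", c2)):
                fv = extract_features(vol, mask, dconf, mode="2D", lesion_id=lid)
                quads[key].append(fv)
                extracted[key] = fv
                circle_rows.append(fv.to_dict() | {"patient_id": pid})
        pd.DataFrame(circle_rows).to_csv(outdir / "features_circles.csv",
                                         index=False)
        circ = circular_roi_comparison(quads["r1"], quads["enc"],
                                       quads["ins"], quads["r2"])
        circ.to_csv(outdir / "circular_comparison.csv")
        results["circular_comparison"] = circ
        counts["main_lesions"] = len(main_idx)

    # ---- provenance ----------------------------------------------------
    (outdir / "exclusions.json").write_text(
        json.dumps({"excluded": exclusion_log, "load_errors": load_errors},
                   indent=2))
    manifest = {
        "software": {"name": "texrobust", "version": __version__},
        "config": config.to_jsonable(),
        "counts": counts,
        "lesions": [
            {"lesion_id": lid, "patient_id": pid,
             "provenance": ("synthetic" if config.input_mode == "synthetic"
                            else "labelmap"),
             "master_seed": cohort.master_seed}
            for lid, pid in zip(ids, patient_ids)
        ],
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    results["counts"] = counts
    return results


def simulate_to_directory(config: PipelineConfig, outdir: str | Path) -> Path:
    """Generate the synthetic cohort of ``config`` and write it as NIfTI files."""
    cohort = generate_cohort(
        config.n_lesions, config.master_seed,
        population_ranges=config.population_ranges or None,
        spacing=config.spacing,
        reader1=config.reader1, reader2=config.reader2,
    )
    return write_cohort(cohort, outdir)
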