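"""End-to-end orchestration: config, validation, stage outputs, manifest.

A run is driven by a single :class:`RunConfig` (YAML-loadable, unknown keys
rejected, every numeric parameter range-checked).  Stages execute in the
method's order — simulate (optional) -> bin/preprocess -> annotate ->
classify -> regress -> trends -> enrich — each writing delimited outputs
into the run directory, and a JSON manifest records the package version,
config hash, per-stage seeds and row/feature counts.  Every stage seed is
derived from the master seed by hashing the stage name, so any stage can be
reproduced in isolation; rerunning an identical config yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import FormulaDB, annotate_matrix, composition_summary, records_to_frame
from .binning import (FeatureMatrix, STAGES, bin_sample_set, log2_transform,
                      normalise_tic, occupancy_filter, qc_rsd_filter, read_mzml)
from .enrichment import (build_knowledge_graph, cluster_functional_enrichment,
                         cluster_structural_enrichment)
from .rf_models import (classical_mds, confidence_ellipse, fit_rf_classifier,
                        intraclass_distance_summary, permutation_test,
                        proximity_to_distance, regression_significance)
from .synthetic_data import (SyntheticSpec, generate_feature_matrix,
                             generate_reference, matrix_to_scans)
from .trends import cluster_quality_report, kmeans_trends, log2_ratio_profiles

logger = logging.getLogger("leafprint")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _check_range(name: str, value, lo, hi, lo_open=False, hi_open=False) -> None:
    ok = (value > lo if lo_open else value >= lo) and \
         (value < hi if hi_open else value <= hi)
    if not ok:
        raise ValueError(f"config: {name}={value} outside legal range "
                         f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    seed: int = 1
    # inputs (None -> simulate)
    matrix: str | None = None
    metadata: str | None = None
    mzml_dir: str | None = None
    compounds: str | None = None
    edges: str | None = None
    # simulation
    n_per_class: int = 24
    classes: tuple[str, ...] = ("garden3", "garden4")
    n_features: int = 500
    n_discriminating: int = 10
    n_trend_per_archetype: int = 20
    effect_size: float = 0.9
    noise_sd: float = 0.3
    qc_n: int = 5
    qc_rsd: float = 0.10
    zero_rate: float = 0.10
    n_compounds: int = 40
    n_pathways: int = 5
    from_scans: bool = False
    n_scans: int = 5
    jitter_ppm: float = 0.5
    # binning / filtering
    bin_width: float = 0.01
    mz_min: float = 55.0
    mz_max: float = 1200.0
    tic_fraction: float = 0.5
    occupancy: float = 2 / 3
    qc_rsd_max: float = 0.5
    # annotation
    ppm: float = 3.0
    consensus: float = 0.66
    # models
    label: str = "group"
    time_col: str = "hour"
    n_trees: int = 1000
    n_perm: int = 3000
    alpha: float = 0.05
    # trends
    baseline: str = "09:00"
    k: int = 5
    n_restarts: int = 10
    # enrichment
    damping: float = 0.85
    n_null: int = 1000

    def __post_init__(self) -> None:
        _check_range("seed", self.seed, 0, 2 ** 31 - 1)
        _check_range("bin_width", self.bin_width, 0, 10, lo_open=True)
        _check_range("occupancy", self.occupancy, 0, 1)
        _check_range("qc_rsd_max", self.qc_rsd_max, 0, 10, lo_open=True)
        _check_range("tic_fraction", self.tic_fraction, 0, 1, lo_open=True)
        _check_range("ppm", self.ppm, 0, 1000, lo_open=True)
        _check_range("consensus", self.consensus, 0, 1, lo_open=True)
        _check_range("n_trees", self.n_trees, 1, 10 ** 6)
        _check_range("n_perm", self.n_perm, 1, 10 ** 7)
        _check_range("alpha", self.alpha, 0, 1, lo_open=True, hi_open=True)
        _check_range("k", self.k, 1, 10 ** 4)
        _check_range("damping", self.damping, 0, 1, lo_open=True, hi_open=True)
        _check_range("n_null", self.n_null, 1, 10 ** 7)
        if self.mz_min >= self.mz_max:
            raise ValueError("config: mz_min must be below mz_max")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        if "classes" in raw:
            raw = {**raw, "classes": tuple(raw["classes"])}
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = list(d["classes"])
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def demo_config(seed: int = 1, **overrides) -> RunConfig:
    """Desk-scale settings: the full study design with reduced resampling
    depth (forest size, permutation and null counts) so an end-to-end run
    completes in minutes on one CPU."""
    base = dict(seed=seed, n_trees=200, n_perm=200, n_null=200)
    base.update(overrides)
    return RunConfig.from_dict(base)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(matrix: FeatureMatrix, samples: pd.DataFrame) -> list[dict]:
    """Machine-readable issue list; an empty list means the inputs are clean."""
    issues: list[dict] = []
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        issues.append({"issue": "duplicate sample id", "detail": sorted(set(dup))})
    known = set(samples["sample_id"])
    for sid in matrix.sample_ids:
        if sid not in known:
            issues.append({"issue": "unmatched sample", "detail": sid})
    bad_roles = set(samples["role"]) - {"sample", "QC", "blank"}
    if bad_roles:
        issues.append({"issue": "unknown role", "detail": sorted(bad_roles)})
    if matrix.stage not in STAGES:
        issues.append({"issue": "unknown stage flag", "detail": matrix.stage})
    if matrix.stage != "log2":
        arr = matrix.data.to_numpy()
        for i, j in zip(*np.nonzero(arr < 0)):
            issues.append({"issue": "negative intensity",
                           "detail": f"{matrix.sample_ids[i]}/{matrix.bin_ids[j]}"})
    return issues


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str})
    meta["group"] = meta.get("group", pd.Series(dtype=str)).fillna("")
    meta["timepoint"] = meta.get("timepoint", pd.Series(dtype=str)).fillna("")
    return meta


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages, writing outputs and a manifest.

    Returns the manifest dict.  On stage failure the partial outputs remain
    and a FAILED marker file names the stage; the exception propagates.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "leafprint", "version": __version__,
                      "config_hash": config.config_hash,
                      "config": config.to_dict(),
                      "seeds": {}, "stages": {}}
    current = "setup"
    try:
        # ---- inputs: simulate or load -----------------------------------
        current = "simulate"
        seed_sim = stage_seed(config.seed, "simulate")
        manifest["seeds"]["simulate"] = seed_sim
        if config.matrix is None:
            db, edge_df = generate_reference(
                n_compounds=config.n_compounds, n_pathways=config.n_pathways,
                seed=stage_seed(config.seed, "reference"))
            spec = SyntheticSpec(
                classes=tuple(config.classes), n_per_class=config.n_per_class,
                n_features=config.n_features,
                n_discriminating=config.n_discriminating,
                n_trend_features_per_archetype=config.n_trend_per_archetype,
                effect_size=config.effect_size, noise_sd=config.noise_sd,
                qc_n=config.qc_n, qc_rsd=config.qc_rsd,
                zero_rate=config.zero_rate, seed=seed_sim)
            fm, truth, meta = generate_feature_matrix(spec, reference=db,
                                                      bin_width=config.bin_width)
            if config.from_scans:
                scans = matrix_to_scans(fm, config.jitter_ppm, config.n_scans,
                                        seed=stage_seed(config.seed, "scans"),
                                        bin_width=config.bin_width,
                                        tic_fraction=config.tic_fraction)
                fm = bin_sample_set(list(scans.values()), config.tic_fraction,
                                    config.bin_width,
                                    (config.mz_min, config.mz_max))
            db.write(out / "compounds.csv")
            edge_df.to_csv(out / "edges.csv", index=False)
            meta.to_csv(out / "metadata.csv", index=False)
            fm.write(out / "matrix_raw.csv")
            truth.discriminating.to_csv(out / "truth_discriminating.csv", index=False)
            truth.trend_bins.to_csv(out / "truth_trends.csv", index=False)
            truth.compound_truth.to_csv(out / "truth_compounds.csv", index=False)
        else:
            if config.mzml_dir is not None:
                scansets = [read_mzml(p) for p in
                            sorted(Path(config.mzml_dir).glob("*.mzML"))]
                fm = bin_sample_set(scansets, config.tic_fraction,
                                    config.bin_width,
                                    (config.mz_min, config.mz_max))
            else:
                fm = FeatureMatrix.read(config.matrix)
            meta = read_metadata(config.metadata)
            db = FormulaDB.read(config.compounds) if config.compounds else None
            edge_df = pd.read_csv(config.edges) if config.edges else None
        issues = validate_inputs(fm, meta)
        if issues:
            raise ValueError(f"input validation failed: {issues[:5]}")
        manifest["stages"]["input"] = {"samples": len(fm.sample_ids),
                                       "bins": len(fm.bin_ids)}

        # ---- preprocessing ----------------------------------------------
        current = "preprocess"
        fm1 = occupancy_filter(fm, meta, class_key=config.label,
                               min_occupancy=config.occupancy)
        fm2 = qc_rsd_filter(fm1, meta, max_rsd=config.qc_rsd_max)
        fml = log2_transform(normalise_tic(fm2))
        fml.write(out / "matrix_log2.csv")
        manifest["stages"]["preprocess"] = {
            "bins_in": len(fm.bin_ids),
            "bins_after_occupancy": len(fm1.bin_ids),
            "bins_after_qc": len(fm2.bin_ids)}

        # ---- annotation --------------------------------------------------
        current = "annotate"
        records = []
        if db is not None:
            records = annotate_matrix(fml, db, tolerance_ppm=config.ppm,
                                      consensus_threshold=config.consensus)
            records_to_frame(records).to_csv(out / "annotations.csv", index=False)
            composition_summary(records).to_csv(out / "composition.csv", index=False)
            manifest["stages"]["annotate"] = {
                "bins": len(records),
                "classified": sum(r.classified for r in records)}

        # ---- classification ---------------------------------------------
        current = "classify"
        seed_cls = stage_seed(config.seed, "classify")
        manifest["seeds"]["classify"] = seed_cls
        bio = meta[meta["role"] == "sample"]
        Xc = fml.data.loc[bio["sample_id"]]
        yc = bio.set_index("sample_id")[config.label]
        fit = fit_rf_classifier(Xc, yc, n_trees=config.n_trees, seed=seed_cls)
        perm = permutation_test(Xc, yc, "margin", n_perm=config.n_perm,
                                n_trees=config.n_trees, seed=seed_cls)
        fit.p_value, fit.n_permutations = perm.p_value, perm.n_permutations
        fit.votes.to_csv(out / "votes.csv", float_format="%.6g")
        fit.proximity.to_csv(out / "proximity.csv", float_format="%.6g")
        D = proximity_to_distance(fit.proximity)
        ord_res = classical_mds(D, dims=2)
        coords = ord_res.coordinates.join(yc)
        coords.to_csv(out / "mds_coordinates.csv", float_format="%.6g")
        ell_rows = []
        for cls in fit.classes:
            pts = ord_res.coordinates[yc.reindex(ord_res.coordinates.index) == cls]
            if len(pts) >= 3:
                e = confidence_ellipse(pts, level=0.95)
                ell_rows.append({"class": cls, "cx": e.centre[0], "cy": e.centre[1],
                                 "cov_xx": e.covariance[0, 0],
                                 "cov_xy": e.covariance[0, 1],
                                 "cov_yy": e.covariance[1, 1],
                                 "radius2": e.quantile_radius2})
        pd.DataFrame(ell_rows).to_csv(out / "ellipses.csv", index=False,
                                      float_format="%.6g")
        intra = intraclass_distance_summary(D, yc)
        intra.drop(columns="distances").to_csv(out / "intraclass_distances.csv",
                                               index=False, float_format="%.6g")
        manifest["stages"]["classify"] = {
            "margin": fit.margin, "p_value": fit.p_value,
            "n_permutations": config.n_perm,
            "intraclass_medians": dict(zip(intra["class"], intra["median"]))}

        # ---- regression on sampling hour --------------------------------
        current = "regress"
        seed_reg = stage_seed(config.seed, "regress")
        manifest["seeds"]["regress"] = seed_reg
        hours = bio.set_index("sample_id")[config.time_col].astype(float)
        reg = regression_significance(fml.data.loc[hours.index], hours,
                                      n_perm=config.n_perm,
                                      n_trees=config.n_trees, seed=seed_reg,
                                      alpha=config.alpha)
        imp = pd.DataFrame({"importance": reg.importance,
                            "p_value": reg.importance_p})
        imp.index.name = "bin_id"
        imp.to_csv(out / "importance.csv", float_format="%.6g")
        pd.Series(reg.explanatory, name="bin_id").to_csv(
            out / "explanatory.csv", index=False)
        manifest["stages"]["regress"] = {
            "r2": reg.r2, "p_value": reg.p_value,
            "n_explanatory": len(reg.explanatory)}

        # ---- trend clustering -------------------------------------------
        current = "trends"
        seed_tr = stage_seed(config.seed, "trends")
        manifest["seeds"]["trends"] = seed_tr
        clusters = None
        if reg.explanatory:
            profiles = log2_ratio_profiles(fml, meta, reg.explanatory,
                                           baseline=config.baseline)
            k = min(config.k, len(profiles))
            tc = kmeans_trends(profiles, k=k, n_restarts=config.n_restarts,
                               seed=seed_tr)
            clusters = tc.assignments
            prof_out = profiles.copy()
            prof_out.insert(0, "cluster", clusters)
            prof_out.index.name = "bin_id"
            prof_out.to_csv(out / "trend_profiles.csv", float_format="%.6g")
            tc.centroids.rename_axis("cluster").to_csv(
                out / "trend_centroids.csv", float_format="%.6g")
            if len(profiles) > 3:  # elbow/silhouette report to justify k
                cluster_quality_report(profiles, seed=seed_tr).to_csv(
                    out / "trend_cluster_quality.csv", index=False,
                    float_format="%.6g")
            manifest["stages"]["trends"] = {
                "k": k, "sizes": clusters.value_counts().sort_index().to_dict()}

        # ---- enrichment --------------------------------------------------
        current = "enrich"
        seed_en = stage_seed(config.seed, "enrich")
        manifest["seeds"]["enrich"] = seed_en
        if clusters is not None and records:
            rec_by_bin = {r.bin_id: r for r in records}
            terms = {b: set(rec_by_bin[b].consensus_lineage)
                     for b in clusters.index if b in rec_by_bin}
            struct = cluster_structural_enrichment(clusters, terms)
            struct.to_csv(out / "structural_enrichment.csv", index=False,
                          float_format="%.6g")
            n_struct = len(struct)
            n_func = 0
            if edge_df is not None and len(edge_df):
                G = build_knowledge_graph(edge_df,
                                          compounds=list(db.table["compound_id"]))
                fc = {b: rec_by_bin[b].matched_compounds
                      for b in clusters.index if b in rec_by_bin}
                func = cluster_functional_enrichment(
                    clusters, fc, G, damping=config.damping,
                    n_null=config.n_null, seed=seed_en)
                func.to_csv(out / "functional_enrichment.csv", index=False,
                            float_format="%.6g")
                n_func = len(func)
            manifest["stages"]["enrich"] = {"structural_rows": n_struct,
                                            "functional_rows": n_func}
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {err}\n")
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", out)
    return manifest
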