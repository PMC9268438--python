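"""Declarative end-to-end pipeline: simulate/load -> preprocess ->
annotate -> normalize -> baselines -> SVM -> markers -> predict -> report.

:class:`PipelineConfig` captures every knob of the workflow (paths or
a synthetic-data section, screening thresholds, alignment tolerances,
missingness cutoff, model settings, seeds); :func:`run_pipeline`
executes the stages in order into a run directory, writing each
artifact as CSV/JSON plus a manifest with SHA-256 checksums and a
structured log with stage timings.  Every stochastic stage draws its
seed from the master seed through a fixed counter scheme
(``SeedSequence([master_seed, stage_counter])``), so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ginsengms import svm as svm_mod
from ginsengms.annotation import annotate_features, hits_to_frame, load_reference_db
from ginsengms.features import (
    FeatureTable,
    align_peaks,
    filter_common_peaks,
    project_onto_features,
    screen_peaks,
)
from ginsengms.markers import (
    ClassificationReport,
    accuracy_from_pairs,
    permutation_importance,
    predict_external,
    refit_on_markers,
    select_markers,
)
from ginsengms.multivariate import (
    fit_pca,
    fit_plsda,
    normalize_mean,
    normalize_zscore,
)
from ginsengms.simulate import SyntheticSpec, generate_peak_lists
from ginsengms.svm import cross_validate, grid_search

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "ARTIFACT_NAMES"]

logger = logging.getLogger(__name__)

# every successful run writes exactly these artifacts (plus manifest/log)
ARTIFACT_NAMES = [
    "feature_table.csv",
    "annotation_hits.csv",
    "normalized_mean.csv",
    "normalized_zscore.csv",
    "pca_summary.csv",
    "plsda_summary.csv",
    "grid_surface.csv",
    "training_report_raw.csv",
    "training_report_normalized.csv",
    "importance_report.csv",
    "marker_model.json",
    "test_report.csv",
    "summary.json",
]

# stage counters for the documented master-seed scheme
_SEED_SIMULATE = 1
_SEED_TEST_DATA = 2
_SEED_CV = 3
_SEED_IMPORTANCE = 4


@dataclass
class PipelineConfig:
    """All pipeline settings with study-condition defaults."""

    out_dir: str = "ginsengms_run"
    # input: either peak-list CSV paths (+ optional origins) or a synthetic spec
    peak_list_paths: list[str] = field(default_factory=list)
    origins: list[str] = field(default_factory=list)
    synthetic: dict[str, Any] = field(default_factory=dict)
    n_test_per_class: int = 3
    annotation_db: str | None = None  # None -> packaged reference DB
    # screening and alignment
    min_area: float = 1000.0
    charge: int = 1
    min_quality: float = 60.0
    mz_tol_ppm: float = 10.0
    rt_tol: float = 0.2
    max_missing_frac: float = 0.8
    annotate_mz_tol_ppm: float = 15.0
    annotate_rt_tol: float = 0.5
    # models
    pca_components: int = 2
    plsda_components: int = 2
    cv_folds: int = 10
    C_grid: list[float] | None = None
    gamma_grid: list[float] | None = None
    importance_repeats: int = 10
    report_mode: str = "out_of_fold"  # or "resubstitution"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.report_mode not in ("out_of_fold", "resubstitution"):
            raise ValueError("report_mode must be out_of_fold or resubstitution")
        for p in self.peak_list_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"peak list not found: {p}")
        if self.annotation_db is not None and not Path(self.annotation_db).exists():
            raise FileNotFoundError(f"annotation DB not found: {self.annotation_db}")
        if self.peak_list_paths and self.origins and len(self.origins) != len(
            self.peak_list_paths
        ):
            raise ValueError("origins must align with peak_list_paths")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, counter: int) -> int:
    return int(np.random.SeedSequence([master, counter]).generate_state(1)[0] % (2**31))


def make_report(
    raw_pairs: list[tuple[str, str]],
    norm_pairs: list[tuple[str, str]],
    test_pairs: list[tuple[str, str]] | None = None,
) -> str:
    """Side-by-side raw vs normalized classification table, plus an
    optional external-test block, as printable text."""
    if not raw_pairs or not norm_pairs:
        raise ValueError("pair lists must be nonempty")
    if len(raw_pairs) != len(norm_pairs):
        raise ValueError("raw and normalized blocks must have equal length")
    lines = [
        f"Raw Data (Accuracy = {accuracy_from_pairs(raw_pairs)}%)"
        f"    Normalized Data (Accuracy = {accuracy_from_pairs(norm_pairs)}%)",
        f"{'actual':>8} {'recognized':>11}    {'actual':>8} {'recognized':>11}",
    ]
    for (a1, r1), (a2, r2) in zip(raw_pairs, norm_pairs):
        lines.append(f"{a1:>8} {r1:>11}    {a2:>8} {r2:>11}")
    if test_pairs:
        lines.append("")
        lines.append(f"Test Samples (Accuracy = {accuracy_from_pairs(test_pairs)}%)")
        for a, r in test_pairs:
            lines.append(f"{a:>8} {r:>11}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage of the workflow into ``config.out_dir``.

    Returns the run directory; raises with the stage name on failure.
    The directory contains the artifacts in :data:`ARTIFACT_NAMES`,
    ``manifest.json`` (artifact checksums, seed, timings) and
    ``pipeline.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # ---- input: load or simulate peak lists -----------------------
        stage = "input"
        t0 = time.perf_counter()
        test_table = None
        truth_info: dict[str, Any] = {}
        if config.peak_list_paths:
            from ginsengms.features import PeakList

            origins = config.origins or [None] * len(config.peak_list_paths)
            peak_lists = [
                PeakList.from_csv(p, origin=o)
                for p, o in zip(config.peak_list_paths, origins)
            ]
        else:
            spec = SyntheticSpec(
                **{
                    "reference_coordinates": True,
                    **config.synthetic,
                    "seed": _stage_seed(config.seed, _SEED_SIMULATE),
                }
            )
            peak_lists, _, truth = generate_peak_lists(spec)
            truth_info = {
                "informative_features": truth.informative.tolist(),
            }
            # held-out batches: same population (same structural seed),
            # fresh per-sample draws
            test_spec = dataclasses.replace(spec, n_per_class=config.n_test_per_class)
            test_lists, _, _ = generate_peak_lists(
                test_spec, sample_seed=_stage_seed(config.seed, _SEED_TEST_DATA)
            )
        timings[stage] = time.perf_counter() - t0
        logger.info("input: %d peak lists", len(peak_lists))

        # ---- preprocess: screen, align, filter -------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        screened = [
            screen_peaks(pl, config.min_area, config.charge, config.min_quality)
            for pl in peak_lists
        ]
        table = align_peaks(screened, config.mz_tol_ppm, config.rt_tol)
        table = filter_common_peaks(table, config.max_missing_frac)
        table.to_csv(out / "feature_table.csv")
        if not config.peak_list_paths:
            test_screened = [
                screen_peaks(pl, config.min_area, config.charge, config.min_quality)
                for pl in test_lists
            ]
            # targeted extraction against the training features keeps
            # test columns aligned with the trained model by construction
            test_table = project_onto_features(
                table, test_screened, config.mz_tol_ppm, config.rt_tol
            )
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "preprocess: %d samples x %d common peaks", table.n_samples, table.n_features
        )
        if table.origins is None:
            raise ValueError("origin labels are required for classification")

        # ---- annotation -------------------------------------------------
        stage = "annotate"
        t0 = time.perf_counter()
        if config.annotation_db is None:
            db = load_reference_db()
        else:
            db = _load_db_csv(config.annotation_db)
        hits = annotate_features(
            table, db, config.annotate_mz_tol_ppm, config.annotate_rt_tol
        )
        hits_to_frame(hits).to_csv(out / "annotation_hits.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        logger.info("annotate: %d hits", len(hits))

        # ---- normalization ---------------------------------------------
        stage = "normalize"
        t0 = time.perf_counter()
        norm_mean = normalize_mean(table)
        norm_z = normalize_zscore(table)
        _write_matrix(out / "normalized_mean.csv", norm_mean.values, table)
        _write_matrix(out / "normalized_zscore.csv", norm_z.values, table)
        timings[stage] = time.perf_counter() - t0

        # ---- baselines: PCA and PLS-DA ---------------------------------
        stage = "baselines"
        t0 = time.perf_counter()
        pca = fit_pca(norm_z.values, config.pca_components)
        plsda = fit_plsda(
            norm_z.values,
            table.origins,
            n_components=config.plsda_components,
            seed=_stage_seed(config.seed, _SEED_CV),
        )
        _write_pca_summary(out / "pca_summary.csv", pca)
        _write_plsda_summary(out / "plsda_summary.csv", plsda)
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "baselines: PC1+PC2 %.1f%%, R2Y %.3f, Q2 %.3f",
            100 * pca.explained_variance_ratio.sum(),
            plsda.r2y,
            plsda.q2,
        )

        # ---- SVM grid search + training reports ------------------------
        stage = "svm"
        t0 = time.perf_counter()
        cv_seed = _stage_seed(config.seed, _SEED_CV)
        gs = grid_search(
            norm_z.values,
            table.origins,
            C_grid=config.C_grid,
            gamma_grid=config.gamma_grid,
            k=config.cv_folds,
            seed=cv_seed,
        )
        gs.to_frame().to_csv(out / "grid_surface.csv", index=False)
        raw_report = _training_report(table.areas, table, gs, config, cv_seed)
        norm_report = _training_report(norm_z.values, table, gs, config, cv_seed)
        raw_report.to_frame().to_csv(out / "training_report_raw.csv", index=False)
        norm_report.to_frame().to_csv(out / "training_report_normalized.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "svm: best C=%g gamma=%g, raw %d%%, normalized %d%%",
            gs.best_C,
            gs.best_gamma,
            raw_report.accuracy_percent,
            norm_report.accuracy_percent,
        )

        # ---- markers ----------------------------------------------------
        stage = "markers"
        t0 = time.perf_counter()
        imp = permutation_importance(
            norm_z.values,
            table.origins,
            C=gs.best_C,
            gamma=gs.best_gamma,
            n_repeats=config.importance_repeats,
            seed=_stage_seed(config.seed, _SEED_IMPORTANCE),
            cv_folds=config.cv_folds,
        )
        imp.feature_ids = table.feature_ids
        imp.to_frame().to_csv(out / "importance_report.csv", index=False)
        selected = select_markers(imp)
        if not selected:
            selected = [int(imp.ranking[0])]
            logger.warning("no positive-importance feature; falling back to top-ranked")
        marker_model, marker_report, marker_gs = refit_on_markers(
            norm_z.values,
            table.origins,
            selected,
            sample_ids=table.sample_ids,
            C_grid=config.C_grid,
            gamma_grid=config.gamma_grid,
            k=config.cv_folds,
            seed=cv_seed,
        )
        marker_model.to_json(out / "marker_model.json")
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "markers: %d selected, marker-model CV accuracy %d%%",
            len(selected),
            marker_report.accuracy_percent,
        )

        # ---- external prediction ---------------------------------------
        stage = "predict"
        t0 = time.perf_counter()
        if test_table is not None:
            test_report = predict_external(
                marker_model,
                test_table.areas,
                test_table.feature_ids,
                norm_z,
                [table.feature_ids[j] for j in selected],
                test_table.sample_ids,
                actual=test_table.origins,
            )
        else:
            test_report = ClassificationReport([], [], [])
        test_report.to_frame().to_csv(out / "test_report.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        # ---- summary + manifest ----------------------------------------
        stage = "report"
        summary = {
            "seed": config.seed,
            "n_samples": table.n_samples,
            "n_common_peaks": table.n_features,
            "n_annotation_hits": len(hits),
            "pca_first_two_pct": float(100 * pca.explained_variance_ratio[:2].sum()),
            "plsda_r2y": plsda.r2y,
            "plsda_q2": plsda.q2,
            "best_C": gs.best_C,
            "best_gamma": gs.best_gamma,
            "raw_accuracy_pct": raw_report.accuracy_percent,
            "normalized_accuracy_pct": norm_report.accuracy_percent,
            "n_markers": len(selected),
            "marker_accuracy_pct": marker_report.accuracy_percent,
            "test_accuracy_pct": (
                test_report.accuracy_percent if test_report.sample_ids else None
            ),
            "ground_truth": truth_info,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        report_text = make_report(
            raw_report.pairs,
            norm_report.pairs,
            test_report.pairs if test_report.sample_ids else None,
        )
        (out / "report.txt").write_text(report_text)
        manifest = {
            "seed": config.seed,
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
            "artifacts": {
                name: _sha256(out / name) for name in ARTIFACT_NAMES
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _load_db_csv(path: str):
    import pandas as pd

    from ginsengms.annotation import GinsenosideRecord, classify_aglycone

    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for r in df.itertuples():
        frags = tuple(float(x) for x in str(r.fragment_ions).split(";") if x.strip())
        records.append(
            GinsenosideRecord(
                index=int(r.no),
                rt=float(r.rt_min),
                name=str(r.name),
                formula=str(r.formula),
                mass_ion_mz=float(r.mass_ion_mz),
                ion_type=str(r.ion_type),
                error_ppm=float(r.error_ppm),
                fragment_ions=frags,
                aglycone_class=classify_aglycone(frags),
                reference=str(getattr(r, "reference", "")),
                notes=str(getattr(r, "notes", "")),
            )
        )
    return records


def _training_report(
    X: np.ndarray,
    table: FeatureTable,
    gs: svm_mod.GridSearchResult,
    config: PipelineConfig,
    cv_seed: int,
) -> ClassificationReport:
    if config.report_mode == "out_of_fold":
        _, recognized = cross_validate(
            X, table.origins, C=gs.best_C, gamma=gs.best_gamma,
            k=config.cv_folds, seed=cv_seed,
        )
    else:
        model = svm_mod.fit_multiclass_svm(
            X, table.origins, C=gs.best_C, gamma=gs.best_gamma
        )
        recognized = model.predict(X)
    return ClassificationReport(
        sample_ids=list(table.sample_ids),
        actual=list(table.origins),
        recognized=list(recognized),
    )


def _write_matrix(path: Path, values: np.ndarray, table: FeatureTable) -> None:
    import pandas as pd

    df = pd.DataFrame(values, columns=table.feature_ids)
    df.insert(0, "origin", table.origins if table.origins is not None else "")
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False)


def _write_pca_summary(path: Path, pca) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.explained_variance_ratio) + 1),
            "explained_variance_ratio": pca.explained_variance_ratio,
        }
    ).to_csv(path, index=False)


def _write_plsda_summary(path: Path, plsda) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "metric": ["n_components", "r2y", "q2"],
            "value": [plsda.n_components, plsda.r2y, plsda.q2],
        }
    ).to_csv(path, index=False)
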