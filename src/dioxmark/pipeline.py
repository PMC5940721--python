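"""End-to-end marker-identification pipeline.

Composes the stages in the order of the underlying analysis: LOD/2
substitution and the all-matrix 50% detection filter; per-matrix
Spearman-dissimilarity clustering with multiscale-bootstrap AU
stability; MGV transformation, PC1 summary and greedy marker selection
inside each stable cluster with more than two members; and finally the
representative-PCB sum vs total PCDD/F correlations plus the
per-congener cross-matrix correlation table.  All randomness flows from
one master seed through documented per-stage substreams, so a run is
fully reproducible from its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import DendrogramNode, agglomerate, spearman_matrix
from .correlate import (
    CorrelationResult,
    cross_matrix_table,
    marker_sum_analysis,
    results_to_frame,
)
from .dataset import ExposureDataset
from .io import read_exposure_csv
from .markers import MarkerSelectionResult, pc1_score, select_markers
from .mgv import mgv
from .panel import MATRICES, default_panel
from .preprocess import FilterReport, filter_detect, impute_lod
from .simulate import generate_dataset, study_blockspec
from .stability import (
    DEFAULT_LAMBDAS,
    ClusteringConfig,
    ClusterStabilityRecord,
    bootstrap_bp,
    fit_all,
    stable_clusters,
)

#: The higher-chlorinated dl-PCBs added to the cord-tissue marker sum in
#: the augmented analysis variant.
MEDIUM_HIGH_DLPCBS = ["PCB114", "PCB156", "PCB157", "PCB167", "PCB169", "PCB189"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    # input: either CSV paths or a synthetic cohort
    matrix_paths: Optional[dict[str, str]] = None
    panel_path: Optional[str] = None
    detected_paths: Optional[dict[str, str]] = None
    n_subjects: int = 41
    rho_within: float = 0.9
    rho_between: float = 0.3
    lod_placement: str = "empirical"
    # preprocessing
    detection_threshold: float = 0.5
    # clustering / stability
    linkage: str = "average"
    tie_rule: str = "average"
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    bootstrap_B: int = 1000
    au_threshold: float = 0.95
    # MGV / marker selection
    mgv_knots: int = 3
    mgv_tol: float = 1e-6
    mgv_max_iter: int = 50
    r2_target: float = 0.95
    # correlation stage
    ci_B: int = 10000
    ci_level: float = 0.95
    add_to_marker_sum: tuple[str, ...] = ("PCB77",)
    extra_congeners: dict[str, list[str]] = field(
        default_factory=lambda: {"cord_tissue": list(MEDIUM_HIGH_DLPCBS)}
    )
    # bookkeeping
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lambdas" in doc:
            doc["lambdas"] = tuple(doc["lambdas"])
        if "add_to_marker_sum" in doc:
            doc["add_to_marker_sum"] = tuple(doc["add_to_marker_sum"])
        return cls(**doc)

    def validate(self) -> None:
        if not 0 <= self.detection_threshold <= 1:
            raise ValueError("detection_threshold must lie in [0, 1]")
        if not 0 < self.au_threshold <= 1:
            raise ValueError("au_threshold must lie in (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.bootstrap_B < 1 or self.ci_B < 1:
            raise ValueError("bootstrap replicate counts must be >= 1")
        if any(not 0 < l <= 2 for l in self.lambdas):
            raise ValueError("sampling fractions must lie in (0, 2]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class MatrixAnalysis:
    """Per-matrix clustering, stability and marker-selection results."""

    matrix: str
    dissimilarity: pd.DataFrame
    dendrogram: DendrogramNode
    stability: dict[frozenset[str], ClusterStabilityRecord]
    stable: list[frozenset[str]]
    selections: list[MarkerSelectionResult] = field(default_factory=list)
    transformed: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: ExposureDataset  # imputed, filtered, TEQ units
    filter_report: FilterReport
    per_matrix: dict[str, MatrixAnalysis]
    markers_per_matrix: dict[str, list[str]]
    correlations: list[CorrelationResult]
    cross_matrix: pd.DataFrame
    scatter_data: pd.DataFrame


def _stage_seed(master: int, stage: int) -> int:
    state = np.random.SeedSequence([master, stage]).generate_state(1)[0]
    return int(state % (2**31))


def load_input(config: RunConfig) -> ExposureDataset:
    """Read the configured CSVs, or draw the synthetic cohort."""
    if config.matrix_paths:
        if not config.panel_path:
            raise ValueError("panel_path required with matrix_paths")
        return read_exposure_csv(
            config.matrix_paths, config.panel_path, config.detected_paths
        )
    panel = default_panel()
    spec = study_blockspec(
        rho_within=config.rho_within, rho_between=config.rho_between
    )
    return generate_dataset(
        panel,
        config.n_subjects,
        spec,
        seed=_stage_seed(config.seed, 0),
        lod_placement=config.lod_placement,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the report bundle."""
    config.validate()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = load_input(config)

    filtered, report = filter_detect(raw, config.detection_threshold)
    data = impute_lod(filtered)

    cluster_cfg = ClusteringConfig(linkage=config.linkage, tie_rule=config.tie_rule)
    per_matrix: dict[str, MatrixAnalysis] = {}
    markers_per_matrix: dict[str, list[str]] = {}
    for mi, m in enumerate(data.matrices):
        x = data.matrices[m]
        dm = spearman_matrix(
            x, tie_rule=config.tie_rule, seed=_stage_seed(config.seed, 10 + mi)
        )
        root = agglomerate(dm, linkage=config.linkage)
        records = bootstrap_bp(
            x,
            root,
            lambdas=config.lambdas,
            B=config.bootstrap_B,
            clustering=cluster_cfg,
            seed=_stage_seed(config.seed, 20 + mi),
        )
        fit_all(records, threshold=config.au_threshold)
        stable = stable_clusters(records, config.au_threshold, n_leaves=x.shape[1])

        analysis = MatrixAnalysis(
            matrix=m,
            dissimilarity=dm.d,
            dendrogram=root,
            stability=records,
            stable=stable,
        )
        marker_ids: list[str] = []
        for cl in stable:
            members = sorted(cl)
            label = "+".join(members)
            if len(members) > 2:
                tm = mgv(
                    x[members],
                    k=config.mgv_knots,
                    tol=config.mgv_tol,
                    max_iter=config.mgv_max_iter,
                )
                scores, pc1_var = pc1_score(tm.scores)
                sel = select_markers(
                    x[members], scores, r2_target=config.r2_target, k=config.mgv_knots
                )
                sel.pc1_var = pc1_var
                analysis.transformed[label] = tm.scores
            else:
                # two-member stable clusters bypass PCA/selection
                sel = MarkerSelectionResult(
                    cluster=members,
                    pc1_var=np.nan,
                    markers=members,
                    final_r2=np.nan,
                )
            analysis.selections.append(sel)
            marker_ids.extend(
                c for c in sel.markers if data.panel.compound_class(c) == "dlPCB"
            )
        per_matrix[m] = analysis
        markers_per_matrix[m] = sorted(dict.fromkeys(marker_ids))

    # matrices without any stable dl-PCB cluster borrow the union of
    # markers found elsewhere (the representative set still has to be
    # summable in that matrix)
    union = sorted(
        {c for mk in markers_per_matrix.values() for c in mk}
    )
    retained = set(data.congeners)
    for m in markers_per_matrix:
        if not markers_per_matrix[m]:
            markers_per_matrix[m] = union
    sum_sets = {
        m: [c for c in dict.fromkeys(list(config.add_to_marker_sum) + mk)
            if c in retained]
        for m, mk in markers_per_matrix.items()
    }
    extra = {
        m: [c for c in cs if c in retained]
        for m, cs in (config.extra_congeners or {}).items()
        if m in sum_sets
    }
    pcddf = [
        c
        for c in data.congeners
        if data.panel.compound_class(c) in ("PCDD", "PCDF")
    ]

    correlations = marker_sum_analysis(
        data,
        sum_sets,
        pcddf_group=pcddf,
        extra_congeners=extra,
        B=config.ci_B,
        level=config.ci_level,
        seed=_stage_seed(config.seed, 30),
    )
    cross = cross_matrix_table(data)

    from .preprocess import sum_groups

    scatter_rows = []
    for m, mk in sum_sets.items():
        sums = sum_groups(data, {"pcb_sum": mk, "pcddf_sum": pcddf})[m]
        for sid, row in sums.iterrows():
            scatter_rows.append(
                {
                    "matrix": m,
                    "subject_id": sid,
                    "pcb_sum": row["pcb_sum"],
                    "pcddf_sum": row["pcddf_sum"],
                }
            )
    scatter = pd.DataFrame(scatter_rows)

    result = PipelineResult(
        config=config,
        dataset=data,
        filter_report=report,
        per_matrix=per_matrix,
        markers_per_matrix=markers_per_matrix,
        correlations=correlations,
        cross_matrix=cross,
        scatter_data=scatter,
    )
    if config.outdir:
        write_report_bundle(result, config.outdir)
    return result


def stability_frame(
    records: dict[frozenset[str], ClusterStabilityRecord]
) -> pd.DataFrame:
    rows = []
    for rec in records.values():
        row = {"members": ";".join(sorted(rec.members))}
        for lam, bp in sorted(rec.bp.items()):
            row[f"bp_{lam:g}"] = bp
        row.update(
            alpha=rec.alpha, beta=rec.beta, au=rec.au,
            stable=rec.stable, fit_ok=rec.fit_ok,
        )
        rows.append(row)
    rows.sort(key=lambda r: r["members"])
    return pd.DataFrame(rows)


def write_report_bundle(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.filter_report.to_csv(out / "filter_report.csv")
    marker_rows = []
    for m, analysis in result.per_matrix.items():
        result.dataset.matrices[m]  # noqa: B018 - presence check
        analysis.dissimilarity.to_csv(
            out / f"dissimilarity_{m}.csv", index_label="congener_id"
        )
        (out / f"dendrogram_{m}.nwk").write_text(
            analysis.dendrogram.to_newick() + "\n"
        )
        stability_frame(analysis.stability).to_csv(
            out / f"stability_{m}.csv", index=False
        )
        for label, scores in analysis.transformed.items():
            scores.to_csv(
                out / f"transformed_{m}_{label}.csv", index_label="subject_id"
            )
        for sel in analysis.selections:
            marker_rows.append(
                {"matrix": m, "cluster": ";".join(sel.cluster), **sel.to_row()}
            )
    pd.DataFrame(marker_rows).to_csv(out / "markers.csv", index=False)
    results_to_frame(result.correlations).to_csv(
        out / "correlations.csv", index=False
    )
    result.scatter_data.to_csv(out / "scatter_data.csv", index=False)
    result.cross_matrix.to_csv(out / "cross_matrix.csv", index_label="congener_id")

    manifest = {
        "dioxmark_version": __version__,
        "seed": result.config.seed,
        "config": _jsonable(asdict(result.config)),
        "n_subjects": result.dataset.n_subjects,
        "n_congeners_retained": len(result.dataset.congeners),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
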