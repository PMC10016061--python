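"""End-to-end orchestration: simulate -> normalize -> filter -> integrate ->
semi-metric -> compare -> report.

Two entry styles are provided.  :func:`process_subject` / :func:`run_cohort`
work in memory and are what tests, simulations and the analysis drivers use.
The staged functions (``stage_simulate`` .. ``stage_report``) mirror the same
computation on disk — every stage writes its intermediates as CSV into a run
directory so any step can be re-run and audited — and back the command-line
interface.  Identical config and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import integration, semimetric, stats, volumes
from .core import (
    INTEGRATED,
    ConnectomeError,
    MultiLayerConnectome,
    NetworkDescriptors,
    RegionTable,
    WeightedConnectome,
    descriptors,
    normalize_connectome,
    read_connectome,
    write_connectome,
)
from .omst import OMSTTrace, omst_filter
from .synthetic import SyntheticConfig, generate_cohort, generate_volumes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Serializable settings of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alpha: float = 0.05
    max_rounds: int | None = None
    t_min_exp: float = -2.5
    t_max_exp: float = 2.5
    t_num: int = 100
    weight_strategy: str = "mean"
    edge_presence_threshold: float = 0.5
    volume_asymmetry_shift: float = 0.0

    def t_grid(self) -> np.ndarray:
        return np.logspace(self.t_min_exp, self.t_max_exp, self.t_num)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SubjectResult:
    """Everything the pipeline derives for one subject."""

    subject_id: str
    filtered: MultiLayerConnectome
    traces: dict[str, OMSTTrace]
    gdd: np.ndarray
    layer_weights: dict[str, float]
    integrated: WeightedConnectome
    descriptors: NetworkDescriptors
    smr: semimetric.SMRMatrix
    summary: semimetric.SemiMetricSummary


@dataclass
class CohortResults:
    """Cohort-level collection feeding the group statistics."""

    manifest: pd.DataFrame
    regions: RegionTable
    summaries: pd.DataFrame  # indexed by subject_id
    smp_nodes: pd.DataFrame  # subjects x nodes
    smr_stack: np.ndarray  # (subjects, N, N), NaN where absent
    descriptors: pd.DataFrame
    bai_vol: pd.DataFrame | None = None
    subject_results: list[SubjectResult] | None = None

    def groups(self) -> pd.Series:
        return self.manifest.set_index("subject_id")["group"]


def process_subject(ml: MultiLayerConnectome, cfg: RunConfig | None = None) -> SubjectResult:
    """Normalise, filter, fuse and profile one subject's nine layers."""
    cfg = cfg or RunConfig()
    filtered = {}
    traces = {}
    for name, layer in ml.layers.items():
        norm = normalize_connectome(layer)
        f, trace = omst_filter(norm, max_rounds=cfg.max_rounds)
        filtered[name] = f
        traces[name] = trace
    fml = MultiLayerConnectome(subject_id=ml.subject_id, layers=filtered)
    gdd = integration.gdd_matrix(fml, t_grid=cfg.t_grid())
    weights = integration.informativeness_weights(
        gdd, list(fml.layers), strategy=cfg.weight_strategy
    )
    integrated = integration.integrate_layers(fml, weights)
    smr, summary = semimetric.semimetric_profile(integrated)
    return SubjectResult(
        subject_id=ml.subject_id,
        filtered=fml,
        traces=traces,
        gdd=gdd,
        layer_weights=weights,
        integrated=integrated,
        descriptors=descriptors(integrated),
        smr=smr,
        summary=summary,
    )


def run_cohort(
    subjects: list[MultiLayerConnectome],
    manifest: pd.DataFrame,
    cfg: RunConfig | None = None,
    subject_volumes: dict[str, volumes.VolumeSet] | None = None,
    keep_subject_results: bool = False,
) -> CohortResults:
    """Process every subject and assemble the cohort-level tables."""
    cfg = cfg or RunConfig()
    regions = subjects[0].regions
    rows = {}
    smp_rows = {}
    desc_rows = {}
    stack = np.full((len(subjects), regions.n, regions.n), np.nan)
    results = [] if keep_subject_results else None
    for k, ml in enumerate(subjects):
        res = process_subject(ml, cfg)
        rows[ml.subject_id] = res.summary.as_row()
        smp_rows[ml.subject_id] = res.summary.smp_node
        desc_rows[ml.subject_id] = res.descriptors.as_dict()
        stack[k] = res.smr.smr
        if results is not None:
            results.append(res)
    order = [ml.subject_id for ml in subjects]
    summaries = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    smp_nodes = pd.DataFrame.from_dict(smp_rows, orient="index", columns=regions.names).loc[order]
    desc = pd.DataFrame.from_dict(desc_rows, orient="index").loc[order]
    bai_vol_df = None
    if subject_volumes is not None:
        nets = volumes.default_subnetworks(regions)
        bai_vol_df = pd.DataFrame(
            {
                net.name: {
                    sid: volumes.bai_vol(subject_volumes[sid], net, regions)
                    for sid in order
                }
                for net in nets
            }
        ).loc[order]
    return CohortResults(
        manifest=manifest,
        regions=regions,
        summaries=summaries,
        smp_nodes=smp_nodes,
        smr_stack=stack,
        descriptors=desc,
        bai_vol=bai_vol_df,
        subject_results=results,
    )


def compare_cohort(res: CohortResults, cfg: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    cfg = cfg or RunConfig()
    return stats.compare_groups(
        res.groups(),
        res.summaries,
        res.smp_nodes,
        res.smr_stack,
        res.regions,
        descriptors=res.descriptors,
        bai_vol=res.bai_vol,
        alpha=cfg.alpha,
        edge_presence_threshold=cfg.edge_presence_threshold,
    )


def run_pipeline(
    cfg: RunConfig, outdir: str | Path
) -> tuple[CohortResults, dict[str, pd.DataFrame]]:
    """Full synthetic run on disk: all stages, intermediates written."""
    outdir = Path(outdir)
    stage_simulate(cfg, outdir)
    stage_filter(cfg, outdir)
    stage_integrate(cfg, outdir)
    stage_semimetric(cfg, outdir)
    families = stage_compare(cfg, outdir)
    stage_report(cfg, outdir)
    res = _load_cohort_results(cfg, outdir)
    return res, families


# ---------------------------------------------------------------------------
# Disk stages


def _matrix_path(root: Path, sid: str, metric: str) -> Path:
    return root / f"{sid}_{metric}.csv"


def _read_manifest(outdir: Path) -> pd.DataFrame:
    path = outdir / "cohort" / "manifest.csv"
    if not path.exists():
        raise ConnectomeError(f"[simulate] no manifest at {path}; run simulate first")
    return pd.read_csv(path)


def _regions_of_run(outdir: Path) -> RegionTable:
    return RegionTable.from_csv(outdir / "cohort" / "regions.csv")


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate the synthetic cohort and write matrices, manifest, volumes."""
    logger.info("[simulate] generating cohort (seed=%d)", cfg.synthetic.seed)
    outdir = Path(outdir)
    cohort_dir = outdir / "cohort"
    mat_dir = cohort_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    subjects, manifest = generate_cohort(cfg.synthetic)
    regions = subjects[0].regions
    regions.to_csv(cohort_dir / "regions.csv")
    manifest.to_csv(cohort_dir / "manifest.csv", index=False)
    for ml in subjects:
        for metric, layer in ml.layers.items():
            write_connectome(layer, _matrix_path(mat_dir, ml.subject_id, metric))
    vols = generate_volumes(cfg.synthetic, cfg.volume_asymmetry_shift)
    vol_rows = [
        {"subject_id": sid, "region": i + 1, "volume": v}
        for sid, vs in vols.items()
        for i, v in enumerate(vs.volumes)
    ]
    pd.DataFrame(vol_rows).to_csv(cohort_dir / "volumes.csv", index=False)
    pd.DataFrame(
        [
            {"subject_id": sid, "icv_left": vs.icv_left, "icv_right": vs.icv_right}
            for sid, vs in vols.items()
        ]
    ).to_csv(cohort_dir / "icv.csv", index=False)


def _layer_names_of_run(cfg: RunConfig) -> tuple[str, ...]:
    return cfg.synthetic.layer_names()


def stage_filter(cfg: RunConfig, outdir: Path) -> None:
    """Normalise every layer and apply OMST filtering; write filtered
    matrices plus a per-layer trace summary."""
    outdir = Path(outdir)
    manifest = _read_manifest(outdir)
    regions = _regions_of_run(outdir)
    mat_dir = outdir / "cohort" / "matrices"
    out_dir = outdir / "filtered"
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_rows = []
    for sid in manifest["subject_id"]:
        for metric in _layer_names_of_run(cfg):
            layer = read_connectome(_matrix_path(mat_dir, sid, metric), regions, metric)
            norm = normalize_connectome(layer)
            filt, trace = omst_filter(norm, max_rounds=cfg.max_rounds)
            write_connectome(filt, _matrix_path(out_dir, sid, metric))
            sel = trace.rounds[trace.selected_round - 1]
            trace_rows.append(
                {
                    "subject_id": sid,
                    "metric": metric,
                    "selected_round": trace.selected_round,
                    "rounds_scanned": len(trace.rounds),
                    "cost": sel.cost,
                    "global_efficiency": sel.global_efficiency,
                    "objective": sel.objective,
                }
            )
        logger.info("[filter] %s done", sid)
    pd.DataFrame(trace_rows).to_csv(out_dir / "omst_summary.csv", index=False)


def stage_integrate(cfg: RunConfig, outdir: Path) -> None:
    """Fuse the filtered layers of every subject; write integrated matrices,
    per-subject GDD matrices and the layer-weight table."""
    outdir = Path(outdir)
    manifest = _read_manifest(outdir)
    regions = _regions_of_run(outdir)
    filt_dir = outdir / "filtered"
    out_dir = outdir / "integrated"
    gdd_dir = out_dir / "gdd"
    gdd_dir.mkdir(parents=True, exist_ok=True)
    names = list(_layer_names_of_run(cfg))
    weight_rows = []
    for sid in manifest["subject_id"]:
        layers = {
            m: read_connectome(_matrix_path(filt_dir, sid, m), regions, m) for m in names
        }
        fml = MultiLayerConnectome(subject_id=sid, layers=layers)
        gdd = integration.gdd_matrix(fml, t_grid=cfg.t_grid())
        weights = integration.informativeness_weights(gdd, names, strategy=cfg.weight_strategy)
        integrated = integration.integrate_layers(fml, weights)
        write_connectome(integrated, out_dir / f"{sid}.csv")
        pd.DataFrame(gdd, index=names, columns=names).to_csv(gdd_dir / f"{sid}.csv")
        weight_rows.append({"subject_id": sid, **weights})
        logger.info("[integrate] %s done", sid)
    pd.DataFrame(weight_rows).to_csv(out_dir / "layer_weights.csv", index=False)


def stage_semimetric(cfg: RunConfig, outdir: Path) -> None:
    """Semi-metric analysis of every integrated network; write the SMR
    matrices, scale summaries, node-level SMP and network descriptors."""
    outdir = Path(outdir)
    manifest = _read_manifest(outdir)
    regions = _regions_of_run(outdir)
    int_dir = outdir / "integrated"
    out_dir = outdir / "semimetric"
    smr_dir = out_dir / "smr"
    smr_dir.mkdir(parents=True, exist_ok=True)
    sum_rows = {}
    smp_rows = {}
    desc_rows = {}
    for sid in manifest["subject_id"]:
        integrated = read_connectome(int_dir / f"{sid}.csv", regions, INTEGRATED)
        smr, summary = semimetric.semimetric_profile(integrated)
        smr.to_frame(regions).to_csv(smr_dir / f"{sid}.csv", float_format="%.10g")
        sum_rows[sid] = summary.as_row()
        smp_rows[sid] = summary.smp_node
        desc_rows[sid] = descriptors(integrated).as_dict()
        logger.info("[semimetric] %s done", sid)
    pd.DataFrame.from_dict(sum_rows, orient="index").rename_axis("subject_id").to_csv(
        out_dir / "summaries.csv"
    )
    pd.DataFrame.from_dict(smp_rows, orient="index", columns=regions.names).rename_axis(
        "subject_id"
    ).to_csv(out_dir / "smp_nodes.csv")
    pd.DataFrame.from_dict(desc_rows, orient="index").rename_axis("subject_id").to_csv(
        out_dir / "descriptors.csv"
    )


def _load_cohort_results(cfg: RunConfig, outdir: Path) -> CohortResults:
    outdir = Path(outdir)
    manifest = _read_manifest(outdir)
    regions = _regions_of_run(outdir)
    sm_dir = outdir / "semimetric"
    if not (sm_dir / "summaries.csv").exists():
        raise ConnectomeError("[compare] no semi-metric outputs; run semimetric first")
    summaries = pd.read_csv(sm_dir / "summaries.csv", index_col="subject_id")
    smp_nodes = pd.read_csv(sm_dir / "smp_nodes.csv", index_col="subject_id")
    desc = pd.read_csv(sm_dir / "descriptors.csv", index_col="subject_id")
    order = manifest["subject_id"].tolist()
    stack = np.full((len(order), regions.n, regions.n), np.nan)
    for k, sid in enumerate(order):
        df = pd.read_csv(sm_dir / "smr" / f"{sid}.csv", index_col=0)
        stack[k] = df.to_numpy(dtype=float)
    vols_df = pd.read_csv(outdir / "cohort" / "volumes.csv")
    icv_df = pd.read_csv(outdir / "cohort" / "icv.csv").set_index("subject_id")
    subject_volumes = {}
    for sid, sub in vols_df.groupby("subject_id"):
        v = sub.sort_values("region")["volume"].to_numpy()
        subject_volumes[sid] = volumes.VolumeSet(
            volumes=v,
            icv_left=float(icv_df.loc[sid, "icv_left"]),
            icv_right=float(icv_df.loc[sid, "icv_right"]),
        )
    nets = volumes.default_subnetworks(regions)
    bai_vol_df = pd.DataFrame(
        {
            net.name: {sid: volumes.bai_vol(subject_volumes[sid], net, regions) for sid in order}
            for net in nets
        }
    ).loc[order]
    return CohortResults(
        manifest=manifest,
        regions=regions,
        summaries=summaries.loc[order],
        smp_nodes=smp_nodes.loc[order],
        smr_stack=stack,
        descriptors=desc.loc[order],
        bai_vol=bai_vol_df,
    )


def stage_compare(cfg: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    """Group comparisons per family; write the family tables and a JSON
    report of rejection counts and settings."""
    outdir = Path(outdir)
    res = _load_cohort_results(cfg, outdir)
    families = compare_cohort(res, cfg)
    stats_dir = outdir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    for fid, df in families.items():
        df.to_csv(stats_dir / f"family_{fid}.csv", index=False)
    report = {
        "alpha": cfg.alpha,
        "edge_presence_threshold": cfg.edge_presence_threshold,
        "families": stats.rejection_counts(families),
    }
    with open(stats_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("[compare] families written to %s", stats_dir)
    return families


def summarize_cohort(res: CohortResults) -> pd.DataFrame:
    """Group mean +- SD of every scale-level index (report layout)."""
    joined = res.summaries.join(res.descriptors).join(
        res.manifest.set_index("subject_id")["group"]
    )
    if res.bai_vol is not None:
        joined = joined.join(res.bai_vol.add_prefix("bai_vol_"))
    grouped = joined.groupby("group")
    mean = grouped.mean(numeric_only=True)
    sd = grouped.std(numeric_only=True)
    out = pd.concat({"mean": mean, "sd": sd}, axis=0)
    return out.round(6)


def render_report(res: CohortResults, families: dict[str, pd.DataFrame]) -> str:
    """Human-readable run summary."""
    lines = ["semiconn run report", "=" * 60]
    table = summarize_cohort(res)
    lines.append("\nScale-level indices (group mean / SD):\n")
    lines.append(table.T.to_string())
    lines.append("\nRejections per family (alpha-level FDR within family):")
    for fid, c in stats.rejection_counts(families).items():
        lines.append(f"  {fid:12s} {c['n_significant']:4d} / {c['n_comparisons']} significant")
    for fid in ("smr_scales", "smp_scales", "descriptors", "bai_vol"):
        if fid in families and len(families[fid]):
            lines.append(f"\nFamily {fid}:")
            lines.append(families[fid].to_string(index=False))
    return "\n".join(lines) + "\n"


def stage_report(cfg: RunConfig, outdir: Path) -> str:
    outdir = Path(outdir)
    if not (outdir / "stats" / "report.json").exists():
        msg = f"no outputs under {outdir}; nothing to report\n"
        (outdir / "report.txt").parent.mkdir(parents=True, exist_ok=True)
        (outdir / "report.txt").write_text(msg)
        return msg
    res = _load_cohort_results(cfg, outdir)
    families = {
        p.stem.removeprefix("family_"): pd.read_csv(p)
        for p in sorted((outdir / "stats").glob("family_*.csv"))
    }
    text = render_report(res, families)
    (outdir / "report.txt").write_text(text)
    return text
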