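"""End-to-end orchestration: simulate/load -> preprocess -> PLI -> MST -> power -> stats.

The pipeline consumes either a synthetic cohort specification or a
manifest of recordings on disk, and emits (i) a wide cohort table with
one row per subject and band holding mean PLI, the four MST descriptors,
MST dissimilarity against the control reference tree, and relative band
power; (ii) a long per-epoch table; (iii) group-comparison and
correlation tables with FDR control over the four bands; and (iv) a
JSON run manifest echoing every convention in force, sufficient to
re-run the analysis identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ConnectivityMatrix, global_mean_pli, mean_upper_triangle, pli_matrix
from .io import read_manifest, read_recording
from .mst import SpanningTree, build_mst, compute_metrics, mst_dissimilarity, reference_tree
from .preprocess import (
    BANDS,
    BandDefinition,
    Recording,
    bandpass_filter,
    drop_bad_channels,
    extract_epochs,
    rereference_common_average,
)
from .simulate import CohortSpec, Subject, generate_cohort
from .spectral import relative_band_power, welch_psd
from .stats import TestResult, epoch_level_correlation, fdr_bh, mann_whitney, spearman

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report"]

#: Outcome columns subjected to group comparison and correlation analysis.
OUTCOMES: tuple[str, ...] = (
    "mean_pli",
    "leaf_fraction",
    "diameter",
    "kappa",
    "hierarchy",
    "dissimilarity",
    "relative_power",
)


@dataclass
class RunConfig:
    """Every convention of a pipeline run in one place.

    Exactly one of ``cohort`` (synthetic specification) or ``manifest``
    (path to a table of recordings on disk) must be provided.
    """

    cohort: CohortSpec | None = None
    manifest: str | Path | None = None
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    n_epochs: int = 4
    epoch_length: int = 2048
    filter_order: int = 4
    edge_trim: int = 0
    rereference: bool = True
    reference_exclusions: tuple[str, ...] = ()
    bad_channels: tuple[str, ...] = ()
    welch_nperseg: int = 512
    welch_overlap: float = 0.5
    welch_window: str = "hamming"
    normalize_diameter: bool = True
    aggregation: str = "epoch_metrics"
    q: float = 0.05
    exact_threshold: int = 8
    compute_power: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("provide exactly one of cohort= or manifest=")
        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise ValueError(f"unknown band names {unknown}; choose from {sorted(BANDS)}")
        if self.aggregation not in ("epoch_metrics", "mean_matrix"):
            raise ValueError("aggregation must be 'epoch_metrics' or 'mean_matrix'")


@dataclass
class PipelineResult:
    """All pipeline outputs, as pandas tables plus the run manifest dict."""

    cohort_table: pd.DataFrame
    epoch_table: pd.DataFrame
    group_stats: pd.DataFrame
    correlations: pd.DataFrame
    epoch_correlations: pd.DataFrame
    run_manifest: dict


def _load_subjects(config: RunConfig) -> list[Subject]:
    if config.cohort is not None:
        logger.info(
            "simulating cohort: %d patients, %d controls, %d channels",
            config.cohort.n_patients,
            config.cohort.n_controls,
            config.cohort.control_topology.n_channels,
        )
        return generate_cohort(config.cohort)
    df = read_manifest(config.manifest)
    subjects = []
    for row in df.itertuples(index=False):
        rec = read_recording(row.path, fs=float(getattr(row, "fs", 256.0)))
        subjects.append(
            Subject(
                subject_id=str(row.subject_id),
                group=str(row.group),
                disability=int(row.disability),
                recording=rec,
                topology_shift=float("nan"),
                tree_edges=(),
            )
        )
    return subjects


def _preprocess(rec: Recording, config: RunConfig):
    rec = replace(
        rec,
        bad_channels=config.bad_channels,
        reference_exclusions=config.reference_exclusions,
    )
    if config.rereference:
        rec = rereference_common_average(rec)
    rec = drop_bad_channels(rec)
    return extract_epochs(rec, config.n_epochs, config.epoch_length)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; deterministic given the config (incl. seed)."""
    subjects = _load_subjects(config)
    bands = [BANDS[b] for b in config.bands]

    # Per-subject connectivity, spectra, and per-band matrices.
    per_subject: dict[str, dict] = {}
    for subj in subjects:
        epochs = _preprocess(subj.recording, config)
        entry: dict = {"subject": subj, "bands": {}}
        if config.compute_power:
            nperseg = min(config.welch_nperseg, config.epoch_length)
            psds = [
                welch_psd(
                    epochs.data[e],
                    fs=epochs.fs,
                    nperseg=nperseg,
                    overlap=config.welch_overlap,
                    window=config.welch_window,
                )
                for e in range(epochs.n_epochs)
            ]
            entry["psds"] = psds
        for band in bands:
            filtered = bandpass_filter(epochs, band, order=config.filter_order)
            mats = pli_matrix(filtered, edge_trim=config.edge_trim)
            entry["bands"][band.name] = {"matrices": mats}
        per_subject[subj.subject_id] = entry
    logger.info(
        "connectivity done: %d subjects, %d epochs x %d bands each",
        len(subjects),
        config.n_epochs,
        len(bands),
    )

    # Reference tree per band from the mean of all control matrices.
    references: dict[str, SpanningTree] = {}
    for band in bands:
        control_mats: list[ConnectivityMatrix] = []
        for entry in per_subject.values():
            if entry["subject"].group == "control":
                control_mats.extend(entry["bands"][band.name]["matrices"])
        references[band.name] = reference_tree(control_mats) if control_mats else None

    wide_rows: list[dict] = []
    long_rows: list[dict] = []
    for subj in subjects:
        entry = per_subject[subj.subject_id]
        for band in bands:
            mats = entry["bands"][band.name]["matrices"]
            ref = references[band.name]
            epoch_metrics = []
            for e, mat in enumerate(mats):
                tree = build_mst(mat)
                m = compute_metrics(tree, ref, config.normalize_diameter)
                epoch_metrics.append(m)
                row = {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "disability": subj.disability,
                    "band": band.name,
                    "epoch": e,
                    "mean_pli": mean_upper_triangle(mat),
                    **m.as_dict(),
                }
                if config.compute_power:
                    row["relative_power"] = relative_band_power(entry["psds"][e], band)
                long_rows.append(row)
            if config.aggregation == "mean_matrix":
                mean_mat = ConnectivityMatrix(
                    weights=np.mean([m.weights for m in mats], axis=0),
                    labels=mats[0].labels,
                    band=mats[0].band,
                )
                subj_metrics = compute_metrics(
                    build_mst(mean_mat), ref, config.normalize_diameter
                ).as_dict()
            else:
                subj_metrics = {
                    k: float(np.mean([m.as_dict()[k] for m in epoch_metrics]))
                    for k in epoch_metrics[0].as_dict()
                }
            wrow = {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "disability": subj.disability,
                "band": band.name,
                "mean_pli": global_mean_pli(mats),
                **subj_metrics,
            }
            if config.compute_power:
                wrow["relative_power"] = float(
                    np.mean([relative_band_power(p, band) for p in entry["psds"]])
                )
            wide_rows.append(wrow)

    cohort_table = pd.DataFrame(wide_rows)
    epoch_table = pd.DataFrame(long_rows)

    group_stats = _group_statistics(cohort_table, config)
    correlations = _correlations(cohort_table, config)
    epoch_correlations = _epoch_correlations(epoch_table, config)

    run_manifest = _build_run_manifest(config, subjects)
    result = PipelineResult(
        cohort_table=cohort_table,
        epoch_table=epoch_table,
        group_stats=group_stats,
        correlations=correlations,
        epoch_correlations=epoch_correlations,
        run_manifest=run_manifest,
    )
    if config.out_dir is not None:
        report(result, config.out_dir)
    return result


def _present_outcomes(table: pd.DataFrame) -> list[str]:
    return [c for c in OUTCOMES if c in table.columns]


def _group_statistics(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Mann-Whitney patients vs controls per outcome and band; FDR over bands."""
    rows = []
    for outcome in _present_outcomes(table):
        per_band: list[dict] = []
        for band in config.bands:
            sel = table[table["band"] == band]
            a = sel.loc[sel["group"] == "patient", outcome].to_numpy()
            b = sel.loc[sel["group"] == "control", outcome].to_numpy()
            if a.size == 0 or b.size == 0:
                per_band.append(
                    {
                        "outcome": outcome,
                        "band": band,
                        "note": "not computable: a group is empty",
                        "p_value": np.nan,
                    }
                )
                continue
            res = mann_whitney(a, b, exact_threshold=config.exact_threshold)
            per_band.append(
                {
                    "outcome": outcome,
                    "band": band,
                    "n_patients": res.n1,
                    "n_controls": res.n2,
                    "patient_mean": float(a.mean()),
                    "patient_sd": float(a.std(ddof=1)) if a.size > 1 else np.nan,
                    "control_mean": float(b.mean()),
                    "control_sd": float(b.std(ddof=1)) if b.size > 1 else np.nan,
                    "U": res.statistic,
                    "W": res.rank_sum_w,
                    "p_value": res.p_value,
                    "cohens_d": res.effect_size,
                    "method": res.method,
                }
            )
        ps = np.array([r["p_value"] for r in per_band])
        valid = ~np.isnan(ps)
        flags = np.zeros(len(per_band), dtype=bool)
        if valid.any():
            flags[valid] = fdr_bh(ps[valid], q=config.q)
        for r, f in zip(per_band, flags):
            r["fdr_significant"] = bool(f)
        rows.extend(per_band)
    return pd.DataFrame(rows)


def _correlations(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Spearman correlation of each outcome with disability, patients only."""
    rows = []
    patients = table[table["group"] == "patient"]
    for outcome in _present_outcomes(table):
        for band in config.bands:
            sel = patients[patients["band"] == band]
            row: dict = {"outcome": outcome, "band": band, "n": len(sel)}
            try:
                res = spearman(sel["disability"].to_numpy(), sel[outcome].to_numpy())
                row.update(rho=res.statistic, p_value=res.p_value)
            except ValueError as exc:
                row.update(rho=np.nan, p_value=np.nan, note=f"not computable: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)


def _epoch_correlations(epoch_table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Single-epoch-level Spearman correlations with disability, patients only."""
    rows = []
    patients = epoch_table[epoch_table["group"] == "patient"]
    subject_ids = sorted(patients["subject_id"].unique())
    for outcome in _present_outcomes(epoch_table):
        for band in config.bands:
            sel = patients[patients["band"] == band]
            values = [
                sel.loc[sel["subject_id"] == s, outcome].to_numpy() for s in subject_ids
            ]
            disability = np.array(
                [sel.loc[sel["subject_id"] == s, "disability"].iloc[0] for s in subject_ids]
            ) if subject_ids else np.array([])
            row: dict = {"outcome": outcome, "band": band, "n_points": int(len(sel))}
            try:
                res = epoch_level_correlation(values, disability)
                row.update(rho=res.statistic, p_value=res.p_value, note=res.notes)
            except ValueError as exc:
                row.update(rho=np.nan, p_value=np.nan, note=f"not computable: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _build_run_manifest(config: RunConfig, subjects: list[Subject]) -> dict:
    return {
        "mstnet_version": __version__,
        "config": _jsonable(config),
        "conventions": {
            "pli": "abs mean sign(sin(phase difference)); sign(0) = 0",
            "mst": "Kruskal on 1-PLI; ties broken on (weight, smaller label, larger label)",
            "diameter_normalization": "link count / (N-1)" if config.normalize_diameter else "link count",
            "kappa": "<k^2>/<k>",
            "hierarchy": "L / (2 (N-1) B_max), B_max normalized by (N-1)(N-2)/2",
            "dissimilarity": "1 - shared edges / (N-1) vs control-average reference MST",
            "subject_aggregation": config.aggregation,
            "relative_power_denominator": "[1, 30) Hz",
            "fdr_family": "the four frequency bands, per outcome",
            "correlations": "patients only, Spearman vs disability (48 - ALSFRS-R)",
        },
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group, "disability": s.disability}
            for s in subjects
        ],
    }


def report(result: PipelineResult, out_dir: str | Path, plots: bool = False) -> list[Path]:
    """Write result tables (and optional beta-band figures) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "cohort_table.csv": result.cohort_table,
        "epoch_table.csv": result.epoch_table,
        "group_stats.csv": result.group_stats,
        "correlations.csv": result.correlations,
        "epoch_correlations.csv": result.epoch_correlations,
    }
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    p = out / "run_manifest.json"
    p.write_text(json.dumps(result.run_manifest, indent=2, sort_keys=True))
    written.append(p)
    if plots:
        written.extend(_render_plots(result, out))
    return written


def _render_plots(result: PipelineResult, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    table = result.cohort_table
    bands = sorted(table["band"].unique())
    metrics = [m for m in ("leaf_fraction", "diameter", "kappa", "hierarchy") if m in table]
    for band in bands:
        sel = table[table["band"] == band]
        fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3.2))
        for ax, metric in zip(np.atleast_1d(axes), metrics):
            for x, group in enumerate(("control", "patient")):
                vals = sel.loc[sel["group"] == group, metric]
                ax.scatter(np.full(len(vals), x) + 0.05 * np.random.default_rng(0).standard_normal(len(vals)), vals, s=12)
            ax.set_xticks([0, 1], ["control", "patient"])
            ax.set_title(f"{metric} ({band})")
        fig.tight_layout()
        p = out / f"mst_metrics_{band}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
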