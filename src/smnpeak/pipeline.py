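"""End-to-end orchestration: simulate -> preprocess -> ICA -> identify ->
peaks -> reliability, with on-disk stage outputs and reproducible reports.

Every (subject, visit, condition, component-setting) cell yields one ICA
decomposition; the run ledger records one row per decomposition with status
ok / unidentified / failed, and partial failures never abort the cohort.
Reports follow the layout of published reliability tables: an ICC table
with per-axis raw, truncated and averaged values (raw negatives displayed
as "<0"), and per-subject distance tables with Mean and STD rows where
unidentified runs appear as "-".
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ica import icasso_decompose, zscore_align
from .netmatch import identify_smn
from .peaks import PeakRecord, extract_peak, peak_table
from .preprocess import discard_initial_volumes, smooth_gaussian
from .reliability import axis_averaged_icc, peak_distances
from .synthdata import CohortConfig, derive_seed, simulate_cohort
from .volume import Volume4D, load_mask, load_volume4d

__all__ = ["PipelineConfig", "enumerate_decompositions", "analyze_run",
           "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline on a synthetic or real cohort.

    Either ``cohort`` (a synthetic-cohort config) or ``manifest_path`` (a CSV
    with columns subject, visit, scanner, condition, path, next to
    brain_mask.nii.gz and smn_mask.nii.gz) must be set.
    """

    out_dir: Path
    cohort: CohortConfig | None = None
    manifest_path: Path | None = None
    n_components_settings: tuple = (20, 30, 40)
    n_runs_icasso: int = 20
    n_discard: int = 10
    fwhm_mm: float = 6.0
    z_threshold: float = 1.0
    dice_floor: float = 0.10
    laterality_cut: float = 0.5
    visit_pairs: tuple = (("V1", "V2"), ("V1", "V3"), ("V2", "V3"))
    seed: int = 0
    ica_max_iter: int = 512
    ica_tol: float = 1e-6
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_components_settings:
            raise ValueError("need at least one component-count setting")
        if self.cohort is None and self.manifest_path is None:
            raise ValueError("either cohort or manifest_path must be given")

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def enumerate_decompositions(manifest: pd.DataFrame,
                             settings) -> pd.DataFrame:
    """The planned decomposition grid: one row per (run x setting).

    The full design -- 21 subjects x 2 conditions x 3 visits x settings
    {20, 30, 40} -- enumerates to 378 single-subject decompositions.
    """
    rows = [
        {"subject": run.subject, "visit": run.visit, "scanner": run.scanner,
         "condition": run.condition, "n_components": int(n)}
        for run in manifest.itertuples(index=False)
        for n in settings
    ]
    return pd.DataFrame(rows, columns=["subject", "visit", "scanner",
                                       "condition", "n_components"])


def analyze_run(vol: Volume4D, brain_mask: np.ndarray, smn_mask: np.ndarray,
                config: PipelineConfig, labels: dict
                ) -> tuple[list[PeakRecord], list[dict]]:
    """Preprocess one run and extract both sides' peaks for every setting.

    Returns (peak records, ledger rows). Unidentified or failed settings
    yield missing peak records so downstream statistics can exclude them
    pairwise.
    """
    vol = discard_initial_volumes(vol, config.n_discard)
    vol = smooth_gaussian(vol, config.fwhm_mm)

    records: list[PeakRecord] = []
    ledger: list[dict] = []
    for setting in config.n_components_settings:
        row = dict(labels, n_components=int(setting))
        ica_seed = derive_seed(config.seed, "ica", labels["subject"],
                               labels["visit"], labels["condition"], setting)
        try:
            decomp = icasso_decompose(vol, brain_mask, int(setting),
                                      n_runs=config.n_runs_icasso,
                                      seed=ica_seed, tol=config.ica_tol,
                                      max_iter=config.ica_max_iter)
            decomp = zscore_align(decomp)
            selection = identify_smn(decomp, smn_mask,
                                     z_threshold=config.z_threshold,
                                     dice_floor=config.dice_floor,
                                     laterality_cut=config.laterality_cut)
        except Exception as exc:  # ledger the failure, keep going
            warnings.warn(f"decomposition failed for {row}: {exc}",
                          RuntimeWarning, stacklevel=2)
            ledger.append(dict(row, status="failed", mode="", dice_top1=np.nan,
                               seed=ica_seed))
            for side in ("left", "right"):
                records.append(PeakRecord(side=side, missing=True, **row))
            continue

        if selection.mode == "unidentified":
            ledger.append(dict(row, status="unidentified", mode="unidentified",
                               dice_top1=selection.dice_top1, seed=ica_seed))
            for side in ("left", "right"):
                records.append(PeakRecord(side=side, missing=True, **row))
            continue

        ledger.append(dict(row, status="ok", mode=selection.mode,
                           dice_top1=selection.dice_top1, seed=ica_seed))
        for side in ("left", "right"):
            records.append(extract_peak(selection, decomp, smn_mask, side, **row))
    return records, ledger


def _reliability_cells(peaks: pd.DataFrame, config: PipelineConfig):
    """All (condition, side, setting, visit-pair) ICC and distance results."""
    icc_results, distance_tables, notes = [], [], []
    conditions = sorted(peaks["condition"].unique())
    for condition in conditions:
        for side in ("left", "right"):
            for setting in config.n_components_settings:
                cell = peaks[(peaks["condition"] == condition)
                             & (peaks["side"] == side)
                             & (peaks["n_components"] == int(setting))]
                for va, vb in config.visit_pairs:
                    a = cell[cell["visit"] == va]
                    b = cell[cell["visit"] == vb]
                    if a.empty or b.empty:
                        continue
                    try:
                        icc_results.append(axis_averaged_icc(
                            a, b, condition=condition, side=side,
                            visit_pair=(va, vb), n_components=int(setting)))
                        distance_tables.append(peak_distances(
                            a, b, condition=condition, side=side,
                            visit_pair=(va, vb), n_components=int(setting)))
                    except ValueError as exc:
                        notes.append(str(exc))
    return icc_results, distance_tables, notes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict with ledger, peak table, ICC results,
    distance tables and the report directory. Re-running with the same
    config and seed reproduces identical reports."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        data_dir = out_dir / "cohort"
        manifest = simulate_cohort(config.cohort, data_dir)
    else:
        manifest = pd.read_csv(config.manifest_path)
        data_dir = Path(config.manifest_path).parent
    brain, _ = load_mask(data_dir / "brain_mask.nii.gz")
    smn, _ = load_mask(data_dir / "smn_mask.nii.gz")

    all_records: list[PeakRecord] = []
    ledger_rows: list[dict] = []
    for run in manifest.itertuples(index=False):
        vol = load_volume4d(data_dir / run.path)
        labels = {"subject": run.subject, "visit": run.visit,
                  "scanner": run.scanner, "condition": run.condition}
        records, ledger = analyze_run(vol, brain, smn, config, labels)
        all_records.extend(records)
        ledger_rows.extend(ledger)

    peaks = peak_table(all_records)
    ledger = pd.DataFrame(ledger_rows)
    icc_results, distance_tables, notes = _reliability_cells(peaks, config)
    report_dir = write_report(icc_results, distance_tables, ledger, peaks,
                              out_dir, config, notes)
    return {"ledger": ledger, "peaks": peaks, "icc_results": icc_results,
            "distance_tables": distance_tables, "report_dir": report_dir}


def _fmt(value: float) -> str:
    return f"{value:.2f}"


def write_report(icc_results, distance_tables, ledger: pd.DataFrame,
                 peaks: pd.DataFrame, out_dir, config: PipelineConfig,
                 notes=()) -> Path:
    """Write the report bundle: ICC CSV, distance CSVs, ledger, peak table
    and a provenance JSON (config hash, seed, versions)."""
    out_dir = Path(out_dir)
    report_dir = out_dir / "report"
    try:
        report_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {report_dir}: {exc}") from exc

    ledger.to_csv(report_dir / "ledger.csv", index=False)
    peaks.to_csv(report_dir / "peak_table.csv", index=False)

    icc_rows = []
    for r in icc_results:
        icc_rows.append({
            "condition": r.condition, "side": r.side,
            "visit_pair": f"{r.visit_pair[0]} vs. {r.visit_pair[1]}",
            "n_components": r.n_components,
            "icc_x": "< 0" if r.icc_x < 0 else _fmt(r.icc_x),
            "icc_y": "< 0" if r.icc_y < 0 else _fmt(r.icc_y),
            "icc_z": "< 0" if r.icc_z < 0 else _fmt(r.icc_z),
            "icc_x_trunc": r.icc_x_trunc, "icc_y_trunc": r.icc_y_trunc,
            "icc_z_trunc": r.icc_z_trunc,
            "icc_avg": _fmt(r.icc_avg),
            "n_subjects_used": r.n_subjects_used,
        })
    pd.DataFrame(icc_rows).to_csv(report_dir / "icc_table.csv", index=False)

    for setting in sorted({t.n_components for t in distance_tables}):
        tables = [t for t in distance_tables if t.n_components == setting]
        subjects = sorted({s for t in tables for s in t.distances},
                          key=lambda s: str(s))
        columns = {}
        for t in tables:
            name = (f"{t.condition}_{t.side}_"
                    f"{t.visit_pair[0]}v{t.visit_pair[1]}")
            col = ["-" if t.distances.get(s) is None else _fmt(t.distances[s])
                   for s in subjects]
            col += [_fmt(t.mean_mm),
                    "-" if np.isnan(t.std_mm) else _fmt(t.std_mm)]
            columns[name] = col
        frame = pd.DataFrame(columns,
                             index=[str(s) for s in subjects] + ["Mean", "STD"])
        frame.index.name = "subject"
        frame.to_csv(report_dir / f"distances_{setting}components.csv")

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_components_settings": list(config.n_components_settings),
        "n_runs_icasso": config.n_runs_icasso,
        "numpy": np.__version__,
        "notes": list(notes),
    }
    (report_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return report_dir
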