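"""Orchestration: simulate -> extract -> select, with run manifests.

Each stage writes its outputs plus a ``run_manifest.json`` recording the
configuration snapshot, every file read or written (with SHA-256
checksums), the package version, the seed and per-stage log lines, so a run
can be audited and reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .io import PipelineConfig, load_stack, write_feature_matrix, write_stack_nifti, read_feature_matrix
from .global_features import FeatureMatrix, extract_features, write_feature_manifest
from .stats import group_summary, select_feature, youden_cutoff
from .synthetic import CohortSpec, generate_cohort

__all__ = ["run_simulate", "run_extract", "run_select", "count_included", "RunManifest"]

logger = logging.getLogger(__name__)

#: overfitting guard: flag selections with fewer samples per selected feature
MIN_SAMPLES_PER_FEATURE = 10


def count_included(total: int, exclusions: list[int] | tuple[int, ...]) -> int:
    """Cohort accounting: patients remaining after the exclusion criteria."""
    included = total - sum(exclusions)
    if included < 0:
        raise ValueError("exclusions exceed the total cohort")
    return included


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Collects stage provenance and writes it as JSON."""

    def __init__(self, stage: str, config: dict, seed: int | None = None):
        self.data = {
            "stage": stage,
            "package_version": __version__,
            "config": config,
            "seed": seed,
            "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            "inputs": {},
            "outputs": {},
            "log": [],
        }

    def log(self, msg: str) -> None:
        self.data["log"].append(msg)
        logger.info("%s", msg)

    def add_input(self, path: Path) -> None:
        self.data["inputs"][str(path)] = _sha256(path)

    def add_output(self, path: Path) -> None:
        self.data["outputs"][str(path)] = _sha256(path)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "run_manifest.json"
        path.write_text(json.dumps(self.data, indent=2) + "\n")
        return path


def run_simulate(cohort: CohortSpec, out_dir: str | Path) -> Path:
    """Generate a phantom cohort and write NIfTI stacks plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("simulate", dataclasses.asdict(cohort), seed=cohort.seed)
    stacks, labels = generate_cohort(cohort)
    rows = []
    for stack, label in zip(stacks, labels):
        img = out_dir / f"{stack.patient_id}_t2w.nii.gz"
        msk = out_dir / f"{stack.patient_id}_mask.nii.gz"
        write_stack_nifti(stack, img, msk)
        manifest.add_output(img)
        manifest.add_output(msk)
        rows.append(
            {
                "patient_id": stack.patient_id,
                "group": label,
                "image": img.name,
                "mask": msk.name,
                "pixel_spacing_mm": stack.pixel_spacing_mm,
            }
        )
    cohort_csv = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(cohort_csv, index=False)
    manifest.add_output(cohort_csv)
    spec_yaml = out_dir / "cohort_spec.yaml"
    spec_yaml.write_text(yaml.safe_dump(dataclasses.asdict(cohort), sort_keys=True))
    manifest.add_output(spec_yaml)
    manifest.log(f"wrote {len(stacks)} phantom stacks to {out_dir}")
    manifest.write(out_dir)
    return cohort_csv


def run_extract(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    out_csv: str | Path | None = None,
) -> Path:
    """Extract the 84-feature matrix for every patient in a cohort directory.

    Strict by default: per-patient failures are collected, reported, and
    abort the run if any patient fails.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    cohort_csv = input_dir / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(f"no cohort manifest at {cohort_csv}")
    out_csv = Path(out_csv) if out_csv else input_dir / "features.csv"
    manifest = RunManifest("extract", config.to_dict(), seed=config.rng_seed)
    manifest.add_input(cohort_csv)
    cohort = pd.read_csv(cohort_csv)
    vectors, groups, failures = [], [], []
    for row in cohort.itertuples(index=False):
        try:
            img = input_dir / row.image
            msk = input_dir / row.mask
            for p in (img, msk):
                if not p.exists():
                    raise FileNotFoundError(f"patient {row.patient_id}: missing {p.name}")
            stack = load_stack(
                [img], [msk], row.pixel_spacing_mm, patient_id=str(row.patient_id)
            )
            vectors.append(extract_features(stack, config))
            groups.append(row.group)
            manifest.add_input(img)
            manifest.add_input(msk)
            manifest.log(f"extracted {row.patient_id}")
        except Exception as exc:  # noqa: BLE001 - collected and re-raised below
            failures.append(f"{row.patient_id}: {exc}")
    if failures:
        manifest.log(f"{len(failures)} patient(s) failed")
        manifest.write(out_csv.parent)
        raise RuntimeError("feature extraction failed for: " + "; ".join(failures))
    matrix = FeatureMatrix.from_vectors(vectors, groups)
    write_feature_matrix(matrix, out_csv)
    manifest.add_output(out_csv)
    manifest_json = out_csv.parent / "feature_manifest.json"
    write_feature_manifest(manifest_json)
    manifest.add_output(manifest_json)
    manifest.log(f"wrote {len(matrix)}x{matrix.features.shape[1]} feature matrix")
    manifest.write(out_csv.parent)
    return out_csv


def run_select(
    features_csv: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Univariate selection + ROC report on a feature matrix CSV.

    Writes ``report.json``, a human-readable ``report.txt`` and a
    ``waterfall.csv`` (per-patient selected score minus the Youden cut-off)
    to ``out_dir`` and returns the report dict.
    """
    config = config or PipelineConfig()
    features_csv = Path(features_csv)
    out_dir = Path(out_dir) if out_dir else features_csv.parent / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("select", config.to_dict(), seed=config.rng_seed)
    manifest.add_input(features_csv)
    matrix = read_feature_matrix(features_csv)
    selection = select_feature(matrix, alpha=config.alpha)
    report: dict = {
        "n_patients": len(matrix),
        "n_features": matrix.features.shape[1],
        "alpha": selection.alpha,
        "m_tests": selection.m_tests,
        "bonferroni_threshold": selection.threshold,
        "selected_feature": selection.selected_feature,
        "n_smallest_class": selection.n_smallest_class,
        "n_features_selected": selection.n_features_selected,
        "ratio_r": selection.ratio_r,
        "per_feature": [dataclasses.asdict(t) for t in selection.per_feature],
    }
    if selection.ratio_r is not None and selection.ratio_r < MIN_SAMPLES_PER_FEATURE:
        report["overfitting_warning"] = (
            f"ratio r = {selection.ratio_r:.1f} < {MIN_SAMPLES_PER_FEATURE}: "
            "too few samples per selected feature"
        )
    if selection.selected_feature is None:
        report["roc"] = None
        manifest.log("no discriminative feature survived step 1")
    else:
        name = selection.selected_feature
        scores = matrix.frame[name].to_numpy(dtype=float)
        labels = matrix.groups.to_numpy()
        roc = youden_cutoff(
            scores, labels, bootstrap_reps=config.bootstrap_reps, seed=config.rng_seed
        )
        # re-verify the confusion identities before anything is written
        roc.check_identities(
            int((labels == "TRG01").sum()), int((labels == "TRG23").sum())
        )
        selected_p = next(
            t for t in selection.per_feature if t.feature_name == name
        )
        report["selected_p_value"] = selected_p.p_value
        report["selected_p_bonferroni"] = selected_p.p_bonferroni
        report["roc"] = dataclasses.asdict(roc)
        report["group_summary"] = group_summary(scores, labels)
        # roc.cutoff lives on the oriented scale (scores negated if flipped)
        oriented = -scores if roc.flipped else scores
        waterfall = pd.DataFrame(
            {
                "patient_id": matrix.frame["patient_id"],
                "group": labels,
                "score": scores,
                "score_minus_cutoff": oriented - roc.cutoff,
            }
        ).sort_values("score_minus_cutoff", ascending=False, kind="mergesort")
        wf_csv = out_dir / "waterfall.csv"
        waterfall.to_csv(wf_csv, index=False)
        manifest.add_output(wf_csv)
        manifest.log(f"selected {name}: p={selected_p.p_value:.3g}, AUC={roc.auc:.3f}")
    report_json = out_dir / "report.json"
    report_json.write_text(json.dumps(report, indent=2) + "\n")
    report_txt = out_dir / "report.txt"
    report_txt.write_text(_format_report(report))
    manifest.add_output(report_json)
    manifest.add_output(report_txt)
    manifest.write(out_dir)
    return report


def _format_report(report: dict) -> str:
    lines = [
        "Univariate feature selection report",
        "===================================",
        f"patients: {report['n_patients']}  features: {report['n_features']}",
        f"alpha: {report['alpha']}  survivors (m): {report['m_tests']}",
    ]
    if report["m_tests"]:
        lines.append(f"Bonferroni threshold alpha/m: {report['bonferroni_threshold']:.3g}")
    if report["selected_feature"] is None:
        lines.append("no discriminative feature survived step 1")
    else:
        roc = report["roc"]
        gs = report["group_summary"]
        lines += [
            f"selected feature: {report['selected_feature']}",
            f"  p = {report['selected_p_value']:.3g} "
            f"(Bonferroni-corrected {report['selected_p_bonferroni']:.3g})",
            f"  N/l ratio r = {report['ratio_r']:.0f}",
            f"  AUC = {roc['auc']:.2f} (95% CI {roc['auc_ci_low']:.2f}-{roc['auc_ci_high']:.2f})",
            f"  Youden index = {roc['youden']:.2f} at cut-off {roc['cutoff']:.3g}"
            + (" (orientation flipped)" if roc["flipped"] else ""),
            f"  SE = {roc['sensitivity']:.0%}  SP = {roc['specificity']:.0%}  "
            f"PPV = {roc['ppv']:.0%}  NPV = {roc['npv']:.0%}",
            f"  confusion: TP={roc['tp']} FP={roc['fp']} TN={roc['tn']} FN={roc['fn']}",
            "  group medians [Q1, Q3]: "
            + "; ".join(
                f"{g}: {s['median']:.3g} [{s['q1']:.3g}, {s['q3']:.3g}]"
                for g, s in gs.items()
            ),
        ]
    if "overfitting_warning" in report:
        lines.append("WARNING: " + report["overfitting_warning"])
    return "\n".join(lines) + "\n"
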