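"""End-to-end pipeline: config, artifact writing, and the alpha sweep."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterAssignment, scan_clusters, spectral_cluster
from .fusion import FusionParams, FusionResult, skf
from .io import Cohort, align_cohort, read_clinical_tsv, read_expression_tsv
from .kernels import SimilarityKernel
from .survival import km_curves, logrank_test, neglog10_p

logger = logging.getLogger(__name__)

__all__ = ["ViewInput", "ClinicalInput", "RunConfig", "run_pipeline", "alpha_scan", "DEFAULT_ALPHAS"]

DEFAULT_ALPHAS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))

_FLOAT_FMT = "%.10g"


@dataclass
class ViewInput:
    path: str
    orientation: str = "patients_in_rows"
    name: str | None = None


@dataclass
class ClinicalInput:
    path: str
    time_col: str = "time"
    event_col: str = "event"
    event_recode: dict | None = None
    time_unit: str = "days"


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serialized into the manifest."""

    views: list[ViewInput]
    clinical: ClinicalInput | None = None
    params: FusionParams = dataclasses.field(default_factory=FusionParams)
    n_clusters: int | None = None
    c_range: tuple[int, int] | None = None
    seed: int = 0
    outdir: str = "skfuse_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        views = [ViewInput(**v) for v in raw.get("views", [])]
        clinical = ClinicalInput(**raw["clinical"]) if raw.get("clinical") else None
        params = FusionParams(**raw.get("params", {}))
        c_range = tuple(raw["c_range"]) if raw.get("c_range") else None
        return cls(
            views=views,
            clinical=clinical,
            params=params,
            n_clusters=raw.get("n_clusters"),
            c_range=c_range,
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "skfuse_out")),
        )

    def validate(self) -> None:
        if len(self.views) < 2:
            raise ValueError("config must list at least two views")
        for v in self.views:
            if not Path(v.path).exists():
                raise FileNotFoundError(f"view file not found: {v.path}")
        if self.clinical is not None and not Path(self.clinical.path).exists():
            raise FileNotFoundError(f"clinical file not found: {self.clinical.path}")
        if self.n_clusters is None and self.c_range is None:
            raise ValueError("config must set n_clusters or c_range")
        if self.c_range is not None:
            if self.clinical is None:
                raise ValueError("a cluster-number scan (c_range) requires clinical data")
            lo, hi = self.c_range
            if not 2 <= lo <= hi:
                raise ValueError(f"invalid c_range {self.c_range}")


def load_cohort(config: RunConfig) -> Cohort:
    views = [
        read_expression_tsv(v.path, orientation=v.orientation, view_name=v.name)
        for v in config.views
    ]
    survival = None
    if config.clinical is not None:
        c = config.clinical
        survival = read_clinical_tsv(
            c.path, c.time_col, c.event_col, event_recode=c.event_recode, time_unit=c.time_unit
        )
    return align_cohort(views, survival)


def _write_kernel(kernel: SimilarityKernel, path: Path) -> None:
    df = pd.DataFrame(kernel.matrix, index=kernel.patient_ids, columns=kernel.patient_ids)
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _write_km(survival, assignment: ClusterAssignment, path: Path) -> None:
    frames = []
    for curve in km_curves(survival, assignment):
        frames.append(
            pd.DataFrame(
                {
                    "cluster": curve.group,
                    "time": curve.times,
                    "survival_prob": curve.survival_prob,
                    "at_risk": curve.at_risk,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def run_pipeline(config: RunConfig) -> dict:
    """Fuse, cluster, evaluate, and write all artifacts to ``config.outdir``.

    Writes the fused kernel, per-patient cluster assignments, the C-scan
    table and Kaplan-Meier step functions (when clinical data is present),
    and a manifest with every parameter and the package version. Returns the
    in-memory results keyed like the files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config)
    fusion: FusionResult = skf(cohort, config.params)
    _write_kernel(fusion.fused, outdir / "fused_kernel.tsv")

    scan = None
    if config.c_range is not None:
        lo, hi = config.c_range
        scan = scan_clusters(fusion.fused, range(lo, hi + 1), cohort.survival, seed=config.seed)
        scan.to_csv(outdir / "scan.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        chosen_c = int(scan.loc[scan["p_value"].idxmin(), "n_clusters"])
    else:
        chosen_c = int(config.n_clusters)

    assignment = spectral_cluster(fusion.fused, chosen_c, seed=config.seed)
    assignment.to_frame().to_csv(outdir / "assignments.tsv", sep="\t", index=False)

    evaluation = None
    if cohort.survival is not None:
        res = logrank_test(cohort.survival, assignment)
        evaluation = {
            "chi_square": res.chi_square,
            "df": res.df,
            "p_value": res.p_value,
            "neg_log10_p": neglog10_p(res.p_value),
            "group_sizes": res.group_sizes,
        }
        _write_km(cohort.survival, assignment, outdir / "km_curves.tsv")

    manifest = {
        "package": "skfuse",
        "version": _version(),
        "config": _config_dict(config),
        "n_patients": cohort.n_patients,
        "n_views": len(cohort.views),
        "chosen_n_clusters": chosen_c,
        "fusion": {
            "iterations_run": fusion.iterations_run,
            "converged": fusion.converged,
        },
        "evaluation": evaluation,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest)), fh, sort_keys=False)
    return {
        "cohort": cohort,
        "fusion": fusion,
        "assignment": assignment,
        "scan": scan,
        "chosen_n_clusters": chosen_c,
        "evaluation": evaluation,
    }


def alpha_scan(config: RunConfig, alphas=DEFAULT_ALPHAS) -> pd.DataFrame:
    """Sweep the diffusion weight alpha and report the best C per value.

    For each alpha the kernels are re-fused, every C in ``c_range`` is
    clustered, and the minimum-p row is kept. The default grid runs from 0
    to 1 in steps of 0.1.
    """
    config.validate()
    if config.c_range is None:
        raise ValueError("alpha_scan requires c_range in the config")
    cohort = load_cohort(config)
    lo, hi = config.c_range
    rows = []
    for alpha in alphas:
        params = dataclasses.replace(config.params, alpha=float(alpha))
        fusion = skf(cohort, params)
        scan = scan_clusters(fusion.fused, range(lo, hi + 1), cohort.survival, seed=config.seed)
        best = scan.loc[scan["p_value"].idxmin()]
        rows.append(
            {
                "alpha": float(alpha),
                "best_n_clusters": int(best["n_clusters"]),
                "chi_square": float(best["chi_square"]),
                "p_value": float(best["p_value"]),
                "neg_log10_p": float(best["neg_log10_p"]),
            }
        )
    table = pd.DataFrame(rows)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "alpha_scan.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return table


def _config_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def _version() -> str:
    try:
        return metadata.version("skfuse")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"
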