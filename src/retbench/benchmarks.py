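"""Retention benchmarks and the end-to-end pipeline.

Two statistics summarize each paired dataset:

* ``p_star`` — the smallest proportion of the disturbed area that must be
  retained unlogged to maintain a target fraction ``q`` (default 0.90) of
  the richness of species unique to the unlogged habitat;
* ``frac_at_half`` — the fraction of unique-to-unlogged richness maintained
  when half of the area is retained (``p = 0.5``).

Both come from the normalized unique-species detection curve, which needs
no extrapolation, so these headline statistics are independent of the
extrapolation policy of the mixture module.  Benchmarks are averaged with
equal weight per species matrix across grouping variables (disturbance
type, saproxylic status, taxonomic group, year since disturbance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .data_io import PairedDataset, StudyMetadata
from .mixture import compute_mixture_decomposition, partition_species, unique_unlogged_curve

__all__ = [
    "BenchmarkResult",
    "GroupSummary",
    "PipelineConfig",
    "normalized_unique_curve",
    "retention_for_fraction",
    "unique_fraction_at_retention",
    "compute_benchmark",
    "summarize_benchmarks",
    "run_pipeline",
    "GROUPINGS",
]

logger = logging.getLogger(__name__)

GROUPINGS = ("all", "disturbance_type", "saproxylic", "taxon_group", "year")

STATUS_OK = "ok"
STATUS_NO_UNIQUE = "undefined_no_unique_species"


class EmptyUniqueClassError(ValueError):
    """The dataset has no species unique to the unlogged habitat."""


def _require_unique_class(paired: PairedDataset) -> None:
    if not partition_species(paired).unique_unlogged:
        raise EmptyUniqueClassError(
            f"dataset {paired.meta.dataset_id} has no unique-to-unlogged species"
        )


def normalized_unique_curve(paired: PairedDataset, p) -> float:
    """Fraction of observed unique-to-unlogged richness expected to be
    maintained when a proportion ``p`` of the area is retained unlogged."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    _require_unique_class(paired)
    T1 = paired.T1
    return unique_unlogged_curve(paired, p * T1) / unique_unlogged_curve(paired, T1)


def retention_for_fraction(paired: PairedDataset, q: float = 0.9, tol: float = 1e-6) -> float:
    """Smallest retention proportion ``p*`` with normalized unique richness
    >= ``q``, by root finding on the continuous curve (grid-free)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0, 1)")
    _require_unique_class(paired)

    def f(p: float) -> float:
        return normalized_unique_curve(paired, p) - q

    # the curve is continuous and strictly increasing from 0 to 1
    p_star = float(brentq(f, 0.0, 1.0, xtol=min(tol * 1e-3, 1e-9), rtol=1e-14))
    residual = abs(normalized_unique_curve(paired, p_star) - q)
    if residual > tol and 0.0 < p_star < 1.0:
        raise RuntimeError(
            f"inversion residual {residual:.2e} exceeds tol {tol:.2e} "
            f"(dataset {paired.meta.dataset_id})"
        )
    return p_star


def unique_fraction_at_retention(paired: PairedDataset, p: float = 0.5) -> float:
    """Normalized unique-to-unlogged richness at retention proportion ``p``."""
    return normalized_unique_curve(paired, p)


@dataclass(frozen=True)
class BenchmarkResult:
    dataset_id: str
    p_star: float | None
    frac_at_half: float | None
    n_unique: int
    T_unlogged: int
    T_logged: int
    status: str

    def as_row(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "p_star": self.p_star,
            "frac_at_half": self.frac_at_half,
            "n_unique": self.n_unique,
            "T_unlogged": self.T_unlogged,
            "T_logged": self.T_logged,
            "status": self.status,
        }


def compute_benchmark(
    paired: PairedDataset, q: float = 0.9, p_eval: float = 0.5, tol: float = 1e-6
) -> BenchmarkResult:
    """Both benchmark statistics for one dataset.

    An empty unique-to-unlogged class yields status
    ``undefined_no_unique_species`` rather than an exception, so one
    degenerate dataset cannot halt a collection run.
    """
    part = partition_species(paired)
    n_unique = len(part.unique_unlogged)
    if n_unique == 0:
        return BenchmarkResult(
            dataset_id=paired.meta.dataset_id,
            p_star=None,
            frac_at_half=None,
            n_unique=0,
            T_unlogged=paired.T1,
            T_logged=paired.T2,
            status=STATUS_NO_UNIQUE,
        )
    return BenchmarkResult(
        dataset_id=paired.meta.dataset_id,
        p_star=retention_for_fraction(paired, q=q, tol=tol),
        frac_at_half=unique_fraction_at_retention(paired, p=p_eval),
        n_unique=n_unique,
        T_unlogged=paired.T1,
        T_logged=paired.T2,
        status=STATUS_OK,
    )


# ---------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class GroupSummary:
    grouping: str
    level: str
    n: int
    mean: float
    sd: float | None  # missing (None) when n = 1


def _group_labels(meta: StudyMetadata, grouping: str) -> str:
    if grouping == "all":
        return "all"
    if grouping == "disturbance_type":
        return meta.disturbance_type
    if grouping == "saproxylic":
        return "saproxylic" if meta.saproxylic else "non_saproxylic"
    if grouping == "taxon_group":
        return meta.taxon_group
    if grouping == "year":
        return str(int(round(meta.years_since_disturbance)))
    if grouping == "study_id":  # regression covariate, not a summary grouping
        return meta.study_id
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


def summarize_benchmarks(
    results: Sequence[BenchmarkResult],
    metadata: Sequence[StudyMetadata],
    grouping: str = "all",
    response: str = "p_star",
) -> list[GroupSummary]:
    """Unweighted mean and sample SD (n-1) of a benchmark across datasets
    within each level of a grouping variable.  Undefined results are
    excluded (with a logged count); single-dataset groups report SD missing."""
    if response not in ("p_star", "frac_at_half"):
        raise ValueError(f"unknown response {response!r}")
    meta_by_id = {m.dataset_id: m for m in metadata}
    rows = []
    n_undefined = 0
    for r in results:
        if r.status != STATUS_OK:
            n_undefined += 1
            continue
        meta = meta_by_id.get(r.dataset_id)
        if meta is None:
            raise KeyError(f"no metadata for dataset {r.dataset_id}")
        rows.append((_group_labels(meta, grouping), getattr(r, response)))
    if n_undefined:
        logger.info("summarize: excluded %d undefined benchmark(s)", n_undefined)
    if not rows:
        raise ValueError("no defined benchmarks to summarize")
    df = pd.DataFrame(rows, columns=["level", "value"])
    out = []
    for level, grp in df.groupby("level", sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(
            GroupSummary(
                grouping=grouping,
                level=str(level),
                n=len(vals),
                mean=float(np.mean(vals)),
                sd=sd,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    q_target: float = 0.9
    p_eval: float = 0.5
    n_grid: int = 201
    bisect_tol: float = 1e-6
    extrapolation_policy: str = "unique_logged"
    unique_definition: str = "reference"
    weight_by_study: bool = False
    # saproxylic status is a property of the taxon group, so including both
    # would alias the dummies; study identity likewise aliases disturbance
    # type whenever studies are nested within it (configurable regardless)
    regression_covariates: tuple[str, ...] = ("disturbance_type", "taxon_group")
    df_smooth: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "regression_covariates" in raw:
            raw["regression_covariates"] = tuple(raw["regression_covariates"])
        return cls(**raw)


def _float_fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return format(float(x), ".10g")


def run_pipeline(
    collection: Iterable[PairedDataset],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run benchmarks, group summaries and the time-since-disturbance
    regression over a dataset collection.

    Returns a dict with ``benchmarks`` and ``summaries`` DataFrames, the
    per-dataset ``curves`` DataFrame and a ``regression`` report dict (None
    when too few defined benchmarks).  When ``out_dir`` is given, writes
    ``benchmarks.csv``, ``summaries.csv``, ``curves.csv``, ``regression.json``
    and ``run.log``; outputs are deterministic for a fixed config, so re-runs
    are byte-identical.
    """
    config = config or PipelineConfig()
    collection = list(collection)
    if not collection:
        raise ValueError("no datasets to analyse")

    log_lines: list[str] = []
    results: list[BenchmarkResult] = []
    curve_frames: list[pd.DataFrame] = []
    for paired in collection:
        res = compute_benchmark(
            paired, q=config.q_target, p_eval=config.p_eval, tol=config.bisect_tol
        )
        results.append(res)
        decomp = compute_mixture_decomposition(
            paired,
            n_grid=config.n_grid,
            unique_definition=config.unique_definition,
            extrapolation_policy=config.extrapolation_policy,
        )
        curve_frames.append(decomp.to_frame())
        log_lines.append(
            f"dataset {res.dataset_id}: status={res.status} "
            f"n_unique={res.n_unique} T1={res.T_unlogged} T2={res.T_logged}"
        )
    n_ok = sum(r.status == STATUS_OK for r in results)
    if n_ok == 0:
        raise RuntimeError(
            "all datasets undefined: " + "; ".join(log_lines)
        )
    log_lines.append(f"defined benchmarks: {n_ok}/{len(results)}")

    benchmarks_df = pd.DataFrame([r.as_row() for r in results])
    curves_df = pd.concat(curve_frames, ignore_index=True)

    metas = [d.meta for d in collection]
    summary_rows = []
    for response in ("p_star", "frac_at_half"):
        for grouping in GROUPINGS:
            try:
                for s in summarize_benchmarks(results, metas, grouping, response):
                    summary_rows.append(
                        {
                            "response": response,
                            "grouping": s.grouping,
                            "level": s.level,
                            "n": s.n,
                            "mean": s.mean,
                            "sd": s.sd,
                        }
                    )
            except ValueError as exc:
                log_lines.append(f"summary skipped ({response}/{grouping}): {exc}")
    summaries_df = pd.DataFrame(summary_rows)

    regression = _pipeline_regression(results, metas, config, log_lines)

    out = {
        "benchmarks": benchmarks_df,
        "summaries": summaries_df,
        "curves": curves_df,
        "regression": regression,
        "log": log_lines,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        benchmarks_df.to_csv(out_dir / "benchmarks.csv", index=False, float_format="%.10g")
        summaries_df.to_csv(out_dir / "summaries.csv", index=False, float_format="%.10g")
        curves_df.to_csv(out_dir / "curves.csv", index=False, float_format="%.10g")
        with open(out_dir / "regression.json", "w") as fh:
            json.dump(regression, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _pipeline_regression(results, metas, config: PipelineConfig, log_lines: list[str]):
    """Fit the time-since-disturbance beta regression for both responses."""
    from .beta_regression import fit_beta_gam  # deferred: optional stage

    meta_by_id = {m.dataset_id: m for m in metas}
    ok = [r for r in results if r.status == STATUS_OK]
    if len(ok) < 10:
        log_lines.append(f"regression skipped: only {len(ok)} defined benchmarks (< 10)")
        return None
    years = np.array([meta_by_id[r.dataset_id].years_since_disturbance for r in ok])
    cov = pd.DataFrame(
        {
            name: [_group_labels(meta_by_id[r.dataset_id], name) for r in ok]
            for name in config.regression_covariates
        }
    )
    report = {}
    for response in ("p_star", "frac_at_half"):
        y = np.array([getattr(r, response) for r in ok], dtype=float)
        try:
            fit = fit_beta_gam(y, years, covariates=cov, df_smooth=config.df_smooth)
            report[response] = fit.report()
            log_lines.append(
                f"regression {response}: edf={fit.edf} p={fit.p_value:.4g} "
                f"pseudo_r2={fit.pseudo_r2:.4g}"
            )
        except Exception as exc:  # fit failures must not kill the benchmark run
            log_lines.append(f"regression {response} failed: {exc}")
            report[response] = {"error": str(exc)}
    return report
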