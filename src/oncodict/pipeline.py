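"""Stage-stratified orchestration of the full analysis chain.

For each stratum (e.g. tumor stage) of a cohort the pipeline runs:
atom-count selection (PCA rule) -> hyperparameter selection (BIC) ->
dictionary fit -> band-level atom report -> Theta binarization ->
oncogenetic tree-mixture fit -> DOT/JSON export, writing every artifact
plus a run manifest under one output directory. A separate operation
tests the association between patient age and carriage of loss atoms.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import efllat, postprocess, trees
from .band_grid import CohortMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the pipeline; defaults match the package's choices."""

    n_per_band: int = 10
    knn_k: int = 10
    pca_fraction: float = 0.70
    hyper_grid: list = field(default_factory=lambda: [
        (0.001, 0.1, 0.001), (0.001, 1.0, 0.001), (0.01, 0.1, 0.01),
    ])
    theta_max: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    epsilon: float = postprocess.DEFAULT_EPSILON
    theta_threshold: float = postprocess.DEFAULT_THETA_THRESHOLD
    K: int = 1
    pseudocount: float = 0.5
    weight_schema: str = "flat"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hyper_grid"] = [list(t) for t in self.hyper_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hyper_grid" in d:
            d["hyper_grid"] = [tuple(t) for t in d["hyper_grid"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def sort_theta_report(Theta: np.ndarray, threshold: float = postprocess.DEFAULT_THETA_THRESHOLD):
    """Order atoms (rows) by usage for display: most-used first.

    Usage = number of samples whose coefficient clears the binarization
    threshold; ties broken by total coefficient weight, then by the
    original atom order (stable).
    """
    Theta = np.asarray(Theta)
    usage = (Theta > threshold).sum(axis=1)
    weight = Theta.sum(axis=1)
    order = sorted(range(Theta.shape[0]), key=lambda j: (-usage[j], -weight[j], j))
    return Theta[order], list(order)


def age_association(patterns, ages: np.ndarray, atom_subset,
                    method: str = "mann-whitney") -> tuple[float, float]:
    """Compare ages of carriers vs non-carriers of a set of atoms.

    A sample carries the subset when at least one of its atoms is
    present. "mann-whitney": two-sided rank test on ages (exact null for
    small untied samples, normal approximation otherwise).
    "fisher": Fisher's exact test on carrier status x age dichotomized
    at the median. Returns (statistic, p-value).
    """
    X = patterns.X if isinstance(patterns, trees.PatternSet) else np.asarray(patterns)
    ages = np.asarray(ages, dtype=float)
    if X.shape[0] != ages.size:
        raise ValueError("one age per pattern required")
    subset = list(atom_subset)
    carrier = X[:, subset].any(axis=1) if subset else np.zeros(X.shape[0], bool)
    a_carrier, a_other = ages[carrier], ages[~carrier]
    if a_carrier.size < 2:
        raise ValueError("carrier group has fewer than 2 samples")
    if a_other.size < 2:
        raise ValueError("non-carrier group has fewer than 2 samples")
    if method == "mann-whitney":
        res = stats.mannwhitneyu(a_carrier, a_other, alternative="two-sided",
                                 method="auto")
        return float(res.statistic), float(res.pvalue)
    if method == "fisher":
        old = ages > np.median(ages)
        table = [[int(np.sum(carrier & old)), int(np.sum(carrier & ~old))],
                 [int(np.sum(~carrier & old)), int(np.sum(~carrier & ~old))]]
        stat, p = stats.fisher_exact(table)
        return float(stat), float(p)
    raise ValueError(f"unknown association method {method!r}")


def loss_atom_indices(report) -> list[int]:
    """Atoms whose band alterations include at least one loss."""
    return [j for j, row in enumerate(report)
            if any(l.startswith("-") for l in row["labels"])]


@dataclass
class StratumResult:
    stratum: str
    sample_ids: list[str]
    J: int
    best_triple: tuple
    bic_table: pd.DataFrame
    fit: efllat.FitResult
    report: list
    patterns: trees.PatternSet
    mixture_fit: trees.MixtureFit


def run_stratum(cohort: CohortMatrix, stratum: str, config: RunConfig,
                seed: int) -> StratumResult:
    """The full chain on one stratum's cohort."""
    t0 = time.monotonic()
    if cohort.S < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than 2 samples")
    w = efllat.make_weights(cohort.grid, schema=config.weight_schema)
    J = efllat.select_n_atoms(cohort, fraction=config.pca_fraction)
    h = efllat.Hyperparams(theta_max=config.theta_max, J=J, seed=seed,
                           max_iter=config.max_iter, tol=config.tol)
    best, table, fit = efllat.select_hyperparams(cohort, config.hyper_grid, h, w)
    logger.info("stratum %s: S=%d J=%d best (lambda, mu, tau)=%s [%.1fs]",
                stratum, cohort.S, J, best, time.monotonic() - t0)
    report = postprocess.atom_report(fit.B, cohort.grid, epsilon=config.epsilon)
    bits = postprocess.binarize_theta(fit.Theta,
                                      threshold=config.theta_threshold * config.theta_max)
    patterns = trees.PatternSet(bits.T)
    mix = trees.fit_mixture(patterns, K=config.K, seed=seed,
                            pseudocount=config.pseudocount)
    logger.info("stratum %s: mixture loglik=%.3f star weight=%.3f [%.1fs]",
                stratum, mix.log_likelihood, mix.mixture.weights[0],
                time.monotonic() - t0)
    return StratumResult(stratum=stratum, sample_ids=list(cohort.sample_ids),
                         J=J, best_triple=best, bic_table=table, fit=fit,
                         report=report, patterns=patterns, mixture_fit=mix)


def run_stratified(cohort: CohortMatrix, manifest: pd.DataFrame, config: RunConfig,
                   outdir: str | Path | None = None) -> dict[str, StratumResult]:
    """Run the chain independently per stage stratum; optionally write artifacts.

    ``manifest`` needs columns sample_id and stage; every cohort sample
    must be assigned a stratum. Strata are processed independently (no
    information crosses them), each with a seed derived from the base
    seed and the stratum order so runs are reproducible.
    """
    stage = dict(zip(manifest["sample_id"].astype(str), manifest["stage"].astype(str)))
    missing = [s for s in cohort.sample_ids if s not in stage]
    if missing:
        raise ValueError(f"samples missing from manifest: {missing[:5]}")
    results: dict[str, StratumResult] = {}
    for i, stratum in enumerate(sorted(set(stage[s] for s in cohort.sample_ids))):
        ids = [s for s in cohort.sample_ids if stage[s] == stratum]
        sub = cohort.subset(ids)
        results[stratum] = run_stratum(sub, stratum, config, seed=config.seed + i)
    if outdir is not None:
        write_run(results, config, Path(outdir))
    return results


def write_run(results: dict[str, StratumResult], config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "strata": {}}
    for stratum, res in results.items():
        d = outdir / f"stage_{stratum}"
        d.mkdir(exist_ok=True)
        atom_ids = [f"A{j + 1}" for j in range(res.fit.B.shape[1])]
        pd.DataFrame(res.fit.B, columns=atom_ids).to_csv(d / "atoms.tsv", sep="\t", index=False)
        pd.DataFrame(res.fit.Theta, index=atom_ids, columns=res.sample_ids).to_csv(
            d / "theta.tsv", sep="\t", index_label="atom")
        res.bic_table.to_csv(d / "bic.tsv", sep="\t", index=False)
        pd.DataFrame([{"atom": r["atom"], "labels": ", ".join(r["labels"])}
                      for r in res.report]).to_csv(d / "atom_report.tsv", sep="\t", index=False)
        with open(d / "atom_report.json", "w") as fh:
            json.dump([{"atom": r["atom"], "labels": r["labels"], "empty": r["empty"]}
                       for r in res.report], fh, indent=1)
        pd.DataFrame(res.patterns.X, index=res.sample_ids, columns=atom_ids).to_csv(
            d / "patterns.tsv", sep="\t", index_label="sample_id")
        atom_labels = {j: r["labels"] for j, r in enumerate(res.report)}
        dots, mix_json = trees.export_tree(res.mixture_fit.mixture, atom_ids, atom_labels)
        for k, dot in enumerate(dots):
            (d / f"tree_{k}.dot").write_text(dot)
        with open(d / "mixture.json", "w") as fh:
            json.dump(mix_json, fh, indent=1)
        manifest["strata"][stratum] = {
            "n_samples": len(res.sample_ids),
            "J": res.J,
            "best_triple": list(res.best_triple),
            "objective": res.fit.objective,
            "converged": res.fit.converged,
            "mixture_loglik": res.mixture_fit.log_likelihood,
            "mixture_weights": res.mixture_fit.mixture.weights.tolist(),
        }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
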