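"""Seeded benchmark experiments built on the simulator and the metric.

Four experiment families, each a pure function of an
:class:`ExperimentConfig` returning a tidy result table:

``contamination_sweep``
    Scale by reference sets mixing true references with an increasing
    fraction of differential genes; record the deviation from ground
    truth and the downstream DE metrics at each contamination level.
``normalizer_comparison``
    Score the ground-truth scaling and six normalizers across a sweep of
    differential-gene fractions.
``mse_concordance``
    Many random-set normalizations per differential fraction, recording
    deviation and reference fold-change MSE side by side.
``random_reference_null``
    Deviation of scalings by subsets of the true references versus by
    random same-size gene sets.

Seed discipline: one master seed; every replicate/draw derives its own
substream deterministically, so a config reproduces its table bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import evaluate_normalization, fold_change_mse
from .exceptions import CdevError, DegenerateReferenceError
from .metric import cdev_from_factors
from .normalize import (
    apply_factors,
    deges_tmm_factors,
    deseq_factors,
    poissonseq_factors,
    reference_factors,
    tc_factors,
    tmm_factors,
    uq_factors,
)
from .simulate import SimConfig, simulate

logger = logging.getLogger(__name__)

EXPERIMENTS = (
    "contamination_sweep",
    "normalizer_comparison",
    "mse_concordance",
    "random_reference_null",
)

_DEFAULT_SWEEPS = {
    "contamination_sweep": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "normalizer_comparison": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "mse_concordance": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "random_reference_null": [0.5],
}


@dataclass
class ExperimentConfig:
    """Configuration of one benchmark experiment run."""

    experiment: str
    sim: SimConfig = field(default_factory=SimConfig)
    sweep_values: list[float] | None = None
    n_replicates: int = 5
    seed: int = 0
    output_dir: str | None = None
    set_size: int | None = None
    n_random_sets: int = 100
    n_draws: int = 50
    subset_size: int | None = None
    fdr: float = 0.05
    deges_fdr: float = 0.10

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.sweep_values is None:
            self.sweep_values = list(_DEFAULT_SWEEPS[self.experiment])
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _child_seed(ss: np.random.SeedSequence) -> int:
    """A 31-bit integer seed derived from a seed-sequence substream."""
    return int(ss.generate_state(1)[0] % (2**31))


def _sim_for(cfg: ExperimentConfig, ss: np.random.SeedSequence, **overrides):
    sim_cfg = dataclasses.replace(cfg.sim, seed=_child_seed(ss), **overrides)
    return simulate(sim_cfg)


def _mixed_scaling_set(
    rng: np.random.Generator,
    ref_ids: pd.Index,
    de_ids: pd.Index,
    size: int,
    contamination: float,
) -> pd.Index:
    n_de = min(int(round(contamination * size)), len(de_ids))
    n_ref = min(size - n_de, len(ref_ids))
    parts = []
    if n_ref:
        parts.append(rng.choice(ref_ids.to_numpy(), size=n_ref, replace=False))
    if n_de:
        parts.append(rng.choice(de_ids.to_numpy(), size=n_de, replace=False))
    return pd.Index(np.concatenate(parts))


def contamination_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Deviation and DE metrics versus scaling-set contamination."""
    rows = []
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    for rep, child in enumerate(children):
        truth = _sim_for(cfg, child)
        Y = truth.counts
        ref_ids = Y.index[~truth.de_mask]
        de_ids = Y.index[truth.de_mask]
        truth_fac = reference_factors(Y, ref_ids).factors
        rng = np.random.default_rng(child)
        # large enough that subset-sampling noise stays well below the
        # contamination signal at zero contamination
        size = cfg.set_size or min(2000, len(ref_ids))
        for c in cfg.sweep_values:
            S = _mixed_scaling_set(rng, ref_ids, de_ids, size, c)
            fac = reference_factors(Y, S).factors
            report = evaluate_normalization(
                Y, fac, truth_fac, truth.condition_labels,
                ref_ids, truth.de_mask, fdr=cfg.fdr,
            )
            rows.append({"replicate": rep, "contamination": c, **report.to_dict()})
    return pd.DataFrame(rows)


_COMPARED_METHODS = (
    "reference", "tc", "uq", "tmm", "deseq", "deges_tmm", "poissonseq",
)


def normalizer_comparison(cfg: ExperimentConfig) -> pd.DataFrame:
    """Score ground truth and six normalizers across DE fractions.

    A method failing on a particular simulated matrix contributes a row
    with missing metrics and a ``note`` naming the error, not a crash.
    """
    rows = []
    all_children = np.random.SeedSequence(cfg.seed).spawn(
        len(cfg.sweep_values) * cfg.n_replicates
    )
    for i_frac, frac in enumerate(cfg.sweep_values):
        children = all_children[
            i_frac * cfg.n_replicates : (i_frac + 1) * cfg.n_replicates
        ]
        for rep, child in enumerate(children):
            truth = _sim_for(cfg, child, de_fraction=frac)
            Y = truth.counts
            ref_ids = Y.index[~truth.de_mask]
            truth_fac = reference_factors(Y, ref_ids).factors
            for method in _COMPARED_METHODS:
                t0 = time.perf_counter()
                try:
                    fac = _factors_by_method(cfg, method, Y, truth, truth_fac)
                    report = evaluate_normalization(
                        Y, fac, truth_fac, truth.condition_labels,
                        ref_ids, truth.de_mask, fdr=cfg.fdr,
                    )
                    row = report.to_dict()
                    note = ""
                except CdevError as exc:
                    row = dict.fromkeys(
                        ("cdev_to_truth", "auc", "fpr", "fnr", "fold_change_mse"),
                        np.nan,
                    )
                    note = f"{type(exc).__name__}: {exc}"
                    logger.warning("method %s failed at fraction %s: %s",
                                   method, frac, note)
                logger.info("%s @ de_fraction=%.2f rep=%d: %.2fs",
                            method, frac, rep, time.perf_counter() - t0)
                rows.append({
                    "de_fraction": frac, "replicate": rep, "method": method,
                    **row, "note": note,
                })
    return pd.DataFrame(rows)


def _factors_by_method(cfg, method, Y, truth, truth_fac):
    if method == "reference":
        return truth_fac
    if method == "tc":
        return tc_factors(Y).factors
    if method == "uq":
        return uq_factors(Y).factors
    if method == "tmm":
        return tmm_factors(Y).factors
    if method == "deseq":
        return deseq_factors(Y).factors
    if method == "deges_tmm":
        return deges_tmm_factors(
            Y, truth.condition_labels, fdr=cfg.deges_fdr
        ).factors
    if method == "poissonseq":
        return poissonseq_factors(Y).factors
    raise ValueError(f"unknown method {method!r}")


def mse_concordance(cfg: ExperimentConfig) -> pd.DataFrame:
    """Deviation versus reference fold-change MSE on random normalizations.

    For each DE fraction, ``n_random_sets`` scaling sets are drawn with a
    random contamination level so the resulting normalizations span a wide
    quality range; each contributes one (cdev, MSE) pair.
    """
    rows = []
    children = np.random.SeedSequence(cfg.seed).spawn(len(cfg.sweep_values))
    for frac, child in zip(cfg.sweep_values, children):
        truth = _sim_for(cfg, child, de_fraction=frac)
        Y = truth.counts
        ref_ids = Y.index[~truth.de_mask]
        de_ids = Y.index[truth.de_mask]
        truth_fac = reference_factors(Y, ref_ids).factors
        rng = np.random.default_rng(child)
        size = cfg.set_size or min(500, len(ref_ids))
        for draw in range(cfg.n_random_sets):
            c = rng.uniform(0.0, 1.0)
            S = _mixed_scaling_set(rng, ref_ids, de_ids, size, c)
            fac = reference_factors(Y, S).factors
            dev = cdev_from_factors(truth_fac, fac).value
            X = apply_factors(Y, fac)
            mse = fold_change_mse(X, truth.condition_labels, ref_ids)
            rows.append({
                "de_fraction": frac, "draw": draw, "contamination": c,
                "cdev_to_truth": dev, "fold_change_mse": mse,
            })
    return pd.DataFrame(rows)


def mse_concordance_correlations(table: pd.DataFrame) -> pd.Series:
    """Pearson correlation of deviation and MSE within each DE fraction."""
    return table.groupby("de_fraction").apply(
        lambda g: float(np.corrcoef(g["cdev_to_truth"], g["fold_change_mse"])[0, 1]),
        include_groups=False,
    ).rename("pearson_r")


def random_reference_null(cfg: ExperimentConfig) -> pd.DataFrame:
    """Deviation of subset-of-reference scalings versus random-gene scalings."""
    rows = []
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    for rep, child in enumerate(children):
        truth = _sim_for(cfg, child)
        Y = truth.counts
        ref_ids = Y.index[~truth.de_mask]
        truth_fac = reference_factors(Y, ref_ids).factors
        rng = np.random.default_rng(child)
        size = cfg.subset_size or max(10, min(100, len(ref_ids) // 2))
        all_ids = Y.index.to_numpy()
        for draw in range(cfg.n_draws):
            S = rng.choice(ref_ids.to_numpy(), size=size, replace=False)
            dev_sub = cdev_from_factors(
                truth_fac, reference_factors(Y, S).factors
            ).value
            rows.append({"replicate": rep, "draw": draw, "kind": "subset",
                         "cdev_to_truth": dev_sub})
            dev_rand = None
            for _ in range(100):
                G = rng.choice(all_ids, size=size, replace=False)
                try:
                    dev_rand = cdev_from_factors(
                        truth_fac, reference_factors(Y, G).factors
                    ).value
                    break
                except DegenerateReferenceError:
                    continue
            if dev_rand is None:
                raise DegenerateReferenceError(
                    "could not draw a usable random gene set in 100 attempts"
                )
            rows.append({"replicate": rep, "draw": draw, "kind": "random",
                         "cdev_to_truth": dev_rand})
    return pd.DataFrame(rows)


def null_quantiles(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary of the subset and random deviation distributions."""
    qs = [0.05, 0.25, 0.5, 0.75, 0.95]
    return table.groupby("kind")["cdev_to_truth"].quantile(qs).unstack()


_DISPATCH = {
    "contamination_sweep": contamination_sweep,
    "normalizer_comparison": normalizer_comparison,
    "mse_concordance": mse_concordance,
    "random_reference_null": random_reference_null,
}


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run an experiment; write TSV + JSON sidecar if an output dir is set."""
    t0 = time.perf_counter()
    table = _DISPATCH[cfg.experiment](cfg)
    logger.info("experiment %s finished in %.1fs", cfg.experiment,
                time.perf_counter() - t0)
    if cfg.output_dir:
        save_results(table, cfg)
    return table


def save_results(table: pd.DataFrame, cfg: ExperimentConfig) -> Path:
    from . import __version__

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / f"{cfg.experiment}.tsv"
    header = not tsv.exists()  # append-safe: repeated runs accumulate rows
    table.to_csv(tsv, sep="\t", index=False, mode="a", header=header)
    sidecar = out / f"{cfg.experiment}.config.json"
    sidecar.write_text(json.dumps(
        {"config": cfg.to_dict(), "package_version": __version__}, indent=2,
    ))
    return tsv


def load_experiment_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim_raw = raw.pop("sim", {}) or {}
    for key in ("n_samples", "fc_range", "dispersion_trend"):
        if key in sim_raw and sim_raw[key] is not None:
            sim_raw[key] = tuple(sim_raw[key])
    return ExperimentConfig(sim=SimConfig(**sim_raw), **raw)


def scatter_plot(table: pd.DataFrame, x: str, y: str, path,
                 hue: str | None = None, log_y: bool = False) -> None:
    """Write an SVG scatter of two result columns (optional grouping)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if hue:
        for key, grp in table.groupby(hue):
            ax.scatter(grp[x], grp[y], s=12, alpha=0.7, label=str(key))
        ax.legend(title=hue, fontsize=8)
    else:
        ax.scatter(table[x], table[y], s=12, alpha=0.7)
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
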