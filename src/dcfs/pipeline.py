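"""End-to-end run: filter -> matrix -> weighting -> top-D1 -> BPSO -> metrics.

One run executes the two-stage protocol twice — once with the plain CFS
objective (alpha = 1, positive class only) fed to the same weighting
algorithm, and once with the dual objective at the configured alpha —
and evaluates all four resulting feature sets (CFS-D1, CFS-D2, DCFS-D1,
DCFS-D2) with the same k-fold SVM protocol. Every artifact is a plain
text file re-derivable from (config, seed); nothing timestamped is
written, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bpso import BPSOParams, bpso_optimize, cv_f1_fitness, merit_fitness
from .evaluate import kfold_cv, make_linear_classifier
from .matrix import FeatureMatrix, read_labels
from .merit import MeritParams
from .variants import build_matrix, filter_variants, read_variant_table, records_to_frame
from .weighting import run_weighting, select_top

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameter set of one end-to-end run.

    Exactly one input route must be given: ``variants`` + ``labels``
    (the 3-step filter runs first) or ``matrix`` + ``labels``.
    """

    # inputs
    variants: str | None = None
    matrix: str | None = None
    labels: str | None = None
    encoding: str = "binary"
    min_tumor_freq: float = 10.0
    max_fisher_p: float = 0.01
    # merit
    alpha: float = 0.5
    correlation: str = "pearson"
    negative_correlation_policy: str = "clip_to_zero"
    # weighting
    phi_min: int = 2
    phi_max: int = 100
    t1: int = 10**6
    d1: int = 50
    # BPSO
    t2: int = 100
    n_particles: int = 100
    inertia: float = 0.5
    c1: float = 2.0
    c2: float = 2.0
    v_min: float = -6.0
    v_max: float = 6.0
    fitness: str = "cv_f1"
    # evaluation
    k: int = 10
    stratified: bool = True
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix is None and self.variants is None:
            raise ValueError("config must provide 'matrix' or 'variants'")
        if self.labels is None:
            raise ValueError("config must provide 'labels'")
        if self.fitness not in ("cv_f1", "merit"):
            raise ValueError("fitness must be 'cv_f1' or 'merit'")
        if self.d1 < 1:
            raise ValueError("d1 must be >= 1")
        MeritParams(  # reuse its validation
            alpha=self.alpha,
            correlation=self.correlation,
            negative_correlation_policy=self.negative_correlation_policy,
        )
        BPSOParams(
            n_iterations=self.t2,
            inertia=self.inertia,
            c1=self.c1,
            c2=self.c2,
            v_min=self.v_min,
            v_max=self.v_max,
            n_particles=self.n_particles,
        )

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key: value mapping")
        raw.update(overrides or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # coerce strings from --set key=value overrides
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, str) and f.type in ("int", "float", "bool", "int | None"):
                v = yaml.safe_load(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: RunConfig, out: Path) -> FeatureMatrix:
    if config.variants is not None:
        records = read_variant_table(config.variants)
        report = filter_variants(records, config.min_tumor_freq, config.max_fisher_p)
        audit = records_to_frame(records, config.min_tumor_freq, config.max_fisher_p)
        audit.to_csv(out / "filtered_variants.tsv", sep="\t", index=False)
        logger.info("filter counts: %s", report.counts)
        with open(out / "filter_counts.json", "w") as fh:
            json.dump(report.counts, fh, indent=2, sort_keys=True)
            fh.write("\n")
        labels = read_labels(config.labels)
        fm = build_matrix(report.survivors, labels, encoding=config.encoding)
        fm.to_tsv(out / "matrix.tsv")
        return fm
    return FeatureMatrix.from_tsv(config.matrix, config.labels)


def _write_selection(path: Path, feature_ids, indices, mask=None) -> None:
    ids = [feature_ids[i] for i in indices]
    sel = pd.DataFrame({"feature_id": ids})
    if mask is not None:
        sel["selected"] = np.asarray(mask, dtype=int)
    sel.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full protocol; returns the metrics mapping it writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    t0 = time.perf_counter()
    fm = _load_inputs(config, out)
    logger.info("matrix: %d samples x %d features (%.2fs)", fm.n_samples, fm.n_features, time.perf_counter() - t0)
    if fm.n_features < 2:
        raise ValueError("need at least 2 features after filtering")

    d1 = min(config.d1, fm.n_features)
    phi_max = min(config.phi_max, fm.n_features)
    classifier = make_linear_classifier()
    seeds = {"weighting": config.seed, "bpso": config.seed + 1, "cv": config.seed + 2}
    metrics: dict = {"seed": config.seed, "k": config.k, "conditions": {}}

    for mode, alpha in (("cfs", 1.0), ("dcfs", config.alpha)):
        params = MeritParams(
            alpha=alpha,
            correlation=config.correlation,
            negative_correlation_policy=config.negative_correlation_policy,
        )
        t0 = time.perf_counter()
        wres = run_weighting(
            fm.X,
            fm.c_pos,
            params=params,
            phi_set=range(config.phi_min, phi_max + 1),
            n_iterations=config.t1,
            seed=seeds["weighting"],
        )
        logger.info("%s weighting done (%.2fs)", mode, time.perf_counter() - t0)
        wres.to_frame(fm.feature_ids).to_csv(out / f"weights_{mode}.tsv", sep="\t", index=False)
        d1_idx = select_top(wres.weights, d1)
        _write_selection(out / f"selection_{mode}_d1.tsv", fm.feature_ids, d1_idx)

        sub = fm.subset_features(d1_idx)
        if config.fitness == "merit":
            fitness = merit_fitness(sub.X, sub.c_pos, params)
        else:
            fitness = cv_f1_fitness(
                sub.X, sub.c_pos, estimator=classifier, k=config.k,
                seed=seeds["cv"], stratified=config.stratified,
            )
        bparams = BPSOParams(
            n_iterations=config.t2,
            inertia=config.inertia,
            c1=config.c1,
            c2=config.c2,
            v_min=config.v_min,
            v_max=config.v_max,
            n_particles=config.n_particles,
        )
        t0 = time.perf_counter()
        bres = bpso_optimize(fitness, sub.n_features, bparams, seed=seeds["bpso"])
        logger.info(
            "%s BPSO done: D2=%d, fitness=%.4f (%.2fs)",
            mode, bres.n_selected, bres.fitness, time.perf_counter() - t0,
        )
        d2_idx = d1_idx[bres.mask]
        _write_selection(out / f"selection_{mode}_d2.tsv", fm.feature_ids, d2_idx)

        for stage, idx in ((f"{mode}_d1", d1_idx), (f"{mode}_d2", d2_idx)):
            if idx.size == 0:
                entry = {"num": 0, "f1": 0.0, "accuracy": 0.0}
            else:
                cv = kfold_cv(
                    fm.X[:, idx], fm.c_pos, classifier,
                    k=config.k, seed=seeds["cv"], stratified=config.stratified,
                )
                entry = {"num": int(idx.size), "f1": cv.mean_f1, "accuracy": cv.mean_accuracy}
            if stage.endswith("_d2"):
                entry["bpso_fitness"] = bres.fitness
            metrics["conditions"][stage] = entry

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_meta.json", "w") as fh:
        json.dump(
            {
                "seeds": seeds,
                "phi": [config.phi_min, phi_max],
                "t1": config.t1,
                "t2": config.t2,
                "alpha": config.alpha,
                "correlation": config.correlation,
                "d1": d1,
                "fitness": config.fitness,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return metrics


__all__ = ["RunConfig", "run_pipeline"]
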