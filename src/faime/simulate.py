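"""Synthetic fixture generation.

Generates geneset collections, multi-cohort two-group expression matrices
with planted mechanism-level deregulation, and exponential recurrence
times for a validation cohort — everything the pipeline consumes, in the
exact file formats the readers accept, fully seed-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from faime.io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleGroups,
    write_expression_tsv,
    write_gmt,
    write_groups_tsv,
)
from faime.prognosis import SurvivalTable, write_survival_tsv

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_sets: int = 100
    set_size_range: tuple[int, int] = (10, 30)
    n_planted: int = 5
    effect_size: float = 1.5  # standardized mean shift in units of noise_sd
    n_tumor: int = 20
    n_normal: int = 20
    noise_sd: float = 1.0
    n_datasets: int = 1
    hazard_good: float = 0.01  # per month
    hazard_poor: float = 0.03
    censor_fraction: float = 0.2
    followup_horizon: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError(
                f"set sizes up to {hi} exceed the {self.n_genes}-gene universe"
            )
        if self.n_planted > self.n_sets:
            raise ValueError("n_planted cannot exceed n_sets")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.hazard_good <= 0 or self.hazard_poor <= 0:
            raise ValueError("hazards must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "set_size_range" in d:
            d["set_size_range"] = tuple(d["set_size_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *key)))


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(cfg.n_genes)]


def simulate_collection(cfg: SimulationConfig) -> GeneSetCollection:
    """Random genesets with sizes uniform in ``set_size_range``; sets may overlap."""
    rng = _rng(cfg, 0)
    genes = np.array(_gene_ids(cfg))
    lo, hi = cfg.set_size_range
    sets: dict[str, frozenset[str]] = {}
    for k in range(cfg.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"M{k:04d}"] = frozenset(members.tolist())
    return GeneSetCollection("synthetic", sets)


def _simulate_dataset(
    cfg: SimulationConfig,
    coll: GeneSetCollection,
    truth: list[tuple[str, int]],
    rng: np.random.Generator,
    dataset_tag: str,
    group_labels: tuple[str, str] = ("tumor", "normal"),
) -> tuple[ExpressionMatrix, SampleGroups]:
    """One cohort: Gaussian baseline plus planted shifts in case samples.

    ``group_labels[0]`` is the deregulated (case) group.  A per-gene
    baseline offset models dataset-specific heterogeneity in multi-cohort
    mode.
    """
    genes = _gene_ids(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_samples = cfg.n_tumor + cfg.n_normal
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    if cfg.n_datasets > 1:
        offsets = rng.normal(0.0, 0.5 * cfg.noise_sd, size=cfg.n_genes)
        values += offsets[:, None]
    case_cols = np.arange(cfg.n_tumor)
    for set_id, sign in truth:
        rows = [gene_index[g] for g in coll.sets[set_id]]
        values[np.ix_(rows, case_cols)] += sign * cfg.effect_size * cfg.noise_sd
    sample_ids = [f"{dataset_tag}S{j:03d}" for j in range(n_samples)]
    labels = {
        s: (group_labels[0] if j < cfg.n_tumor else group_labels[1])
        for j, s in enumerate(sample_ids)
    }
    return (
        ExpressionMatrix(genes, sample_ids, values),
        SampleGroups(labels),
    )


def simulate_expression(
    cfg: SimulationConfig, coll: GeneSetCollection
) -> tuple[list[tuple[ExpressionMatrix, SampleGroups]], list[tuple[str, int]]]:
    """Simulate ``n_datasets`` cohorts sharing one planted truth.

    Each of ``n_planted`` randomly chosen sets receives a random sign; in
    every cohort the member genes' tumor-sample means are shifted by
    ``sign * effect_size * noise_sd``.  Cohorts share the truth but not
    the noise (and get dataset-specific baseline offsets when
    ``n_datasets > 1``).

    Returns the list of (expression, groups) pairs and the ground-truth
    (set_id, sign) list.
    """
    rng_truth = _rng(cfg, 1)
    set_ids = np.array(coll.mechanism_ids)
    planted = rng_truth.choice(set_ids, size=cfg.n_planted, replace=False)
    signs = rng_truth.choice([-1, 1], size=cfg.n_planted)
    truth = [(str(m), int(s)) for m, s in zip(planted, signs)]

    datasets = []
    for d in range(cfg.n_datasets):
        rng = _rng(cfg, 2, d)
        datasets.append(
            _simulate_dataset(cfg, coll, truth, rng, dataset_tag=f"D{d + 1}")
        )
    return datasets, truth


def simulate_survival(
    cfg: SimulationConfig, assignment_truth: Mapping[str, str]
) -> SurvivalTable:
    """Exponential recurrence times for two latent prognosis groups.

    ``assignment_truth`` maps sample id to ``"good"`` or ``"poor"``.  A
    random ``censor_fraction`` of subjects receive an independent
    Uniform(0, followup_horizon) censoring time; everyone is additionally
    censored at the horizon.  ``event = 1`` iff recurrence precedes both.
    """
    rng = _rng(cfg, 3)
    sample_ids = list(assignment_truth)
    hazards = np.array(
        [
            cfg.hazard_poor if assignment_truth[s] == "poor" else cfg.hazard_good
            for s in sample_ids
        ]
    )
    if not all(v in ("good", "poor") for v in assignment_truth.values()):
        raise ValueError("assignment_truth values must be 'good' or 'poor'")
    t_event = rng.exponential(1.0 / hazards)
    censor = np.full(len(sample_ids), np.inf)
    n_cens = int(round(cfg.censor_fraction * len(sample_ids)))
    if n_cens:
        idx = rng.choice(len(sample_ids), size=n_cens, replace=False)
        censor[idx] = rng.uniform(0.0, cfg.followup_horizon, size=n_cens)
    censor = np.minimum(censor, cfg.followup_horizon)
    observed = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return SurvivalTable(sample_ids, observed, event)


def generate_fixture(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete multi-cohort fixture plus a ready pipeline config.

    Emits: ``sets.gmt``, per-cohort ``dataset_<i>.expr.tsv`` /
    ``dataset_<i>.groups.tsv``, a validation cohort (expression, latent
    good/poor groups, survival), ``truth.json``, and ``pipeline.yaml``.
    Returns a manifest dict of the written paths and the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coll = simulate_collection(cfg)
    write_gmt(coll, outdir / "sets.gmt")
    datasets, truth = simulate_expression(cfg, coll)

    ds_entries = []
    for i, (expr, groups) in enumerate(datasets, start=1):
        expr_path = outdir / f"dataset_{i}.expr.tsv"
        grp_path = outdir / f"dataset_{i}.groups.tsv"
        write_expression_tsv(expr, expr_path)
        write_groups_tsv(groups, grp_path)
        ds_entries.append(
            {"name": f"dataset_{i}", "expression": expr_path.name, "groups": grp_path.name}
        )

    # validation cohort: latent poor group carries the planted deregulation
    rng_val = _rng(cfg, 4)
    val_expr, val_groups = _simulate_dataset(
        cfg, coll, truth, rng_val, dataset_tag="V", group_labels=("poor", "good")
    )
    surv = simulate_survival(cfg, val_groups.labels)
    write_expression_tsv(val_expr, outdir / "validation.expr.tsv")
    write_groups_tsv(val_groups, outdir / "validation.groups.tsv")
    write_survival_tsv(surv, outdir / "validation.surv.tsv")

    truth_doc = {
        "planted": [[m, s] for m, s in truth],
        "validation_groups": val_groups.labels,
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg.__dict__.items()
            }
        },
    }
    with open(outdir / "truth.json", "wt") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)

    pipeline_cfg = {
        "seed": cfg.seed,
        "gmt": "sets.gmt",
        "tumor_label": "tumor",
        "fdr": 0.05,
        "t_variant": "student",
        "rank_orientation": "high-is-max",
        "min_set_size": 2,
        "max_set_size": None,
        "datasets": ds_entries,
        "validation": {
            "expression": "validation.expr.tsv",
            "survival": "validation.surv.tsv",
        },
    }
    with open(outdir / "pipeline.yaml", "wt") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    log.info("fixture written to %s (%d cohorts)", outdir, len(datasets))
    return {"outdir": str(outdir), "truth": truth, "pipeline": pipeline_cfg}
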