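"""Directional differential-mechanism signatures.

Per-mechanism two-sample t-test between the two phenotype groups,
Benjamini-Hochberg multiplicity adjustment, FDR thresholding, and
direction assignment from the sign of (tumor mean - normal mean) of the
rescaled scores: a positive difference means the mechanism's members are
predominantly up-regulated in tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from faime.io import SampleGroups
from faime.scoring import MechanismScoreMatrix

log = logging.getLogger(__name__)

T_VARIANTS = ("student", "welch")


@dataclass
class DifferentialMechanismRecord:
    mechanism_id: str
    t_statistic: float
    p_value: float
    q_value: float
    direction: Optional[int]  # +1 up in tumor, -1 down, None if exactly 0
    mean_tumor: float
    mean_normal: float


@dataclass
class DirectionalSignature:
    """Mechanisms retained at an FDR level, each tagged with a direction."""

    label: str
    fdr_level: float
    entries: dict[str, int]
    n_tested: Optional[int] = None
    collection_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        for mid, d in self.entries.items():
            if d not in (1, -1):
                raise ValueError(f"direction for {mid!r} must be +1 or -1, got {d!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mechanism_ids(self) -> frozenset[str]:
        return frozenset(self.entries)

    @property
    def pct_of_tested(self) -> Optional[float]:
        if not self.n_tested:
            return None
        return 100.0 * len(self.entries) / self.n_tested


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_mechanisms(
    scores: MechanismScoreMatrix,
    groups: SampleGroups,
    tumor_label: Optional[str] = None,
    variant: str = "student",
    on: str = "rescaled",
) -> list[DifferentialMechanismRecord]:
    """Two-sided two-sample t-test per mechanism.

    Parameters
    ----------
    tumor_label
        Which of the two group labels is the tumor (case) group; defaults
        to the label ``"tumor"`` when present, otherwise it is required.
    variant
        ``"student"`` (pooled variance, default) or ``"welch"``.
    on
        Test rescaled (default) or raw scores.
    """
    if variant not in T_VARIANTS:
        raise ValueError(f"unknown t-test variant {variant!r}")
    labels = groups.group_labels
    if tumor_label is None:
        if "tumor" in labels:
            tumor_label = "tumor"
        else:
            raise ValueError(
                f"tumor_label required; group labels are {labels!r}"
            )
    if tumor_label not in labels:
        raise ValueError(f"tumor label {tumor_label!r} not among groups {labels!r}")
    normal_label = labels[0] if labels[1] == tumor_label else labels[1]

    sample_index = {s: i for i, s in enumerate(scores.sample_ids)}
    for s in groups.labels:
        if s not in sample_index:
            raise ValueError(f"labeled sample {s!r} missing from score matrix")
    t_cols = [sample_index[s] for s in groups.samples(tumor_label)]
    n_cols = [sample_index[s] for s in groups.samples(normal_label)]
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    mat = scores._pick(on)
    x_t = mat[:, t_cols]
    x_n = mat[:, n_cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(
            x_t, x_n, axis=1, equal_var=(variant == "student")
        )
    mean_t = x_t.mean(axis=1)
    mean_n = x_n.mean(axis=1)
    diff = mean_t - mean_n

    # degenerate rows: zero variance within both groups
    flat = (x_t.var(axis=1) == 0) & (x_n.var(axis=1) == 0)
    for i in np.flatnonzero(flat):
        if diff[i] == 0.0:
            t_stat[i], p_val[i] = 0.0, 1.0
            log.info(
                "mechanism %r has zero variance and equal means; t=0, p=1",
                scores.mechanism_ids[i],
            )
        else:
            t_stat[i] = np.sign(diff[i]) * np.inf
            p_val[i] = 0.0
            log.info(
                "mechanism %r has zero variance but unequal means; p=0",
                scores.mechanism_ids[i],
            )
    q_val = bh_adjust(p_val)

    records = []
    for i, mid in enumerate(scores.mechanism_ids):
        d = int(np.sign(diff[i])) if diff[i] != 0.0 else None
        records.append(
            DifferentialMechanismRecord(
                mechanism_id=mid,
                t_statistic=float(t_stat[i]),
                p_value=float(p_val[i]),
                q_value=float(q_val[i]),
                direction=d,
                mean_tumor=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
            )
        )
    return records


test_mechanisms.__test__ = False  # not a pytest test, despite the name


def build_signature(
    records: Iterable[DifferentialMechanismRecord],
    fdr_level: float,
    label: str,
    collection_label: Optional[str] = None,
) -> DirectionalSignature:
    """Retain mechanisms with q <= fdr_level, tagged with their direction.

    Records with an exactly zero group-mean difference carry no direction
    and cannot enter a signature.
    """
    records = list(records)
    entries: dict[str, int] = {}
    for rec in records:
        if rec.q_value <= fdr_level and rec.direction is not None:
            entries[rec.mechanism_id] = rec.direction
    sig = DirectionalSignature(
        label=label,
        fdr_level=fdr_level,
        entries=entries,
        n_tested=len(records),
        collection_label=collection_label,
    )
    if not entries:
        log.warning("signature %r is empty at FDR %g", label, fdr_level)
    else:
        log.info(
            "signature %r: %d of %d mechanisms (%.0f%%) at FDR %g",
            label,
            len(entries),
            len(records),
            sig.pct_of_tested or 0.0,
            fdr_level,
        )
    return sig


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------


def records_to_frame(
    records: Sequence[DifferentialMechanismRecord],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mechanism_id": [r.mechanism_id for r in records],
            "t": [r.t_statistic for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "direction": [r.direction if r.direction is not None else 0 for r in records],
            "mean_tumor": [r.mean_tumor for r in records],
            "mean_normal": [r.mean_normal for r in records],
        }
    )


def write_records_tsv(
    records: Sequence[DifferentialMechanismRecord], path: str | Path
) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_signature_tsv(sig: DirectionalSignature, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# label={sig.label}\n")
        fh.write(f"# fdr_level={sig.fdr_level:g}\n")
        if sig.n_tested is not None:
            fh.write(f"# n_tested={sig.n_tested}\n")
        if sig.collection_label is not None:
            fh.write(f"# collection={sig.collection_label}\n")
        fh.write("mechanism_id\tdirection\n")
        for mid in sorted(sig.entries):
            fh.write(f"{mid}\t{sig.entries[mid]:+d}\n")


def read_signature_tsv(path: str | Path) -> DirectionalSignature:
    meta: dict[str, str] = {}
    rows: list[tuple[str, int]] = []
    with open(path, "rt") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key] = value
                continue
            if not line:
                continue
            if not header_seen:
                header_seen = True
                continue
            mid, d = line.split("\t")
            rows.append((mid, int(d)))
    return DirectionalSignature(
        label=meta.get("label", str(path)),
        fdr_level=float(meta.get("fdr_level", "0.05")),
        entries=dict(rows),
        n_tested=int(meta["n_tested"]) if "n_tested" in meta else None,
        collection_label=meta.get("collection"),
    )
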