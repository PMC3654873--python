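"""Prognostic stratification: k-medoids partitioning and survival analysis.

A validation cohort's score matrix is restricted to a signature's
mechanisms, samples are split into two groups by classic Partitioning
Around Medoids (deterministic BUILD + SWAP, k = 2, Euclidean distance),
and recurrence-free survival separation between the groups is assessed
with Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from faime.differential import DirectionalSignature
from faime.exceptions import FormatError
from faime.scoring import MechanismScoreMatrix

log = logging.getLogger(__name__)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (months) and event indicator (1 = event)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in survival table")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("times must be finite and >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValueError(f"samples without survival data: {missing}")
        rows = [index[s] for s in sample_ids]
        return SurvivalTable(sample_ids, self.time[rows], self.event[rows])


@dataclass
class CohortAssignment:
    """Two-cluster PAM assignment with medoids and final total dissimilarity."""

    assignment: dict[str, int]  # sample -> 1 or 2
    medoids: tuple[str, str]
    total_dissimilarity: float

    def samples(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    group_n: dict[int, int]
    group_events: dict[int, int]
    km: dict[int, pd.DataFrame]


def restrict_scores(
    scores: MechanismScoreMatrix, signature: DirectionalSignature
) -> MechanismScoreMatrix:
    """Restrict the score matrix rows to the signature's mechanisms."""
    keep = [m for m in scores.mechanism_ids if m in signature.entries]
    absent = sorted(signature.mechanism_ids - set(scores.mechanism_ids))
    if absent:
        log.warning(
            "%d signature mechanism(s) absent from the score matrix: %s",
            len(absent),
            absent[:10],
        )
    if not keep:
        raise ValueError("no signature mechanism present in the score matrix")
    rows = [scores.mechanism_ids.index(m) for m in keep]
    return MechanismScoreMatrix(
        keep,
        list(scores.sample_ids),
        rescaled=scores.rescaled[rows, :],
        raw=None if scores.raw is None else scores.raw[rows, :],
    )


# ---------------------------------------------------------------------------
# PAM (k = 2)
# ---------------------------------------------------------------------------


def _pam2(dist: np.ndarray) -> tuple[tuple[int, int], np.ndarray, float]:
    """Classic deterministic PAM with k=2: greedy BUILD then best-improvement
    SWAP to convergence.  Ties are broken by the lowest index."""
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance
    m1 = int(np.argmin(dist.sum(axis=1)))
    # second medoid maximizes the total decrease in cost
    gains = np.maximum(dist[:, m1][:, None] - dist, 0.0).sum(axis=0)
    gains[m1] = -np.inf
    m2 = int(np.argmax(gains))
    medoids = [m1, m2]

    def cost(meds: list[int]) -> float:
        return float(np.minimum(dist[meds[0]], dist[meds[1]]).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_cost, best_swap = current, None
        for slot in (0, 1):
            other = medoids[1 - slot]
            for h in range(n):
                if h in medoids:
                    continue
                c = cost([h, other])
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (slot, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            current = best_cost
            improved = True

    medoids = sorted(medoids)
    labels = np.where(dist[medoids[0]] <= dist[medoids[1]], 1, 2)
    labels[medoids[0]] = 1
    labels[medoids[1]] = 2
    return (medoids[0], medoids[1]), labels, current


def pam_partition(
    scores: MechanismScoreMatrix, standardize: bool = False
) -> CohortAssignment:
    """Two-cluster PAM on Euclidean distances between samples' score vectors.

    Deterministic: BUILD is greedy and SWAP uses best-improvement with
    ties broken by sample order.  With ``standardize`` each mechanism is
    z-scored across samples before distances are computed.
    """
    if len(scores.sample_ids) < 4:
        raise ValueError("need at least 4 samples for a 2-cluster partition")
    x = scores.rescaled.T.astype(float)  # samples x mechanisms
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    dist = squareform(pdist(x, metric="euclidean"))
    (m1, m2), labels, total = _pam2(dist)
    if len(set(labels)) < 2:  # pragma: no cover - medoids force non-empty
        raise RuntimeError("PAM produced an empty cluster")
    assignment = {s: int(labels[i]) for i, s in enumerate(scores.sample_ids)}
    return CohortAssignment(
        assignment=assignment,
        medoids=(scores.sample_ids[m1], scores.sample_ids[m2]),
        total_dissimilarity=total,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def _km_table(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate; censored subjects leave the risk set after
    their time (same-time events precede censorings)."""
    n = time.size
    rows = [(0.0, n, 0, 1.0)]
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])


def km_estimate(
    surv: SurvivalTable, assignment: CohortAssignment
) -> dict[int, pd.DataFrame]:
    """Kaplan-Meier curve per PAM cluster."""
    out: dict[int, pd.DataFrame] = {}
    for cluster in (1, 2):
        members = assignment.samples(cluster)
        if not members:
            raise ValueError(f"cluster {cluster} has no samples")
        sub = surv.subset(members)
        out[cluster] = _km_table(sub.time, sub.event)
    return out


def logrank_test(surv: SurvivalTable, assignment: CohortAssignment) -> LogRankResult:
    """Standard two-group log-rank test (1 df).

    At each distinct event time the observed minus expected events in
    group 1 is accumulated with the hypergeometric variance; ties are
    handled by the simultaneous-event convention.
    """
    sub1 = surv.subset(assignment.samples(1))
    sub2 = surv.subset(assignment.samples(2))
    t1, e1, t2, e2 = sub1.time, sub1.event, sub2.time, sub2.event
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        exp1 = d * n1 / n
        o_minus_e += d1 - exp1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)

    km = km_estimate(surv, assignment)
    if var == 0.0:
        log.warning("no informative events; log-rank statistic set to 0")
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(chi2.sf(stat, df=1))
    return LogRankResult(
        chi_square=float(stat),
        p_value=p,
        group_n={1: t1.size, 2: t2.size},
        group_events={1: int(e1.sum()), 2: int(e2.sum())},
        km=km,
    )


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------


def read_survival_tsv(path: str | Path) -> SurvivalTable:
    """Read a survival table with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: survival table needs columns {sorted(required)}"
        )
    return SurvivalTable(
        list(df["sample_id"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )


def write_survival_tsv(surv: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_assignment_tsv(assignment: CohortAssignment, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# medoids={assignment.medoids[0]},{assignment.medoids[1]}\n")
        fh.write(f"# total_dissimilarity={assignment.total_dissimilarity:.12g}\n")
        fh.write("sample_id\tcluster\n")
        for sid, c in assignment.assignment.items():
            fh.write(f"{sid}\t{c}\n")
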