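"""Per-sample mechanism scoring via exponentially rank-weighted centroids.

For each sample, genes are ranked by expression and assigned the weight
``w = r * exp(-r / |G|)``, where ``r`` is the gene's rank and ``|G|`` the
number of measured genes.  A mechanism's raw score is the mean weight of
its member genes minus the mean weight of the non-members; per sample,
scores are then rescaled by subtracting the minimum raw score across the
mechanisms of the collection, so every sample's rescaled minimum is 0.

Rank orientation
----------------
The weight function is increasing on ``[1, |G|]``, so assigning the
highest-expressed gene the maximal rank ``|G|`` is what gives highly
expressed genes the largest weights (the default, ``"high-is-max"``).
The inverse orientation is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from faime.exceptions import DegenerateSetError
from faime.io import ExpressionMatrix, GeneSetCollection

log = logging.getLogger(__name__)

RANK_ORIENTATIONS = ("high-is-max", "high-is-min")


@dataclass
class MechanismScoreMatrix:
    """Mechanisms x samples score matrix (raw and per-sample-rescaled).

    ``raw`` may be ``None`` for matrices loaded from a file that stored a
    single variant.
    """

    mechanism_ids: list[str]
    sample_ids: list[str]
    rescaled: np.ndarray
    raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rescaled = np.asarray(self.rescaled, dtype=float)
        shape = (len(self.mechanism_ids), len(self.sample_ids))
        if self.rescaled.shape != shape:
            raise ValueError(f"rescaled matrix shape {self.rescaled.shape} != {shape}")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)
            if self.raw.shape != shape:
                raise ValueError(f"raw matrix shape {self.raw.shape} != {shape}")
        if len(set(self.mechanism_ids)) != len(self.mechanism_ids):
            raise ValueError("duplicate mechanism ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_mechanisms(self) -> int:
        return len(self.mechanism_ids)

    def to_frame(self, which: str = "rescaled") -> pd.DataFrame:
        mat = self._pick(which)
        return pd.DataFrame(mat, index=self.mechanism_ids, columns=self.sample_ids)

    def _pick(self, which: str) -> np.ndarray:
        if which == "rescaled":
            return self.rescaled
        if which == "raw":
            if self.raw is None:
                raise ValueError("raw scores not available on this matrix")
            return self.raw
        raise ValueError(f"unknown matrix kind {which!r}")


def rank_sample(
    expr_column: Sequence[float] | np.ndarray,
    orientation: str = "high-is-max",
) -> np.ndarray:
    """Rank one sample's expression values.

    The highest-expressed gene receives rank ``|G|`` and the lowest rank 1
    (under the default orientation); tied values receive the average of
    their would-be ranks.
    """
    values = np.asarray(expr_column, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector of at least 2 expression values")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if orientation == "high-is-max":
        return rankdata(values)
    if orientation == "high-is-min":
        return rankdata(-values)
    raise ValueError(f"unknown rank orientation {orientation!r}")


def compute_weights(ranks: np.ndarray, n_genes: int) -> np.ndarray:
    """Exponential rank weights ``w = r * exp(-r / n_genes)``."""
    ranks = np.asarray(ranks, dtype=float)
    if np.any(ranks < 1.0) or np.any(ranks > n_genes):
        raise ValueError(f"ranks must lie in [1, {n_genes}]")
    return ranks * np.exp(-ranks / n_genes)


def faime_raw_score(
    weights: Mapping[str, float] | pd.Series,
    member_genes: Iterable[str],
) -> float:
    """Raw score of one gene set in one sample: centroid difference.

    ``NC(set) - NC(complement)``, where ``NC`` is the arithmetic mean of
    the rank weights over the respective genes.
    """
    w = pd.Series(weights, dtype=float)
    members = frozenset(member_genes)
    if not members:
        raise ValueError("member_genes must be non-empty")
    missing = members - set(w.index)
    if missing:
        raise KeyError(f"member gene(s) without weights: {sorted(missing)}")
    in_mask = w.index.isin(members)
    if in_mask.all():
        raise DegenerateSetError(
            "gene set equals the measured universe; complement is empty"
        )
    return float(w[in_mask].mean() - w[~in_mask].mean())


def faime_transform(
    expr: ExpressionMatrix,
    coll: GeneSetCollection,
    rank_orientation: str = "high-is-max",
) -> MechanismScoreMatrix:
    """Score every mechanism in every sample.

    ``coll`` must already be filtered against ``expr`` (see
    :func:`faime.io.filter_collection`): every member gene measured and no
    set equal to the measured universe.
    """
    if rank_orientation not in RANK_ORIENTATIONS:
        raise ValueError(f"unknown rank orientation {rank_orientation!r}")
    n_genes, n_samples = expr.values.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    mech_ids = coll.mechanism_ids
    if len(mech_ids) < 2:
        log.warning(
            "collection has %d mechanism(s); rescaling forces a lone "
            "mechanism to 0 everywhere",
            len(mech_ids),
        )

    membership = np.zeros((len(mech_ids), n_genes), dtype=float)
    for row, mid in enumerate(mech_ids):
        members = coll.sets[mid]
        unmeasured = [g for g in members if g not in gene_index]
        if unmeasured:
            raise ValueError(
                f"mechanism {mid!r} contains unmeasured gene(s) "
                f"{sorted(unmeasured)[:5]}; filter the collection first"
            )
        if len(members) == n_genes:
            raise DegenerateSetError(
                f"mechanism {mid!r} equals the measured universe"
            )
        membership[row, [gene_index[g] for g in members]] = 1.0

    ranks = np.apply_along_axis(rankdata, 0, expr.values)
    if rank_orientation == "high-is-min":
        ranks = n_genes + 1.0 - ranks
    weights = ranks * np.exp(-ranks / n_genes)

    sizes = membership.sum(axis=1, keepdims=True)
    member_sums = membership @ weights
    total = weights.sum(axis=0, keepdims=True)
    raw = member_sums / sizes - (total - member_sums) / (n_genes - sizes)
    rescaled = raw - raw.min(axis=0, keepdims=True)
    return MechanismScoreMatrix(
        list(mech_ids), list(expr.sample_ids), rescaled=rescaled, raw=raw
    )


def write_scores_tsv(
    scores: MechanismScoreMatrix, path: str | Path, which: str = "rescaled"
) -> None:
    scores.to_frame(which).to_csv(
        path, sep="\t", index_label="mechanism_id", float_format="%.12g"
    )


def read_scores_tsv(path: str | Path, kind: str = "rescaled") -> MechanismScoreMatrix:
    """Read a scores TSV written by :func:`write_scores_tsv`.

    The stored matrix is placed in the slot named by ``kind``; for
    ``kind="raw"`` the rescaled slot is recomputed per sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if kind == "rescaled":
        return MechanismScoreMatrix(
            list(df.index.astype(str)), list(df.columns.astype(str)), rescaled=values
        )
    if kind == "raw":
        rescaled = values - values.min(axis=0, keepdims=True)
        return MechanismScoreMatrix(
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            rescaled=rescaled,
            raw=values,
        )
    raise ValueError(f"unknown matrix kind {kind!r}")
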