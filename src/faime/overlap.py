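"""Cross-signature overlap accounting and significance.

Directional intersection of signatures (a mechanism counts only when it is
present in every signature with the same direction), one-sided Fisher
exact p-values for mechanism-level overlap, and a fixed-size subset
bootstrap for gene-level overlap between signatures' constituent genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from faime.differential import DirectionalSignature
from faime.io import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    signature_labels: tuple[str, ...]
    entries: dict[str, int]  # mechanism -> shared direction
    pct_of_each: tuple[float, ...]
    fet_p: Optional[float] = None

    @property
    def n_overlap(self) -> int:
        return len(self.entries)

    def to_signature(self, label: str, fdr_level: float = 0.05) -> DirectionalSignature:
        """View the overlap as a directional signature (e.g. for prognosis)."""
        return DirectionalSignature(label=label, fdr_level=fdr_level, entries=dict(self.entries))


@dataclass
class BootstrapOverlapResult:
    observed_overlap: int
    n_draws: int
    n_at_least: int
    empirical_p: float
    seed: int


def directional_intersect(
    signatures: Sequence[DirectionalSignature],
    universe_size: Optional[int] = None,
) -> OverlapResult:
    """Mechanisms shared by ALL signatures with concordant direction.

    Percentages are reported against each signature's own size.  When
    exactly two signatures and a ``universe_size`` (mechanisms tested in
    both datasets) are given, a one-sided Fisher exact p-value is attached.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    coll_labels = {s.collection_label for s in signatures if s.collection_label}
    if len(coll_labels) > 1:
        raise ValueError(
            f"signatures come from different collections: {sorted(coll_labels)}"
        )
    first = signatures[0]
    shared: dict[str, int] = {}
    for mid, d in first.entries.items():
        if all(other.entries.get(mid) == d for other in signatures[1:]):
            shared[mid] = d
    pcts = tuple(
        100.0 * len(shared) / len(s) if len(s) else 0.0 for s in signatures
    )
    fet = None
    if universe_size is not None and len(signatures) == 2:
        fet = fisher_overlap_p(
            len(shared), len(signatures[0]), len(signatures[1]), universe_size
        )
    return OverlapResult(
        signature_labels=tuple(s.label for s in signatures),
        entries=shared,
        pct_of_each=pcts,
        fet_p=fet,
    )


def fisher_overlap_p(
    n_overlap: int, size_a: int, size_b: int, universe_size: int
) -> float:
    """One-sided (enrichment) Fisher exact / hypergeometric tail.

    Probability of an overlap at least as large as observed when a set of
    ``size_b`` is drawn uniformly from a universe containing ``size_a``
    marked elements.
    """
    if not (0 <= n_overlap <= min(size_a, size_b) <= max(size_a, size_b) <= universe_size):
        raise ValueError(
            f"inconsistent counts: overlap={n_overlap}, sizes=({size_a}, {size_b}), "
            f"universe={universe_size}"
        )
    return float(hypergeom.sf(n_overlap - 1, universe_size, size_a, size_b))


def signature_genes(
    signature: DirectionalSignature, coll: GeneSetCollection
) -> frozenset[str]:
    """Union of member genes over the signature's mechanisms (direction ignored)."""
    genes: set[str] = set()
    for mid in signature.entries:
        if mid not in coll.sets:
            raise KeyError(f"mechanism {mid!r} not found in collection {coll.source_label!r}")
        genes |= coll.sets[mid]
    return frozenset(genes)


def bootstrap_overlap_p(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    background_a: Iterable[str],
    background_b: Iterable[str],
    n_draws: int = 10_000,
    seed: int = 0,
    _chunk: int = 256,
) -> BootstrapOverlapResult:
    """Empirical p-value for gene-level overlap via fixed-size subset draws.

    Each draw samples ``|genes_a|`` genes uniformly without replacement
    from ``background_a`` and ``|genes_b|`` from ``background_b``; the
    p-value is the add-one-corrected fraction of draws whose overlap
    reaches the observed ``|genes_a & genes_b|``.
    """
    set_a, set_b = frozenset(genes_a), frozenset(genes_b)
    bg_a, bg_b = frozenset(background_a), frozenset(background_b)
    if not set_a <= bg_a:
        raise ValueError("genes_a is not a subset of background_a")
    if not set_b <= bg_b:
        raise ValueError("genes_b is not a subset of background_b")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    observed = len(set_a & set_b)
    ka, kb = len(set_a), len(set_b)

    union = sorted(bg_a | bg_b)
    index = {g: i for i, g in enumerate(union)}
    codes_a = np.array([index[g] for g in sorted(bg_a)], dtype=np.int64)
    codes_b = np.array([index[g] for g in sorted(bg_b)], dtype=np.int64)

    rng = np.random.default_rng(seed)
    n_at_least = 0
    if ka == 0 or kb == 0:
        # every draw has overlap 0; observed is necessarily 0
        n_at_least = n_draws
    else:
        done = 0
        n_union = len(union)
        while done < n_draws:
            chunk = min(_chunk, n_draws - done)
            pick_a = np.argpartition(
                rng.random((chunk, codes_a.size)), ka - 1, axis=1
            )[:, :ka]
            pick_b = np.argpartition(
                rng.random((chunk, codes_b.size)), kb - 1, axis=1
            )[:, :kb]
            memb_a = np.zeros((chunk, n_union), dtype=bool)
            memb_b = np.zeros((chunk, n_union), dtype=bool)
            rows = np.arange(chunk)[:, None]
            memb_a[rows, codes_a[pick_a]] = True
            memb_b[rows, codes_b[pick_b]] = True
            ov = (memb_a & memb_b).sum(axis=1)
            n_at_least += int((ov >= observed).sum())
            done += chunk

    p = (n_at_least + 1) / (n_draws + 1)
    log.info(
        "bootstrap overlap: observed=%d, draws=%d, at-least=%d, p=%.4g (seed=%d)",
        observed,
        n_draws,
        n_at_least,
        p,
        seed,
    )
    return BootstrapOverlapResult(
        observed_overlap=observed,
        n_draws=n_draws,
        n_at_least=n_at_least,
        empirical_p=p,
        seed=seed,
    )
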