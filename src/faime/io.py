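"""Readers, writers, and probe collapsing for the formats the pipeline touches.

Expression matrices, phenotype tables, and survival tables are plain TSV
(optionally gzip-compressed).  Geneset collections come either from GMT
files (one named set per line) or from NCBI ``gene2go``-format annotation
tables.  Probe-level matrices are collapsed to gene level by retaining, per
gene, the probe with the largest coefficient of variation.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from faime.exceptions import (
    DuplicateIdError,
    EmptyCollectionError,
    FormatError,
    ParseError,
)

log = logging.getLogger(__name__)

VALID_GENE2GO_CATEGORIES = ("Component", "Function", "Process")

_GENE2GO_COLUMNS = [
    "tax_id",
    "GeneID",
    "GO_ID",
    "Evidence",
    "Qualifier",
    "GO_term",
    "PubMed",
    "Category",
]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Invariants: identifiers are unique, and every cell is a finite real
    number.  Both are checked at construction time.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DuplicateIdError(f"duplicate {kind} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            gi, si = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value for gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_ids[si]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class ProbeMatrix:
    """Probes x samples matrix with a many-to-one probe-to-gene mapping.

    Probes with no gene mapping are retained but flagged; they are only
    dropped (with a log message) at collapse time.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probe_to_gene: Mapping[str, str]
    unmapped_probes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("value matrix shape does not match probe/sample ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DuplicateIdError("duplicate probe ids")
        self.unmapped_probes = [
            p for p in self.probe_ids if p not in self.probe_to_gene
        ]
        if self.unmapped_probes:
            log.warning(
                "%d probe(s) have no gene mapping and will be dropped at collapse",
                len(self.unmapped_probes),
            )


@dataclass
class GeneSetCollection:
    """Named genesets ("mechanisms"), each a non-empty set of gene ids."""

    source_label: str
    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for mid, members in self.sets.items():
            fs = frozenset(str(g) for g in members)
            if not fs:
                raise FormatError(f"geneset {mid!r} is empty")
            clean[str(mid)] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, mechanism_id: str) -> bool:
        return mechanism_id in self.sets

    @property
    def mechanism_ids(self) -> list[str]:
        return list(self.sets)

    def gene_universe(self) -> frozenset[str]:
        """Union of all member genes across sets."""
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class SampleGroups:
    """Two-group phenotype labels (e.g. tumor / normal)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        distinct = sorted(set(self.labels.values()))
        if len(distinct) != 2:
            raise FormatError(
                f"expected exactly two group labels, got {distinct!r}"
            )

    @property
    def group_labels(self) -> tuple[str, str]:
        a, b = sorted(set(self.labels.values()))
        return a, b

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == label]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in self.labels if s not in expr.sample_ids]
        if missing:
            raise FormatError(
                f"labeled samples missing from expression matrix: {missing}"
            )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path, orientation: str = "genes-by-samples"
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Parameters
    ----------
    path
        TSV (optionally ``.gz``): first column identifiers, first row
        sample ids.  ``orientation="samples-by-genes"`` transposes after
        reading.
    """
    if orientation not in ("genes-by-samples", "samples-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    dupes = {c for c in col_ids if col_ids.count(c) > 1}
    if dupes:
        raise DuplicateIdError(f"duplicate column ids in {path}: {sorted(dupes)}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.columns = col_ids
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise DuplicateIdError(f"duplicate row ids in {path}: {dup_rows}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[bad[0], bad[1]]!r} at row "
            f"{df.index[bad[0]]!r}, column {df.columns[bad[1]]!r} in {path}"
        )
    if orientation == "samples-by-genes":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Probe collapse
# ---------------------------------------------------------------------------


def collapse_probes_by_cv(probes: ProbeMatrix) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For every gene with multiple probes, keep the probe whose values have
    the largest coefficient of variation (sample standard deviation, n-1
    denominator, divided by the mean); ties are broken by lexicographically
    smallest probe id.  A probe with zero mean has an undefined CV: it is
    ranked last and a warning is logged.  Probes without a gene mapping are
    dropped here.
    """
    if probes.unmapped_probes:
        log.info("dropping %d unmapped probe(s)", len(probes.unmapped_probes))
    means = probes.values.mean(axis=1)
    sds = probes.values.std(axis=1, ddof=1)
    cvs = np.full(len(probes.probe_ids), -math.inf)
    for i, (m, s) in enumerate(zip(means, sds)):
        if m == 0.0:
            log.warning(
                "probe %r has zero mean; CV undefined, ranked last",
                probes.probe_ids[i],
            )
        else:
            cvs[i] = s / m

    best: dict[str, tuple[float, str, int]] = {}  # gene -> (-cv, probe_id, row)
    for i, pid in enumerate(probes.probe_ids):
        gene = probes.probe_to_gene.get(pid)
        if gene is None:
            continue
        key = (-cvs[i], pid, i)
        if gene not in best or key < best[gene]:
            best[gene] = key
    if not best:
        raise EmptyCollectionError("no probes map to any gene")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(genes, list(probes.sample_ids), probes.values[rows, :])


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, source_label: str = "GMT") -> GeneSetCollection:
    """Read a GMT geneset file: name, description, then gene symbols per line.

    Duplicate symbols within a line are deduplicated; a line with fewer
    than three fields (i.e. an empty set) is a format error.
    """
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description, and at least one gene"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: geneset {name!r} is empty")
            if name in sets:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate geneset {name!r}")
            sets[name] = genes
            names[name] = desc
    if not sets:
        raise EmptyCollectionError(f"{path}: no genesets found")
    return GeneSetCollection(source_label, sets, names)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    with open(path, "wt") as fh:
        for mid, members in coll.sets.items():
            desc = coll.names.get(mid, "na") or "na"
            fh.write("\t".join([mid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# gene2go
# ---------------------------------------------------------------------------


def read_gene2go(
    path: str | Path,
    taxon: int | str,
    ontology_branch: str = "Process",
) -> GeneSetCollection:
    """Read NCBI gene2go annotations into a geneset collection.

    One set per GO id, restricted to the requested taxon and ontology
    branch (Category column).  Rows whose qualifier asserts non-membership
    ("NOT ...") are excluded.  No graph propagation is performed: a gene
    belongs only to terms it is directly annotated with.
    """
    if ontology_branch not in VALID_GENE2GO_CATEGORIES:
        raise ValueError(
            f"unknown category {ontology_branch!r}; "
            f"valid categories: {', '.join(VALID_GENE2GO_CATEGORIES)}"
        )
    taxon = str(taxon)
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"gene2go row with {len(fields)} field(s); expected 8"
                )
            row = dict(zip(_GENE2GO_COLUMNS, fields))
            if row["tax_id"] != taxon:
                continue
            if row["Category"] != ontology_branch:
                continue
            if row["Qualifier"].startswith("NOT"):
                continue
            sets.setdefault(row["GO_ID"], set()).add(row["GeneID"])
            names.setdefault(row["GO_ID"], row["GO_term"])
    if not sets:
        raise EmptyCollectionError(
            f"{path}: no annotations for taxon {taxon}, branch {ontology_branch}"
        )
    return GeneSetCollection(
        f"GO-{ontology_branch}",
        {k: frozenset(v) for k, v in sets.items()},
        names,
    )


# ---------------------------------------------------------------------------
# Collection filtering
# ---------------------------------------------------------------------------


def filter_collection(
    coll: GeneSetCollection,
    expr: ExpressionMatrix,
    min_size: int = 5,
    max_size: Optional[int] = None,
) -> GeneSetCollection:
    """Intersect every set with the measured genes and apply size limits.

    Sets whose measured membership falls below ``min_size`` (or above
    ``max_size`` if given) are dropped, as is any set equal to the full
    measured universe — its complement would be empty and the centroid
    difference undefined.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    measured = frozenset(expr.gene_ids)
    kept: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for mid, members in coll.sets.items():
        inter = members & measured
        if len(inter) < min_size:
            continue
        if max_size is not None and len(inter) > max_size:
            continue
        if len(inter) == len(measured):
            log.warning(
                "geneset %r covers the entire measured universe; dropped "
                "(empty complement)",
                mid,
            )
            continue
        kept[mid] = inter
        if mid in coll.names:
            names[mid] = coll.names[mid]
    if not kept:
        raise EmptyCollectionError(
            "no genesets survive filtering against the expression matrix"
        )
    return GeneSetCollection(coll.source_label, kept, names)


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------


def read_groups_tsv(path: str | Path) -> SampleGroups:
    """Read a two-column phenotype table: sample_id, group (header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs >= 2 columns")
    labels = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(labels) != len(df):
        raise DuplicateIdError(f"{path}: duplicate sample ids")
    return SampleGroups(labels)


def write_groups_tsv(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in groups.labels.items():
            fh.write(f"{sid}\t{grp}\n")
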