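"""Domain containers and readers/writers for the tab-separated formats used
throughout the pipeline: GMT gene-set collections, expression matrices
(genes x samples), and clinical/survival tables.

All formats are plain text.  Readers validate and clean on load; every
cleaning action is emitted as a logging warning so nothing is dropped
silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_REQUIRED = ("time", "event")
CLINICAL_OPTIONAL = (
    "age",
    "tumor_size",
    "grade",
    "er_status",
    "ln_status",
    "metastasis",
)
CLINICAL_COLUMNS = CLINICAL_REQUIRED + CLINICAL_OPTIONAL


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of relative expression values.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``.  Gene and sample identifiers are unique and every
    entry is finite.
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
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (the GMT view of a set collection)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_lists(
        cls, named_genes: Mapping[str, Sequence[str]], descriptions: Mapping[str, str] | None = None
    ) -> "GeneSetCollection":
        descriptions = descriptions or {}
        sets = {
            name: GeneSet(name, descriptions.get(name, ""), list(genes))
            for name, genes in named_genes.items()
        }
        return cls(sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name].genes

    def universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out.update(gs.genes)
        return out

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})

    def membership_matrix(self, gene_order: Sequence[str] | None = None) -> pd.DataFrame:
        """Binary genes x sets matrix (the equivalent matrix view)."""
        genes = list(gene_order) if gene_order is not None else sorted(self.universe())
        index = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((len(genes), len(self.sets)), dtype=np.int8)
        for j, gs in enumerate(self.sets.values()):
            for g in gs.genes:
                if g in index:
                    mat[index[g], j] = 1
        return pd.DataFrame(mat, index=genes, columns=self.names)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated (first occurrence kept)
    with a warning; a duplicate set name is an error.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "GMT line %d (%s): %d duplicate genes removed",
                    lineno,
                    name,
                    len(genes) - len(unique),
                )
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, unique)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, one line per set, genes in stored order."""
    path = Path(path)
    with path.open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression table (first row sample ids, first
    column gene ids).

    Rows with any non-numeric cell are rejected with a warning naming the
    gene; duplicate gene rows are collapsed by their mean with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no numeric columns")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        for gene in frame.index[bad]:
            logger.warning("expression row %r rejected: non-numeric cell", gene)
        numeric = numeric.loc[~bad]
    if numeric.shape[0] == 0:
        raise FormatError(f"{path}: no valid numeric rows")
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].unique()
        for gene in dupes:
            logger.warning("duplicate gene row %r collapsed by mean", gene)
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix.from_frame(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate data.

    Wraps a frame indexed by sample id with columns ``time`` (months),
    ``event`` (1 observed / 0 censored) and the optional covariates
    ``age``, ``tumor_size``, ``grade`` (1/2/3), ``er_status``, ``ln_status``
    and ``metastasis``.  Optional values may be NaN (missing).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        for col in CLINICAL_REQUIRED:
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        for col in CLINICAL_OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(CLINICAL_COLUMNS)].astype(float)
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        if df["time"].isna().any() or (df["time"] < 0).any():
            raise FormatError("time must be present and >= 0 for every sample")
        if not df["event"].isin([0.0, 1.0]).all():
            raise FormatError("event must be 0 or 1 for every sample")
        bad_grade = df["grade"].notna() & ~df["grade"].isin([1.0, 2.0, 3.0])
        if bad_grade.any():
            for sid in df.index[bad_grade]:
                logger.warning("sample %s: grade outside {1,2,3} set to missing", sid)
            df.loc[bad_grade, "grade"] = np.nan
        for col in ("er_status", "ln_status", "metastasis"):
            bad = df[col].notna() & ~df[col].isin([0.0, 1.0])
            if bad.any():
                raise FormatError(f"column {col!r} must be binary where present")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def __len__(self) -> int:
        return len(self.data)

    def align_with(self, expr: ExpressionMatrix) -> list[str]:
        """Sample ids common to this table and an expression matrix.

        The overlap is logged (never silently dropped) and returned in the
        expression matrix's sample order.
        """
        clin = set(self.data.index)
        common = [s for s in expr.sample_ids if s in clin]
        logger.info(
            "sample overlap: %d expression, %d clinical, %d shared",
            expr.n_samples,
            len(clin),
            len(common),
        )
        return common


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a tab-separated clinical table.

    Requires columns ``sample``, ``time``, ``event``; optional covariate
    columns are filled with NaN when absent.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if "sample" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'sample'")
    for col in CLINICAL_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    frame = frame.set_index("sample")
    return ClinicalTable(frame)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample", na_rep="")
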