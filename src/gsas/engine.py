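"""Per-sample gene set activity scoring.

For one sample, genes are ranked by relative expression (descending).  A
gene set's preliminary score is the signed maximum deviation between the
empirical cumulative distribution of the set's genes (foreground) and of
the remaining genes (background) along that ranking — a signed KS-style
D statistic in [-1, 1].  The preliminary score is then divided by the mean
absolute preliminary score of ``n_perm`` uniformly drawn gene sets of the
same size, yielding the gene set activity score (GSAS): positive when the
set's genes sit high in the ranking, negative when they sit low, and
calibrated so a random set scores about +/-1.

The permutation null depends only on the ranking and the set size, so the
normalization factor is computed once per (sample, size) pair; the RNG
stream is keyed by (seed, sample id, size) making cached and uncached
evaluation bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import derive_rng
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_MIN_SET_SIZE = 3


@dataclass
class SampleRanking:
    """Genes of one sample ordered by descending relative expression.

    ``ordered_genes[i]`` is the gene at rank ``i + 1``; ``position[g]`` is
    the 0-based rank of gene ``g``.  Ties are broken by ascending gene id,
    and the number of genes involved in ties is recorded.
    """

    sample_id: str
    ordered_genes: list[str]
    ordered_values: np.ndarray
    position: dict[str, int] = field(repr=False)
    n_tied_genes: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.ordered_genes)


@dataclass
class PreliminaryScore:
    """Signed max CDF deviation for one (set, sample) pair."""

    value: float
    argmax_position: int  # 1-based rank where the extreme deviation occurs
    d_plus: float
    d_minus: float
    set_size: int


def standardize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (zero-variance genes -> 0, warned)."""
    values = expr.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat_sd = sd.ravel()
    zero = flat_sd == 0
    if zero.any():
        logger.warning("%d zero-variance genes z-scored to 0", int(zero.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[zero.nonzero()[0], :] = 0.0
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, z)


def rank_genes(expr: ExpressionMatrix, sample: str, standardize: bool = True) -> SampleRanking:
    """Rank a sample's genes by descending relative expression.

    With ``standardize`` (default) each gene is first z-scored across the
    matrix's samples.  Ties are broken by ascending gene id so the ranking
    is deterministic and platform-independent.
    """
    if sample not in expr.sample_ids:
        raise KeyError(f"sample {sample!r} not in matrix")
    source = standardize_expression(expr) if standardize else expr
    j = source.sample_ids.index(sample)
    vals = source.values[:, j]
    genes = np.asarray(source.gene_ids)
    # lexsort: last key is primary (descending value), gene id breaks ties
    order = np.lexsort((genes, -vals))
    ordered_vals = vals[order]
    n_tied = int(np.count_nonzero(ordered_vals[:-1] == ordered_vals[1:]))
    ordered_genes = [str(g) for g in genes[order]]
    position = {g: i for i, g in enumerate(ordered_genes)}
    return SampleRanking(sample, ordered_genes, ordered_vals, position, n_tied)


# ---------------------------------------------------------------------------
# Signed max deviation between foreground and background rank CDFs
# ---------------------------------------------------------------------------


def _signed_max_deviation(positions: np.ndarray, n_genes: int) -> tuple[float, float, int, int]:
    """Extreme deviations of F - B for one set.

    ``positions``: sorted 0-based ranks of the set's genes (length m).
    Returns (d_plus, d_minus, argmax_plus, argmin_minus) where the arg
    values are 1-based rank positions.  F jumps only at member positions,
    so maxima of F - B occur at member positions and minima immediately
    before them; the endpoint value F(G) - B(G) = 0 never exceeds either.
    """
    m = positions.shape[0]
    g = n_genes
    k = np.arange(1, m + 1, dtype=float)
    # at rank i = positions[k-1] + 1 (just after the k-th member)
    d_at = k / m - (positions + 1 - k) / (g - m)
    # at rank positions[k-1] (just before the k-th member)
    d_before = (k - 1) / m - (positions - (k - 1)) / (g - m)
    i_plus = int(np.argmax(d_at))
    i_minus = int(np.argmin(d_before))
    return (
        float(d_at[i_plus]),
        float(d_before[i_minus]),
        int(positions[i_plus]) + 1,
        int(positions[i_minus]),
    )


def _abs_max_deviation_batch(positions: np.ndarray, n_genes: int) -> np.ndarray:
    """|signed max deviation| for a batch of sets (rows of sorted positions)."""
    n_perm, m = positions.shape
    g = n_genes
    k = np.arange(1, m + 1, dtype=float)
    d_at = k / m - (positions + 1 - k) / (g - m)
    d_before = (k - 1) / m - (positions - (k - 1)) / (g - m)
    return np.maximum(d_at.max(axis=1), -d_before.min(axis=1))


def _weighted_deviation(member_mask: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Expression-magnitude-weighted variant of the deviation statistic."""
    w = np.abs(weights)
    fg = np.where(member_mask, w, 0.0)
    bg = np.where(member_mask, 0.0, w)
    fg_tot = fg.sum()
    bg_tot = bg.sum()
    if fg_tot == 0 or bg_tot == 0:
        raise ValueError("weighted deviation undefined: zero total weight")
    d = np.cumsum(fg) / fg_tot - np.cumsum(bg) / bg_tot
    return float(d.max()), float(d.min())


def _pick_signed(d_plus: float, d_minus: float) -> float:
    # ties go to the positive deviation
    return d_plus if d_plus >= -d_minus else d_minus


def preliminary_score(
    ranking: SampleRanking, gene_set: list[str], weighted: bool = False
) -> PreliminaryScore:
    """Signed max deviation between set and complement rank CDFs.

    Genes absent from the ranking are dropped first; the intersected set
    must satisfy 1 <= m < G.
    """
    g = ranking.n_genes
    pos = np.sort([ranking.position[x] for x in set(gene_set) if x in ranking.position])
    m = pos.shape[0]
    if m == 0 or m == g:
        raise ValueError(f"set has {m} of {g} ranked genes; need 1 <= m < G")
    if weighted:
        mask = np.zeros(g, dtype=bool)
        mask[pos] = True
        d_plus, d_minus = _weighted_deviation(mask, ranking.ordered_values)
        arg = int(np.argmax(np.abs([d_plus, d_minus])))
        value = _pick_signed(d_plus, d_minus)
        return PreliminaryScore(value, arg + 1, d_plus, d_minus, m)
    d_plus, d_minus, arg_plus, arg_minus = _signed_max_deviation(pos.astype(float), g)
    if d_plus >= -d_minus:
        return PreliminaryScore(d_plus, arg_plus, d_plus, d_minus, m)
    return PreliminaryScore(d_minus, arg_minus, d_plus, d_minus, m)


def normalization_factor(
    ranking: SampleRanking,
    set_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weighted: bool = False,
) -> float:
    """Mean |preliminary score| over ``n_perm`` random size-matched sets.

    The RNG stream is derived from (seed, sample id, set_size) only, so all
    sets of one size in one sample share the factor and the result does not
    depend on evaluation order or caching.
    """
    g = ranking.n_genes
    if not 1 <= set_size < g:
        raise ValueError(f"set_size must satisfy 1 <= size < {g}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = derive_rng(seed, ranking.sample_id, set_size)
    # sample n_perm subsets of rank positions without replacement
    keys = rng.random((n_perm, g))
    positions = np.sort(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size], axis=1)
    if weighted:
        scores = np.empty(n_perm)
        for i in range(n_perm):
            mask = np.zeros(g, dtype=bool)
            mask[positions[i]] = True
            d_plus, d_minus = _weighted_deviation(mask, ranking.ordered_values)
            scores[i] = max(d_plus, -d_minus)
        return float(scores.mean())
    return float(_abs_max_deviation_batch(positions.astype(float), g).mean())


# ---------------------------------------------------------------------------
# Full collection scoring
# ---------------------------------------------------------------------------


@dataclass
class GsasMatrix:
    """Gene sets x samples activity scores plus scoring provenance."""

    data: pd.DataFrame  # index: set names, columns: sample ids
    n_perm: int
    seed: int
    skipped: dict[str, str] = field(default_factory=dict)
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    standardized: bool = True
    weighted: bool = False

    @property
    def set_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def scores(self, set_name: str) -> pd.Series:
        return self.data.loc[set_name]


def write_gsas(gsas: GsasMatrix, path) -> None:
    """Write a GSAS matrix as TSV (sets x samples) plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    gsas.data.to_csv(path, sep="\t", index_label="set")
    meta = {
        "n_perm": gsas.n_perm,
        "seed": gsas.seed,
        "skipped": gsas.skipped,
        "min_set_size": gsas.min_set_size,
        "standardized": gsas.standardized,
        "weighted": gsas.weighted,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_gsas(path) -> GsasMatrix:
    """Read a GSAS matrix written by :func:`write_gsas`."""
    import json
    from pathlib import Path

    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return GsasMatrix(
        data=data,
        n_perm=int(meta.get("n_perm", 0)),
        seed=int(meta.get("seed", 0)),
        skipped=meta.get("skipped", {}),
        min_set_size=int(meta.get("min_set_size", DEFAULT_MIN_SET_SIZE)),
        standardized=bool(meta.get("standardized", True)),
        weighted=bool(meta.get("weighted", False)),
    )


def score_collection(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    standardize: bool = True,
    weighted: bool = False,
    cache_factors: bool = True,
) -> GsasMatrix:
    """Score every (gene set, sample) pair of a collection.

    GSAS(set, sample) = preliminary score / normalization factor for the
    matching (sample, set size).  Sets whose intersection with the matrix
    falls below ``min_set_size`` (or covers all genes) are skipped and
    listed in the result's metadata.
    """
    source = standardize_expression(expr) if standardize else expr
    gene_index = {g: i for i, g in enumerate(source.gene_ids)}
    n_genes = source.n_genes

    members: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for gs in collection:
        idx = np.array(sorted({gene_index[g] for g in gs.genes if g in gene_index}), dtype=int)
        m = idx.shape[0]
        if m < min_set_size:
            skipped[gs.name] = f"only {m} genes in matrix (min {min_set_size})"
        elif m == n_genes:
            skipped[gs.name] = "set covers every ranked gene"
        else:
            members[gs.name] = idx
    for name, reason in skipped.items():
        logger.warning("set %s skipped: %s", name, reason)
    if not members:
        raise ValueError("no scorable gene sets after intersection/size filter")

    out = np.empty((len(members), source.n_samples))
    set_names = list(members)
    for j, sample in enumerate(source.sample_ids):
        ranking = rank_genes(source, sample, standardize=False)
        pos_of = np.empty(n_genes, dtype=int)
        for g, p in ranking.position.items():
            pos_of[gene_index[g]] = p
        factors: dict[int, float] = {}
        for i, name in enumerate(set_names):
            pos = np.sort(pos_of[members[name]]).astype(float)
            m = pos.shape[0]
            if weighted:
                mask = np.zeros(n_genes, dtype=bool)
                mask[pos.astype(int)] = True
                d_plus, d_minus = _weighted_deviation(mask, ranking.ordered_values)
            else:
                d_plus, d_minus, _, _ = _signed_max_deviation(pos, n_genes)
            prelim = _pick_signed(d_plus, d_minus)
            if cache_factors and m in factors:
                factor = factors[m]
            else:
                factor = normalization_factor(ranking, m, n_perm, seed, weighted)
                if cache_factors:
                    factors[m] = factor
            out[i, j] = prelim / factor
    logger.info(
        "scored %d sets x %d samples (n_perm=%d, seed=%d)",
        len(set_names),
        source.n_samples,
        n_perm,
        seed,
    )
    return GsasMatrix(
        data=pd.DataFrame(out, index=set_names, columns=source.sample_ids),
        n_perm=n_perm,
        seed=seed,
        skipped=skipped,
        min_set_size=min_set_size,
        standardized=standardize,
        weighted=weighted,
    )
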