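"""Cross-dataset consensus differential expression.

Per-dataset preprocessing (log2, quantile normalization), Welch-t ranking
with Benjamini-Hochberg adjustment, robust rank aggregation over the
directional ranked lists, and the final DEG-calling filter that requires both
a small aggregated score and per-dataset significance/fold-change support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Gene x sample matrix (log2 scale) with a binary group label per sample.

    ``group_order`` fixes the contrast: log2 fold changes are
    mean(second label) - mean(first label).
    """

    dataset_id: str
    expr: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> label
    group_order: tuple[str, str]

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dup = self.expr.index[self.expr.index.duplicated()][0]
            raise DataError(f"{self.dataset_id}: duplicate gene symbol {dup!r}")
        self.groups = self.groups.reindex(self.expr.columns)
        if self.groups.isna().any():
            missing = list(self.expr.columns[self.groups.isna()])
            raise DataError(f"{self.dataset_id}: samples without group label: {missing}")
        counts = self.groups.value_counts()
        for g in self.group_order:
            if counts.get(g, 0) < 2:
                raise DataError(
                    f"{self.dataset_id}: group {g!r} has fewer than 2 samples"
                )

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(reference matrix, alternative matrix) as gene x sample arrays."""
        ref, alt = self.group_order
        return (
            self.expr.loc[:, self.groups == ref].to_numpy(),
            self.expr.loc[:, self.groups == alt].to_numpy(),
        )


@dataclass
class RankedGeneList:
    dataset_id: str
    table: pd.DataFrame  # index gene; columns log2fc, p, p_adj, rank_up, rank_down

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass
class RRAResult:
    direction: str  # "up" or "down"
    table: pd.DataFrame  # index gene; rho, score_adj, n_lists, consistency_fraction, direction_consistent


@dataclass
class DEGCall:
    gene: str
    direction: str
    rra_score: float
    passed_filters: bool
    supporting_datasets: list[str]
    direction_consistent: bool


@dataclass
class DEGCallSet:
    calls: list[DEGCall]
    consistency_fraction: float
    score_cut: float
    p_cut: float
    lfc_cut: float

    def passed(self) -> list[DEGCall]:
        return [c for c in self.calls if c.passed_filters]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force all columns onto the mean-of-order-statistics distribution.

    Tied values within a column receive the average of the target values at
    the positions the tie block occupies.
    """
    arr = df.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = target
        # average targets over tie blocks
        s = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated symbol, the row with the largest mean expression."""
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1).to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    best: dict = {}
    for i, g in enumerate(df.index):
        if g not in best or means[i] > means[best[g]]:
            best[g] = i
    keep[list(best.values())] = True
    return df.loc[keep]


def preprocess(
    raw: pd.DataFrame,
    groups: pd.Series,
    dataset_id: str = "dataset",
    group_order: tuple[str, str] | None = None,
    already_log: bool = True,
) -> ExpressionDataset:
    """log2(x+1) transform (unless already log scale), quantile-normalize,
    and collapse duplicate gene symbols by maximum mean expression."""
    df = raw.copy()
    df.index = df.index.astype(str).str.upper()
    if not already_log:
        if (df.to_numpy() < 0).any():
            raise DataError(
                f"{dataset_id}: negative entries but already_log=False"
            )
        df = np.log2(df + 1.0)
    df = collapse_duplicate_genes(df)
    df = quantile_normalize(df)
    groups = groups.astype(str)
    if group_order is None:
        labels = list(pd.unique(groups.reindex(df.columns).dropna()))
        if len(labels) != 2:
            raise DataError(f"{dataset_id}: expected exactly 2 group labels, got {labels}")
        group_order = (labels[0], labels[1])
    return ExpressionDataset(dataset_id, df, groups, tuple(group_order))


def _directional_ranks(p: np.ndarray, lfc: np.ndarray, genes: pd.Index, up: bool) -> np.ndarray:
    """Rank genes 1..n by evidence for the requested direction.

    Score is p for correctly-signed genes, 2 - p for oppositely-signed genes,
    and 1 for zero fold change, so the strongest same-direction genes rank
    first and the strongest opposite-direction genes rank last. Ties break by
    descending |log2fc| then gene symbol.
    """
    sign = lfc if up else -lfc
    score = np.where(sign > 0, p, np.where(sign < 0, 2.0 - p, 1.0))
    order = np.lexsort((genes.to_numpy(), -np.abs(lfc), score))
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(1, len(genes) + 1)
    return ranks


def rank_genes(ds: ExpressionDataset) -> RankedGeneList:
    """Per-gene Welch t statistics and directional ranks for one dataset.

    log2fc is mean(alternative group) - mean(reference group). Genes with
    zero variance in both groups get p = 1 (never NaN).
    """
    ref, alt = ds.split()
    lfc = alt.mean(axis=1) - ref.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(alt, ref, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info(
            "%s: %d gene(s) with zero variance in both groups; p set to 1",
            ds.dataset_id, int(degenerate.sum()),
        )
        p[degenerate] = 1.0
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    genes = ds.expr.index
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "rank_up": _directional_ranks(p, lfc, genes, up=True),
            "rank_down": _directional_ranks(p, lfc, genes, up=False),
        },
        index=genes,
    )
    return RankedGeneList(ds.dataset_id, table)


def rra_scores(normalized_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust rank aggregation rho for rows of normalized ranks in (0, 1].

    For each row the ranks are sorted ascending and, for every k, the beta
    order-statistic tail probability P(k-th smallest of m uniforms <= r_(k))
    is evaluated; rho is the minimum over k and the adjusted score applies a
    Bonferroni factor m, capped at 1.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float), axis=1)
    m = r.shape[1]
    ks = np.arange(1, m + 1)
    tails = stats.beta.cdf(r, ks[np.newaxis, :], (m - ks + 1)[np.newaxis, :])
    rho = tails.min(axis=1)
    return rho, np.minimum(1.0, rho * m)


def rra_aggregate(lists: Sequence[RankedGeneList], direction: str = "up") -> RRAResult:
    """Aggregate directional ranked lists into per-gene rho scores.

    The gene universe is the union across lists; a gene absent from a list
    receives normalized rank 1 (worst) in that list. Direction consistency is
    the fraction of lists containing the gene whose fold-change sign matches
    the aggregation direction.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"unknown direction {direction!r}")
    if len(lists) < 2:
        raise ParameterError("rra_aggregate needs at least 2 ranked lists")
    rank_col = f"rank_{direction}"
    universe = sorted(set().union(*(set(rl.table.index) for rl in lists)))
    m = len(lists)
    R = np.ones((len(universe), m))
    match = np.zeros((len(universe), m))
    present = np.zeros((len(universe), m), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(universe)}
    want_sign = 1.0 if direction == "up" else -1.0
    for j, rl in enumerate(lists):
        n = rl.n_genes
        idx = np.array([gene_pos[g] for g in rl.table.index])
        R[idx, j] = rl.table[rank_col].to_numpy() / n
        present[idx, j] = True
        match[idx, j] = np.sign(rl.table["log2fc"].to_numpy()) == want_sign
    rho, score_adj = rra_scores(R)
    n_present = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        consistency = np.where(n_present > 0, match.sum(axis=1) / np.maximum(n_present, 1), 0.0)
    table = pd.DataFrame(
        {
            "rho": rho,
            "score_adj": score_adj,
            "n_lists": n_present,
            "consistency_fraction": consistency,
            "direction_consistent": consistency == 1.0,
        },
        index=pd.Index(universe, name="gene"),
    )
    return RRAResult(direction, table)


def call_degs(
    lists: Sequence[RankedGeneList],
    rra_up: RRAResult,
    rra_down: RRAResult,
    score_cut: float = 0.05,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
    use_raw_rho: bool = False,
) -> DEGCallSet:
    """Call consensus DEGs.

    A gene is called up when its up-direction aggregated score passes
    ``score_cut`` AND at least one dataset shows adjusted p < ``p_cut`` with
    log2fc >= ``lfc_cut`` (symmetric for down). ``use_raw_rho`` thresholds
    the uncorrected rho instead of the Bonferroni-adjusted score.
    """
    if not (0 < score_cut <= 1) or not (0 < p_cut <= 1):
        raise ParameterError("score_cut and p_cut must be in (0, 1]")
    if lfc_cut < 0:
        raise ParameterError("lfc_cut must be >= 0")
    score_col = "rho" if use_raw_rho else "score_adj"
    calls: list[DEGCall] = []
    seen: dict[str, DEGCall] = {}
    for rra in (rra_up, rra_down):
        up = rra.direction == "up"
        for gene, row in rra.table.iterrows():
            score = float(row[score_col])
            if score >= score_cut:
                continue
            support = []
            for rl in lists:
                if gene not in rl.table.index:
                    continue
                g = rl.table.loc[gene]
                signed_ok = g["log2fc"] >= lfc_cut if up else g["log2fc"] <= -lfc_cut
                if g["p_adj"] < p_cut and signed_ok:
                    support.append(rl.dataset_id)
            call = DEGCall(
                gene=str(gene),
                direction=rra.direction,
                rra_score=score,
                passed_filters=bool(support),
                supporting_datasets=support,
                direction_consistent=bool(row["direction_consistent"]),
            )
            prev = seen.get(gene)
            if prev is None or call.rra_score < prev.rra_score:
                seen[gene] = call
    calls = sorted(seen.values(), key=lambda c: (c.rra_score, c.gene))
    passed = [c for c in calls if c.passed_filters]
    consistency = (
        float(np.mean([c.direction_consistent for c in passed])) if passed else float("nan")
    )
    return DEGCallSet(calls, consistency, score_cut, p_cut, lfc_cut)


def gene_set_intersect(
    degs: Sequence[DEGCall],
    gene_sets: Mapping[str, Sequence[str]],
) -> dict[str, list[tuple[str, str]]]:
    """Intersect called DEGs with named gene sets (case-normalized).

    Returns, per set name, the intersecting (gene, direction) pairs sorted
    by gene symbol.
    """
    by_gene = {c.gene.upper(): c.direction for c in degs if c.passed_filters}
    out: dict[str, list[tuple[str, str]]] = {}
    for name, genes in gene_sets.items():
        genes = [str(g).upper() for g in genes]
        if not genes:
            logger.warning("gene set %r is empty", name)
        out[name] = sorted((g, by_gene[g]) for g in set(genes) if g in by_gene)
    return out
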