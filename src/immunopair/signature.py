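"""Gene-signature (inflamed T-cell profile) scoring of expression samples."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .metadeg import ExpressionDataset
from .repstats import group_compare

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"signature {self.name!r} has duplicate genes")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise DataError(
                f"signature {self.name!r}: {len(self.weights)} weights for "
                f"{len(self.genes)} genes"
            )


@dataclass
class SignatureScoreTable:
    signature: str
    scores: pd.Series  # sample -> score
    groups: pd.Series  # sample -> label
    coverage: float
    used_genes: list[str]
    dropped_zero_variance: list[str]


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Two-column TSV (gene, optional weight); '#' starts a comment line."""
    path = Path(path)
    genes: list[str] = []
    weights: list[float] = []
    any_weight = False
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        genes.append(parts[0])
        if len(parts) > 1:
            any_weight = True
            weights.append(float(parts[1]))
        else:
            weights.append(1.0)
    if not genes:
        raise DataError(f"{path}: signature file contains no genes")
    return GeneSignature(
        name=name or path.stem, genes=genes, weights=weights if any_weight else None
    )


def gep_score(
    ds: ExpressionDataset,
    sig: GeneSignature,
    min_coverage: float = 0.5,
) -> SignatureScoreTable:
    """Per-sample signature score: (weighted) mean of per-gene z-scores.

    Each available signature gene's expression row is z-scored across samples;
    zero-variance genes are dropped with a warning. Coverage is the fraction
    of signature genes found in the dataset and must reach ``min_coverage``.
    """
    if not (0 < min_coverage <= 1):
        raise ParameterError(f"min_coverage must be in (0,1]: {min_coverage}")
    index_upper = ds.expr.index.astype(str).str.upper()
    pos = {g: i for i, g in enumerate(index_upper)}
    present = [g for g in sig.genes if g in pos]
    missing = [g for g in sig.genes if g not in pos]
    coverage = len(present) / len(sig.genes)
    if coverage < min_coverage:
        raise DataError(
            f"signature coverage {coverage:.2f} < {min_coverage}; "
            f"missing genes: {', '.join(missing)}"
        )
    sub = ds.expr.iloc[[pos[g] for g in present]].to_numpy(dtype=float)
    w = (
        np.array([sig.weights[sig.genes.index(g)] for g in present])
        if sig.weights is not None
        else np.ones(len(present))
    )
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(present, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d zero-variance signature gene(s): %s",
            len(dropped), ", ".join(dropped),
        )
    if not keep.any():
        raise DataError("every available signature gene has zero variance")
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    wk = w[keep]
    scores = (wk[:, None] * z).sum(axis=0) / wk.sum()
    return SignatureScoreTable(
        signature=sig.name,
        scores=pd.Series(scores, index=ds.expr.columns, name="score"),
        groups=ds.groups.copy(),
        coverage=coverage,
        used_genes=[g for g, k in zip(present, keep) if k],
        dropped_zero_variance=dropped,
    )


def score_gene_correlation(
    scores: SignatureScoreTable,
    ds: ExpressionDataset,
    genes: Sequence[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate named genes' expression with the signature score.

    Returns a gene-indexed frame with r, p, a ``defined`` flag (False for
    constant genes, whose correlation is undefined rather than NaN-silent)
    and ``in_signature`` marking partially circular comparisons.
    """
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown method {method!r}")
    if len(ds.expr.columns) < 3:
        raise DataError("need at least 3 samples for a correlation")
    index_upper = ds.expr.index.astype(str).str.upper()
    pos = {g: i for i, g in enumerate(index_upper)}
    absent = [g for g in genes if str(g).upper() not in pos]
    if absent:
        raise DataError(f"gene(s) not in dataset: {', '.join(map(str, absent))}")
    in_sig = set(scores.used_genes)
    rows = []
    s = scores.scores.reindex(ds.expr.columns).to_numpy()
    for g in genes:
        gu = str(g).upper()
        x = ds.expr.iloc[pos[gu]].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("gene %s is constant; correlation undefined", gu)
            rows.append((gu, np.nan, np.nan, False, gu in in_sig))
            continue
        fn = stats.pearsonr if method == "pearson" else stats.spearmanr
        res = fn(x, s)
        rows.append((gu, float(res.statistic), float(res.pvalue), True, gu in in_sig))
    return pd.DataFrame(
        rows, columns=["gene", "r", "p", "defined", "in_signature"]
    ).set_index("gene")


def score_group_compare(
    scores: SignatureScoreTable, test: str = "mannwhitney"
) -> dict:
    """Compare signature scores between the two sample groups.

    Returns statistic, two-sided p, and which group is higher by median.
    """
    labels = list(pd.unique(scores.groups))
    if len(labels) != 2:
        raise DataError(f"need exactly 2 groups, got {labels}")
    by_group = {
        lab: scores.scores[scores.groups == lab].to_list() for lab in labels
    }
    stat, p = group_compare(by_group, test=test)
    medians = {lab: float(np.median(v)) for lab, v in by_group.items()}
    higher = max(medians, key=medians.get)
    return {
        "test": test,
        "statistic": stat,
        "p": p,
        "medians": medians,
        "higher_group": higher,
    }
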