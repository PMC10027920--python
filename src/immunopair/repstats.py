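"""Repertoire comparison statistics.

Covers clonal expansion (frequency-bin mass, top-N proportion), cross-sample
clonotype sharing with frequency correlation, V-J segment usage matrices and
their filtered pairwise correlations, and generic two-group tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .repertoire import Repertoire, strip_allele

logger = logging.getLogger(__name__)


@dataclass
class ExpansionSummary:
    sample_id: str
    n_clones: int
    n_clonotypes: int
    bin_fractions: dict[float, float]  # threshold -> fraction strictly above it
    top_n_proportion: float
    top_n: int
    bin_mode: str = "mass"


@dataclass
class SharingSummary:
    sample_pair: tuple[str, str]
    n_shared: int
    fraction_a: float
    fraction_b: float
    jaccard: float
    rho: float | None  # None when undefined (fewer than 3 shared clonotypes)
    p: float | None
    n_shared_used: int
    rho_defined: bool
    corr_method: str = "spearman"
    corr_mode: str = "shared"


@dataclass
class VJUsage:
    sample_id: str
    usage: pd.DataFrame  # V genes x J genes, read-frequency mass
    vector: pd.Series  # flattened (V, J) MultiIndex combination vector


@dataclass
class VJCorrelation:
    retained: list[tuple[str, str]]
    rho: pd.DataFrame  # sample x sample Spearman rho
    p: pd.DataFrame
    reference_ids: list[str]
    min_avg_usage: float


def expansion_summary(
    rep: Repertoire,
    thresholds: Sequence[float] = (0.001, 0.005, 0.01),
    top_n: int = 10,
    bin_mode: str = "mass",
) -> ExpansionSummary:
    """Clonal-expansion summary of one repertoire.

    ``bin_fractions[t]`` is the share of the repertoire held by clonotypes
    whose frequency is strictly greater than ``t``: cumulative read-frequency
    mass when ``bin_mode="mass"`` (default), the fraction of distinct
    clonotypes when ``bin_mode="count"``. ``top_n_proportion`` is the summed
    frequency of the ``top_n`` most frequent clonotypes; ties are broken by
    descending count then lexicographic CDR3 for determinism.
    """
    thr = list(thresholds)
    if any(t <= 0 or t >= 1 for t in thr):
        raise ParameterError(f"thresholds must lie in (0,1): {thr}")
    if any(b >= a for a, b in zip(thr[1:], thr)):
        raise ParameterError(f"thresholds must be strictly increasing: {thr}")
    if top_n < 1:
        raise ParameterError(f"top_n must be >= 1, got {top_n}")
    if bin_mode not in ("mass", "count"):
        raise ParameterError(f"unknown bin_mode {bin_mode!r}")

    freqs = rep.clonotype_frequencies()
    n_clonotypes = len(freqs)
    n_clones = len(rep.aggregate("clone"))
    fvals = np.array(list(freqs.values()))
    bins = {}
    for t in thr:
        above = fvals > t
        bins[t] = float(fvals[above].sum()) if bin_mode == "mass" else float(
            above.sum() / n_clonotypes
        )
    order = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    top = float(sum(f for _, f in order[:top_n]))
    return ExpansionSummary(
        sample_id=rep.sample_id,
        n_clones=n_clones,
        n_clonotypes=n_clonotypes,
        bin_fractions=bins,
        top_n_proportion=min(top, 1.0),
        top_n=top_n,
        bin_mode=bin_mode,
    )


def sharing_summary(
    rep_a: Repertoire,
    rep_b: Repertoire,
    corr_method: str = "spearman",
    corr_mode: str = "shared",
) -> SharingSummary:
    """Clonotype sharing between two repertoires.

    The shared set is the intersection of CDR3 amino-acid key sets. The
    frequency correlation pairs the two frequency vectors over the shared
    clonotypes only (``corr_mode="shared"``, default) or over the union with
    zeros for absent clonotypes (``corr_mode="union-zeros"``). With fewer
    than 3 paired points the correlation is reported as undefined, not zero.
    """
    if corr_method not in ("spearman", "pearson"):
        raise ParameterError(f"unknown corr_method {corr_method!r}")
    if corr_mode not in ("shared", "union-zeros"):
        raise ParameterError(f"unknown corr_mode {corr_mode!r}")
    fa = rep_a.clonotype_frequencies()
    fb = rep_b.clonotype_frequencies()
    if not fa or not fb:
        raise DataError("sharing_summary requires two non-empty repertoires")
    shared = sorted(set(fa) & set(fb))
    union = len(set(fa) | set(fb))
    keys = shared if corr_mode == "shared" else sorted(set(fa) | set(fb))
    x = np.array([fa.get(k, 0.0) for k in keys])
    y = np.array([fb.get(k, 0.0) for k in keys])
    rho = p = None
    defined = False
    if len(keys) >= 3:
        if corr_method == "spearman":
            res = stats.spearmanr(x, y)
        else:
            res = stats.pearsonr(x, y)
        if np.isfinite(res.statistic):
            rho, p, defined = float(res.statistic), float(res.pvalue), True
    if not defined:
        logger.warning(
            "correlation undefined for pair (%s, %s): n=%d paired points",
            rep_a.sample_id, rep_b.sample_id, len(keys),
        )
    return SharingSummary(
        sample_pair=(rep_a.sample_id, rep_b.sample_id),
        n_shared=len(shared),
        fraction_a=len(shared) / len(fa),
        fraction_b=len(shared) / len(fb),
        jaccard=len(shared) / union,
        rho=rho,
        p=p,
        n_shared_used=len(keys),
        rho_defined=defined,
        corr_method=corr_method,
        corr_mode=corr_mode,
    )


def vj_usage(rep: Repertoire, weight: str = "frequency") -> VJUsage:
    """Read-frequency mass over (V gene, J gene) combinations.

    Gene calls are allele-stripped so usage is at gene level. With
    ``weight="clonotype"`` each distinct clone contributes equally instead of
    by read frequency.
    """
    if weight not in ("frequency", "clonotype"):
        raise ParameterError(f"unknown weight mode {weight!r}")
    if not rep.records:
        raise DataError("vj_usage requires a non-empty repertoire")
    mass: dict[tuple[str, str], float] = {}
    if weight == "frequency":
        for r in rep.records:
            key = (strip_allele(r.v_call), strip_allele(r.j_call))
            mass[key] = mass.get(key, 0.0) + r.frequency
    else:
        clones = rep.aggregate("clone")
        w = 1.0 / len(clones)
        for (_, v, _, j) in clones:
            key = (strip_allele(v), strip_allele(j))
            mass[key] = mass.get(key, 0.0) + w
    v_genes = sorted({v for v, _ in mass})
    j_genes = sorted({j for _, j in mass})
    mat = pd.DataFrame(0.0, index=v_genes, columns=j_genes)
    for (v, j), m in mass.items():
        mat.loc[v, j] = m
    vec = pd.Series(
        mass, index=pd.MultiIndex.from_tuples(sorted(mass), names=["v_gene", "j_gene"])
    ).sort_index()
    return VJUsage(sample_id=rep.sample_id, usage=mat, vector=vec)


def vj_usage_correlation(
    usage_list: Sequence[VJUsage],
    reference_ids: Sequence[str] | str,
    min_avg_usage: float = 0.01,
) -> VJCorrelation:
    """Pairwise Spearman correlation of filtered V-J combination vectors.

    A combination is retained when its MEAN usage over the reference samples
    (e.g. all heart samples) exceeds ``min_avg_usage``. Correlations are
    computed on the retained combinations, absent combinations counting as 0.
    """
    if len(usage_list) < 2:
        raise ParameterError("need at least 2 usage matrices")
    if not (0 <= min_avg_usage < 1):
        raise ParameterError(f"min_avg_usage must be in [0,1): {min_avg_usage}")
    if isinstance(reference_ids, str):
        reference_ids = [reference_ids]
    by_id = {u.sample_id: u for u in usage_list}
    unknown = [r for r in reference_ids if r not in by_id]
    if unknown:
        raise ParameterError(f"reference sample(s) not in usage list: {unknown}")

    all_combos = sorted({c for u in usage_list for c in u.vector.index})
    table = pd.DataFrame(
        {u.sample_id: u.vector.reindex(all_combos).fillna(0.0) for u in usage_list}
    )
    ref_mean = table[list(reference_ids)].mean(axis=1)
    # threshold 0 is a documented no-op: every observed combination is kept,
    # including ones absent from the reference samples
    retained = (
        list(all_combos)
        if min_avg_usage == 0
        else [c for c in all_combos if ref_mean[c] > min_avg_usage]
    )
    if not retained:
        raise DataError(
            f"no V-J combination exceeds min_avg_usage={min_avg_usage} "
            f"in the reference samples {list(reference_ids)}"
        )
    sub = table.loc[retained]
    ids = list(table.columns)
    rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    pmat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = float(res.statistic)
            pmat.loc[a, b] = pmat.loc[b, a] = float(res.pvalue)
    return VJCorrelation(
        retained=[tuple(c) for c in retained],
        rho=rho,
        p=pmat,
        reference_ids=list(reference_ids),
        min_avg_usage=min_avg_usage,
    )


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    test: str = "mannwhitney",
) -> tuple[float, float]:
    """Two-sided two-group comparison.

    ``mannwhitney`` uses the exact null when the combined sample size is at
    most 20 and there are no ties, and the tie-corrected normal approximation
    otherwise. ``wilcoxon_paired`` pairs observations positionally; a fully
    degenerate case (all differences zero) is flagged and returns p = 1.
    """
    if test not in ("mannwhitney", "ttest", "wilcoxon_paired"):
        raise ParameterError(f"unknown test {test!r}")
    groups = list(values_by_group.items())
    if len(groups) != 2:
        raise ParameterError(f"need exactly 2 groups, got {len(groups)}")
    (_, a), (_, b) = groups
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 observations")
    if test == "ttest":
        res = stats.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(stat):  # identical constant groups
            stat, p = 0.0, 1.0
        return stat, p
    if test == "wilcoxon_paired":
        if len(a) != len(b):
            raise DataError("paired test requires equal-length groups")
        d = a - b
        if np.all(d == 0):
            logger.warning("wilcoxon_paired: all differences zero (degenerate)")
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    # Mann-Whitney
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
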