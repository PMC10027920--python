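"""Synthetic paired-tissue repertoires and multi-platform expression data.

Both generators are deterministic given their seed, carry their ground truth
alongside the data, and emit plain-text artifacts (AIRR TSV / CSV + JSON) so
every downstream statistic can be validated without external downloads.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .metadeg import ExpressionDataset
from .repertoire import ClonotypeRecord, Repertoire, RepertoireSet, write_airr

logger = logging.getLogger(__name__)

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: clone-size weights are drawn from a discrete power law truncated here
_MAX_CLONE_WEIGHT = 10_000


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def _as_pair_sharing(
    sharing, tissues: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Normalize a sharing spec (pair dict or square matrix) to pair -> fraction."""
    pairs = list(itertools.combinations(tissues, 2))
    if sharing is None:
        return {p: 0.0 for p in pairs}
    if isinstance(sharing, Mapping):
        out = {}
        for p in pairs:
            s = sharing.get(p, sharing.get((p[1], p[0]), sharing.get(_pair_key(*p), 0.0)))
            out[p] = float(s)
    else:
        mat = np.asarray(sharing, dtype=float)
        if mat.shape != (len(tissues), len(tissues)):
            raise ParameterError(
                f"sharing matrix shape {mat.shape} != ({len(tissues)}, {len(tissues)})"
            )
        if not np.allclose(mat, mat.T):
            raise ParameterError("sharing matrix must be symmetric")
        if not np.allclose(np.diag(mat), 1.0):
            raise ParameterError("sharing matrix diagonal must be 1")
        out = {
            (tissues[i], tissues[j]): float(mat[i, j])
            for i, j in itertools.combinations(range(len(tissues)), 2)
        }
    for p, s in out.items():
        if not (0.0 <= s <= 1.0):
            raise ParameterError(f"sharing fraction for {p} out of [0,1]: {s}")
    return out


def _per_tissue(value, tissues: Sequence[str], name: str) -> dict:
    if isinstance(value, Mapping):
        missing = [t for t in tissues if t not in value]
        if missing:
            raise ParameterError(f"{name} missing tissue(s): {missing}")
        return {t: value[t] for t in tissues}
    return {t: value for t in tissues}


@dataclass
class RepertoireSimParams:
    """Parameters of the paired-repertoire simulator.

    ``powerlaw_alpha`` is the exponent of the discrete power law the
    clone-size weights are drawn from: values near 1 give heavy tails
    (strong clonal expansion), large values an almost uniform repertoire.
    ``n_clonotypes`` and ``powerlaw_alpha`` may be scalars or per-tissue
    mappings. ``sharing`` is either a pair -> fraction mapping or a full
    symmetric matrix with unit diagonal aligned with ``tissues``.
    """

    n_patients: int
    tissues: Sequence[str]
    depth: int
    n_clonotypes: int | Mapping[str, int]
    powerlaw_alpha: float | Mapping[str, float]
    sharing: Mapping | Sequence | None = None
    vj_profile: Mapping[str, Mapping[tuple[str, str], float]] | None = None
    n_v_genes: int = 12
    n_j_genes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        self.tissues = list(self.tissues)
        if len(set(self.tissues)) != len(self.tissues) or not self.tissues:
            raise ParameterError("tissues must be a non-empty list of unique labels")
        self.n_clonotypes = _per_tissue(self.n_clonotypes, self.tissues, "n_clonotypes")
        for t, n in self.n_clonotypes.items():
            if n < 1:
                raise ParameterError(f"n_clonotypes[{t}] must be >= 1")
        self.powerlaw_alpha = _per_tissue(self.powerlaw_alpha, self.tissues, "powerlaw_alpha")
        for t, a in self.powerlaw_alpha.items():
            if a <= 1:
                raise ParameterError(f"powerlaw_alpha[{t}] must be > 1")
        self.sharing = _as_pair_sharing(self.sharing, self.tissues)
        # joint feasibility: pairwise shared pools must fit in each universe
        for t in self.tissues:
            need = sum(
                round(s * min(self.n_clonotypes[a], self.n_clonotypes[b]))
                for (a, b), s in self.sharing.items()
                if t in (a, b)
            )
            if need > self.n_clonotypes[t]:
                raise ParameterError(
                    f"sharing targets infeasible for tissue {t}: "
                    f"{need} shared clonotypes requested but universe has "
                    f"{self.n_clonotypes[t]}"
                )


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 21))
        s = "C" + "".join(rng.choice(_AA20, size=length - 2)) + "F"
        if s not in existing:
            existing.add(s)
            return s


def _default_vj_profile(
    rng: np.random.Generator, tissues: Sequence[str], n_v: int, n_j: int
) -> dict[str, dict[tuple[str, str], float]]:
    combos = [
        (f"TRBV{i + 1}", f"TRBJ{j + 1}") for i in range(n_v) for j in range(n_j)
    ]
    out = {}
    for t in tissues:
        probs = rng.dirichlet(np.full(len(combos), 0.5))
        out[t] = dict(zip(combos, probs))
    return out


def _power_law_quantile(u: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile function of the truncated discrete power law P(k) ~ k^-alpha.

    Mapping a per-clonotype uniform propensity through each tissue's quantile
    makes shared clonotypes comonotonic across tissues: a clone expanded in
    one tissue is expanded in the other, which is what gives paired tissues
    with planted sharing a positive shared-frequency correlation.
    """
    k = np.arange(1, _MAX_CLONE_WEIGHT + 1, dtype=float)
    p = k ** (-alpha)
    cdf = np.cumsum(p / p.sum())
    return np.searchsorted(cdf, u, side="right") + 1.0


def simulate_repertoires(params: RepertoireSimParams) -> tuple[RepertoireSet, dict]:
    """Draw paired-tissue repertoires with planted sharing and expansion.

    Per patient: a clonotype universe is built per tissue; for every tissue
    pair a shared pool of ``round(target * min(universe sizes))`` clonotypes
    is planted in both universes; clone-size weights come from a discrete
    power law; ``depth`` reads are drawn multinomially. The truth record
    stores per-patient shared sets, universes and weights, plus the realized
    universe-level sharing fractions.
    """
    rng = np.random.default_rng(params.seed)
    if params.vj_profile is not None:
        profiles = {
            t: dict(params.vj_profile[t]) for t in params.tissues
        }
        for t, prof in profiles.items():
            tot = sum(prof.values())
            if abs(tot - 1.0) > 1e-9:
                raise ParameterError(f"vj_profile[{t}] sums to {tot}, expected 1")
    else:
        profiles = _default_vj_profile(rng, params.tissues, params.n_v_genes, params.n_j_genes)

    rset = RepertoireSet()
    truth_patients: dict = {}
    realized_acc: dict[str, list[float]] = {}
    for pi in range(params.n_patients):
        pid = f"P{pi + 1:02d}"
        pool: set[str] = set()
        shared_sets: dict[tuple[str, str], list] = {}
        for (a, b), s in params.sharing.items():
            n_shared = round(s * min(params.n_clonotypes[a], params.n_clonotypes[b]))
            combos = list(profiles[a])
            probs = np.array([profiles[a][c] for c in combos])
            idx = rng.choice(len(combos), size=n_shared, p=probs)
            shared_sets[(a, b)] = [
                (_random_cdr3(rng, pool), *combos[i], rng.random()) for i in idx
            ]
        universes: dict[str, list] = {}
        for t in params.tissues:
            members = [
                c for pair, cs in shared_sets.items() if t in pair for c in cs
            ]
            combos = list(profiles[t])
            probs = np.array([profiles[t][c] for c in combos])
            n_private = params.n_clonotypes[t] - len(members)
            idx = rng.choice(len(combos), size=n_private, p=probs)
            members = members + [
                (_random_cdr3(rng, pool), *combos[i], rng.random()) for i in idx
            ]
            universes[t] = members

        truth_universe = {}
        for t in params.tissues:
            members = universes[t]
            propensities = np.array([m[3] for m in members])
            weights = _power_law_quantile(propensities, params.powerlaw_alpha[t])
            p = weights / weights.sum()
            counts = rng.multinomial(params.depth, p)
            records = [
                ClonotypeRecord(cdr3, v, "", j, int(c))
                for (cdr3, v, j, _), c in zip(members, counts)
                if c > 0
            ]
            sample_id = f"{pid}_{t}"
            rset.add(Repertoire(sample_id, records, patient_id=pid, tissue=t))
            truth_universe[t] = {
                "cdr3": [m[0] for m in members],
                "v_call": [m[1] for m in members],
                "j_call": [m[2] for m in members],
                "weights": weights.tolist(),
            }
        truth_patients[pid] = {
            "shared": {
                _pair_key(a, b): [c[0] for c in cs] for (a, b), cs in shared_sets.items()
            },
            "universe": truth_universe,
        }
        for (a, b), cs in shared_sets.items():
            ua = set(truth_universe[a]["cdr3"])
            ub = set(truth_universe[b]["cdr3"])
            realized = len(ua & ub) / min(len(ua), len(ub))
            realized_acc.setdefault(_pair_key(a, b), []).append(realized)

    truth = {
        "kind": "repertoire_simulation",
        "seed": params.seed,
        "tissues": list(params.tissues),
        "sharing_targets": {_pair_key(a, b): s for (a, b), s in params.sharing.items()},
        "realized_sharing": {k: float(np.mean(v)) for k, v in realized_acc.items()},
        "powerlaw_alpha": dict(params.powerlaw_alpha),
        "patients": truth_patients,
    }
    return rset, truth


@dataclass
class ExpressionSimParams:
    """Parameters of the multi-platform expression simulator.

    Matrices are generated on a log2-like additive scale. A fraction
    ``deg_fraction`` of genes is planted with a group effect of magnitude
    ``lfc_mean`` (direction per gene: ``deg_direction`` "both" splits up/down
    at random, "up"/"down" force one direction), consistent across datasets.
    ``n_signature_genes`` genes additionally load on a latent per-sample
    infiltration factor with coefficient ``infiltration_coupling``.
    """

    n_datasets: int
    n_genes: int
    n_per_group: int
    deg_fraction: float
    lfc_mean: float
    platform_sd: float
    noise_sd: float
    infiltration_coupling: float = 0.0
    n_signature_genes: int = 20
    deg_direction: str = "both"
    group_labels: tuple[str, str] = ("CON", "CASE")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_datasets", "n_genes", "n_per_group"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not (0 < self.deg_fraction < 1):
            raise ParameterError("deg_fraction must be in (0,1)")
        if round(self.deg_fraction * self.n_genes) < 1:
            raise ParameterError("deg_fraction * n_genes must be >= 1")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.platform_sd < 0 or self.infiltration_coupling < 0:
            raise ParameterError("platform_sd and infiltration_coupling must be >= 0")
        if self.deg_direction not in ("both", "up", "down"):
            raise ParameterError(f"unknown deg_direction {self.deg_direction!r}")
        if self.n_signature_genes < 0 or (
            self.n_signature_genes + round(self.deg_fraction * self.n_genes) > self.n_genes
        ):
            raise ParameterError("n_signature_genes leaves no room beside DEG genes")


def simulate_expression(
    params: ExpressionSimParams,
) -> tuple[list[ExpressionDataset], dict]:
    """Generate ``n_datasets`` gene x sample matrices with shared planted truth.

    Each matrix is baseline + group effect + per-dataset platform shift
    (sd ``platform_sd``) + Gaussian noise (sd ``noise_sd``); signature genes
    add ``infiltration_coupling`` times a per-sample latent factor.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    n_deg = round(params.deg_fraction * params.n_genes)
    special = rng.choice(params.n_genes, size=n_deg + params.n_signature_genes, replace=False)
    deg_idx = special[:n_deg]
    sig_idx = special[n_deg:]
    if params.deg_direction == "both":
        directions = rng.choice([-1.0, 1.0], size=n_deg)
    else:
        directions = np.full(n_deg, 1.0 if params.deg_direction == "up" else -1.0)
    true_lfc = np.zeros(params.n_genes)
    true_lfc[deg_idx] = directions * params.lfc_mean
    is_sig = np.zeros(params.n_genes, dtype=bool)
    is_sig[sig_idx] = True
    baseline = rng.normal(7.0, 1.0, size=params.n_genes)

    ref_label, alt_label = params.group_labels
    datasets: list[ExpressionDataset] = []
    latents: dict[str, dict[str, float]] = {}
    for d in range(params.n_datasets):
        ds_id = f"DS{d + 1}"
        n = params.n_per_group
        sample_ids = [f"{ds_id}_{ref_label}{i + 1}" for i in range(n)] + [
            f"{ds_id}_{alt_label}{i + 1}" for i in range(n)
        ]
        group = np.array([0] * n + [1] * n)
        shift = rng.normal(0.0, params.platform_sd, size=params.n_genes)
        z = rng.normal(0.0, 1.0, size=2 * n)
        mat = (
            baseline[:, None]
            + shift[:, None]
            + true_lfc[:, None] * group[None, :]
            + params.infiltration_coupling * is_sig[:, None] * z[None, :]
            + rng.normal(0.0, params.noise_sd, size=(params.n_genes, 2 * n))
        )
        expr = pd.DataFrame(mat, index=genes, columns=sample_ids)
        groups = pd.Series(
            [ref_label] * n + [alt_label] * n, index=sample_ids, name="group"
        )
        datasets.append(
            ExpressionDataset(ds_id, expr, groups, (ref_label, alt_label))
        )
        latents[ds_id] = dict(zip(sample_ids, z.tolist()))

    truth = {
        "kind": "expression_simulation",
        "seed": params.seed,
        "deg": [
            {"gene": genes[i], "direction": "up" if true_lfc[i] > 0 else "down",
             "lfc": float(true_lfc[i])}
            for i in sorted(deg_idx)
        ],
        "signature_genes": [genes[i] for i in sorted(sig_idx)],
        "latent_factor": latents,
        "group_labels": list(params.group_labels),
    }
    return datasets, truth


# ---------------------------------------------------------------------------
# plain-text emitters


def write_simulated_repertoires(rset: RepertoireSet, truth: dict, outdir) -> None:
    """AIRR TSV per sample + samples.csv sheet + truth JSON."""
    outdir = Path(outdir)
    (outdir / "repertoires").mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in rset:
        write_airr(rep, outdir / "repertoires" / f"{rep.sample_id}.tsv")
        rows.append((rep.sample_id, rep.patient_id, rep.tissue))
    pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue"]).to_csv(
        outdir / "samples.csv", index=False
    )
    (outdir / "repertoire_truth.json").write_text(json.dumps(truth, indent=1))


def write_simulated_expression(
    datasets: Sequence[ExpressionDataset], truth: dict, outdir
) -> None:
    """One genes x samples CSV + group CSV per dataset + truth JSON."""
    outdir = Path(outdir)
    (outdir / "expression").mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        ds.expr.to_csv(outdir / "expression" / f"{ds.dataset_id}.csv")
        ds.groups.rename("group").to_csv(outdir / "expression" / f"{ds.dataset_id}.groups.csv")
    (outdir / "expression_truth.json").write_text(json.dumps(truth, indent=1))
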