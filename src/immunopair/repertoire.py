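"""Clonotype tables: data model, aggregation, and AIRR/MiXCR TSV I/O.

Terminology
-----------
clonotype
    A unique CDR3 amino-acid sequence.
clone
    A unique (CDR3 amino-acid sequence, V call, D call, J call) combination.

Frequencies are always read-count fractions: ``read_count / total reads`` of
the containing repertoire (MiXCR ``cloneFraction`` semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, DataFormatError, ParameterError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids plus the non-productive markers '*' (stop)
#: and '_' (frameshift), which are retained but flagged.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*_")

AIRR_COLUMNS = ("junction_aa", "v_call", "d_call", "j_call", "duplicate_count")
MIXCR_COLUMNS = (
    "cloneCount",
    "aaSeqCDR3",
    "allVHitsWithScore",
    "allDHitsWithScore",
    "allJHitsWithScore",
)


def strip_allele(gene_call: str) -> str:
    """Drop the allele suffix from a gene call (``TRBV5-1*01`` -> ``TRBV5-1``)."""
    return gene_call.split("*", 1)[0]


@dataclass
class ClonotypeRecord:
    """One rearrangement row of a repertoire table."""

    cdr3_aa: str
    v_call: str
    d_call: str
    j_call: str
    read_count: int
    frequency: float = 0.0  # derived; set by the owning Repertoire

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise DataError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise DataError(
                f"cdr3_aa {self.cdr3_aa!r} contains invalid characters {sorted(bad)}"
            )
        if self.read_count < 1:
            raise DataError(f"read_count must be >= 1, got {self.read_count}")

    @property
    def productive(self) -> bool:
        """False when the CDR3 carries a stop ('*') or frameshift ('_') marker."""
        return "*" not in self.cdr3_aa and "_" not in self.cdr3_aa

    @property
    def clone_key(self) -> tuple[str, str, str, str]:
        return (self.cdr3_aa, self.v_call, self.d_call, self.j_call)


class Repertoire:
    """One sample's clonotype table with patient/tissue metadata.

    Records may repeat a clonotype (or clone) key; :meth:`aggregate` provides
    the deduplicated views. Frequencies are (re)computed on construction.
    """

    def __init__(
        self,
        sample_id: str,
        records: Iterable[ClonotypeRecord],
        patient_id: str = "",
        tissue: str = "",
    ) -> None:
        self.sample_id = sample_id
        self.patient_id = patient_id
        self.tissue = tissue
        self.records: list[ClonotypeRecord] = list(records)
        total = sum(r.read_count for r in self.records)
        if total <= 0:
            raise DataError(f"repertoire {sample_id!r} has zero total reads")
        self._total_reads = total
        for r in self.records:
            r.frequency = r.read_count / total

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Repertoire({self.sample_id!r}, tissue={self.tissue!r}, "
            f"records={len(self.records)}, reads={self._total_reads})"
        )

    @property
    def total_reads(self) -> int:
        return self._total_reads

    def aggregate(self, level: str = "clonotype") -> dict:
        """Collapse records to unique keys, summing counts.

        Parameters
        ----------
        level
            ``"clonotype"`` keys on the CDR3 amino-acid sequence alone;
            ``"clone"`` keys on (cdr3_aa, v_call, d_call, j_call).

        Returns
        -------
        dict
            key -> ``(read_count, frequency)``; frequencies sum to 1.
        """
        if level not in ("clonotype", "clone"):
            raise ParameterError(f"unknown aggregation level {level!r}")
        counts: dict = {}
        for r in self.records:
            key = r.cdr3_aa if level == "clonotype" else r.clone_key
            counts[key] = counts.get(key, 0) + r.read_count
        total = self._total_reads
        return {k: (c, c / total) for k, c in counts.items()}

    def clonotype_frequencies(self) -> dict[str, float]:
        """CDR3 -> frequency over the clonotype-level aggregation."""
        return {k: f for k, (_, f) in self.aggregate("clonotype").items()}

    def filtered(
        self, productive_only: bool = False, min_count: int = 1
    ) -> "Repertoire":
        """Return a copy with non-productive and/or low-count records dropped."""
        recs = [
            ClonotypeRecord(r.cdr3_aa, r.v_call, r.d_call, r.j_call, r.read_count)
            for r in self.records
            if (r.productive or not productive_only) and r.read_count >= min_count
        ]
        if not recs:
            raise DataError(
                f"repertoire {self.sample_id!r} empty after filtering"
            )
        return Repertoire(self.sample_id, recs, self.patient_id, self.tissue)


class RepertoireSet:
    """Repertoires keyed by sample_id plus a patient -> tissue -> sample index."""

    def __init__(self, repertoires: Iterable[Repertoire] = ()) -> None:
        self.repertoires: dict[str, Repertoire] = {}
        self.pairing: dict[str, dict[str, str]] = {}
        for rep in repertoires:
            self.add(rep)

    def add(self, rep: Repertoire) -> None:
        if rep.sample_id in self.repertoires:
            raise DataError(f"duplicate sample_id {rep.sample_id!r}")
        self.repertoires[rep.sample_id] = rep
        if rep.patient_id and rep.tissue:
            self.pairing.setdefault(rep.patient_id, {})[rep.tissue] = rep.sample_id

    def __getitem__(self, sample_id: str) -> Repertoire:
        return self.repertoires[sample_id]

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self):
        return iter(self.repertoires.values())

    def sample_ids(self) -> list[str]:
        return list(self.repertoires)

    def paired(self, tissue_a: str, tissue_b: str) -> list[tuple[Repertoire, Repertoire]]:
        """All same-patient (tissue_a, tissue_b) repertoire pairs."""
        out = []
        for tissues in self.pairing.values():
            if tissue_a in tissues and tissue_b in tissues:
                out.append(
                    (self.repertoires[tissues[tissue_a]], self.repertoires[tissues[tissue_b]])
                )
        return out


def _first_mixcr_hit(hits: str) -> str:
    """``'TRBV5-1*00(1200),TRBV5-4*00(900)'`` -> ``'TRBV5-1'`` (empty stays empty)."""
    if not hits or pd.isna(hits):
        return ""
    first = str(hits).split(",", 1)[0]
    return strip_allele(first.split("(", 1)[0].strip())


def read_airr(
    path,
    dialect: str = "airr",
    sample_id: str | None = None,
    patient_id: str = "",
    tissue: str = "",
) -> Repertoire:
    """Read one clonotype table in AIRR Rearrangement or MiXCR-export TSV.

    MiXCR gene hits are truncated at the first ``'*'`` and the first-ranked
    hit is taken; AIRR v/d/j calls keep their stored form (allele stripping
    happens downstream, in V-J analyses).
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    if dialect not in ("airr", "mixcr"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = AIRR_COLUMNS if dialect == "airr" else MIXCR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {', '.join(missing)!s} "
            f"for dialect {dialect!r}"
        )
    records = []
    for _, row in df.iterrows():
        if dialect == "airr":
            d_call = row["d_call"]
            records.append(
                ClonotypeRecord(
                    cdr3_aa=str(row["junction_aa"]),
                    v_call=str(row["v_call"]),
                    d_call="" if pd.isna(d_call) else str(d_call),
                    j_call=str(row["j_call"]),
                    read_count=int(float(row["duplicate_count"])),
                )
            )
        else:
            records.append(
                ClonotypeRecord(
                    cdr3_aa=str(row["aaSeqCDR3"]),
                    v_call=_first_mixcr_hit(row["allVHitsWithScore"]),
                    d_call=_first_mixcr_hit(row["allDHitsWithScore"]),
                    j_call=_first_mixcr_hit(row["allJHitsWithScore"]),
                    read_count=int(round(float(row["cloneCount"]))),
                )
            )
    if not records:
        raise DataError(f"{path}: empty repertoire (no rows)")
    sid = sample_id if sample_id is not None else path.stem
    return Repertoire(sid, records, patient_id=patient_id, tissue=tissue)


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (round-trip safe)."""
    if not rep.records:
        raise DataError("cannot write an empty repertoire")
    df = pd.DataFrame(
        {
            "junction_aa": [r.cdr3_aa for r in rep.records],
            "v_call": [r.v_call for r in rep.records],
            "d_call": [r.d_call for r in rep.records],
            "j_call": [r.j_call for r in rep.records],
            "duplicate_count": [r.read_count for r in rep.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV with columns sample_id, patient_id, tissue."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("sample_id", "patient_id", "tissue") if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: sample sheet missing column(s) {', '.join(missing)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"{path}: duplicate sample_id {dup!r}")
    return df


def load_repertoire_set(
    sheet: pd.DataFrame | Mapping,
    directory,
    dialect: str = "airr",
    productive_only: bool = False,
    min_count: int = 1,
) -> RepertoireSet:
    """Load every sample in a sample sheet from ``directory/<sample_id>.tsv``."""
    directory = Path(directory)
    rset = RepertoireSet()
    if isinstance(sheet, Mapping):
        sheet = pd.DataFrame(sheet)
    for _, row in sheet.iterrows():
        fp = directory / f"{row['sample_id']}.tsv"
        if not fp.exists():
            raise DataError(f"sample {row['sample_id']!r} listed in sheet but {fp} not found")
        rep = read_airr(
            fp,
            dialect=dialect,
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            tissue=row["tissue"],
        )
        if productive_only or min_count > 1:
            rep = rep.filtered(productive_only=productive_only, min_count=min_count)
        rset.add(rep)
    return rset
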