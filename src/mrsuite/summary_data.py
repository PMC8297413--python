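"""Data model and I/O for GWAS summary statistics.

Summary-level association data — one row per variant, with effect sizes
expressed per copy of the effect allele — is the common currency of
two-sample Mendelian randomization.  This module defines the in-memory
containers (:class:`VariantAssociation`, :class:`SummaryDataset`,
:class:`GeneRegion`, :class:`LDInfo`) and the delimited-text readers and
writers the rest of the pipeline builds on.

Conventions
-----------
* Genomic coordinates are 1-based and intervals are inclusive at both ends
  (GRCh37 convention).
* Missing values are encoded as ``NA`` or an empty string on read and
  written back as ``NA``.
* Input p-values of exactly zero are clamped to the smallest positive
  float with a warning; GWAS tables commonly floor extreme p-values.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrsuite")

VALID_ALLELES = frozenset("ACGT")

#: canonical field names a column map may provide
CANONICAL_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

_TINY_P = sys.float_info.min


class ConfigurationError(ValueError):
    """A user-supplied configuration (column map, thresholds, paths) is invalid."""


@dataclass
class VariantAssociation:
    """One variant's summary statistics for one trait.

    ``beta`` is the per-effect-allele change in the trait (trait units for a
    continuous trait, log-odds for a binary one); ``se`` is its standard
    error; ``eaf`` is the effect-allele frequency and may be missing.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chromosome: str = ""
    position: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are both {self.effect_allele!r}"
            )
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.pvalue == 0.0:
            logger.warning("%s: p-value of 0 clamped to %.3e", self.variant_id, _TINY_P)
            self.pvalue = _TINY_P
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.variant_id}: p-value {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; ``None`` if eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True if the allele pair is strand-ambiguous (A/T or G/C)."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"G", "C"})


@dataclass
class SummaryDataset:
    """A named trait plus its ordered collection of variant associations."""

    trait_name: str
    records: list[VariantAssociation] = field(default_factory=list)
    trait_type: str = "continuous"  # {continuous, binary}
    effect_scale: str = "raw-units"  # {raw-units, SD, log-odds}
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            self.effect_scale = "log-odds"
        ids = [r.variant_id for r in self.records]
        dupes = {v for v in ids if ids.count(v) > 1} if len(ids) != len(set(ids)) else set()
        if dupes:
            raise ConfigurationError(
                f"duplicate variant_id in dataset {self.trait_name!r}: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.variant_id: r for r in self.records}
        return self._idx

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the records (one row per variant, canonical columns)."""
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "chromosome": [r.chromosome for r in self.records],
                "position": [r.position for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval (1-based, inclusive both ends)."""

    gene_name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start {self.start} > end {self.end}")

    def contains(self, chromosome: str, position: int | None) -> bool:
        return (
            position is not None
            and str(chromosome) == str(self.chromosome)
            and self.start <= position <= self.end
        )


class LDInfo:
    """Pairwise linkage-disequilibrium r² between variants.

    Stores unordered pairs; ``r2(x, x)`` is implicitly 1 and unknown pairs
    return the supplied default.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._pairs: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
        self._pairs[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), default)

    def __len__(self) -> int:
        return len(self._pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter:
        return {"tab": "\t", "comma": ","}.get(delimiter, delimiter)
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_summary_table(
    path: str,
    column_map: Mapping[str, str],
    trait_name: str = "trait",
    trait_type: str = "continuous",
    effect_scale: str = "raw-units",
    sample_size: int | None = None,
    delimiter: str | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Tab vs comma is inferred from
        the extension (``.csv`` → comma, anything else → tab) unless
        ``delimiter`` is given explicitly (``"tab"``, ``"comma"`` or a literal
        separator).
    column_map
        Mapping from canonical field name (``variant_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pvalue``; optionally
        ``chromosome``, ``position``, ``eaf``, ``n``) to the source column.

    Rows whose beta or se cannot be parsed as finite numbers (or se ≤ 0) are
    dropped with a logged count; missing eaf/n are stored as missing.
    """
    missing_req = [f for f in REQUIRED_FIELDS if f not in column_map]
    if missing_req:
        raise ConfigurationError(f"column_map missing required fields: {missing_req}")

    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str, na_values=["NA", ""],
                     keep_default_na=False)
    missing_cols = [c for c in column_map.values() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: mapped columns absent from header: {missing_cols}"
        )

    records: list[VariantAssociation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        def cell(fieldname: str) -> str | None:
            col = column_map.get(fieldname)
            if col is None:
                return None
            v = row[col]
            return None if pd.isna(v) else str(v)

        beta_s, se_s = cell("beta"), cell("se")
        try:
            beta = float(beta_s)  # type: ignore[arg-type]
            se = float(se_s)  # type: ignore[arg-type]
            if not (math.isfinite(beta) and math.isfinite(se) and se > 0):
                raise ValueError
        except (TypeError, ValueError):
            n_dropped += 1
            continue

        eaf_s, n_s, pos_s = cell("eaf"), cell("n"), cell("position")
        pv_s = cell("pvalue")
        records.append(
            VariantAssociation(
                variant_id=str(cell("variant_id")),
                chromosome=cell("chromosome") or "",
                position=int(float(pos_s)) if pos_s is not None else None,
                effect_allele=str(cell("effect_allele")),
                other_allele=str(cell("other_allele")),
                eaf=float(eaf_s) if eaf_s is not None else None,
                beta=beta,
                se=se,
                pvalue=float(pv_s) if pv_s is not None else 1.0,
                n=int(float(n_s)) if n_s is not None else None,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d row(s) with unparseable beta/se", path, n_dropped)

    return SummaryDataset(
        trait_name=trait_name,
        records=records,
        trait_type=trait_type,
        effect_scale=effect_scale,
        sample_size=sample_size,
    )


def write_summary_table(dataset: SummaryDataset, path: str, delimiter: str | None = None) -> None:
    """Write a dataset back to delimited text with canonical column names."""
    df = dataset.to_frame()
    df.to_csv(path, sep=_sep_for(path, delimiter), index=False, na_rep="NA")


def read_regions_bed(path: str) -> list[GeneRegion]:
    """Read a 4-column gene-interval table (gene_name, chromosome, start, end).

    Coordinates are 1-based inclusive.  A header row is detected (and skipped)
    when the third column of the first line is not numeric.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    first = df.iloc[0]
    try:
        float(first.iloc[2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return [
        GeneRegion(str(r.iloc[0]), str(r.iloc[1]), int(float(r.iloc[2])), int(float(r.iloc[3])))
        for _, r in df.iterrows()
    ]


def read_ld_table(path: str) -> LDInfo:
    """Read pairwise LD as a 3-column table (id1, id2, r2)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    ld = LDInfo()
    for _, r in df.iterrows():
        ld.set(str(r.iloc[0]), str(r.iloc[1]), float(r.iloc[2]))
    return ld


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.10g}"


def write_results_table(estimates: Sequence, path: str) -> None:
    """Write causal estimates as a tab-delimited table.

    Columns: method, exposure, outcome, n_snps, estimate, se, ci_segments
    (semicolon-joined ``lo,hi`` pairs — the contamination-mixture confidence
    set may span several disjoint ranges), pvalue.  Values round-trip at 10
    significant digits.
    """
    if not estimates:
        raise ValueError("estimates collection is empty")
    rows = []
    for est in estimates:
        ci = ";".join(f"{_fmt(lo)},{_fmt(hi)}" for lo, hi in est.ci_segments)
        rows.append(
            {
                "method": est.method,
                "exposure": est.extras.get("exposure", "NA"),
                "outcome": est.extras.get("outcome", "NA"),
                "n_snps": est.n_snps,
                "estimate": _fmt(est.theta),
                "se": _fmt(est.se),
                "ci_segments": ci,
                "pvalue": _fmt(est.pvalue),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results_table(path: str) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    for col in ("n_snps",):
        df[col] = df[col].astype(int)
    for col in ("estimate", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ci_segments"] = df["ci_segments"].map(
        lambda s: tuple(
            tuple(float(x) for x in seg.split(",")) for seg in str(s).split(";")
        )
        if pd.notna(s) and s != ""
        else ()
    )
    return df
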