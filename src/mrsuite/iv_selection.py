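"""Instrument selection for two-sample Mendelian randomization.

Two selection routes are provided:

* *statistical* — genome-wide significant variants (p < 5e-8 by default),
  greedily LD-clumped at r² < 0.001 within a 10,000 kb window;
* *biological* — variants inside candidate-gene regions (e.g. the urate
  transporter genes ABCG2, SLC2A9, SLC22A12, SLC22A11, SLC17A1, SLC17A3),
  genome-wide significant and mutually independent at r² < 0.1 with no
  distance window.

Instrument strength is quantified by the F-statistic (beta/se)² — F > 10 is
the conventional non-weak bar — and by the variance explained, recovered via
the identity r² = F / (F + n − 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .summary_data import GeneRegion, LDInfo, SummaryDataset, VariantAssociation

logger = logging.getLogger("mrsuite")

GENOME_WIDE_P = 5e-8


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    ``clump_r2`` defaults differ by approach: 0.001 for the statistical
    route, 0.1 for the biological route.  ``strict_ld`` controls how an LD
    pair absent from the table is treated when two variants fall within the
    clumping window: dependent (r² = 1) when True, independent with a
    warning when False (the default).
    """

    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    clump_distance_kb: int = 10_000
    f_min: float = 10.0
    approach: str = "statistical"  # {statistical, biological}
    regions: Sequence[GeneRegion] | None = None
    strict_ld: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold {self.p_threshold} outside (0, 1)")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError(f"clump_r2 {self.clump_r2} outside [0, 1]")
        if self.clump_distance_kb <= 0:
            raise ValueError("clump_distance_kb must be positive")
        if self.approach not in ("statistical", "biological"):
            raise ValueError(f"unknown approach {self.approach!r}")


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-instrument strength: F-statistic and variance explained."""

    variant_id: str
    f_stat: float
    r2_explained: float
    weak: bool


class SelectionResult(Sequence):
    """Ordered selected variant ids, optionally annotated with a source gene."""

    def __init__(self, variant_ids: list[str], genes: dict[str, str] | None = None) -> None:
        self.variant_ids = variant_ids
        self.genes = genes or {}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __getitem__(self, i):
        return self.variant_ids[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.variant_ids)

    def __contains__(self, v) -> bool:
        return v in self.variant_ids

    def __repr__(self) -> str:
        return f"SelectionResult({self.variant_ids!r})"


def _sort_key(v: VariantAssociation):
    # p ascending; ties broken lexicographically for a deterministic clump order
    return (v.pvalue, v.chromosome, v.position if v.position is not None else 0, v.variant_id)


def _greedy_clump(
    candidates: list[VariantAssociation],
    ld: LDInfo,
    clump_r2: float,
    clump_distance_kb: int | None,
    strict_ld: bool,
) -> list[VariantAssociation]:
    """Index-variant greedy pruning.

    Candidates are visited in ascending p-value order; each is accepted
    unless it is in LD (r² ≥ ``clump_r2``) with an already-accepted variant,
    where the LD condition applies only within ``clump_distance_kb`` on the
    same chromosome when a window is given, and unconditionally when
    ``clump_distance_kb`` is None.
    """
    accepted: list[VariantAssociation] = []
    warned_missing = False
    for cand in sorted(candidates, key=_sort_key):
        keep = True
        for acc in accepted:
            if clump_distance_kb is not None:
                if cand.chromosome != acc.chromosome:
                    continue
                if cand.position is None or acc.position is None:
                    within = True  # unknown position: be conservative, apply LD rule
                else:
                    within = abs(cand.position - acc.position) <= clump_distance_kb * 1000
                if not within:
                    continue
            r2 = ld.get(cand.variant_id, acc.variant_id)
            if r2 is None:
                if strict_ld:
                    r2 = 1.0
                else:
                    if not warned_missing:
                        logger.warning(
                            "missing LD pair(s) within the clumping window treated as r2=0; "
                            "pass strict_ld=True to treat them as dependent"
                        )
                        warned_missing = True
                    r2 = 0.0
            if r2 >= clump_r2:
                keep = False
                break
        if keep:
            accepted.append(cand)
    return accepted


def select_statistical(
    exposure: SummaryDataset, ld: LDInfo, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Statistically driven instrument selection.

    Variants with p < ``cfg.p_threshold`` are greedily pruned so that no
    retained pair within ``cfg.clump_distance_kb`` on the same chromosome has
    r² ≥ ``cfg.clump_r2``.  Threshold comparisons are strict, matching the
    printed convention (p < 5 × 10⁻⁸, r² < 0.001).
    """
    cfg = cfg or SelectionConfig()
    sig = [v for v in exposure if v.pvalue < cfg.p_threshold]
    if not sig:
        logger.warning("%s: no variants pass p < %g", exposure.trait_name, cfg.p_threshold)
        return SelectionResult([])
    kept = _greedy_clump(sig, ld, cfg.clump_r2, cfg.clump_distance_kb, cfg.strict_ld)
    return SelectionResult([v.variant_id for v in kept])


def select_biological(
    exposure: SummaryDataset,
    regions: Sequence[GeneRegion],
    ld: LDInfo,
    cfg: SelectionConfig | None = None,
) -> SelectionResult:
    """Biologically driven instrument selection within candidate-gene regions.

    Variants are first restricted to those whose position falls inside any
    region (1-based inclusive), then thresholded at ``cfg.p_threshold`` and
    greedily pruned at r² < ``cfg.clump_r2`` (default 0.1) with no distance
    window — within candidate genes, any LD above the bar disqualifies.
    The result carries a variant → gene annotation.
    """
    if not regions:
        raise ValueError("biological selection requires a non-empty region list")
    cfg = cfg or SelectionConfig(approach="biological", clump_r2=0.1)

    gene_of: dict[str, str] = {}
    in_region: list[VariantAssociation] = []
    for v in exposure:
        for reg in regions:
            if reg.contains(v.chromosome, v.position):
                in_region.append(v)
                gene_of[v.variant_id] = reg.gene_name
                break
    for reg in regions:
        if not any(gene_of.get(v.variant_id) == reg.gene_name for v in in_region):
            logger.info("region %s contains no variants", reg.gene_name)

    sig = [v for v in in_region if v.pvalue < cfg.p_threshold]
    kept = _greedy_clump(sig, ld, cfg.clump_r2, None, cfg.strict_ld)
    ids = [v.variant_id for v in kept]
    return SelectionResult(ids, {i: gene_of[i] for i in ids})


def instrument_strength(v: VariantAssociation, n: int) -> InstrumentStrength:
    """F-statistic and variance explained for one instrument.

    F = (beta/se)²; r² = F / (F + n − 2).  Instruments with F ≤ 10 are
    flagged weak.
    """
    if n <= 2:
        raise ValueError(f"sample size {n} too small for variance explained (need n > 2)")
    f = (v.beta / v.se) ** 2
    r2 = f / (f + n - 2)
    return InstrumentStrength(v.variant_id, f, r2, weak=f <= 10.0)
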