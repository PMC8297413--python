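"""Allele harmonization across exposure and outcome summary datasets.

Two GWAS report the same variant relative to whichever allele each chose as
the effect allele, possibly on opposite strands.  Before Wald ratios can be
formed, the outcome association must be re-expressed on the exposure's
effect allele:

* same orientation → keep as-is;
* alleles swapped → flip the sign of the outcome beta and replace its
  effect-allele frequency by 1 − eaf;
* reconcilable only by strand complement (A↔T, C↔G) → complement, then
  apply the two rules above;
* palindromic pair (A/T or G/C) → strand is ambiguous; orient by
  effect-allele-frequency agreement, but exclude outright when the minor
  allele frequency exceeds 0.42 in either dataset (or eaf is missing),
  where frequency is too close to 0.5 to be informative;
* anything else → allele mismatch, excluded.

Each retained instrument carries the per-variant Wald ratio
``beta_outcome / beta_exposure`` with the first-order standard error
``se_outcome / |beta_exposure|`` (the exposure coefficient treated as known,
the NOME approximation; a second-order correction is available via
``second_order_se=True``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .summary_data import SummaryDataset, VariantAssociation

logger = logging.getLogger("mrsuite")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROME_MAF_LIMIT = 0.42

# action labels
KEPT = "kept"
SIGN_FLIPPED = "sign-flipped"
EXCLUDED_PALINDROMIC = "excluded-palindromic"
EXCLUDED_MISMATCH = "excluded-mismatch"
EXCLUDED_MISSING_OUTCOME = "excluded-missing-outcome"
EXCLUDED_ZERO_EXPOSURE = "excluded-zero-exposure-beta"


@dataclass
class HarmonizedInstrument:
    """Per-variant paired exposure/outcome effects on a common effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    ratio: float
    se_ratio: float
    action: str
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None


@dataclass
class InstrumentSet:
    """Retained harmonized instruments plus a log of exclusions."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)  # variant_id -> reason
    outcome_trait_type: str = "continuous"
    n_exposure: int | None = None
    n_outcome: int | None = None

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    def subset(self, variant_ids: Sequence[str]) -> "InstrumentSet":
        keep = set(variant_ids)
        return InstrumentSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            instruments=[i for i in self.instruments if i.variant_id in keep],
            exclusions=dict(self.exclusions),
            outcome_trait_type=self.outcome_trait_type,
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
        )


class EmptyInstrumentSetError(RuntimeError):
    """Harmonization retained zero instruments; downstream estimation is impossible."""


def wald_ratio(
    beta_exposure: float,
    beta_outcome: float,
    se_exposure: float,
    se_outcome: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Per-variant causal estimate and its standard error.

    ratio = beta_outcome / beta_exposure; first-order (default)
    se = se_outcome / |beta_exposure|.  The second-order form adds the
    delta-method term for uncertainty in the exposure coefficient.
    """
    if beta_exposure == 0.0:
        raise ZeroDivisionError("Wald ratio undefined for a zero exposure coefficient")
    ratio = beta_outcome / beta_exposure
    if second_order:
        se = math.sqrt(
            se_outcome**2 / beta_exposure**2
            + beta_outcome**2 * se_exposure**2 / beta_exposure**4
        )
    else:
        se = se_outcome / abs(beta_exposure)
    return ratio, se


def apply_proxies(
    outcome: SummaryDataset,
    proxy_table: Mapping[str, tuple[str, float]],
    min_r2: float = 0.8,
) -> SummaryDataset:
    """Substitute user-supplied proxy variants for ids absent from the outcome.

    ``proxy_table`` maps a missing exposure variant id to ``(proxy_id, r2)``;
    pairs below ``min_r2`` are refused.  The proxy's summary statistics are
    re-labelled with the requested id, so harmonization proceeds as if the
    variant had been present.  No reference-panel lookup is performed — the
    table is the caller's responsibility.
    """
    records = list(outcome.records)
    present = {r.variant_id for r in records}
    for want, (proxy_id, r2) in proxy_table.items():
        if r2 < min_r2:
            raise ValueError(f"proxy {proxy_id} for {want} has r2={r2} < {min_r2}")
        if want in present:
            continue
        src = outcome.get(proxy_id)
        if src is None:
            logger.warning("proxy %s for %s not found in outcome data", proxy_id, want)
            continue
        records.append(
            VariantAssociation(
                variant_id=want,
                chromosome=src.chromosome,
                position=src.position,
                effect_allele=src.effect_allele,
                other_allele=src.other_allele,
                eaf=src.eaf,
                beta=src.beta,
                se=src.se,
                pvalue=src.pvalue,
                n=src.n,
            )
        )
        logger.info("substituted proxy %s (r2=%.3f) for %s", proxy_id, r2, want)
    return SummaryDataset(
        trait_name=outcome.trait_name,
        records=records,
        trait_type=outcome.trait_type,
        effect_scale=outcome.effect_scale,
        sample_size=outcome.sample_size,
    )


def _minor_side(eaf: float) -> bool:
    """True when the effect allele is the minor one."""
    return eaf < 0.5


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    maf_palindrome_limit: float = PALINDROME_MAF_LIMIT,
    variant_ids: Sequence[str] | None = None,
    second_order_se: bool = False,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    Processes the exposure's variants in order (optionally restricted to
    ``variant_ids``), applying the orientation rules described in the module
    docstring.  Retained + excluded counts always equal the number of
    variants considered.
    """
    result = InstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_trait_type=outcome.trait_type,
        n_exposure=exposure.sample_size,
        n_outcome=outcome.sample_size,
    )

    wanted = list(variant_ids) if variant_ids is not None else [r.variant_id for r in exposure]
    for vid in wanted:
        exp = exposure.get(vid)
        if exp is None:
            result.exclusions[vid] = "absent-from-exposure"
            continue
        out = outcome.get(vid)
        if out is None:
            result.exclusions[vid] = EXCLUDED_MISSING_OUTCOME
            continue
        if exp.beta == 0.0:
            result.exclusions[vid] = EXCLUDED_ZERO_EXPOSURE
            continue

        e_pair = (exp.effect_allele, exp.other_allele)
        o_pair = (out.effect_allele, out.other_allele)
        if not (set(e_pair) <= set(COMPLEMENT) and set(o_pair) <= set(COMPLEMENT)):
            result.exclusions[vid] = EXCLUDED_MISMATCH
            continue

        palindromic = exp.is_palindromic
        if palindromic:
            # strand is ambiguous; frequency is the only orientation signal
            mafs = [m for m in (exp.maf, out.maf)]
            if any(m is None for m in mafs) or max(m for m in mafs) > maf_palindrome_limit:
                result.exclusions[vid] = EXCLUDED_PALINDROMIC
                continue
            if set(o_pair) != set(e_pair):
                result.exclusions[vid] = EXCLUDED_MISMATCH
                continue
            # candidate orientation 1: treat outcome as same-orientation
            if _minor_side(out.eaf) == _minor_side(exp.eaf):  # type: ignore[arg-type]
                action, beta_out, eaf_out = KEPT, out.beta, out.eaf
            else:
                action, beta_out, eaf_out = SIGN_FLIPPED, -out.beta, 1.0 - out.eaf  # type: ignore[operator]
        else:
            comp_pair = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
            if o_pair == e_pair:
                action, beta_out, eaf_out = KEPT, out.beta, out.eaf
            elif (o_pair[1], o_pair[0]) == e_pair:
                action, beta_out = SIGN_FLIPPED, -out.beta
                eaf_out = 1.0 - out.eaf if out.eaf is not None else None
            elif comp_pair == e_pair:
                action, beta_out, eaf_out = KEPT, out.beta, out.eaf
            elif (comp_pair[1], comp_pair[0]) == e_pair:
                action, beta_out = SIGN_FLIPPED, -out.beta
                eaf_out = 1.0 - out.eaf if out.eaf is not None else None
            else:
                result.exclusions[vid] = EXCLUDED_MISMATCH
                continue

        ratio, se_ratio = wald_ratio(exp.beta, beta_out, exp.se, out.se, second_order_se)
        result.instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                ratio=ratio,
                se_ratio=se_ratio,
                action=action,
                eaf_exposure=exp.eaf,
                eaf_outcome=eaf_out,
            )
        )

    if not result.instruments:
        logger.error(
            "harmonization of %s vs %s retained zero instruments (%d excluded)",
            exposure.trait_name,
            outcome.trait_name,
            len(result.exclusions),
        )
    return result
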