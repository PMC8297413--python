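"""Sensitivity analyses: leave-one-out, Steiger filtering, bidirectional MR.

* Leave-one-out re-estimates the IVW causal effect J times, each with one
  instrument removed, to expose individually influential variants.
* Steiger filtering removes instruments that explain more variance in the
  outcome than in the exposure — a guard against reverse causation.  Per
  trait, r² is recovered from the t-statistic identity
  r² = t² / (t² + n − 2) with t = beta/se.
* Bidirectional MR reruns the full pipeline in both directions (each with
  its own instrument selection and harmonization) to establish which trait
  drives the association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .estimators import MethodPanel, ivw, estimate_all, METHODS
from .harmonization import InstrumentSet, harmonize
from .iv_selection import SelectionConfig, select_statistical
from .summary_data import LDInfo, SummaryDataset

logger = logging.getLogger("mrsuite")


@dataclass(frozen=True)
class LeaveOneOutRow:
    """IVW estimate with one instrument omitted."""

    omitted_variant: str
    theta: float
    se: float
    ci_lo: float
    ci_hi: float
    crosses_null_changed: bool


@dataclass(frozen=True)
class SteigerRow:
    """Variance explained in exposure vs outcome for one instrument.

    ``direction_ok`` is True when the instrument explains strictly more
    variance in the exposure; None when a sample size was unavailable.
    """

    variant_id: str
    r2_exposure: float | None
    r2_outcome: float | None
    direction_ok: bool | None


def leave_one_out(inst: InstrumentSet) -> list[LeaveOneOutRow]:
    """Leave-one-out IVW analysis (multiplicative random-effects).

    Each row flags whether omitting that instrument changes the null-
    crossing status of the 95% CI relative to the full-set estimate.
    """
    j = len(inst)
    if j < 3:
        raise ValueError(f"leave-one-out requires >= 3 instruments, got {j}")
    full, _ = ivw(inst)
    (flo, fhi), = full.ci_segments
    full_crosses = flo <= 0.0 <= fhi

    rows = []
    ids = inst.variant_ids
    for vid in ids:
        sub = inst.subset([v for v in ids if v != vid])
        est, _ = ivw(sub)
        (lo, hi), = est.ci_segments
        rows.append(
            LeaveOneOutRow(
                omitted_variant=vid,
                theta=est.theta,
                se=est.se,
                ci_lo=lo,
                ci_hi=hi,
                crosses_null_changed=(lo <= 0.0 <= hi) != full_crosses,
            )
        )
    return rows


def _t_r2(beta: float, se: float, n: int) -> float:
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(
    inst: InstrumentSet,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
) -> tuple[InstrumentSet, list[SteigerRow]]:
    """Remove instruments more correlated with the outcome than the exposure.

    Sample sizes default to those carried by the instrument set.  A variant
    is retained only when r²(exposure) strictly exceeds r²(outcome) — ties
    are treated as wrong-direction and removed.  For binary outcomes the
    same t-based identity is applied on the log-odds scale (a pragmatic
    approximation, logged as a caveat).  Variants lacking a sample size on
    either side are retained with ``direction_ok=None`` and a warning.
    """
    n_exposure = n_exposure if n_exposure is not None else inst.n_exposure
    n_outcome = n_outcome if n_outcome is not None else inst.n_outcome
    if inst.outcome_trait_type == "binary":
        logger.info(
            "Steiger filtering on a binary outcome uses the t-based r2 identity "
            "on the log-odds scale (approximation)"
        )

    rows: list[SteigerRow] = []
    keep: list[str] = []
    for i in inst.instruments:
        if n_exposure is None or n_outcome is None or n_exposure <= 2 or n_outcome <= 2:
            logger.warning("%s: missing sample size, direction undetermined; retained", i.variant_id)
            rows.append(SteigerRow(i.variant_id, None, None, None))
            keep.append(i.variant_id)
            continue
        r2_exp = _t_r2(i.beta_exposure, i.se_exposure, n_exposure)
        r2_out = _t_r2(i.beta_outcome, i.se_outcome, n_outcome)
        ok = r2_exp > r2_out
        rows.append(SteigerRow(i.variant_id, r2_exp, r2_out, ok))
        if ok:
            keep.append(i.variant_id)
    return inst.subset(keep), rows


def bidirectional(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    sel_cfg: SelectionConfig | None = None,
    ld: LDInfo | None = None,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    steiger: bool = True,
    maf_palindrome_limit: float = 0.42,
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> dict[str, MethodPanel | None]:
    """Run the full pipeline in both causal directions.

    Both inputs must be genome-wide datasets (not pre-selected instrument
    lists): each direction performs its own statistical instrument
    selection, harmonization (with palindromic exclusion), optional Steiger
    filtering, and the panel of estimators.  A direction lacking significant
    instruments is reported as None; the other is still returned.
    """
    sel_cfg = sel_cfg or SelectionConfig()
    ld = ld or LDInfo()
    panels: dict[str, MethodPanel | None] = {}
    for label, (exp_ds, out_ds) in {
        "forward": (exposure, outcome),
        "reverse": (outcome, exposure),
    }.items():
        selected = select_statistical(exp_ds, ld, sel_cfg)
        if not selected:
            logger.warning("%s direction: no significant instruments", label)
            panels[label] = None
            continue
        inst = harmonize(exp_ds, out_ds, maf_palindrome_limit, variant_ids=list(selected))
        if len(inst) == 0:
            logger.warning("%s direction: all instruments excluded in harmonization", label)
            panels[label] = None
            continue
        if steiger:
            inst, _ = steiger_filter(inst)
        panels[label] = estimate_all(inst, methods=methods, seed=seed,
                                     n_boot=n_boot, n_sim=n_sim)
    return panels
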