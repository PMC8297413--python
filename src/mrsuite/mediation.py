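"""Product-of-coefficients mediation on the log-odds scale.

For an exposure whose total causal effect on a binary outcome is an odds
ratio, and a continuous mediator on the path, the proportion mediated is

    proportion = (beta_exposure→mediator × ln OR_mediator→outcome) / ln OR_total

with all odds ratios converted to natural-log odds before multiplication.
Expressing the mediator effect per unit increase vs per unit decrease is
equivalent as long as both coefficients' signs are flipped together (an OR
of 0.91 per +1 SD is the same effect as ≈1.10 per −1 SD).

No uncertainty propagation is attempted — the calculation combines point
estimates only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MediationResult:
    """Indirect, direct and total effects on the log-odds scale."""

    beta_exp_med: float      # mediator units per exposure unit
    logor_med_out: float     # log-odds per mediator unit
    logor_total: float       # log-odds per exposure unit
    indirect: float          # beta_exp_med * logor_med_out
    proportion: float        # indirect / logor_total
    percent: int             # proportion rounded to the nearest integer percent

    @property
    def direct(self) -> float:
        """Residual (non-mediated) effect on the log-odds scale."""
        return self.logor_total - self.indirect


def proportion_mediated(
    beta_exp_med: float, or_med_out: float, or_total: float
) -> MediationResult:
    """Proportion of a total causal effect explained through a mediator.

    Parameters
    ----------
    beta_exp_med
        Effect of the exposure on the mediator (mediator units per exposure
        unit), sign included.
    or_med_out
        Odds ratio of the outcome per unit increase of the mediator.
    or_total
        Total odds ratio of the outcome per unit increase of the exposure.
    """
    if or_med_out <= 0 or or_total <= 0:
        raise ValueError("odds ratios must be positive")
    if or_total == 1.0:
        raise ValueError("total odds ratio of 1 leaves the proportion mediated undefined")
    logor_med_out = math.log(or_med_out)
    logor_total = math.log(or_total)
    indirect = beta_exp_med * logor_med_out
    proportion = indirect / logor_total
    return MediationResult(
        beta_exp_med=beta_exp_med,
        logor_med_out=logor_med_out,
        logor_total=logor_total,
        indirect=indirect,
        proportion=proportion,
        percent=round(proportion * 100.0),
    )


def invert_or(or_per_increase: float) -> float:
    """Odds ratio per unit decrease from the per-unit-increase value."""
    if or_per_increase <= 0:
        raise ValueError("odds ratio must be positive")
    return 1.0 / or_per_increase
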