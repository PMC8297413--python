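"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from mrsuite import HarmonizedInstrument, InstrumentSet, VariantAssociation


def make_inst(
    beta_exposure,
    beta_outcome,
    se_exposure=None,
    se_outcome=None,
    outcome_trait_type="continuous",
    n_exposure=100_000,
    n_outcome=100_000,
) -> InstrumentSet:
    """Build an InstrumentSet directly from coefficient arrays."""
    be = np.asarray(beta_exposure, dtype=float)
    bo = np.asarray(beta_outcome, dtype=float)
    se_e = np.full_like(be, 0.01) if se_exposure is None else np.asarray(se_exposure, float)
    se_o = np.full_like(bo, 0.01) if se_outcome is None else np.asarray(se_outcome, float)
    inst = InstrumentSet(
        exposure_name="exp",
        outcome_name="out",
        outcome_trait_type=outcome_trait_type,
        n_exposure=n_exposure,
        n_outcome=n_outcome,
    )
    for k in range(be.size):
        inst.instruments.append(
            HarmonizedInstrument(
                variant_id=f"v{k}",
                beta_exposure=float(be[k]),
                se_exposure=float(se_e[k]),
                beta_outcome=float(bo[k]),
                se_outcome=float(se_o[k]),
                ratio=float(bo[k] / be[k]),
                se_ratio=float(se_o[k] / abs(be[k])),
                action="kept",
            )
        )
    return inst


def random_inst(rng: np.random.Generator, j: int = 5, theta: float = 0.3) -> InstrumentSet:
    """A small random instrument set with true slope ``theta``."""
    be = rng.uniform(0.05, 0.2, size=j) * rng.choice([-1.0, 1.0], size=j)
    se_e = rng.uniform(0.003, 0.008, size=j)
    se_o = rng.uniform(0.005, 0.02, size=j)
    bo = theta * be + rng.normal(0.0, se_o)
    return make_inst(be, bo, se_e, se_o)


def variant(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-10, eaf=0.3,
            chrom="1", pos=1000, n=100_000) -> VariantAssociation:
    return VariantAssociation(
        variant_id=vid, chromosome=chrom, position=pos, effect_allele=ea,
        other_allele=oa, eaf=eaf, beta=beta, se=se, pvalue=p, n=n,
    )
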