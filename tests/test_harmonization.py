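"""Allele harmonization: orientation, palindromes, conservation, involution."""

import copy

import pytest

from mrsuite import (
    SimulationConfig,
    SummaryDataset,
    VariantAssociation,
    harmonize,
    simulate_pair,
    wald_ratio,
)
from mrsuite.harmonization import (
    EXCLUDED_MISMATCH,
    EXCLUDED_MISSING_OUTCOME,
    EXCLUDED_PALINDROMIC,
    KEPT,
    SIGN_FLIPPED,
    apply_proxies,
)

from helpers import variant


def _pair(exp_kw, out_kw):
    e = SummaryDataset("exp", [variant(**exp_kw)])
    o = SummaryDataset("out", [variant(**out_kw)])
    return e, o


def test_swapped_alleles_flip_outcome_sign():
    e, o = _pair(dict(ea="A", oa="G", beta=0.10, eaf=0.3),
                 dict(ea="G", oa="A", beta=-0.05, eaf=0.7))
    inst = harmonize(e, o)
    (i,) = inst.instruments
    assert i.action == SIGN_FLIPPED
    assert i.beta_outcome == pytest.approx(0.05)
    assert i.eaf_outcome == pytest.approx(0.3)


def test_same_orientation_kept_unchanged():
    e, o = _pair(dict(ea="A", oa="G", beta=0.10), dict(ea="A", oa="G", beta=0.02))
    (i,) = harmonize(e, o).instruments
    assert i.action == KEPT and i.beta_outcome == 0.02


def test_strand_complement_reconciled():
    # exposure A/G; outcome reported on the other strand as T/C
    e, o = _pair(dict(ea="A", oa="G", beta=0.10), dict(ea="T", oa="C", beta=0.02))
    (i,) = harmonize(e, o).instruments
    assert i.action == KEPT and i.beta_outcome == 0.02
    # complement plus swap: C/T
    e, o = _pair(dict(ea="A", oa="G", beta=0.10), dict(ea="C", oa="T", beta=0.02, eaf=0.7))
    (i,) = harmonize(e, o).instruments
    assert i.action == SIGN_FLIPPED and i.beta_outcome == -0.02


def test_palindromic_high_maf_excluded():
    e, o = _pair(dict(ea="A", oa="T", eaf=0.45), dict(ea="A", oa="T", eaf=0.45))
    inst = harmonize(e, o)
    assert len(inst) == 0
    assert inst.exclusions["rs1"] == EXCLUDED_PALINDROMIC


def test_palindromic_missing_eaf_excluded():
    e, o = _pair(dict(ea="G", oa="C", eaf=0.1), dict(ea="G", oa="C", eaf=None))
    assert harmonize(e, o).exclusions["rs1"] == EXCLUDED_PALINDROMIC


def test_palindromic_low_maf_oriented_by_frequency():
    # same minor-allele side: kept unchanged
    e, o = _pair(dict(ea="G", oa="C", eaf=0.10, beta=0.1), dict(ea="G", oa="C", eaf=0.12, beta=0.03))
    (i,) = harmonize(e, o).instruments
    assert i.action == KEPT and i.beta_outcome == 0.03
    # opposite side of 0.5: interpreted as the flipped orientation
    e, o = _pair(dict(ea="G", oa="C", eaf=0.10, beta=0.1), dict(ea="G", oa="C", eaf=0.88, beta=0.03))
    (i,) = harmonize(e, o).instruments
    assert i.action == SIGN_FLIPPED
    assert i.beta_outcome == pytest.approx(-0.03)
    assert i.eaf_outcome == pytest.approx(0.12)


def test_irreconcilable_alleles_excluded():
    e, o = _pair(dict(ea="A", oa="G"), dict(ea="A", oa="C"))
    assert harmonize(e, o).exclusions["rs1"] == EXCLUDED_MISMATCH


def test_variant_absent_from_outcome_gets_distinct_reason():
    e = SummaryDataset("exp", [variant(vid="rs1"), variant(vid="rs2", pos=2000)])
    o = SummaryDataset("out", [variant(vid="rs1")])
    inst = harmonize(e, o)
    assert inst.exclusions["rs2"] == EXCLUDED_MISSING_OUTCOME
    assert len(inst) == 1


def test_conservation_on_randomized_fixture():
    """retained + excluded = overlap, across random orientations/palindromes."""
    cfg = SimulationConfig(seed=11, J=40, palindromic_fraction=0.4, maf_range=(0.05, 0.49))
    e, o, _ = simulate_pair(cfg)
    inst = harmonize(e, o)
    assert len(inst) + len(inst.exclusions) == len(e)
    assert len(set(inst.variant_ids)) == len(inst)


def test_involution():
    """Harmonizing an already-harmonized pair changes nothing."""
    cfg = SimulationConfig(seed=7, J=20, palindromic_fraction=0.3, maf_range=(0.1, 0.49))
    e, o, _ = simulate_pair(cfg)
    first = harmonize(e, o)
    # rebuild datasets on the exposure orientation from the harmonized output
    e_recs, o_recs = [], []
    for i in first.instruments:
        src = e.get(i.variant_id)
        e_recs.append(copy.deepcopy(src))
        o_recs.append(
            VariantAssociation(
                variant_id=i.variant_id, chromosome=src.chromosome, position=src.position,
                effect_allele=src.effect_allele, other_allele=src.other_allele,
                eaf=i.eaf_outcome, beta=i.beta_outcome,
                se=i.se_outcome, pvalue=0.5, n=o.sample_size,
            )
        )
    second = harmonize(SummaryDataset("exp", e_recs), SummaryDataset("out", o_recs))
    assert len(second) == len(first)
    for a, b in zip(first.instruments, second.instruments):
        assert b.action == KEPT
        assert b.beta_outcome == pytest.approx(a.beta_outcome)
        assert b.ratio == pytest.approx(a.ratio)


def test_outcome_allele_column_swap_is_neutral():
    """Swapping the outcome file's two allele columns yields the same set."""
    cfg = SimulationConfig(seed=13, J=15, palindromic_fraction=0.0)
    e, o, _ = simulate_pair(cfg)
    swapped = SummaryDataset(
        "out",
        [
            VariantAssociation(
                variant_id=r.variant_id, chromosome=r.chromosome, position=r.position,
                effect_allele=r.other_allele, other_allele=r.effect_allele,
                eaf=1.0 - r.eaf, beta=-r.beta, se=r.se, pvalue=r.pvalue, n=r.n,
            )
            for r in o
        ],
    )
    a, b = harmonize(e, o), harmonize(e, swapped)
    assert a.variant_ids == b.variant_ids
    for x, y in zip(a.instruments, b.instruments):
        assert y.beta_outcome == pytest.approx(x.beta_outcome)
        assert y.ratio == pytest.approx(x.ratio)


def test_zero_exposure_beta_excluded_not_infinite():
    e = SummaryDataset("exp", [variant(beta=0.0)])
    o = SummaryDataset("out", [variant(beta=0.05)])
    inst = harmonize(e, o)
    assert len(inst) == 0 and "rs1" in inst.exclusions


@pytest.mark.parametrize(
    "beta_out,beta_exp,se_out,ratio,se_ratio",
    [
        (0.02, 0.10, 0.005, 0.2, 0.05),
        (0.0, 0.10, 0.005, 0.0, 0.05),
        (0.02, -0.10, 0.005, -0.2, 0.05),
    ],
)
def test_wald_ratio_arithmetic(beta_out, beta_exp, se_out, ratio, se_ratio):
    r, s = wald_ratio(beta_exp, beta_out, 0.01, se_out)
    assert r == pytest.approx(ratio) and s == pytest.approx(se_ratio)


def test_wald_ratio_zero_exposure_errors():
    with pytest.raises(ZeroDivisionError):
        wald_ratio(0.0, 0.1, 0.01, 0.01)


def test_second_order_se_exceeds_first_order():
    _, s1 = wald_ratio(0.1, 0.05, 0.02, 0.01)
    _, s2 = wald_ratio(0.1, 0.05, 0.02, 0.01, second_order=True)
    assert s2 > s1


def test_proxy_substitution_enforces_min_r2():
    e = SummaryDataset("exp", [variant(vid="rs1")])
    o = SummaryDataset("out", [variant(vid="rsProxy", beta=0.03)])
    with pytest.raises(ValueError):
        apply_proxies(o, {"rs1": ("rsProxy", 0.5)})
    o2 = apply_proxies(o, {"rs1": ("rsProxy", 0.95)})
    inst = harmonize(e, o2)
    assert inst.variant_ids == ["rs1"]
    assert inst.instruments[0].beta_outcome == pytest.approx(0.03)
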