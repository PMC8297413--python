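"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data a two-sample MR analysis consumes: two
independently drawn sets of summary statistics (exposure and outcome
samples share no individuals, enforced by independent random streams) under
a linear causal model

    Gamma_j = theta * gamma_j + alpha_j

where gamma_j is variant j's true effect on the exposure, alpha_j its
direct (pleiotropic) effect on the outcome — zero for valid instruments —
and theta the causal effect of interest.  Traits are standardized
(variance 1), so for an additive variant with minor-allele frequency m the
per-allele standard error has the closed form se = 1 / sqrt(2 n m (1 - m)).
Observed coefficients are the true values plus normal noise at that se;
p-values follow from the normal reference.

Alleles are assigned with a configurable fraction of palindromic (A/T or
G/C) pairs, and the outcome file's allele orientation is swapped at random
per variant, so harmonization is genuinely exercised.  Binary outcomes are
simulated directly on the log-odds scale (effects and standard errors);
the pipeline only ever consumes summary statistics.

Default parameter values mirror the serum-urate study design this package
is built around: exposure sample ~110,000, outcome sample ~95,000,
25 instruments with strengths spanning F ≈ 35–1400, and a causal effect of
−0.05 SD of outcome per unit exposure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import GeneRegion, LDInfo, SummaryDataset, VariantAssociation

NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass
class SimulationConfig:
    """All parameters of the synthetic two-sample generative model.

    ``gamma_dist`` is the (mean, sd) of true instrument effects on the
    standardized exposure; ``gamma_min`` truncates them from below so every
    intended instrument is genuinely genome-wide detectable.  ``pleiotropy``
    is ``(mode, mean, sd)`` with mode in {none, balanced, directional};
    invalid instruments receive direct outcome effects alpha ~ N(mean, sd)
    (balanced: mean 0).  ``n_null_snps`` adds background variants with no
    effect on either trait.
    """

    seed: int = 0
    J: int = 25
    n_exposure: int = 110_347
    n_outcome: int = 94_595
    theta: float = -0.05
    maf_range: tuple[float, float] = (0.05, 0.45)
    gamma_dist: tuple[float, float] = (0.08, 0.03)
    gamma_min: float = 0.02
    invalid_fraction: float = 0.0
    pleiotropy: tuple[str, float, float] = ("none", 0.0, 0.0)
    n_null_snps: int = 0
    binary_outcome: bool = False
    palindromic_fraction: float = 0.0
    region_layout: Sequence[GeneRegion] | None = None
    id_offset: int = 0  # shifts generated rs-ids so merged simulations stay disjoint

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range {self.maf_range} not well-ordered within (0, 1)")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction outside [0, 1]")
        if self.pleiotropy[0] not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy[0]!r}")
        if self.J <= 0:
            raise ValueError("J must be positive")


@dataclass
class FixtureBundle:
    """Everything a named scenario produces."""

    exposure: SummaryDataset
    outcome: SummaryDataset
    truth: dict
    regions: list[GeneRegion] = field(default_factory=list)
    ld: LDInfo = field(default_factory=LDInfo)
    config: SimulationConfig | None = None


def _se_closed_form(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _positions(n_variants: int, rng: np.random.Generator,
               regions: Sequence[GeneRegion] | None, n_instruments: int):
    """Chromosome/position layout.

    Default layout spaces variants 25,000 kb apart cycling over autosomes,
    well beyond any clumping window, so distance never binds unless a test
    constructs it on purpose.  With a region layout, instruments are placed
    round-robin inside the supplied intervals.
    """
    chroms: list[str] = []
    pos: list[int] = []
    for idx in range(n_variants):
        if regions and idx < n_instruments:
            reg = regions[idx % len(regions)]
            chroms.append(str(reg.chromosome))
            span = reg.end - reg.start
            offset = int(rng.integers(0, span + 1)) if span > 0 else 0
            pos.append(reg.start + offset)
        else:
            chroms.append(str(1 + idx % 22))
            pos.append(1_000_000 + (idx // 22) * 25_000_000)
    return chroms, pos


def simulate_pair(cfg: SimulationConfig) -> tuple[SummaryDataset, SummaryDataset, dict]:
    """Draw one exposure/outcome pair of summary datasets plus the truth record.

    The exposure and outcome samples use independent random streams spawned
    from ``cfg.seed`` (two-sample independence by construction).  The truth
    record stores theta, per-variant validity, direct effects, orientation
    swaps, and the instrument/null id lists.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_exp, ss_out = root.spawn(3)
    rng_layout = np.random.default_rng(ss_layout)
    rng_exp = np.random.default_rng(ss_exp)
    rng_out = np.random.default_rng(ss_out)

    j, n_total = cfg.J, cfg.J + cfg.n_null_snps
    maf = rng_layout.uniform(*cfg.maf_range, size=n_total)

    gamma_true = np.zeros(n_total)
    gamma_true[:j] = np.maximum(
        rng_layout.normal(cfg.gamma_dist[0], cfg.gamma_dist[1], size=j), cfg.gamma_min
    )

    n_invalid = int(round(cfg.invalid_fraction * j))
    valid = np.ones(n_total, dtype=bool)
    alpha = np.zeros(n_total)
    if n_invalid > 0 and cfg.pleiotropy[0] != "none":
        invalid_idx = rng_layout.choice(j, size=n_invalid, replace=False)
        valid[invalid_idx] = False
        mode, mu, sd = cfg.pleiotropy
        mean = 0.0 if mode == "balanced" else mu
        alpha[invalid_idx] = rng_layout.normal(mean, sd, size=n_invalid)

    gamma_out_true = cfg.theta * gamma_true + alpha

    se_exp = _se_closed_form(cfg.n_exposure, maf)
    se_out = _se_closed_form(cfg.n_outcome, maf)
    beta_exp = rng_exp.normal(gamma_true, se_exp)
    beta_out = rng_out.normal(gamma_out_true, se_out)
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp) / se_exp)
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out) / se_out)

    is_palindromic = rng_layout.random(n_total) < cfg.palindromic_fraction
    pair_idx = rng_layout.integers(0, 8, size=n_total)
    swap = rng_layout.random(n_total) < 0.5

    chroms, positions = _positions(n_total, rng_layout, cfg.region_layout, j)

    ids = [f"rs{900000 + cfg.id_offset + k}" for k in range(n_total)]
    exp_records: list[VariantAssociation] = []
    out_records: list[VariantAssociation] = []
    for k in range(n_total):
        if is_palindromic[k]:
            ea, oa = PALINDROMIC_PAIRS[pair_idx[k] % 4]
        else:
            ea, oa = NON_PALINDROMIC_PAIRS[pair_idx[k]]
        eaf = float(maf[k])  # effect allele is the minor allele by construction
        exp_records.append(
            VariantAssociation(
                variant_id=ids[k], chromosome=chroms[k], position=positions[k],
                effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=float(beta_exp[k]), se=float(se_exp[k]),
                pvalue=float(max(p_exp[k], np.finfo(float).tiny)),
                n=cfg.n_exposure,
            )
        )
        if swap[k]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -float(beta_out[k]), 1.0 - eaf
        else:
            o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_out[k]), eaf
        out_records.append(
            VariantAssociation(
                variant_id=ids[k], chromosome=chroms[k], position=positions[k],
                effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
                beta=o_beta, se=float(se_out[k]),
                pvalue=float(max(p_out[k], np.finfo(float).tiny)),
                n=cfg.n_outcome,
            )
        )

    exposure = SummaryDataset(
        trait_name="sim_exposure", records=exp_records, trait_type="continuous",
        effect_scale="raw-units", sample_size=cfg.n_exposure,
    )
    outcome = SummaryDataset(
        trait_name="sim_outcome", records=out_records,
        trait_type="binary" if cfg.binary_outcome else "continuous",
        effect_scale="log-odds" if cfg.binary_outcome else "SD",
        sample_size=cfg.n_outcome,
    )
    truth = {
        "theta": cfg.theta,
        "instrument_ids": ids[:j],
        "null_ids": ids[j:],
        "valid": {ids[k]: bool(valid[k]) for k in range(j)},
        "alpha": {ids[k]: float(alpha[k]) for k in range(j)},
        "gamma_true": {ids[k]: float(gamma_true[k]) for k in range(j)},
        "swapped": {ids[k]: bool(swap[k]) for k in range(n_total)},
        "palindromic": {ids[k]: bool(is_palindromic[k]) for k in range(n_total)},
    }
    return exposure, outcome, truth


def _force_palindromic_high_maf(
    exposure: SummaryDataset, outcome: SummaryDataset, truth: dict, variant_ids: Sequence[str]
) -> None:
    """Rewrite chosen variants as A/T with MAF near 0.5 in both datasets.

    Such variants survive selection but fall to the palindromic-frequency
    exclusion during harmonization — mirroring how strand-ambiguous
    instruments drop out of a real analysis.
    """
    for vid in variant_ids:
        for ds in (exposure, outcome):
            rec = ds.get(vid)
            rec.effect_allele, rec.other_allele = "A", "T"
            rec.eaf = 0.45
        truth["palindromic"][vid] = True


# GRCh37-style intervals for the urate-transporter candidate genes
URATE_TRANSPORTER_REGIONS = [
    GeneRegion("ABCG2", "4", 89_000_000, 89_200_000),
    GeneRegion("SLC2A9", "4", 9_800_000, 10_100_000),
    GeneRegion("SLC22A12", "11", 64_350_000, 64_460_000),
    GeneRegion("SLC22A11", "11", 64_250_000, 64_350_000),
    GeneRegion("SLC17A1", "6", 25_780_000, 25_830_000),
    GeneRegion("SLC17A3", "6", 25_830_000, 25_900_000),
]

SCENARIOS = ("statistical_27", "biological_15", "reverse_85")


def study_scale_fixture(scenario: str, seed: int = 0) -> FixtureBundle:
    """Configure the generator to match a named study-scale scenario.

    * ``statistical_27`` — 27 genome-wide-significant instruments among 100
      background variants; two of them palindromic at MAF 0.45, so 25
      instruments survive harmonization.
    * ``biological_15`` — 15 significant instruments placed inside the six
      urate-transporter gene regions, mutually independent.
    * ``reverse_85`` — 87 significant instruments, two palindromic at high
      MAF, leaving 85 (the outcome-to-exposure direction at study scale).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")

    if scenario == "statistical_27":
        cfg = SimulationConfig(
            seed=seed, J=27, n_null_snps=100, theta=-0.05,
            maf_range=(0.10, 0.45), gamma_dist=(0.12, 0.03), gamma_min=0.09,
        )
        exposure, outcome, truth = simulate_pair(cfg)
        _force_palindromic_high_maf(exposure, outcome, truth, truth["instrument_ids"][:2])
        return FixtureBundle(exposure, outcome, truth, config=cfg)

    if scenario == "biological_15":
        regions = URATE_TRANSPORTER_REGIONS
        # 3+6+4+1+1 instruments over five genes (round-robin placement keeps
        # counts close; what matters is all 15 sit inside candidate regions)
        cfg = SimulationConfig(
            seed=seed, J=15, n_null_snps=100, theta=-0.05,
            maf_range=(0.10, 0.45), gamma_dist=(0.12, 0.03), gamma_min=0.09,
            region_layout=regions[:5],
        )
        exposure, outcome, truth = simulate_pair(cfg)
        return FixtureBundle(exposure, outcome, truth, regions=list(regions), config=cfg)

    # reverse_85
    cfg = SimulationConfig(
        seed=seed, J=87, n_null_snps=100, theta=-0.09,
        maf_range=(0.10, 0.45), gamma_dist=(0.10, 0.03), gamma_min=0.08,
    )
    exposure, outcome, truth = simulate_pair(cfg)
    _force_palindromic_high_maf(exposure, outcome, truth, truth["instrument_ids"][:2])
    return FixtureBundle(exposure, outcome, truth, config=cfg)


def write_fixture(bundle: FixtureBundle, out_prefix: str) -> None:
    """Write a fixture's tables: two summary TSVs, regions BED, truth JSON."""
    from .summary_data import write_summary_table

    write_summary_table(bundle.exposure, f"{out_prefix}_exposure.tsv")
    write_summary_table(bundle.outcome, f"{out_prefix}_outcome.tsv")
    if bundle.regions:
        with open(f"{out_prefix}_regions.bed", "w") as fh:
            for r in bundle.regions:
                fh.write(f"{r.gene_name}\t{r.chromosome}\t{r.start}\t{r.end}\n")
    with open(f"{out_prefix}_truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    if bundle.config is not None:
        with open(f"{out_prefix}_config.json", "w") as fh:
            cfg_dict = dataclasses.asdict(bundle.config)
            cfg_dict["region_layout"] = (
                [dataclasses.asdict(r) for r in bundle.config.region_layout]
                if bundle.config.region_layout
                else None
            )
            json.dump(cfg_dict, fh, indent=1)
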