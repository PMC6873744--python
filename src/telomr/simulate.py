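"""Synthetic two-sample summary statistics with known causal truth.

The generator emulates the statistical structure the estimators assume:
per-SNP true exposure effects ``gamma_i`` drawn uniformly from a range
matching real instrument magnitudes, observed exposure betas
``b_exp_i ~ N(gamma_i, se_exp)``, and outcome betas
``b_out_i ~ N(beta_true * gamma_i + alpha_i, se_out)`` where ``alpha_i`` is
a horizontal-pleiotropy effect for the configured fraction of invalid
instruments. Pleiotropy regimes: ``balanced`` (mean-zero), ``directional``
(non-zero mean, InSIDE holds), and ``inside_violated`` (pleiotropy
correlated with instrument strength). Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clumping import LDMatrix
from .errors import ConfigError
from .summary_data import GwasSummaryRecord, HarmonizedInstrument, InstrumentPanel

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating-model parameters for one synthetic instrument panel.

    Defaults mirror the magnitudes of real telomere-length instruments:
    exposure effects of 0.02-0.15 SD per allele with SE ~0.012, outcome
    (log-odds) SEs ~0.003.
    """

    n_snps: int = 50
    beta_true: float = 0.0
    exposure_effect_range: tuple[float, float] = (0.02, 0.15)
    se_exposure_scale: float = 0.012
    se_outcome_scale: float = 0.003
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    prop_invalid: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.exposure_effect_range
        if not (0 < lo <= hi):
            raise ConfigError("exposure_effect_range must be ordered and positive")
        if self.se_exposure_scale <= 0 or self.se_outcome_scale <= 0:
            raise ConfigError("SE scales must be > 0")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not (0 <= self.prop_invalid <= 1):
            raise ConfigError("prop_invalid must be in [0, 1]")
        if self.prop_invalid > 0 and self.pleiotropy_mode == "none":
            raise ConfigError("invalid instruments require a pleiotropy mode")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """The generating values behind one panel: what estimators should recover."""

    beta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray  # boolean flags
    seed: int


def simulate_panel(config: SimulationConfig) -> tuple[InstrumentPanel, SyntheticTruth]:
    """Draw one instrument panel and its generating truth from the config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    lo, hi = config.exposure_effect_range
    gamma = rng.uniform(lo, hi, n)
    sx = np.full(n, config.se_exposure_scale)
    sy = np.full(n, config.se_outcome_scale)

    n_invalid = int(round(config.prop_invalid * n))
    invalid = np.zeros(n, dtype=bool)
    if n_invalid:
        invalid[rng.choice(n, size=n_invalid, replace=False)] = True

    alpha = np.zeros(n)
    if n_invalid:
        if config.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, config.pleiotropy_sd, n_invalid)
        elif config.pleiotropy_mode == "directional":
            alpha[invalid] = rng.normal(
                config.pleiotropy_mean, config.pleiotropy_sd, n_invalid
            )
        elif config.pleiotropy_mode == "inside_violated":
            # pleiotropy proportional to instrument strength (violates InSIDE),
            # scaled so its mean over invalid SNPs equals pleiotropy_mean
            g = gamma[invalid]
            alpha[invalid] = config.pleiotropy_mean * g / np.mean(g) + rng.normal(
                0.0, config.pleiotropy_sd, n_invalid
            )

    bx = rng.normal(gamma, sx)
    by = rng.normal(config.beta_true * gamma + alpha, sy)
    instruments = tuple(
        HarmonizedInstrument(
            snp_id=f"snp{i + 1:04d}",
            beta_exposure=float(abs(bx[i])) or 1e-12,
            se_exposure=float(sx[i]),
            beta_outcome=float(by[i] if bx[i] >= 0 else -by[i]),
            se_outcome=float(sy[i]),
            action="unchanged",
        )
        for i in range(n)
    )
    panel = InstrumentPanel(instruments=instruments)
    truth = SyntheticTruth(
        beta_true=config.beta_true, gamma=gamma, alpha=alpha,
        invalid=invalid, seed=config.seed,
    )
    return panel, truth


def simulate_gwas_records(
    config: SimulationConfig,
) -> tuple[list[GwasSummaryRecord], list[GwasSummaryRecord], SyntheticTruth]:
    """Full exposure/outcome record tables for one synthetic panel.

    SNPs are placed on chromosome 1 at 3-Mb spacing (outside any clumping
    window) with A/G alleles and matching frequencies in both sources, so
    downstream harmonization and clumping are exercised end to end.
    """
    panel, truth = simulate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    from scipy import stats as _stats

    exposure, outcome = [], []
    for i, instr in enumerate(panel.instruments):
        freq = float(rng.uniform(0.1, 0.9))
        common = dict(
            snp_id=instr.snp_id,
            chromosome="1",
            position=(i + 1) * 3_000_000,
            effect_allele="A",
            other_allele="G",
        )
        p_exp = float(2 * _stats.norm.sf(abs(instr.beta_exposure / instr.se_exposure)))
        p_out = float(2 * _stats.norm.sf(abs(instr.beta_outcome / instr.se_outcome)))
        exposure.append(
            GwasSummaryRecord(
                effect_allele_freq=freq,
                beta=instr.beta_exposure,
                se=instr.se_exposure,
                p_value=max(p_exp, 5e-324),
                **common,
            )
        )
        outcome.append(
            GwasSummaryRecord(
                effect_allele_freq=freq,
                beta=instr.beta_outcome,
                se=instr.se_outcome,
                p_value=max(p_out, 5e-324),
                **common,
            )
        )
    return exposure, outcome, truth


def simulate_ld_blocks(
    records: list[GwasSummaryRecord] | list[HarmonizedInstrument],
    block_of: dict[str, str],
    r2_within: float = 0.8,
) -> LDMatrix:
    """Block LD matrix: ``r2_within`` inside a shared block, 0 elsewhere."""
    if not (0 <= r2_within <= 1):
        raise ConfigError("r2_within must be in [0, 1]")
    ids = [r.snp_id for r in records]
    unmapped = [s for s in ids if s not in block_of]
    if unmapped:
        raise ConfigError(f"SNPs missing from block mapping: {unmapped}")
    n = len(ids)
    r2 = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if block_of[ids[i]] == block_of[ids[j]]:
                r2[i, j] = r2[j, i] = r2_within
    return LDMatrix(snp_ids=tuple(ids), r2=r2)


def replicate_seeds(root_seed: int, n_replicates: int) -> list[int]:
    """Stream independent per-replicate seeds from a single root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(n_replicates)
    return [int(s % (2**31)) for s in state]
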