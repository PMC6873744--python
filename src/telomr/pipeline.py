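"""End-to-end pipeline: load -> harmonize -> clump -> estimate -> diagnose -> report.

`run_pipeline` executes the stages in order, logging per-stage record counts,
and returns a ReportBundle whose tables are also written to the output
directory as TSV/JSON. With a fixed config and seeds the bundle is
byte-identical across runs. ``packaged_study_config()`` builds the configuration that
reproduces the packaged telomere-length -> Alzheimer's disease study from
the bundled 16-SNP instrument table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clumping import LDMatrix, greedy_clump, locus_blocks
from .diagnostics import cochran_q, leave_one_out, mr_presso
from .errors import ConfigError
from .estimators import (
    MREstimate,
    all_estimates,
    egger,
    ivw,
    wald_ratio,
)
from .simulate import simulate_ld_blocks
from .summary_data import (
    build_panel,
    harmonize_tables,
    load_packaged_instruments,
    read_gwas_table,
)

logger = logging.getLogger(__name__)

#: column map for the packaged fixture layout
FIXTURE_EXPOSURE_COLUMNS = {
    "snp_id": "SNP", "chromosome": "Chr", "position": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "effect_allele_freq": "Freq_TL", "beta": "Beta_TL",
    "se": "SE_TL", "p_value": "P_TL", "gene_label": "Gene",
}
FIXTURE_OUTCOME_COLUMNS = {
    **FIXTURE_EXPOSURE_COLUMNS,
    "effect_allele_freq": "Freq_AD", "beta": "Beta_AD",
    "se": "SE_AD", "p_value": "P_AD",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly."""

    exposure_path: str | None = None   # None -> packaged instrument table
    outcome_path: str | None = None
    exposure_columns: dict = field(default_factory=lambda: dict(FIXTURE_EXPOSURE_COLUMNS))
    outcome_columns: dict = field(default_factory=lambda: dict(FIXTURE_OUTCOME_COLUMNS))
    ld_path: str | None = None         # None -> locus-block LD from gene labels
    ld_r2_within: float = 0.8
    ld_proximity_bp: int = 200_000
    r2_max: float = 0.001
    window_bp: int = 2_000_000
    palindrome_maf_limit: float = 0.42
    variance_model: str = "multiplicative_re"
    ratio_se: str = "first_order"
    phi: float = 1.0
    n_boot: int = 1000
    presso_n_sim: int = 5000
    seed: int = 20190843
    sign_convention: str = "per_sd_decrease"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def packaged_study_config(out_dir: str | None = None, **overrides) -> PipelineConfig:
    """Configuration reproducing the packaged telomere->AD study run."""
    return PipelineConfig(out_dir=out_dir, **overrides)


@dataclass(frozen=True)
class ReportBundle:
    """All pipeline outputs: estimate/diagnostic tables plus plot data."""

    estimates: pd.DataFrame
    diagnostics: dict
    loo: pd.DataFrame
    clump_audit: pd.DataFrame
    scatter_data: pd.DataFrame
    forest_data: pd.DataFrame
    provenance: dict


def _estimate_row(est: MREstimate) -> dict:
    return {
        "method": est.method,
        "n_snps": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_value": est.p_value,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "convention": est.convention,
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write its artifacts."""
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    _stage("load")
    if config.exposure_path is None or config.outcome_path is None:
        exposure, outcome = load_packaged_instruments()
    else:
        exposure = read_gwas_table(config.exposure_path, config.exposure_columns)
        outcome = read_gwas_table(config.outcome_path, config.outcome_columns)
    logger.info("loaded %d exposure / %d outcome records", len(exposure), len(outcome))

    _stage("clump")
    if config.ld_path is not None:
        ld = LDMatrix.from_table(config.ld_path)
    else:
        blocks = locus_blocks(exposure, proximity_bp=config.ld_proximity_bp)
        ld = simulate_ld_blocks(exposure, blocks, r2_within=config.ld_r2_within)
    clump = greedy_clump(exposure, ld, r2_max=config.r2_max, window_bp=config.window_bp)
    logger.info("clumping kept %d of %d SNPs", clump.n_kept, len(exposure))

    _stage("harmonize")
    kept_ids = set(clump.kept)
    harmonized = harmonize_tables(
        [r for r in exposure if r.snp_id in kept_ids],
        [r for r in outcome if r.snp_id in kept_ids],
        palindrome_maf_limit=config.palindrome_maf_limit,
    )
    panel = build_panel(harmonized, sign_convention=config.sign_convention)

    _stage("estimate")
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    estimates = all_estimates(
        panel,
        variance_model=config.variance_model,
        phi=config.phi,
        n_boot=config.n_boot,
        seed=int(seeds[0]),
        ratio_se=config.ratio_se,
    )
    est_df = pd.DataFrame([_estimate_row(e) for e in estimates])

    _stage("diagnose")
    q_ivw = cochran_q(panel, context="ivw")
    q_egger = cochran_q(panel, context="egger")
    egger_fit = egger(panel)
    presso = mr_presso(panel, n_sim=config.presso_n_sim, seed=int(seeds[1]))
    loo = leave_one_out(panel)
    diagnostics = {
        "heterogeneity": {
            "ivw": {"Q": q_ivw.statistic, "df": q_ivw.df, "p_value": q_ivw.p_value},
            "egger": {"Q": q_egger.statistic, "df": q_egger.df, "p_value": q_egger.p_value},
        },
        "egger_intercept": {
            "value": egger_fit.intercept,
            "se": egger_fit.intercept_se,
            "p_value": egger_fit.intercept_p,
        },
        "mr_presso": {
            "rss_observed": presso.rss_observed,
            "global_p": presso.global_p,
            "outliers": list(presso.outliers),
            "per_snp_outlier_p": dict(presso.per_snp_outlier_p),
            "distortion_p": presso.distortion_p,
            "n_sim": presso.n_sim,
            "seed": presso.seed,
        },
    }

    _stage("report")
    loo_df = pd.DataFrame(
        [{"excluded_snp": snp, **_estimate_row(e)} for snp, e in loo.entries]
    )
    audit_rows = [
        {"snp_id": s, "kept": True, "index_snp": "", "r2": np.nan, "reason": ""}
        for s in clump.kept
    ] + [
        {"snp_id": s, "kept": False, "index_snp": rm.index_snp, "r2": rm.r2,
         "reason": rm.reason}
        for s, rm in clump.removed.items()
    ]
    audit_df = pd.DataFrame(audit_rows)

    scatter_df = pd.DataFrame({
        "snp_id": panel.snp_ids,
        "beta_exposure": panel.beta_exposure,
        "se_exposure": panel.se_exposure,
        "beta_outcome": panel.beta_outcome,
        "se_outcome": panel.se_outcome,
    })
    # fitted slopes on the per-SD-increase working scale, plus Egger intercept
    sign = -1.0 if config.sign_convention == "per_sd_decrease" else 1.0
    for est in estimates:
        scatter_df[f"slope_{est.method}"] = sign * est.beta
    scatter_df["egger_intercept"] = egger_fit.intercept

    forest_rows = []
    for instr in panel.instruments:
        wr = wald_ratio(instr, convention=config.sign_convention)
        forest_rows.append({"snp_id": instr.snp_id, **_estimate_row(wr)})
    forest_df = pd.DataFrame(forest_rows)

    cfg = config.to_dict()
    cfg.pop("out_dir")  # analytic config only: bundles from different dirs compare equal
    provenance = {
        "package": "telomr",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {"estimators": int(seeds[0]), "presso": int(seeds[1])},
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_instruments": panel.n_snps,
    }

    bundle = ReportBundle(
        estimates=est_df,
        diagnostics=diagnostics,
        loo=loo_df,
        clump_audit=audit_df,
        scatter_data=scatter_df,
        forest_data=forest_df,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
    bundle.loo.to_csv(out / "loo.tsv", sep="\t", index=False)
    bundle.clump_audit.to_csv(out / "clump_audit.tsv", sep="\t", index=False)
    bundle.scatter_data.to_csv(out / "scatter_data.tsv", sep="\t", index=False)
    bundle.forest_data.to_csv(out / "forest_data.tsv", sep="\t", index=False)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(bundle.diagnostics, fh, indent=2, sort_keys=True)
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)


def render_plots(bundle: ReportBundle, out_dir) -> list[str]:
    """Optionally draw scatter/forest/leave-one-out figures (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = bundle.scatter_data
    ax.errorbar(sc["beta_exposure"], sc["beta_outcome"],
                xerr=sc["se_exposure"], yerr=sc["se_outcome"],
                fmt="o", ms=3, lw=0.8, color="k")
    xs = np.linspace(0, sc["beta_exposure"].max() * 1.05, 50)
    for col in [c for c in sc.columns if c.startswith("slope_")]:
        slope = sc[col].iloc[0]
        icpt = sc["egger_intercept"].iloc[0] if col == "slope_egger_slope" else 0.0
        ax.plot(xs, icpt + slope * xs, label=col.removeprefix("slope_"))
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "scatter.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))

    for name, df, label in [
        ("forest.png", bundle.forest_data, "snp_id"),
        ("leave_one_out.png", bundle.loo, "excluded_snp"),
    ]:
        fig, ax = plt.subplots(figsize=(5, 0.3 * len(df) + 1.5))
        y = np.arange(len(df))
        ax.errorbar(df["beta"], y,
                    xerr=[df["beta"] - df["ci_low"], df["ci_high"] - df["beta"]],
                    fmt="o", ms=3, color="k")
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y, df[label])
        ax.set_xlabel("log OR per SD")
        ax.invert_yaxis()
        fig.tight_layout()
        p = out / name
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(str(p))
    return written
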