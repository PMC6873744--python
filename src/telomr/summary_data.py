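"""GWAS summary statistics: records, table reading, and allele harmonization.

Two-sample Mendelian randomization needs, for every instrument SNP, the
exposure and outcome association statistics expressed for the *same* effect
allele. This module provides the per-SNP record type, a delimited-table
reader with per-row validation, the harmonization step that aligns the two
GWAS sources (allele flips, strand complements, palindromic-SNP frequency
inference), and the packaged 16-SNP telomere-length / Alzheimer's disease
instrument table used by the reproduction pipeline.

Conventions
-----------
Exposure betas are in SD units of the exposure per effect allele; outcome
betas are log odds ratios per the same allele. After harmonization every
retained instrument is oriented so that ``beta_exposure > 0`` (the effect
allele is the exposure-increasing allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))

#: fields of GwasSummaryRecord that a column map must cover
REQUIRED_FIELDS = (
    "snp_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "effect_allele_freq",
    "beta",
    "se",
    "p_value",
)
OPTIONAL_FIELDS = ("gene_label",)

_FIXTURE = "telomere_ad_instruments.tsv"


@dataclass(frozen=True)
class GwasSummaryRecord:
    """One SNP's association summary in one GWAS.

    ``beta`` is per copy of ``effect_allele``: SD units for a quantitative
    exposure, log odds for a binary outcome.
    """

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_allele_freq: float
    beta: float
    se: float
    p_value: float
    gene_label: str | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p_value must be in (0, 1], got {self.p_value}")
        if not (0 <= self.effect_allele_freq <= 1):
            raise ValueError(
                f"{self.snp_id}: effect_allele_freq must be in [0, 1], "
                f"got {self.effect_allele_freq}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be > 0, got {self.position}")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in COMPLEMENT:
                raise ValueError(f"{self.snp_id}: allele {allele!r} is not one of A/C/G/T")

    @property
    def minor_allele_freq(self) -> float:
        return min(self.effect_allele_freq, 1.0 - self.effect_allele_freq)

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variant: strand cannot be resolved from alleles alone."""
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_SETS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects aligned to a common effect allele.

    ``action`` records what harmonization did: ``unchanged``,
    ``allele_flipped`` (outcome effect re-signed to the exposure's effect
    allele and/or both betas negated to orient the exposure-increasing
    allele), or ``dropped`` with ``reason`` one of ``ambiguous`` /
    ``incompatible``.
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    action: str
    reason: str | None = None

    def __post_init__(self):
        if self.action not in ("unchanged", "allele_flipped", "dropped"):
            raise ValueError(f"invalid action {self.action!r}")
        if self.action != "dropped":
            if self.se_exposure <= 0 or self.se_outcome <= 0:
                raise ValueError(f"{self.snp_id}: standard errors must be > 0")
            if self.beta_exposure <= 0:
                raise ValueError(
                    f"{self.snp_id}: beta_exposure must be > 0 after orientation"
                )

    @property
    def dropped(self) -> bool:
        return self.action == "dropped"

    @property
    def wald_ratio_point(self) -> float:
        return self.beta_outcome / self.beta_exposure


@dataclass(frozen=True)
class InstrumentPanel:
    """Ordered, de-duplicated set of harmonized instruments.

    ``sign_convention`` declares how pooled estimates are reported:
    ``per_sd_increase`` (the internal working scale) or ``per_sd_decrease``
    (log odds negated at report time).
    """

    instruments: tuple[HarmonizedInstrument, ...]
    sign_convention: str = "per_sd_increase"

    def __post_init__(self):
        if self.sign_convention not in ("per_sd_increase", "per_sd_decrease"):
            raise ValueError(f"invalid sign convention {self.sign_convention!r}")
        if len(self.instruments) < 1:
            raise ValueError("panel needs at least one instrument")
        ids = [i.snp_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_ids in panel")
        if any(i.dropped for i in self.instruments):
            raise ValueError("dropped instruments cannot enter a panel")

    @property
    def n_snps(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(i.snp_id for i in self.instruments)

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([i.beta_exposure for i in self.instruments])

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([i.se_exposure for i in self.instruments])

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([i.beta_outcome for i in self.instruments])

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([i.se_outcome for i in self.instruments])

    def subset(self, keep: Iterable[str] | None = None, exclude: Iterable[str] = ()) -> "InstrumentPanel":
        exclude = set(exclude)
        keep = set(keep) if keep is not None else None
        chosen = tuple(
            i
            for i in self.instruments
            if i.snp_id not in exclude and (keep is None or i.snp_id in keep)
        )
        return replace(self, instruments=chosen)

    def with_convention(self, sign_convention: str) -> "InstrumentPanel":
        return replace(self, sign_convention=sign_convention)


def read_gwas_table(
    path,
    column_map: Mapping[str, str],
    *,
    delimiter: str | None = None,
) -> list[GwasSummaryRecord]:
    """Read a delimited GWAS summary table into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Maps record field names (see ``REQUIRED_FIELDS``) to column names in
        the file, so arbitrary GWAS dialects load without rewriting files.
    delimiter
        Explicit delimiter; sniffed from the header when omitted.

    Rows violating record invariants (non-positive SE, p outside (0,1],
    non-numeric beta, ...) are rejected individually with a row-indexed log
    warning; a missing mapped column raises :class:`ConfigError`.
    """
    missing_fields = [f for f in REQUIRED_FIELDS if f not in column_map]
    if missing_fields:
        raise ConfigError(f"column_map lacks required fields: {missing_fields}")
    df = pd.read_csv(path, sep=delimiter, engine="python")
    missing_cols = [
        column_map[f] for f in REQUIRED_FIELDS if column_map[f] not in df.columns
    ]
    if missing_cols:
        raise ConfigError(f"{path}: mapped columns absent from header: {missing_cols}")
    if df.empty:
        logger.warning("%s: empty data section, returning no records", path)
        return []

    records: list[GwasSummaryRecord] = []
    for idx, row in df.iterrows():
        try:
            kwargs = {
                "snp_id": str(row[column_map["snp_id"]]),
                "chromosome": str(row[column_map["chromosome"]]),
                "position": int(row[column_map["position"]]),
                "effect_allele": str(row[column_map["effect_allele"]]).upper(),
                "other_allele": str(row[column_map["other_allele"]]).upper(),
                "effect_allele_freq": float(row[column_map["effect_allele_freq"]]),
                "beta": float(row[column_map["beta"]]),
                "se": float(row[column_map["se"]]),
                "p_value": float(row[column_map["p_value"]]),
            }
            if "gene_label" in column_map and column_map["gene_label"] in df.columns:
                val = row[column_map["gene_label"]]
                kwargs["gene_label"] = None if pd.isna(val) else str(val)
            records.append(GwasSummaryRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            logger.warning("%s: rejecting row %d: %s", path, idx, exc)
    return records


def _fixture_frame() -> pd.DataFrame:
    with resources.as_file(resources.files("telomr").joinpath("data", _FIXTURE)) as p:
        return pd.read_csv(p, sep="\t")


def load_packaged_instruments() -> tuple[list[GwasSummaryRecord], list[GwasSummaryRecord]]:
    """Load the packaged 16-SNP telomere-length / AD instrument table.

    Returns ``(exposure_records, outcome_records)``, 16 each, already aligned
    to a common effect allele (the telomere-lengthening allele; all exposure
    betas positive). Exposure statistics come from the 9,190-participant
    telomere-length GWAS meta-analysis; outcome statistics from the
    71,880-case / 383,378-control AD GWAS.
    """
    df = _fixture_frame()
    exposure, outcome = [], []
    for _, row in df.iterrows():
        common = dict(
            snp_id=row["SNP"],
            chromosome=str(row["Chr"]),
            position=int(row["BP"]),
            effect_allele=row["A1"],
            other_allele=row["A2"],
            gene_label=row["Gene"],
        )
        exposure.append(
            GwasSummaryRecord(
                effect_allele_freq=float(row["Freq_TL"]),
                beta=float(row["Beta_TL"]),
                se=float(row["SE_TL"]),
                p_value=float(row["P_TL"]),
                **common,
            )
        )
        outcome.append(
            GwasSummaryRecord(
                effect_allele_freq=float(row["Freq_AD"]),
                beta=float(row["Beta_AD"]),
                se=float(row["SE_AD"]),
                p_value=float(row["P_AD"]),
                **common,
            )
        )
    return exposure, outcome


def load_packaged_removed() -> set[str]:
    """SNPs flagged as removed by LD clumping in the packaged study table."""
    df = _fixture_frame()
    return set(df.loc[df["Removed"] == "Yes", "SNP"])


def harmonize_pair(
    exposure: GwasSummaryRecord,
    outcome: GwasSummaryRecord,
    palindrome_maf_limit: float = 0.42,
    freq_warn_diff: float = 0.1,
) -> HarmonizedInstrument:
    """Align one SNP's outcome statistics to the exposure's effect allele.

    Resolution order: same alleles in order -> unchanged; reversed ->
    outcome beta negated (frequency complemented); resolvable only by strand
    complement -> complement then apply the above. Palindromic (A/T, C/G)
    SNPs cannot be resolved from alleles; they are kept, with strand inferred
    from allele frequency, only when the exposure minor-allele frequency is
    below ``palindrome_maf_limit``, else dropped as ambiguous. Finally the
    instrument is oriented so ``beta_exposure > 0``.

    A large aligned-frequency discrepancy between the two sources is logged
    as a warning but does not drop the SNP.
    """
    if exposure.snp_id != outcome.snp_id:
        raise DataError(
            f"cannot harmonize different SNPs {exposure.snp_id!r} / {outcome.snp_id!r}"
        )

    def _dropped(reason: str) -> HarmonizedInstrument:
        logger.warning("%s dropped during harmonization: %s", exposure.snp_id, reason)
        return HarmonizedInstrument(
            snp_id=exposure.snp_id,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=outcome.beta,
            se_outcome=outcome.se,
            action="dropped",
            reason=reason,
        )

    exp_set = frozenset((exposure.effect_allele, exposure.other_allele))
    out_set = frozenset((outcome.effect_allele, outcome.other_allele))
    comp_out = frozenset(COMPLEMENT[a] for a in out_set)

    if exposure.is_palindromic:
        if out_set != exp_set:
            return _dropped("incompatible")
        if exposure.minor_allele_freq >= palindrome_maf_limit:
            return _dropped("ambiguous")
        # infer strand/orientation from which side of 0.5 the frequencies fall
        flip = (exposure.effect_allele_freq - 0.5) * (outcome.effect_allele_freq - 0.5) < 0
    else:
        exp_pair = (exposure.effect_allele, exposure.other_allele)
        out_pair = (outcome.effect_allele, outcome.other_allele)
        comp_pair = tuple(COMPLEMENT[a] for a in out_pair)
        if out_pair == exp_pair:
            flip = False
        elif out_pair == (exp_pair[1], exp_pair[0]):
            flip = True
        elif comp_pair == exp_pair:
            flip = False
        elif comp_pair == (exp_pair[1], exp_pair[0]):
            flip = True
        else:
            return _dropped("incompatible")

    beta_outcome = -outcome.beta if flip else outcome.beta
    out_freq_aligned = 1.0 - outcome.effect_allele_freq if flip else outcome.effect_allele_freq
    if abs(exposure.effect_allele_freq - out_freq_aligned) > freq_warn_diff:
        logger.warning(
            "%s: effect-allele frequency discordance between sources (%.2f vs %.2f)",
            exposure.snp_id,
            exposure.effect_allele_freq,
            out_freq_aligned,
        )

    beta_exposure = exposure.beta
    oriented = False
    if beta_exposure < 0:  # orient to the exposure-increasing allele
        beta_exposure = -beta_exposure
        beta_outcome = -beta_outcome
        oriented = True
    elif beta_exposure == 0:
        return _dropped("null exposure effect")

    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        beta_exposure=beta_exposure,
        se_exposure=exposure.se,
        beta_outcome=beta_outcome,
        se_outcome=outcome.se,
        action="allele_flipped" if (flip or oriented) else "unchanged",
    )


def harmonize_tables(
    exposure: Sequence[GwasSummaryRecord],
    outcome: Sequence[GwasSummaryRecord],
    palindrome_maf_limit: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Harmonize all SNPs present in both sources, keeping exposure order."""
    out_by_id = {r.snp_id: r for r in outcome}
    harmonized = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            logger.warning("%s absent from outcome source; skipped", exp.snp_id)
            continue
        harmonized.append(
            harmonize_pair(exp, out, palindrome_maf_limit=palindrome_maf_limit)
        )
    return harmonized


def build_panel(
    instruments: Iterable[HarmonizedInstrument],
    sign_convention: str = "per_sd_increase",
) -> InstrumentPanel:
    """Assemble retained (non-dropped) instruments into a panel."""
    kept = tuple(i for i in instruments if not i.dropped)
    if not kept:
        raise DataError("no instruments survived harmonization")
    return InstrumentPanel(instruments=kept, sign_convention=sign_convention)
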