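"""Reading, validation, harmonization and QC of per-study GWAS summary statistics.

Summary statistics arrive as tab- or whitespace-delimited text with a
header (the GWAMA dialect), one row per variant, carrying the per-allele
effect estimate (beta), its standard error, effect-allele frequency and
sample size, plus optional per-study QC fields (call rate, minor allele
count, Hardy-Weinberg p, imputation info).  Rows violating type
invariants are quarantined with a reason code, never silently dropped.
Coordinates are GRCh37, 1-based, autosomes only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Default column dialect (file header -> canonical name).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "MARKERNAME": "marker_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "NEA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "N": "n",
    "INFO": "info",
    "STRAND": "strand",
    "CALLRATE": "call_rate",
    "HWE_P": "hwe_p",
    "MAC": "mac",
}

#: Canonical -> file header, for writing.
CANONICAL_TO_HEADER = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}

MANDATORY = ("marker_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n")
OPTIONAL_NUMERIC = ("chrom", "pos", "info", "call_rate", "hwe_p", "mac")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


@dataclass
class StudyPanel:
    """One study x sex stratum of summary statistics.

    ``records`` holds the harmonizable rows; ``malformed`` holds quarantined
    rows with a REASON column.  The genotyping design selects the genomic
    control rule downstream (Metabochip studies estimate lambda from a
    designated null-SNP subset rather than all variants).
    """

    study_id: str
    sex: str  # female | male | combined
    trait: str = "FG"  # FG | FI (extensible)
    genotyping_design: str = "gwas"  # gwas | metabochip | custom
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    malformed: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "combined"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if len(self.records) and self.records["marker_id"].duplicated().any():
            dup = self.records.loc[self.records["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id {dup!r} in study {self.study_id}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QCReport:
    """Itemized removal counts from one qc_filter pass."""

    n_input: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    n_removed_mac: int = 0
    n_removed_hwe: int = 0
    n_removed_info: int = 0
    n_removed_malformed: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_callrate
            + self.n_removed_maf
            + self.n_removed_mac
            + self.n_removed_hwe
            + self.n_removed_info
            + self.n_removed_malformed
        )

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed


@dataclass(frozen=True)
class QCThresholds:
    """Variant-level QC thresholds.

    Defaults: exclude call rate < 0.95, MAF < 0.01, minor allele count < 10,
    Hardy-Weinberg p < 1e-4, imputation info < 0.5.  A stricter info cut of
    0.7 applies after summary-statistic imputation (``post_imputation``).
    All rules are strict inequalities; a value exactly at the threshold is
    retained.  Absent fields never trigger removal.
    """

    call_rate: float = 0.95
    maf: float = 0.01
    mac: float = 10.0
    hwe_p: float = 1e-4
    info: float = 0.5
    info_post_imputation: float = 0.7

    def info_threshold(self, post_imputation: bool) -> float:
        return self.info_post_imputation if post_imputation else self.info


class MissingColumnError(ValueError):
    """A mandatory summary-statistic column is absent."""


def _parse_float(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _malformed_reasons(df: pd.DataFrame) -> pd.Series:
    """First violated invariant per row, or '' for clean rows."""
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, code: str) -> None:
        sel = mask.fillna(False) & (reason == "")
        reason[sel] = code

    ea, oa = df["effect_allele"], df["other_allele"]
    flag(~ea.isin(VALID_ALLELES) | ~oa.isin(VALID_ALLELES), "non_acgt_allele")
    flag(ea == oa, "identical_alleles")
    for col in ("eaf", "beta", "se", "n"):
        flag(df[col].isna(), f"unparseable_{col}")
    flag(~(df["se"] > 0), "nonpositive_se")
    flag((df["eaf"] < 0) | (df["eaf"] > 1), "eaf_out_of_range")
    if "pos" in df and df["pos"].notna().any():
        flag(df["pos"].notna() & (df["pos"] < 1), "nonpositive_pos")
    if "chrom" in df and df["chrom"].notna().any():
        flag(df["chrom"].notna() & ~df["chrom"].isin(range(1, 23)), "non_autosomal")
    return reason


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    study_id: str = "study",
    sex: str = "combined",
    trait: str = "FG",
    genotyping_design: str = "gwas",
) -> StudyPanel:
    """Parse a GWAMA-style summary-statistic file into a :class:`StudyPanel`.

    ``column_map`` maps file headers to canonical names and defaults to the
    documented dialect.  Gzip input is handled transparently (by suffix).
    Alleles are upper-cased; rows failing a type invariant are collected in
    ``panel.malformed`` with a REASON column rather than dropped.

    Raises :class:`MissingColumnError` if a mandatory column is absent.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    df = raw.rename(columns={c: cmap[c] for c in raw.columns if c in cmap})
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path}: missing mandatory column(s) {missing} "
            f"(headers seen: {list(raw.columns)})"
        )
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    if "strand" not in df.columns:
        df["strand"] = pd.NA
    for col in ("eaf", "beta", "se", "n", *OPTIONAL_NUMERIC):
        if col in df.columns:
            # float() round-trips repr-precision output exactly; pandas'
            # fast parser does not
            df[col] = df[col].map(_parse_float)
        else:
            df[col] = np.nan
    reason = _malformed_reasons(df)
    bad = reason != ""
    malformed = df[bad].copy()
    malformed["REASON"] = reason[bad]
    return StudyPanel(
        study_id=study_id,
        sex=sex,
        trait=trait,
        genotyping_design=genotyping_design,
        records=df[~bad].reset_index(drop=True),
        malformed=malformed.reset_index(drop=True),
    )


def write_sumstats(panel: StudyPanel, path: str | Path, *, quarantine: str | Path | None = None) -> None:
    """Write a panel in the default dialect (tab-delimited, gzip by suffix).

    Floats are written with ``repr`` precision so a read/write cycle
    round-trips all finite fields bit-identically.  If ``quarantine`` is
    given, malformed rows are written there with their REASON column.
    """
    cols = [c for c in DEFAULT_COLUMN_MAP.values() if c in panel.records.columns]
    out = panel.records[cols].rename(columns=CANONICAL_TO_HEADER)
    out.to_csv(path, sep="\t", index=False)
    if quarantine is not None and len(panel.malformed):
        q = panel.malformed.rename(columns=CANONICAL_TO_HEADER)
        q.to_csv(quarantine, sep="\t", index=False)


def qc_filter(
    panel: StudyPanel,
    thresholds: QCThresholds = QCThresholds(),
    *,
    post_imputation: bool = False,
) -> tuple[StudyPanel, QCReport]:
    """Apply variant-level QC; absent (NaN) fields never cause removal.

    Returns the surviving panel and a report itemizing removals.  Each
    removed row is attributed to the first rule it fails, in the fixed
    order call rate, MAF, MAC, HWE, info, so counts sum to
    ``n_input - n_output``; the surviving set itself does not depend on
    rule order.
    """
    df = panel.records
    report = QCReport(
        n_input=len(df) + len(panel.malformed),
        n_removed_malformed=len(panel.malformed),
        thresholds=dataclasses.asdict(thresholds),
    )
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    info_thr = thresholds.info_threshold(post_imputation)
    rules = [
        ("n_removed_callrate", df.get("call_rate"), thresholds.call_rate),
        ("n_removed_maf", maf, thresholds.maf),
        ("n_removed_mac", df.get("mac"), thresholds.mac),
        ("n_removed_hwe", df.get("hwe_p"), thresholds.hwe_p),
        ("n_removed_info", df.get("info"), info_thr),
    ]
    removed = pd.Series(False, index=df.index)
    for attr, values, thr in rules:
        if values is None:
            continue
        fails = values.notna() & (values < thr) & ~removed
        setattr(report, attr, int(fails.sum()))
        removed |= fails
    kept = df[~removed].reset_index(drop=True)
    out = dataclasses.replace(panel, records=kept, malformed=panel.malformed)
    return out, report


class HarmonizationError(ValueError):
    """Record alleles irreconcilable with the reference pair."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def harmonize(
    record: Mapping,
    reference_ea: str,
    reference_oa: str,
    *,
    reference_eaf: float | None = None,
    palindromic_freq_margin: float = 0.08,
) -> dict:
    """Align one record to a reference effect/other allele pair.

    Tries, in order: direct match, allele swap, strand complement, then
    complement + swap.  A swap negates beta and reflects eaf; a pure strand
    complement changes neither.  Palindromic pairs (A/T, C/G) are
    orientation-ambiguous and are resolved by allele frequency: both the
    record's and the reference's eaf must sit more than
    ``palindromic_freq_margin`` from 0.5, in which case matching frequency
    sides imply direct orientation and opposite sides imply a swap;
    otherwise the record is rejected (reason ``palindromic_ambiguous``).

    Returns a plain dict with the harmonized fields; idempotent, and an
    involution under reference swap.
    """
    reference_ea, reference_oa = reference_ea.upper(), reference_oa.upper()
    rec = dict(record)
    ea, oa = rec["effect_allele"].upper(), rec["other_allele"].upper()
    if reference_ea == reference_oa:
        raise HarmonizationError("bad_reference", "reference alleles identical")

    def _swap(r: dict) -> dict:
        r = dict(r)
        r["effect_allele"], r["other_allele"] = reference_ea, reference_oa
        r["beta"] = -r["beta"]
        r["eaf"] = 1.0 - r["eaf"]
        return r

    def _keep(r: dict) -> dict:
        r = dict(r)
        r["effect_allele"], r["other_allele"] = reference_ea, reference_oa
        return r

    if _is_palindromic(ea, oa):
        if not _is_palindromic(reference_ea, reference_oa) or frozenset((ea, oa)) != frozenset(
            (reference_ea, reference_oa)
        ):
            raise HarmonizationError(
                "allele_mismatch",
                f"palindromic {ea}/{oa} vs reference {reference_ea}/{reference_oa}",
            )
        eaf = rec.get("eaf")
        if (
            reference_eaf is None
            or eaf is None
            or np.isnan(eaf)
            or abs(eaf - 0.5) <= palindromic_freq_margin
            or abs(reference_eaf - 0.5) <= palindromic_freq_margin
        ):
            raise HarmonizationError(
                "palindromic_ambiguous",
                f"palindromic {ea}/{oa}: frequencies too close to 0.5 to orient",
            )
        same_side = (eaf - 0.5) * (reference_eaf - 0.5) > 0
        if ea == reference_ea:
            return _keep(rec) if same_side else _swap(rec)
        return _swap(rec) if same_side else _keep(rec)

    for transform in (lambda a: a, lambda a: COMPLEMENT[a]):
        tea, toa = transform(ea), transform(oa)
        if (tea, toa) == (reference_ea, reference_oa):
            return _keep(rec)
        if (toa, tea) == (reference_ea, reference_oa):
            return _swap(rec)
    raise HarmonizationError(
        "allele_mismatch", f"{ea}/{oa} irreconcilable with reference {reference_ea}/{reference_oa}"
    )


def reference_from_panel(panel: StudyPanel) -> pd.DataFrame:
    """Allele reference table (marker-indexed EA/OA/eaf) from one panel's coding.

    Any panel can anchor cross-study harmonization; its own records pass
    through :func:`harmonize_panel` unchanged.
    """
    return (
        panel.records[["marker_id", "effect_allele", "other_allele", "eaf"]]
        .set_index("marker_id")
    )


def harmonize_panel(
    panel: StudyPanel,
    reference: pd.DataFrame,
    **kwargs,
) -> tuple[StudyPanel, pd.DataFrame]:
    """Harmonize every record of a panel against a reference allele table.

    ``reference`` is indexed by marker_id with columns ``effect_allele``,
    ``other_allele`` and optionally ``eaf``.  Returns the harmonized panel
    and a DataFrame of rejected rows with a REASON column.  Markers absent
    from the reference pass through unchanged.
    """
    has_ref_eaf = "eaf" in reference.columns
    rows, rejected = [], []
    for rec in panel.records.to_dict("records"):
        mid = rec["marker_id"]
        if mid not in reference.index:
            rows.append(rec)
            continue
        ref = reference.loc[mid]
        try:
            rows.append(
                harmonize(
                    rec,
                    ref["effect_allele"],
                    ref["other_allele"],
                    reference_eaf=float(ref["eaf"]) if has_ref_eaf else None,
                    **kwargs,
                )
            )
        except HarmonizationError as err:
            rej = dict(rec)
            rej["REASON"] = err.reason
            rejected.append(rej)
    out = dataclasses.replace(
        panel,
        records=pd.DataFrame(rows, columns=panel.records.columns),
        malformed=panel.malformed,
    )
    return out, pd.DataFrame(rejected)
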