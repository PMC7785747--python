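"""Fixed-effects meta-analysis with genomic control and sex-dimorphism tests.

The statistical core: inverse-variance-weighted (IVW) pooling of per-study
effect estimates within each sex, genomic-control correction of residual
test-statistic inflation, the sex-combined 1-df test, the 2-df
sex-dimorphic chi-square test (z_f^2 + z_m^2), Cochran's Q test for
between-sex heterogeneity, and the I-squared statistic.

An exact algebraic identity ties the pieces together: for any two per-sex
estimates, z_f^2 + z_m^2 = z_pooled^2 + Q, i.e. the 2-df statistic
decomposes into the sex-combined association component and the
heterogeneity component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Median of the 1-df chi-square distribution, the genomic-control anchor.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642311957305

#: Floor applied to reported p-values to avoid underflow; the chi-square
#: statistic is always reported alongside.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class Estimate:
    """A (beta, se) pair, optionally with its sample count."""

    beta: float
    se: float
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p(self) -> float:
        """Two-sided p-value from the 1-df chi-square of z^2."""
        return chi2_p(self.z**2, 1)


@dataclass(frozen=True)
class HetResult:
    """Cochran's Q heterogeneity test result."""

    q: float
    df: int
    p: float
    i2: float


@dataclass(frozen=True)
class DimorphicResult:
    """2-df sex-dimorphic test: t2 = z_f^2 + z_m^2, p = exp(-t2/2)."""

    t2: float
    p: float


@dataclass(frozen=True)
class GCReport:
    """Genomic-control inflation factor lambda = median(chi2) / 0.4549364."""

    lam: float
    n_variants_used: int
    subset_rule: str = "all"

    @property
    def correction(self) -> float:
        """SE multiplier sqrt(lambda), floored at 1 (GC never deflates)."""
        return float(np.sqrt(max(1.0, self.lam)))


def chi2_p(stat: float | np.ndarray, df: int):
    """Two-sided p from a chi-square statistic, floored at 1e-300."""
    return np.maximum(stats.chi2.sf(stat, df), P_FLOOR)


def ivw_meta(estimates: Iterable[Estimate]) -> Estimate:
    """Fixed-effects inverse-variance-weighted pooling.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2; se = 1/sqrt(sum w_i).
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("ivw_meta requires at least one estimate")
    betas = np.array([e.beta for e in ests])
    w = np.array([1.0 / e.se**2 for e in ests])
    ns = [e.n for e in ests]
    n = float(sum(x for x in ns if x is not None)) if any(x is not None for x in ns) else None
    return Estimate(beta=float(betas @ w / w.sum()), se=float(1.0 / np.sqrt(w.sum())), n=n)


def ivw_arrays(betas: np.ndarray, ses: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IVW pooling along ``axis``; returns (beta, se) arrays."""
    w = 1.0 / np.asarray(ses) ** 2
    wsum = w.sum(axis=axis)
    return (np.asarray(betas) * w).sum(axis=axis) / wsum, 1.0 / np.sqrt(wsum)


def cochran_q(estimates: Sequence[Estimate]) -> HetResult:
    """Cochran's Q test of homogeneity across k >= 2 estimates.

    Q = sum w_i (b_i - b_pooled)^2 with IVW weights; chi-square with k-1 df
    under homogeneity.  For k = 2 this reduces to
    (b_1 - b_2)^2 / (se_1^2 + se_2^2).
    """
    ests = list(estimates)
    if len(ests) < 2:
        raise ValueError("cochran_q requires at least two estimates")
    pooled = ivw_meta(ests)
    w = np.array([1.0 / e.se**2 for e in ests])
    betas = np.array([e.beta for e in ests])
    q = float(w @ (betas - pooled.beta) ** 2)
    df = len(ests) - 1
    return HetResult(q=q, df=df, p=float(chi2_p(q, df)), i2=i_squared(q, df))


def sex_dimorphic_test(female: Estimate, male: Estimate) -> DimorphicResult:
    """2-df sex-dimorphic chi-square test from per-sex estimates.

    t2 = (b_f/se_f)^2 + (b_m/se_m)^2, referred to a chi-square with two
    degrees of freedom (closed form p = exp(-t2/2)).  Both sexes are
    required; a missing sex is an error at this level (callers flag the
    result unavailable rather than fall back to 1 df).
    """
    t2 = female.z**2 + male.z**2
    return DimorphicResult(t2=float(t2), p=float(chi2_p(t2, 2)))


def i_squared(q: float, df: int) -> float:
    """I-squared percentage: max(0, (Q - df)/Q) * 100; 0 when Q = 0.

    Quantifies the share of variation across estimates attributable to
    heterogeneity, independent of the number of estimates.
    """
    if q < 0:
        raise ValueError("Q must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if q == 0:
        return 0.0
    return float(max(0.0, (q - df) / q) * 100.0)


def genomic_control(
    z_or_chi2: np.ndarray,
    subset: np.ndarray | None = None,
    *,
    statistic: str = "chi2",
    subset_rule: str = "all",
) -> GCReport:
    """Estimate the genomic-control inflation factor from test statistics.

    lambda = median(chi2) / 0.4549364 (the 1-df chi-square median).  For
    Metabochip-style designs, ``subset`` restricts the median to a
    designated set of variants with no expected trait association (the
    QT-interval follow-up SNPs in the original design); label the choice
    via ``subset_rule``.  ``statistic`` is ``"chi2"`` or ``"z"``.
    """
    x = np.asarray(z_or_chi2, dtype=float)
    if statistic == "z":
        x = x**2
    elif statistic != "chi2":
        raise ValueError("statistic must be 'chi2' or 'z'")
    if subset is not None:
        x = x[np.asarray(subset)]
        subset_rule = subset_rule if subset_rule != "all" else "qt_interval_subset"
    if x.size == 0:
        raise ValueError("genomic_control requires at least one statistic")
    lam = float(np.median(x) / CHI2_1DF_MEDIAN)
    return GCReport(lam=lam, n_variants_used=int(x.size), subset_rule=subset_rule)


def apply_gc(ses: np.ndarray, report: GCReport) -> np.ndarray:
    """Inflate standard errors by sqrt(lambda) when lambda > 1.

    Equivalent to dividing the chi-square statistics by lambda.  Lambda
    below 1 leaves the data unchanged: GC never deflates.
    """
    return np.asarray(ses) * report.correction


@dataclass
class MetaConfig:
    """Switches for :func:`meta_pipeline`.

    ``study_gc``: estimate and apply per-study genomic control before
    pooling.  ``meta_gc``: second-stage GC on the pooled per-sex statistics
    (the meta-level lambdas reported alongside sex-differentiated GWAS
    suggest meta-level monitoring; default on).  ``combined_strategy``:
    'joint' pools every contributing study in one IVW pass (default);
    'two_stage' IVW-combines the two sex-level meta estimates plus any
    combined-only studies.
    """

    study_gc: bool = True
    meta_gc: bool = True
    combined_strategy: str = "joint"
    min_lambda_variants: int = 10
    extra: dict = field(default_factory=dict)


#: Column order of the meta-analysis output table.
META_COLUMNS = [
    "MARKER", "CHR", "POS", "EA", "NEA", "EAF",
    "BETA_F", "SE_F", "P_F", "N_F",
    "BETA_M", "SE_M", "P_M", "N_M",
    "BETA_ALL", "SE_ALL", "P_ALL", "N_ALL",
    "CHI2_2DF", "P_DIMORPHIC", "Q", "P_HET", "I2",
]


def _study_frame(panel) -> pd.DataFrame:
    df = panel.records.copy()
    df["study_id"] = panel.study_id
    df["sex"] = panel.sex
    df["design"] = panel.genotyping_design
    return df


def meta_pipeline(panels: Sequence, config: MetaConfig | None = None) -> pd.DataFrame:
    """Run the full per-variant sex-stratified meta-analysis.

    ``panels`` are harmonized, QC-passed :class:`~sexdimorph.sumstats_io.StudyPanel`
    objects.  Per sex, study estimates (after optional per-study GC) are
    IVW-pooled; the sex-combined column pools all contributing studies —
    family-based combined-only panels enter only there.  The 2-df
    sex-dimorphic and Cochran's Q statistics are computed from the pooled
    per-sex estimates (after optional second-stage GC).  Variants present
    in only one sex still get a combined estimate, with dimorphic and
    heterogeneity columns set to NaN.

    Returns a DataFrame in :data:`META_COLUMNS` order.
    """
    config = config or MetaConfig()
    frames = []
    for panel in panels:
        df = _study_frame(panel)
        if config.study_gc and len(df) >= config.min_lambda_variants:
            chi2 = (df["beta"] / df["se"]) ** 2
            rep = genomic_control(chi2.to_numpy())
            df = df.assign(se=apply_gc(df["se"].to_numpy(), rep))
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)

    pooled = {}
    for sex in ("female", "male"):
        sub = allrows[allrows["sex"] == sex]
        if len(sub) == 0:
            continue
        pooled[sex] = _pool(sub)
    if config.combined_strategy == "joint":
        pooled["combined"] = _pool(allrows)
    else:
        # Two-stage: IVW of the two pooled sex estimates plus combined-only studies.
        parts = [pooled[s].assign(sex=s) for s in ("female", "male") if s in pooled]
        comb_only = allrows[allrows["sex"] == "combined"]
        stacked = pd.concat(
            parts + ([comb_only.rename(columns={})] if len(comb_only) else []),
            ignore_index=True,
        )
        pooled["combined"] = _pool(stacked)

    if config.meta_gc:
        for sex in ("female", "male"):
            if sex in pooled and len(pooled[sex]) >= config.min_lambda_variants:
                chi2 = (pooled[sex]["beta"] / pooled[sex]["se"]) ** 2
                rep = genomic_control(chi2.to_numpy())
                pooled[sex] = pooled[sex].assign(se=apply_gc(pooled[sex]["se"].to_numpy(), rep))

    meta = _assemble(pooled)
    return meta


def _pool(sub: pd.DataFrame) -> pd.DataFrame:
    """IVW-pool one stack of study rows per marker; n-weighted EAF."""
    w = 1.0 / sub["se"] ** 2
    g = sub.assign(
        w=w,
        wb=w * sub["beta"],
        nw_eaf=sub["eaf"] * sub["n"],
    ).groupby("marker_id", sort=False)
    agg = g.agg(
        wsum=("w", "sum"),
        wbsum=("wb", "sum"),
        n=("n", "sum"),
        nw_eaf=("nw_eaf", "sum"),
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
    )
    return pd.DataFrame(
        {
            "marker_id": agg.index,
            "beta": agg["wbsum"] / agg["wsum"],
            "se": 1.0 / np.sqrt(agg["wsum"]),
            "n": agg["n"],
            "eaf": agg["nw_eaf"] / agg["n"],
            "chrom": agg["chrom"],
            "pos": agg["pos"],
            "effect_allele": agg["effect_allele"],
            "other_allele": agg["other_allele"],
        }
    ).reset_index(drop=True)


def _assemble(pooled: dict[str, pd.DataFrame]) -> pd.DataFrame:
    comb = pooled["combined"].set_index("marker_id")
    fem = pooled.get("female", pd.DataFrame()).set_index("marker_id") if "female" in pooled else None
    mal = pooled.get("male", pd.DataFrame()).set_index("marker_id") if "male" in pooled else None
    out = pd.DataFrame(index=comb.index)
    out["CHR"] = comb["chrom"]
    out["POS"] = comb["pos"]
    out["EA"] = comb["effect_allele"]
    out["NEA"] = comb["other_allele"]
    out["EAF"] = comb["eaf"]
    for label, tab in (("F", fem), ("M", mal)):
        if tab is None:
            out[f"BETA_{label}"] = np.nan
            out[f"SE_{label}"] = np.nan
            out[f"N_{label}"] = np.nan
        else:
            out[f"BETA_{label}"] = tab["beta"].reindex(out.index)
            out[f"SE_{label}"] = tab["se"].reindex(out.index)
            out[f"N_{label}"] = tab["n"].reindex(out.index)
        z2 = (out[f"BETA_{label}"] / out[f"SE_{label}"]) ** 2
        out[f"P_{label}"] = np.where(z2.notna(), chi2_p(z2.fillna(0.0), 1), np.nan)
    out["BETA_ALL"] = comb["beta"]
    out["SE_ALL"] = comb["se"]
    out["P_ALL"] = chi2_p((comb["beta"] / comb["se"]) ** 2, 1)
    out["N_ALL"] = comb["n"]

    zf2 = (out["BETA_F"] / out["SE_F"]) ** 2
    zm2 = (out["BETA_M"] / out["SE_M"]) ** 2
    both = zf2.notna() & zm2.notna()
    t2 = zf2 + zm2
    out["CHI2_2DF"] = t2.where(both)
    out["P_DIMORPHIC"] = np.where(both, chi2_p(t2.fillna(0.0), 2), np.nan)
    q = (out["BETA_F"] - out["BETA_M"]) ** 2 / (out["SE_F"] ** 2 + out["SE_M"] ** 2)
    out["Q"] = q.where(both)
    out["P_HET"] = np.where(both, chi2_p(q.fillna(0.0), 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(out["Q"] > 0, np.maximum(0.0, (out["Q"] - 1.0) / out["Q"]) * 100.0, 0.0)
    out["I2"] = np.where(both, i2, np.nan)
    out = out.reset_index().rename(columns={"marker_id": "MARKER"})
    return out[META_COLUMNS]
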