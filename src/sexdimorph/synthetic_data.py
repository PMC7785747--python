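"""Generators for every input the pipeline consumes, with recorded truth.

Emulates the structure of a multi-study, sex-stratified GWAS of
quantitative glycemic traits: per-study per-sex summary statistics whose
effect estimates are normally distributed around configurable sex-specific
true effects with sampling variance 1/(2 N f (1-f)) (unit-variance trait,
Hardy-Weinberg genotype frequencies), optional per-study genomic-control
inflation, and optional allele-coding discordance (swaps and strand
complements) to exercise harmonization.  Also generates MR instrument
systems with a known causal slope and optional directional pleiotropy,
and expression matrices with sex-specific eQTL slopes.

Every generator is seed-mandatory and returns a machine-readable truth
table alongside its data; downstream recovery tests read truth only from
there.  Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sexdimorph.sumstats_io import StudyPanel, COMPLEMENT

#: Non-palindromic allele pairs used for generated variants; palindromic
#: pairs (A/T, C/G) are injected only on request to test the rejection path.
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of one synthetic meta-analysis cohort.

    Defaults mirror the reference study conditions: roughly 70,000
    individuals per sex spread over several studies, causal effects in SD
    units of a unit-variance trait, allele frequencies drawn uniformly
    from [0.05, 0.5].
    """

    seed: int
    n_f: int = 70_000
    n_m: int = 70_000
    n_studies: int = 6
    n_variants: int = 1_000
    fraction_causal: float = 0.0
    beta_f_sd: float = 0.03
    beta_m_sd: float = 0.03
    beta_corr: float = 0.0  # correlation of female/male causal effects
    caf_range: tuple[float, float] = (0.05, 0.5)
    gc_lambda: float | tuple[float, ...] = 1.0  # per-study inflation of sampling var
    allele_discordance_rate: float = 0.0
    palindromic_rate: float = 0.0
    residual_var: float = 1.0

    def __post_init__(self) -> None:
        for frac in (self.fraction_causal, self.allele_discordance_rate, self.palindromic_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def study_lambdas(self) -> np.ndarray:
        lam = self.gc_lambda
        if np.isscalar(lam):
            return np.full(self.n_studies, float(lam))
        lam = np.asarray(lam, dtype=float)
        if lam.size != self.n_studies:
            raise ValueError("gc_lambda tuple must have one entry per study")
        return lam


@dataclass(frozen=True)
class PhenotypePrepSpec:
    """Trait preparation rules for fasting glucose and fasting insulin.

    Whole-blood FG is scaled to plasma level by 1.13; individuals with
    diagnosed/treated diabetes or plasma FG >= 7 mmol/L are excluded; FI
    (pmol/L) is natural-log transformed, FG left untransformed.
    """

    fg_whole_blood_factor: float = 1.13
    fg_exclusion_mmol: float = 7.0

    def __post_init__(self) -> None:
        if not self.fg_whole_blood_factor > 1:
            raise ValueError("whole-blood correction factor must exceed 1")


def prepare_phenotypes(
    raw: pd.DataFrame, spec: PhenotypePrepSpec = PhenotypePrepSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply trait preparation; returns (analysis-ready table, exclusion report).

    ``raw`` columns: FG (mmol/L), FI (pmol/L), WHOLE_BLOOD (bool),
    DIABETES (bool).  Exclusions: diabetes flag, plasma FG >= 7 mmol/L
    (after whole-blood correction), nonpositive FI (log undefined).
    """
    df = raw.copy()
    if "WHOLE_BLOOD" in df.columns:
        wb = df["WHOLE_BLOOD"].fillna(False).astype(bool)
        df.loc[wb, "FG"] = df.loc[wb, "FG"] * spec.fg_whole_blood_factor
    reason = pd.Series("", index=df.index, dtype=object)
    if "DIABETES" in df.columns:
        dia = df["DIABETES"].fillna(False).astype(bool)
        reason[dia & (reason == "")] = "diabetes"
    high = df["FG"] >= spec.fg_exclusion_mmol
    reason[high.fillna(False) & (reason == "")] = "fg_at_or_above_7"
    if "FI" in df.columns:
        bad_fi = df["FI"].notna() & (df["FI"] <= 0)
        reason[bad_fi & (reason == "")] = "nonpositive_fi"
    keep = reason == ""
    out = df[keep].copy()
    if "FI" in out.columns:
        out["FI"] = np.log(out["FI"])
    report = df[~keep].copy()
    report["REASON"] = reason[~keep]
    return out.reset_index(drop=True), report.reset_index(drop=True)


def _draw_variants(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    nv = spec.n_variants
    lo, hi = spec.caf_range
    caf = rng.uniform(lo, hi, size=nv)
    n_pal = rng.binomial(nv, spec.palindromic_rate) if spec.palindromic_rate else 0
    pairs = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))] if i < n_pal
        else _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        for i in range(nv)
    ]
    rng.shuffle(pairs)
    causal = rng.random(nv) < spec.fraction_causal
    z = rng.standard_normal((nv, 2))
    rho = spec.beta_corr
    bf = np.where(causal, spec.beta_f_sd * z[:, 0], 0.0)
    bm = np.where(
        causal,
        spec.beta_m_sd * (rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 1]),
        0.0,
    )
    chrom = rng.integers(1, 23, size=nv)
    pos = rng.integers(1, 250_000_000, size=nv)
    return pd.DataFrame(
        {
            "marker_id": [f"rs{i + 1:07d}" for i in range(nv)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "caf": caf,
            "causal": causal,
            "beta_f": bf,
            "beta_m": bm,
        }
    )


def generate_study_sumstats(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, list[StudyPanel]], pd.DataFrame]:
    """Generate per-study, per-sex summary-statistic panels plus truth.

    Per variant, study and sex, beta_hat ~ Normal(beta_sex,
    lambda_study * se^2) with se = sqrt(residual / (2 n f (1-f))) and n the
    study's per-sex slice of the cohort; the reported SE is the nominal
    (uninflated) one, so a study-level lambda > 1 shows up as genomic
    inflation downstream.  A spec-controlled fraction of rows is emitted
    with swapped or strand-complemented alleles (equal probability) to
    exercise harmonization; the truth table records the reference allele
    coding and true effects.

    When ``out_dir`` is given, panels are written in the GWAMA dialect and
    truth to ``truth.tsv``.
    """
    rng = np.random.default_rng(spec.seed)
    # separate stream for allele-coding injection so that turning the
    # discordance rate on or off leaves the effect-estimate draws untouched
    rng_discord = np.random.default_rng([spec.seed, 7])
    truth = _draw_variants(spec, rng)
    n_per_study = {
        "female": _split(spec.n_f, spec.n_studies),
        "male": _split(spec.n_m, spec.n_studies),
    }
    lambdas = spec.study_lambdas()
    panels: dict[str, list[StudyPanel]] = {"female": [], "male": []}
    f = truth["caf"].to_numpy()
    for s in range(spec.n_studies):
        lam = lambdas[s]
        for sex in ("female", "male"):
            n = n_per_study[sex][s]
            beta_true = truth[f"beta_{sex[0]}"].to_numpy()
            se = np.sqrt(spec.residual_var / (2.0 * n * f * (1.0 - f)))
            bhat = rng.normal(beta_true, se * np.sqrt(lam))
            df = truth[["marker_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
            df["eaf"] = f
            df["beta"] = bhat
            df["se"] = se
            df["n"] = n
            df["info"] = 1.0
            df["strand"] = "+"
            df = _inject_discordance(df, spec.allele_discordance_rate, rng_discord)
            panels[sex].append(
                StudyPanel(
                    study_id=f"study{s + 1:02d}",
                    sex=sex,
                    records=df.reset_index(drop=True),
                )
            )
    if out_dir is not None:
        from sexdimorph.sumstats_io import write_sumstats

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sex, plist in panels.items():
            for p in plist:
                write_sumstats(p, out / f"{p.study_id}_{sex}.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return panels, truth


def _split(total: int, k: int) -> list[int]:
    base = total // k
    out = [base] * k
    out[0] += total - base * k
    return out


def _inject_discordance(
    df: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Re-express a fraction of rows with swapped or complemented alleles.

    Swap negates beta and reflects eaf; strand complement changes neither.
    Both are information-preserving and must be undone by harmonization.
    """
    if rate <= 0:
        return df
    df = df.copy()
    hit = rng.random(len(df)) < rate
    swap = hit & (rng.random(len(df)) < 0.5)
    comp = hit & ~swap
    ea = df["effect_allele"].copy()
    oa = df["other_allele"].copy()
    df.loc[swap, "effect_allele"] = oa[swap]
    df.loc[swap, "other_allele"] = ea[swap]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    df.loc[comp, "effect_allele"] = ea[comp].map(COMPLEMENT)
    df.loc[comp, "other_allele"] = oa[comp].map(COMPLEMENT)
    df.loc[comp, "strand"] = "-"
    return df


def generate_mr_system(
    k: int,
    true_slope: float,
    *,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
    beta_exp_sd: float = 0.03,
    se_exp: float = 0.001,
    se_out: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """One harmonized MR instrument table with known causal structure.

    True exposure effects are spread half-normally away from zero (offset
    by one sd to keep Wald ratios stable) in the exposure-increasing
    orientation, where directional pleiotropy with the stated mean is
    added to the outcome; half the instruments are then re-expressed with
    both betas negated, the allele-coding ambiguity Egger's orientation
    step undoes.  Outcome effects are slope * beta_exp + pleiotropy +
    noise with the stated SEs.  Returns the instrument table (columns
    MARKER, EA, NEA, BETA_EXP, SE_EXP, BETA_OUT, SE_OUT, EAF) and a truth
    dict.
    """
    rng = np.random.default_rng(seed)
    bx_true = beta_exp_sd + np.abs(rng.normal(0.0, beta_exp_sd, size=k))
    pleio = rng.normal(pleiotropy_mean, pleiotropy_sd, size=k) if (
        pleiotropy_mean or pleiotropy_sd
    ) else np.zeros(k)
    bx = rng.normal(bx_true, se_exp)
    by = rng.normal(true_slope * bx_true + pleio, se_out)
    flip = rng.random(k) < 0.5
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    pairs = [_NONPALINDROMIC_PAIRS[int(i)] for i in rng.integers(len(_NONPALINDROMIC_PAIRS), size=k)]
    table = pd.DataFrame(
        {
            "MARKER": [f"iv{i + 1:04d}" for i in range(k)],
            "EA": [p[0] for p in pairs],
            "NEA": [p[1] for p in pairs],
            "BETA_EXP": bx,
            "SE_EXP": se_exp,
            "BETA_OUT": by,
            "SE_OUT": se_out,
            "EAF": rng.uniform(0.05, 0.95, size=k),
        }
    )
    truth = {
        "true_slope": true_slope,
        "pleiotropy_mean": pleiotropy_mean,
        "pleiotropy_sd": pleiotropy_sd,
        "k": k,
        "seed": seed,
    }
    return table, truth


@dataclass(frozen=True)
class ExpressionSpec:
    """Conditions for a synthetic expression experiment."""

    seed: int
    n_genes: int = 200
    n_f: int = 500
    n_m: int = 500
    n_plates: int = 4
    caf: float = 0.3
    noise_sd: float = 1.0
    plate_sd: float = 0.2
    sex_effect: dict[int, float] = field(default_factory=dict)  # gene idx -> effect
    eqtl_slopes: dict[int, tuple[float, float]] = field(default_factory=dict)  # idx -> (bf, bm)


def generate_expression(spec: ExpressionSpec):
    """Synthetic gene x sample matrix with planted sex and eQTL effects.

    Expression of gene g in sample i is
    mu + sex_effect[g] * 1{female} + plate_effect + beta_sex * dosage + noise,
    with Hardy-Weinberg dosages at the spec's allele frequency.  Returns
    an :class:`~sexdimorph.expression_models.ExpressionDataset` whose
    ``truth`` table records planted effects per gene.
    """
    from sexdimorph.expression_models import ExpressionDataset

    rng = np.random.default_rng(spec.seed)
    n = spec.n_f + spec.n_m
    sex = np.array(["female"] * spec.n_f + ["male"] * spec.n_m)
    plate = rng.integers(1, spec.n_plates + 1, size=n)
    dosage = rng.binomial(2, spec.caf, size=n).astype(float)
    plate_fx = rng.normal(0.0, spec.plate_sd, size=spec.n_plates)
    female = (sex == "female").astype(float)
    Y = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    Y += plate_fx[plate - 1][None, :]
    truth_rows = []
    for g in range(spec.n_genes):
        s_fx = spec.sex_effect.get(g, 0.0)
        bf, bm = spec.eqtl_slopes.get(g, (0.0, 0.0))
        Y[g] += s_fx * female + dosage * (bf * female + bm * (1.0 - female))
        truth_rows.append({"gene": f"gene{g + 1:04d}", "sex_effect": s_fx, "beta_f": bf, "beta_m": bm})
    genes = [f"gene{g + 1:04d}" for g in range(spec.n_genes)]
    samples = [f"s{i + 1:05d}" for i in range(n)]
    expression = pd.DataFrame(Y, index=genes, columns=samples)
    sheet = pd.DataFrame({"SEX": sex, "PLATE": plate}, index=samples)
    genotype = pd.Series(dosage, index=samples, name="dosage")
    return ExpressionDataset(
        expression=expression,
        samples=sheet,
        genotype=genotype,
        truth=pd.DataFrame(truth_rows).set_index("gene"),
    )
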