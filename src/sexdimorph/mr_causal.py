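"""Bidirectional two-sample Mendelian randomization (IVW and MR-Egger).

Given an instrument table of per-SNP exposure and outcome effects
(harmonized to a common effect allele), the per-variant causal estimate
is the ratio beta_outcome / beta_exposure with a Delta-method standard
error.  Instruments are combined by random-effect inverse-variance
weighting — equivalently the weighted zero-intercept regression of
outcome on exposure effects with weights 1/se_outcome^2, with the
standard error inflated multiplicatively by sqrt(max(1, Q/(k-1))).
MR-Egger adds a free intercept; a non-zero intercept indicates
directional pleiotropy, and the Egger slope remains a consistent causal
estimate under directional (InSIDE-valid) pleiotropy.

The bidirectional orchestration runs both causal directions in each sex
(four tests), judged at the Bonferroni level 0.05/4 = 0.0125.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sexdimorph.meta_core import Estimate

#: Instrument selection defaults: genome-wide significance and near-complete
#: LD independence.
INSTRUMENT_P = 5e-8
INSTRUMENT_R2 = 0.001

#: Bonferroni threshold for the four direction x sex tests.
BONFERRONI_4TESTS = 0.05 / 4

INSTRUMENT_COLUMNS = ["MARKER", "EA", "NEA", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT", "EAF"]


@dataclass(frozen=True)
class MRResult:
    """Combined causal estimate from one method on one instrument set."""

    method: str  # ivw_random | egger
    beta_iv: float
    se_iv: float
    p_iv: float
    k: int
    q_ivw: float
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None


def select_instruments(
    gwas: pd.DataFrame,
    *,
    p_threshold: float = INSTRUMENT_P,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = INSTRUMENT_R2,
    distance_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Greedy LD pruning of genome-wide-significant SNPs.

    ``gwas`` needs columns MARKER, P and (for the distance fallback) CHR,
    POS.  Keep the lowest-p SNP, drop everything with r^2 >= threshold to
    it, repeat.  Without an LD table, SNPs within ``distance_bp`` of a
    kept SNP are dropped instead and the result carries a
    ``pruning="distance"`` attribute flag.
    """
    sig = gwas[gwas["P"] <= p_threshold].sort_values(["P", "MARKER"], kind="mergesort")
    if len(sig) == 0:
        raise ValueError(
            f"no SNP passes p <= {p_threshold:g}; relax the significance threshold"
        )
    kept: list[pd.Series] = []
    if ld is not None:
        linked: dict[str, set[str]] = {}
        for _, row in ld.iterrows():
            if row["R2"] >= r2_threshold:
                linked.setdefault(row["MARKER1"], set()).add(row["MARKER2"])
                linked.setdefault(row["MARKER2"], set()).add(row["MARKER1"])
        dropped: set[str] = set()
        for _, row in sig.iterrows():
            if row["MARKER"] in dropped:
                continue
            kept.append(row)
            dropped |= linked.get(row["MARKER"], set())
        pruning = "ld"
    else:
        for _, row in sig.iterrows():
            if any(
                row["CHR"] == k["CHR"] and abs(row["POS"] - k["POS"]) < distance_bp
                for k in kept
            ):
                continue
            kept.append(row)
        pruning = "distance"
    out = pd.DataFrame(kept).reset_index(drop=True)
    out.attrs["pruning"] = pruning
    return out


def ratio_estimate(inst: pd.Series | dict, *, second_order: bool = False) -> Estimate:
    """Per-variant Wald ratio beta_out/beta_exp with Delta-method SE.

    First-order (default): se = se_out / |beta_exp|.  The second-order
    correction adds the exposure-uncertainty term
    beta_out^2 se_exp^2 / beta_exp^4 under the variance.
    """
    bx, by = float(inst["BETA_EXP"]), float(inst["BETA_OUT"])
    sx, sy = float(inst["SE_EXP"]), float(inst["SE_OUT"])
    if bx == 0:
        raise ValueError("ratio estimate undefined for beta_exposure = 0")
    var = sy**2 / bx**2
    if second_order:
        var += by**2 * sx**2 / bx**4
    return Estimate(beta=by / bx, se=float(np.sqrt(var)))


def _check_table(instruments: pd.DataFrame, k_min: int, method: str) -> pd.DataFrame:
    if len(instruments) < k_min:
        raise ValueError(f"{method} requires at least {k_min} instruments, got {len(instruments)}")
    return instruments


def ivw(instruments: pd.DataFrame) -> MRResult:
    """Random-effect IVW causal estimate.

    Slope of the weighted zero-intercept regression of BETA_OUT on
    BETA_EXP with weights 1/SE_OUT^2; Cochran's Q over the per-variant
    ratio estimates; SE inflated by sqrt(max(1, Q/(k-1))).  With
    homogeneous ratios (Q = 0) this is exactly the fixed-effects IVW.
    """
    df = _check_table(instruments, 2, "IVW")
    bx = df["BETA_EXP"].to_numpy(dtype=float)
    by = df["BETA_OUT"].to_numpy(dtype=float)
    w = 1.0 / df["SE_OUT"].to_numpy(dtype=float) ** 2
    sxx = float(w @ bx**2)
    slope = float(w @ (bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    k = len(df)
    q = float(w @ (by - slope * bx) ** 2)
    infl = float(np.sqrt(max(1.0, q / (k - 1))))
    se = se_fixed * infl
    z = slope / se
    return MRResult(
        method="ivw_random",
        beta_iv=slope,
        se_iv=float(se),
        p_iv=float(2 * stats.norm.sf(abs(z))),
        k=k,
        q_ivw=q,
    )


def egger(instruments: pd.DataFrame) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure with intercept.

    Instruments are first oriented so beta_exposure >= 0 (flipping both
    betas where needed — the orientation convention Egger regression
    requires).  Standard errors use multiplicative overdispersion floored
    at 1; p-values refer to a t distribution with k - 2 df.
    """
    df = _check_table(instruments, 3, "MR-Egger").copy()
    flip = df["BETA_EXP"] < 0
    df.loc[flip, ["BETA_EXP", "BETA_OUT"]] *= -1.0
    bx = df["BETA_EXP"].to_numpy(dtype=float)
    by = df["BETA_OUT"].to_numpy(dtype=float)
    w = 1.0 / df["SE_OUT"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T * w @ X
    coef = np.linalg.solve(XtWX, X.T * w @ by)
    resid = by - X @ coef
    k = len(df)
    q = float(w @ resid**2)
    sigma2 = max(1.0, q / (k - 2))
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    tstats = coef / se
    pvals = 2 * stats.t.sf(np.abs(tstats), df=k - 2)
    return MRResult(
        method="egger",
        beta_iv=float(coef[1]),
        se_iv=float(se[1]),
        p_iv=float(pvals[1]),
        k=k,
        q_ivw=q,
        intercept=float(coef[0]),
        se_intercept=float(se[0]),
        p_intercept=float(pvals[0]),
    )


def harmonize_instruments(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> pd.DataFrame:
    """Join exposure and outcome tables on MARKER, aligning effect alleles.

    Where the outcome row carries the swapped allele pair, its beta is
    negated (and EAF reflected).  Irreconcilable allele pairs are dropped.
    """
    out = outcome.set_index("MARKER")
    rows = []
    for _, e in exposure.iterrows():
        if e["MARKER"] not in out.index:
            continue
        o = out.loc[e["MARKER"]]
        bo, eafo = float(o["BETA"]), float(o.get("EAF", np.nan))
        if (o["EA"], o["NEA"]) == (e["EA"], e["NEA"]):
            pass
        elif (o["NEA"], o["EA"]) == (e["EA"], e["NEA"]):
            bo, eafo = -bo, 1.0 - eafo
        else:
            continue
        rows.append(
            {
                "MARKER": e["MARKER"],
                "EA": e["EA"],
                "NEA": e["NEA"],
                "BETA_EXP": float(e["BETA"]),
                "SE_EXP": float(e["SE"]),
                "BETA_OUT": bo,
                "SE_OUT": float(o["SE"]),
                "EAF": float(e.get("EAF", np.nan)),
            }
        )
    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def bidirectional(
    gwas_a: dict[str, pd.DataFrame],
    gwas_b: dict[str, pd.DataFrame],
    *,
    label_a: str = "A",
    label_b: str = "B",
    p_threshold: float = INSTRUMENT_P,
    ld: dict[str, pd.DataFrame] | None = None,
    r2_threshold: float = INSTRUMENT_R2,
    bonferroni: float = BONFERRONI_4TESTS,
) -> pd.DataFrame:
    """Run both causal directions in each sex: 4 IVW + 4 Egger results.

    ``gwas_a`` and ``gwas_b`` map sex ('female'/'male') to association
    tables with columns MARKER, EA, NEA, EAF, BETA, SE, P, CHR, POS.
    For each direction, instruments are selected from the exposure GWAS,
    harmonized against the outcome GWAS, and fed to IVW and Egger.
    Significance is judged at the four-test Bonferroni level (0.0125).
    """
    rows = []
    for sex in ("female", "male"):
        for exp_label, exp, out_label, out in (
            (label_a, gwas_a[sex], label_b, gwas_b[sex]),
            (label_b, gwas_b[sex], label_a, gwas_a[sex]),
        ):
            sel = select_instruments(
                exp,
                p_threshold=p_threshold,
                ld=None if ld is None else ld.get(sex),
                r2_threshold=r2_threshold,
            )
            inst = harmonize_instruments(
                sel.rename(columns={"BETA": "BETA", "SE": "SE"}), out
            )
            for res in (ivw(inst), egger(inst)):
                rows.append(
                    {
                        "EXPOSURE": exp_label,
                        "OUTCOME": out_label,
                        "SEX": sex,
                        "METHOD": res.method,
                        "K": res.k,
                        "BETA_IV": res.beta_iv,
                        "SE_IV": res.se_iv,
                        "P_IV": res.p_iv,
                        "Q_IVW": res.q_ivw,
                        "INTERCEPT": res.intercept,
                        "SE_INTERCEPT": res.se_intercept,
                        "P_INTERCEPT": res.p_intercept,
                        "SIGNIFICANT": res.p_iv < bonferroni,
                    }
                )
    return pd.DataFrame(rows)
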