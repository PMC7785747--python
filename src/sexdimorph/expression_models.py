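"""Sex-interaction expression models: eQTL slopes per sex, differential
expression by sex, and Benjamini-Hochberg FDR control.

Two nested linear models per gene drive the sex-specific eQTL analysis:

    common slope:       y_i = mu_sex(i) + pi_plate(i) + beta * g_i + e_i
    sex-specific slope: y_i = mu_sex(i) + pi_plate(i) + beta_sex(i) * g_i + e_i

where g is genotype dosage in [0, 2].  The sex-interaction test compares
the female and male slopes — the 1-df contrast beta_f - beta_m from the
joint fit, asymptotically equivalent to the nested-model F test.  Because
the design matrix is shared across genes, fits are vectorized: one pseudo
inverse prices every gene.

Sex-differential expression regresses (probe-averaged) gene expression on
sex plus covariates; the sign convention is positive = higher expression
in women.  Multiple testing uses Benjamini-Hochberg step-up FDR, with
optional label-permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionDataset:
    """Gene x sample expression with per-sample sex, plate and covariates.

    ``expression`` is genes x samples; ``samples`` carries SEX
    ('female'/'male'), PLATE, and any numeric covariate columns;
    ``genotype`` is an optional per-sample dosage series for the variant
    under test.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    genotype: pd.Series | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples.index):
            raise ValueError("expression columns must match sample-sheet index")
        if self.samples["SEX"].isna().any():
            raise ValueError("missing sex is not allowed")
        if self.genotype is not None:
            g = self.genotype
            if ((g < 0) | (g > 2)).any():
                raise ValueError("genotype dosage must lie in [0, 2]")


class RankDeficientDesign(ValueError):
    """The model design matrix is not full rank (aliased terms)."""


def _design(
    samples: pd.DataFrame,
    genotype: pd.Series | None,
    model: str,
    covariates: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the shared design matrix; female indicator codes the sex mean."""
    female = (samples["SEX"] == "female").to_numpy(dtype=float)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(samples)))]
    cols.append(("female", female))
    if "PLATE" in samples.columns:
        plates = pd.get_dummies(samples["PLATE"], drop_first=True)
        for name in plates.columns:
            cols.append((f"plate_{name}", plates[name].to_numpy(dtype=float)))
    for cov in covariates or []:
        cols.append((cov, samples[cov].to_numpy(dtype=float)))
    if model == "common_slope":
        cols.append(("g", genotype.to_numpy(dtype=float)))
    elif model == "sex_specific_slope":
        g = genotype.to_numpy(dtype=float)
        cols.append(("g_female", g * female))
        cols.append(("g_male", g * (1.0 - female)))
    elif model != "sex_only":
        raise ValueError(f"unknown model {model!r}")
    names = [n for n, _ in cols]
    X = np.column_stack([v for _, v in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal does not drop the rank
        aliased = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise RankDeficientDesign(f"design is rank deficient; aliased terms: {aliased}")
    return X, names


def _ols_all_genes(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene OLS with a shared design: coefficients, residual variance, XtX^-1."""
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    B = Y @ H.T  # genes x p
    resid = Y - B @ X.T
    dof = X.shape[0] - X.shape[1]
    s2 = (resid**2).sum(axis=1) / dof
    return B, s2, XtX_inv


def fit_eqtl(
    data: ExpressionDataset,
    *,
    model: str = "sex_specific_slope",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene eQTL fits with a common or sex-specific genotype slope.

    For the sex-specific model, the returned table carries beta_female,
    beta_male, their SEs, the sex-interaction 1-df chi-square
    (slope-difference contrast) with p_interaction, and BH-adjusted
    p_bh.  For the common-slope model, a single beta/se/p per gene.
    """
    if data.genotype is None:
        raise ValueError("fit_eqtl requires genotype dosages")
    X, names = _design(data.samples, data.genotype, model, covariates)
    Y = data.expression.to_numpy(dtype=float)
    B, s2, XtX_inv = _ols_all_genes(Y, X)
    dof = X.shape[0] - X.shape[1]
    out = pd.DataFrame(index=data.expression.index)
    if model == "common_slope":
        j = names.index("g")
        se = np.sqrt(s2 * XtX_inv[j, j])
        out["beta"] = B[:, j]
        out["se"] = se
        tt = B[:, j] / se
        out["p_raw"] = 2 * stats.t.sf(np.abs(tt), dof)
    else:
        jf, jm = names.index("g_female"), names.index("g_male")
        out["beta_female"] = B[:, jf]
        out["beta_male"] = B[:, jm]
        out["se_female"] = np.sqrt(s2 * XtX_inv[jf, jf])
        out["se_male"] = np.sqrt(s2 * XtX_inv[jm, jm])
        c_var = XtX_inv[jf, jf] + XtX_inv[jm, jm] - 2 * XtX_inv[jf, jm]
        diff = B[:, jf] - B[:, jm]
        se_diff = np.sqrt(s2 * c_var)
        out["beta_diff"] = diff
        out["se_diff"] = se_diff
        chi2 = (diff / se_diff) ** 2
        out["chi2_interaction"] = chi2
        out["p_raw"] = stats.chi2.sf(chi2, 1)
    out["p_bh"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def interaction_f_test(data: ExpressionDataset, covariates: list[str] | None = None) -> pd.DataFrame:
    """Nested-model F test: sex-specific slopes vs one common slope (1 extra df)."""
    X0, _ = _design(data.samples, data.genotype, "common_slope", covariates)
    X1, _ = _design(data.samples, data.genotype, "sex_specific_slope", covariates)
    Y = data.expression.to_numpy(dtype=float)
    rss0 = ((Y - Y @ np.linalg.pinv(X0).T @ X0.T) ** 2).sum(axis=1)
    rss1 = ((Y - Y @ np.linalg.pinv(X1).T @ X1.T) ** 2).sum(axis=1)
    dof1 = X1.shape[0] - X1.shape[1]
    F = (rss0 - rss1) / (rss1 / dof1)
    return pd.DataFrame(
        {"F": F, "p_raw": stats.f.sf(F, 1, dof1)}, index=data.expression.index
    )


def sex_differential_expression(
    data: ExpressionDataset,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene sex effect on expression, positive = higher in women.

    Genes with undefined SEs (constant expression) are flagged via
    ``excluded`` and given NaN statistics rather than dropped silently.
    """
    X, names = _design(data.samples, None, "sex_only", covariates)
    Y = data.expression.to_numpy(dtype=float)
    B, s2, XtX_inv = _ols_all_genes(Y, X)
    dof = X.shape[0] - X.shape[1]
    j = names.index("female")
    se = np.sqrt(s2 * XtX_inv[j, j])
    gene_var = Y.var(axis=1)
    ok = (se > 0) & (gene_var > 1e-12 * np.abs(Y).max(initial=1.0) ** 2)
    beta = B[:, j]
    t = np.divide(beta, se, out=np.full_like(beta, np.nan), where=ok)
    p = np.where(ok, 2 * stats.t.sf(np.abs(np.nan_to_num(t)), dof), np.nan)
    out = pd.DataFrame(
        {
            "beta_sex": np.where(ok, beta, np.nan),
            "se_sex": np.where(ok, se, np.nan),
            "t": t,
            "p_raw": p,
            "excluded": ~ok,
        },
        index=data.expression.index,
    )
    out.loc[ok, "p_bh"] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_pvalues(
    data: ExpressionDataset,
    *,
    statistic: str = "interaction",
    n_perm: int = 10_000,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Label-permutation p-values for the interaction or sex-effect statistic.

    Permutes sex labels (jointly breaking both the sex mean and any
    sex-specific slope), recomputes the statistic, and reports
    (1 + #{perm >= observed}) / (1 + n_perm) per gene.
    """
    rng = np.random.default_rng(seed)
    if statistic == "interaction":
        observed = fit_eqtl(data, covariates=covariates)["chi2_interaction"].to_numpy()

        def stat(d: ExpressionDataset) -> np.ndarray:
            return fit_eqtl(d, covariates=covariates)["chi2_interaction"].to_numpy()

    elif statistic == "sex":
        observed = np.abs(sex_differential_expression(data, covariates)["t"].to_numpy())

        def stat(d: ExpressionDataset) -> np.ndarray:
            return np.abs(sex_differential_expression(d, covariates)["t"].to_numpy())

    else:
        raise ValueError("statistic must be 'interaction' or 'sex'")
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = data.samples.copy()
        perm["SEX"] = rng.permutation(perm["SEX"].to_numpy())
        d = ExpressionDataset(data.expression, perm, data.genotype)
        exceed += stat(d) >= observed
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"p_perm": p_perm}, index=data.expression.index)
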