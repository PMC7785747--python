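"""Locus significance/novelty calls and two-SNP approximate conditional analysis.

A lead SNP must reach genome-wide significance (P <= 5e-8) in either the
2-df sex-dimorphic or the 1-df sex-combined test.  A lead is novel when it
lies more than 500 kb from every previously reported lead for the trait
and is not in LD with any of them (r^2 < 0.01); otherwise it maps to an
established locus.  Heterogeneity at established loci is screened at the
Bonferroni level for the trait's locus count (0.05/36 for FG, 0.05/19 for
FI).

The conditional analysis reconstructs the two-SNP joint least-squares fit
from marginal summary statistics and an LD correlation, in the manner of
summary-statistic conditional analysis with an external LD reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sexdimorph.meta_core import Estimate, chi2_p

GENOME_WIDE_P = 5e-8
NOVELTY_DISTANCE_BP = 500_000
NOVELTY_R2 = 0.01

#: Bonferroni heterogeneity screens at established loci.
HET_BONFERRONI = {"FG": 0.05 / 36, "FI": 0.05 / 19}


@dataclass(frozen=True)
class LocusThresholds:
    p_dimorphic: float = GENOME_WIDE_P
    p_combined: float = GENOME_WIDE_P
    novelty_distance_bp: int = NOVELTY_DISTANCE_BP
    novelty_r2: float = NOVELTY_R2
    window_bp: int = 1_000_000  # lead-selection window (+-500 kb)


@dataclass(frozen=True)
class ConditionalResult:
    """Target SNP effect conditioned on an adjacent SNP."""

    beta_cond: float
    se_cond: float
    p_cond: float
    r: float


LOCUS_COLUMNS = [
    "lead_marker", "chrom", "pos", "p_dimorphic", "p_combined", "winning_test",
    "classification", "nearest_known", "distance_to_nearest_known", "r2_to_known",
    "p_het", "het_significant",
]


def _ld_lookup(ld: pd.DataFrame | None, m1: str, m2: str) -> float | None:
    if ld is None or len(ld) == 0:
        return None
    hit = ld[
        ((ld["MARKER1"] == m1) & (ld["MARKER2"] == m2))
        | ((ld["MARKER1"] == m2) & (ld["MARKER2"] == m1))
    ]
    if len(hit) == 0:
        return None
    return float(hit["R2"].max())


def classify_loci(
    results: pd.DataFrame,
    known: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    thresholds: LocusThresholds = LocusThresholds(),
    *,
    trait: str = "FG",
) -> pd.DataFrame:
    """Select lead SNPs and classify each as novel or established.

    ``results`` is a meta-analysis table (:data:`~sexdimorph.meta_core.META_COLUMNS`);
    ``known`` has columns TRAIT, MARKER, CHR, POS and is filtered to the
    analyzed trait.  Lead selection is greedy per 1-Mb window: the variant
    with the lowest relevant p (min of the two qualifying tests) wins, ties
    broken by position; all candidates within the window are absorbed.
    When no LD table is supplied the distance rule alone decides and
    ``r2_to_known`` is left absent.  Deterministic and invariant to input
    row order.
    """
    known = known[known["TRAIT"] == trait] if "TRAIT" in known.columns else known
    df = results.copy()
    p_dim = df["P_DIMORPHIC"].to_numpy(dtype=float)
    p_all = df["P_ALL"].to_numpy(dtype=float)
    sig = (np.nan_to_num(p_dim, nan=1.0) <= thresholds.p_dimorphic) | (
        np.nan_to_num(p_all, nan=1.0) <= thresholds.p_combined
    )
    cand = df[sig].copy()
    cand["p_best"] = np.fmin(cand["P_DIMORPHIC"].fillna(1.0), cand["P_ALL"].fillna(1.0))
    cand = cand.sort_values(["p_best", "CHR", "POS"], kind="mergesort").reset_index(drop=True)

    half = thresholds.window_bp // 2
    calls = []
    taken = np.zeros(len(cand), dtype=bool)
    for i in range(len(cand)):
        if taken[i]:
            continue
        lead = cand.iloc[i]
        same = (cand["CHR"] == lead["CHR"]) & ((cand["POS"] - lead["POS"]).abs() <= half)
        taken |= same.to_numpy()
        calls.append(lead)

    rows = []
    for lead in calls:
        dim_sig = (not np.isnan(lead["P_DIMORPHIC"])) and lead["P_DIMORPHIC"] <= thresholds.p_dimorphic
        comb_sig = (not np.isnan(lead["P_ALL"])) and lead["P_ALL"] <= thresholds.p_combined
        if dim_sig and (not comb_sig or lead["P_DIMORPHIC"] <= lead["P_ALL"]):
            win = "dimorphic"
        else:
            win = "combined"
        nearest, dist, r2 = None, np.inf, None
        same_chr = known[known["CHR"] == lead["CHR"]]
        for _, k in same_chr.iterrows():
            d = abs(int(k["POS"]) - int(lead["POS"]))
            if d < dist:
                nearest, dist = k["MARKER"], d
        # LD against every known lead (not only the nearest)
        r2s = [
            _ld_lookup(ld, lead["MARKER"], k)
            for k in known["MARKER"]
        ]
        r2s = [x for x in r2s if x is not None]
        r2 = max(r2s) if r2s else None
        far = dist > thresholds.novelty_distance_bp
        unlinked = r2 is None or r2 < thresholds.novelty_r2
        classification = "novel" if (far and unlinked) else "established"
        p_het = lead.get("P_HET", np.nan)
        bonf = HET_BONFERRONI.get(trait, 0.05)
        rows.append(
            {
                "lead_marker": lead["MARKER"],
                "chrom": lead["CHR"],
                "pos": lead["POS"],
                "p_dimorphic": lead["P_DIMORPHIC"],
                "p_combined": lead["P_ALL"],
                "winning_test": win,
                "classification": classification,
                "nearest_known": nearest,
                "distance_to_nearest_known": None if np.isinf(dist) else int(dist),
                "r2_to_known": r2,
                "p_het": p_het,
                "het_significant": bool(p_het <= bonf) if not np.isnan(p_het) else False,
            }
        )
    out = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def established_het_screen(results: pd.DataFrame, known: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Heterogeneity screen at established loci at the trait's Bonferroni level."""
    known = known[known["TRAIT"] == trait] if "TRAIT" in known.columns else known
    sub = results[results["MARKER"].isin(known["MARKER"])].copy()
    sub["het_significant"] = sub["P_HET"] <= HET_BONFERRONI.get(trait, 0.05)
    return sub[["MARKER", "Q", "P_HET", "I2", "het_significant"]].reset_index(drop=True)


def approx_conditional(
    target: Estimate,
    conditioning: Estimate,
    *,
    target_eaf: float,
    conditioning_eaf: float,
    r: float,
    n: float,
    n_tolerance: float = 0.2,
) -> ConditionalResult:
    """Two-SNP joint regression reconstructed from marginal summaries.

    With genotype variances v_j = 2 f_j (1 - f_j) under Hardy-Weinberg and
    covariance c = r sqrt(v_1 v_2), the joint coefficients solve
    V b_joint = (v_1 b_1, v_2 b_2) where V = [[v_1, c], [c, v_2]] and
    b_j are the marginal estimates.  The phenotypic variance is recovered
    from each SNP's marginal fit (var_y ~= n v se^2 + v b^2, averaged) and
    the joint residual variance prices the conditional standard error.

    ``r`` with |r| >= 0.99 raises (the system is numerically singular);
    r = 0 returns the marginal estimate unchanged (orthogonal predictors
    leave the fit untouched).  Mismatched per-SNP sample sizes beyond
    ``n_tolerance`` (fractional) emit a warning.
    """
    if abs(r) >= 0.99:
        raise ValueError(f"|r| = {abs(r):.3f} >= 0.99: conditional system is singular")
    if target.n is not None and conditioning.n is not None:
        ns = (float(target.n), float(conditioning.n))
        if abs(ns[0] - ns[1]) > n_tolerance * max(ns):
            import warnings

            warnings.warn(
                f"per-SNP sample sizes differ by more than {n_tolerance:.0%}: {ns}",
                stacklevel=2,
            )
    if r == 0.0:
        return ConditionalResult(
            beta_cond=target.beta,
            se_cond=target.se,
            p_cond=float(chi2_p(target.z**2, 1)),
            r=0.0,
        )
    v1 = 2.0 * target_eaf * (1.0 - target_eaf)
    v2 = 2.0 * conditioning_eaf * (1.0 - conditioning_eaf)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("monomorphic SNP: eaf must lie strictly inside (0, 1)")
    c = r * np.sqrt(v1 * v2)
    V = np.array([[v1, c], [c, v2]])
    xty = np.array([v1 * target.beta, v2 * conditioning.beta])
    b_joint = np.linalg.solve(V, xty)
    # phenotypic variance from each marginal fit: se^2 = sigma^2/(n v),
    # sigma^2 = var_y - v b^2  =>  var_y = n v se^2 + v b^2
    var_y = float(
        np.mean(
            [
                n * v1 * target.se**2 + v1 * target.beta**2,
                n * v2 * conditioning.se**2 + v2 * conditioning.beta**2,
            ]
        )
    )
    sigma2 = max(var_y - float(b_joint @ V @ b_joint), 1e-12 * var_y)
    Vinv = np.linalg.inv(V)
    se_cond = float(np.sqrt(sigma2 * Vinv[0, 0] / n))
    beta_cond = float(b_joint[0])
    p_cond = float(chi2_p((beta_cond / se_cond) ** 2, 1))
    return ConditionalResult(beta_cond=beta_cond, se_cond=se_cond, p_cond=p_cond, r=float(r))
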