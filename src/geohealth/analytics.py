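"""Environment-health association statistics.

Two analyses over the regional tables:

* Urban-to-rural odds ratios with 95% confidence intervals — a 2x2 table of
  distinct patients (case = carries the ICD group, exposure = resides in a
  designated urban region), OR = (a*d)/(b*c) with the Woolf log-scale CI
  ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``; any zero cell
  triggers the Haldane-Anscombe 0.5 correction (applied to all four cells,
  flagged in the result).
* Spearman rank correlation between regional features and prevalence
  targets across regions, with Benjamini-Hochberg adjustment across all
  feature x target pairs. p-values use the exact permutation distribution
  of the rank correlation for small tie-free samples (n <= 8, where the
  usual t approximation is visibly off) and the t approximation with
  n - 2 df otherwise — the same convention R's ``cor.test`` follows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("geohealth")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Distinct-patient counts: a/b = urban cases/non-cases, c/d = rural."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2
    haldane_corrected: bool = False


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Woolf odds ratio and 95% CI; zero cells get the 0.5 correction."""
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    corrected = any(v == 0 for v in cells)
    if corrected:
        cells = [v + 0.5 for v in cells]
        log.warning("odds_ratio: zero cell, Haldane-Anscombe 0.5 correction applied")
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - Z_95 * se)
    hi = math.exp(math.log(or_) + Z_95 * se)
    return OddsRatioResult(or_, lo, hi, table, corrected)


def build_urban_rural_table(
    claims: pd.DataFrame,
    urban_ids: set[str],
    group: str,
    hierarchy,
    years: list[int] | None = None,
) -> ContingencyTable2x2:
    """2x2 distinct-patient table for one ICD group, urban vs rural.

    A patient is a case if any of their codes rolls up to ``group`` within
    the pooled years; exposure is residence in an urban region (patients
    appearing in several regions count by the stratum of each appearance;
    with static residences each patient has exactly one stratum).
    """
    from .prevalence import truncate_to_category

    df = claims.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    if years is not None:
        df = df[df["year"].isin(years)]
    all_regions = set(df["region_id"].unique())
    if not urban_ids:
        raise ValueError("urban_ids must be non-empty")
    if not urban_ids < all_regions:
        raise ValueError("urban_ids must be a proper subset of observed regions")

    df["urban"] = df["region_id"].isin(urban_ids)
    coded = df[df["icd_code"].astype(str).str.len() > 0].copy()
    cat_of = {c: truncate_to_category(c) for c in coded["icd_code"].unique()}
    coded["category"] = coded["icd_code"].map(cat_of)
    coded = coded[coded["category"].map(lambda c: c in hierarchy)]
    in_group_of = {
        c: any(g == group for g, _ in hierarchy.ancestry(c))
        for c in coded["category"].unique()
    }
    in_group = coded["category"].map(in_group_of)
    if not in_group.any():
        raise ValueError(f"group {group!r} absent from all claims")
    case_patients = set(coded.loc[in_group, "patient_id"])

    strata = df.groupby("patient_id")["urban"].max()
    is_case = strata.index.isin(case_patients)
    a = int((strata & is_case).sum())
    b = int((strata & ~is_case).sum())
    c = int((~strata & is_case).sum())
    d = int((~strata & ~is_case).sum())
    return ContingencyTable2x2(a, b, c, d)


def urban_rural_or(
    claims: pd.DataFrame,
    urban_ids: set[str],
    group: str,
    hierarchy,
    years: list[int] | None = None,
) -> OddsRatioResult:
    """Urban-to-rural odds ratio for one ICD group (years pooled by default)."""
    return odds_ratio(build_urban_rural_table(claims, urban_ids, group, hierarchy, years))


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

EXACT_P_MAX_N = 8


@lru_cache(maxsize=8)
def _exact_abs_rho_distribution(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    from itertools import permutations

    base = np.arange(1, n + 1, dtype=float)
    base = base - base.mean()
    denom = float((base ** 2).sum())
    vals = [abs(float(np.dot(base, p)) / denom)
            for p in permutations(base)]
    return np.sort(np.asarray(vals))


def _spearman_p(rho: float, n: int, tie_free: bool) -> float:
    if tie_free and n <= EXACT_P_MAX_N:
        dist = _exact_abs_rho_distribution(n)
        k = np.searchsorted(dist, abs(rho) - 1e-12, side="left")
        return float((len(dist) - k) / len(dist))
    t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2)) if abs(rho) < 1 \
        else math.inf * np.sign(rho)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return max(p, 5e-324)  # keep p in (0, 1] even at |rho| = 1


def spearman_matrix(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Spearman rho between every feature column and every target column.

    Rows of the two frames are paired on their (region or region-year)
    index. rho is the Pearson correlation of average ranks; p-values use
    the t approximation with n - 2 df; the adjusted p-value applies the
    requested ``statsmodels`` multiple-testing method across all pairs.
    Constant columns yield a missing rho with a reason. Result columns:
    (feature, target, rho, p, p_adj, n, note).
    """
    common = features.index.intersection(targets.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    X = features.loc[common]
    Y = targets.loc[common]

    rows = []
    for t in Y.columns:
        y = Y[t].to_numpy(dtype=float)
        for f in X.columns:
            x = X[f].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                rows.append((f, t, np.nan, np.nan, n, "fewer than 3 paired values"))
                continue
            xs, ys = x[ok], y[ok]
            if np.all(xs == xs[0]) or np.all(ys == ys[0]):
                rows.append((f, t, np.nan, np.nan, n, "constant input"))
                continue
            rho = float(stats.spearmanr(xs, ys).statistic)
            tie_free = (len(np.unique(xs)) == n) and (len(np.unique(ys)) == n)
            p = _spearman_p(rho, n, tie_free)
            rows.append((f, t, rho, p, n, ""))
    out = pd.DataFrame(rows, columns=["feature", "target", "rho", "p", "n", "note"])

    out["p_adj"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(out.loc[valid, "p"], method=adjust)[1]
    return out[["feature", "target", "rho", "p", "p_adj", "n", "note"]]


def correlation_heatmap(corr: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Render the feature x target rho matrix (significant pairs only) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = corr[corr["p_adj"] <= alpha]
    if sig.empty:
        log.warning("correlation_heatmap: no pairs significant at %g", alpha)
        sig = corr
    mat = sig.pivot(index="feature", columns="target", values="rho")
    fig, ax = plt.subplots(figsize=(1 + 0.5 * mat.shape[1], 1 + 0.3 * mat.shape[0]))
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def or_results_table(results: dict[str, OddsRatioResult]) -> pd.DataFrame:
    rows = []
    for group, r in sorted(results.items()):
        rows.append({
            "icd_group": group,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "haldane_corrected": r.haldane_corrected,
        })
    return pd.DataFrame(rows)
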