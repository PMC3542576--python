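"""Expression preprocessing and pairwise differential expression.

The pipeline mirrors the standard two-colourless GeneChip workflow on the
log2 scale: quantile normalization across arrays, median-polish
summarization from probe level to gene level, then per-gene moderated
t-tests between two conditions with empirical-Bayes variance shrinkage and
Benjamini-Hochberg control of the false discovery rate at adjusted p < 0.05.

The moderated t statistic shrinks each gene's pooled variance s2_g (on d_g
degrees of freedom) toward a prior s2_0 estimated across genes:

    s2_post = (d_0 * s2_0 + d_g * s2_g) / (d_0 + d_g)
    t_mod   = (mean_A - mean_B) / sqrt(s2_post * (1/n_A + 1/n_B))

with p-values from a t distribution on d_0 + d_g degrees of freedom.  The
hyperparameters (d_0, s2_0) are estimated by method of moments on log s2_g
under a scaled-F model (Smyth-style); a non-estimable spread collapses to
d_0 = infinity (all genes share s2_0) and the reference distribution
becomes normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_matrix",
    "read_design",
    "quantile_normalize",
    "median_polish_summarize",
    "moderated_t_test",
    "bh_adjust",
    "call_significant",
    "DESummary",
    "de_analysis",
]


# ---------------------------------------------------------------------------
# I/O


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV (first column = gene id) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Design TSV with columns sample, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    missing = {"sample", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if df["condition"].isna().any():
        raise ValueError("design has missing condition labels")
    return df


# ---------------------------------------------------------------------------
# preprocessing


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns onto the mean distribution of order statistics.

    After normalization every column's sorted values equal the cross-column
    mean of order statistics.  Tied values within a column receive the mean
    of the target values over their tie run, so ranks (with stable tie
    handling) are preserved.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in matrix")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        col = np.empty(X.shape[0])
        col[order] = target
        # average target values across ties
        s = pd.Series(col).groupby(pd.Series(X[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish_summarize(
    probe_matrix: pd.DataFrame | np.ndarray,
    tol: float = 0.01,
    max_iter: int = 10,
) -> tuple[pd.Series, dict]:
    """Median-polish summary of a probes x samples block.

    Alternating row/column median sweeps (Tukey) run until the largest sweep
    adjustment falls below ``tol`` or ``max_iter`` is reached.  The summary
    for each sample is overall effect + column effect, the usual expression
    index.  Non-convergence sets ``info['converged'] = False`` rather than
    failing.
    """
    if isinstance(probe_matrix, pd.DataFrame):
        columns = probe_matrix.columns
        Z = probe_matrix.to_numpy(dtype=float).copy()
    else:
        Z = np.asarray(probe_matrix, dtype=float).copy()
        columns = pd.RangeIndex(Z.shape[1])
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("probe matrix must be 2-D with >= 1 row")
    overall = 0.0
    row_eff = np.zeros(Z.shape[0])
    col_eff = np.zeros(Z.shape[1])
    converged = False
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        delta = 0.0
        rmed = np.median(Z, axis=1)
        Z -= rmed[:, None]
        row_eff += rmed
        delta = max(delta, np.abs(rmed).max(initial=0.0))
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift
        cmed = np.median(Z, axis=0)
        Z -= cmed[None, :]
        col_eff += cmed
        delta = max(delta, np.abs(cmed).max(initial=0.0))
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift
        if delta < tol:
            converged = True
            break
    summary = pd.Series(overall + col_eff, index=columns)
    info = {
        "converged": converged,
        "iterations": iterations,
        "residuals": Z,
        "row_effects": row_eff,
        "overall": overall,
    }
    return summary, info


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(
        lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-10
    ))


def _estimate_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Method-of-moments fit of (d_0, s2_0) from per-gene variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_bar = e.mean()
    var_e = e.var(ddof=1)
    excess = var_e - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        d0 = np.inf
        s20 = float(np.exp(e_bar))
    else:
        x = _trigamma_inverse(excess)
        d0 = 2.0 * x
        s20 = float(np.exp(
            e_bar + special.digamma(x) - np.log(x)
        ))
    return float(d0), s20


def moderated_t_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of ``cond_a`` versus ``cond_b``.

    ``prior_df`` overrides the estimated d_0: 0 disables shrinkage (classic
    pooled two-sample t), ``numpy.inf`` shares one variance across genes,
    ``None`` (default) estimates d_0 and s2_0 from the data.  Positive log2
    fold changes mean higher expression in ``cond_a``.

    Returns a DataFrame indexed by gene with columns ``mean_a, mean_b, lfc,
    s2, df, s2_post, t, p`` and estimation metadata in ``DataFrame.attrs``.
    """
    samples_a = design.loc[design["condition"] == cond_a, "sample"]
    samples_b = design.loc[design["condition"] == cond_b, "sample"]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition; got "
            f"{len(samples_a)} for {cond_a!r} and {len(samples_b)} "
            f"for {cond_b!r}"
        )
    A = matrix[list(samples_a)].to_numpy(dtype=float)
    B = matrix[list(samples_b)].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    d_g = n_a + n_b - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    lfc = mean_a - mean_b

    if prior_df is None:
        d0, s20 = _estimate_prior(s2, d_g)
        if d0 <= 0:  # degenerate estimate: fall back to no shrinkage
            d0, s20 = 0.0, 0.0
    elif prior_df == 0:
        d0, s20 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s20 = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if np.isinf(d0) \
            else float(np.median(s2))
        if np.isinf(d0):
            # with d_0 -> inf every gene shares the prior variance
            pass
    if np.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(d_g)
    else:
        s2_post = (d0 * s20 + d_g * s2) / (d0 + d_g)
        df_total = float(d0 + d_g)

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (lfc != 0), np.inf * np.sign(lfc), t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "lfc": lfc,
            "s2": s2,
            "df": d_g,
            "s2_post": s2_post,
            "t": t,
            "p": p,
        },
        index=matrix.index,
    )
    out.attrs.update(
        {"d0": d0, "s20": s20, "cond_a": cond_a, "cond_b": cond_b,
         "n_a": n_a, "n_b": n_b, "df_total": df_total}
    )
    return out


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DESummary:
    """Count summary of a comparison, rendered as ``n (k up / m down)``."""

    n_significant: int
    n_up: int
    n_down: int

    def __str__(self) -> str:
        return f"{self.n_significant} ({self.n_up}↑/{self.n_down}↓)"


def call_significant(
    de: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, DESummary]:
    """Attach BH-adjusted p-values and up/down/ns calls at adjusted p < alpha.

    Returns the augmented table (columns ``padj`` and ``call`` added) and a
    :class:`DESummary` of total / up / down counts.
    """
    out = de.copy()
    out.attrs = dict(de.attrs)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    sig = out["padj"] < alpha
    call = np.where(~sig, "ns", np.where(out["lfc"] > 0, "up", "down"))
    out["call"] = call
    n_up = int(((call == "up")).sum())
    n_down = int(((call == "down")).sum())
    return out, DESummary(n_up + n_down, n_up, n_down)


def de_analysis(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, DESummary]:
    """Moderated t-test + BH adjustment + significance calls in one step."""
    de = moderated_t_test(matrix, design, cond_a, cond_b, prior_df=prior_df)
    return call_significant(de, alpha=alpha)
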