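"""Differential expression.

Two routes, matching how the analysis uses them:

* Welch's t-test on log-normalized expression between two cell groups
  (antibody-extreme spike-in vs derived XEN cells).
* Per-gene negative-binomial regression on raw counts with a log link,
  design = one dummy per (condition, replicate) subset plus the log total
  count per cell as a covariate, inference on an averaged-coefficient
  contrast (mean of one side's replicate coefficients minus the mean of the
  other side's) by a Wald test.

All p-values are Benjamini-Hochberg adjusted.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import CountMatrix, NormalizedMatrix

LN2 = np.log(2.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def select_extreme_cells(
    antibody: pd.Series, eligible: np.ndarray, n: int = 100, side: str = "high"
) -> np.ndarray:
    """The n eligible cells with highest (or lowest) antibody count.

    ``antibody`` is indexed by cell_id; ``eligible`` lists the candidate
    cell ids. Boundary ties resolve by lexicographic cell_id, so the
    selection is stable across runs.
    """
    sub = antibody.loc[list(eligible)]
    if n > len(sub):
        raise ValueError(f"n={n} exceeds the {len(sub)} eligible cells")
    asc = sub.sort_index().sort_values(kind="stable", ascending=(side == "low"))
    return asc.index.to_numpy()[:n]


def welch_de(nm: NormalizedMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene Welch t-test between two cell-id groups on log expression."""
    ia = np.flatnonzero(np.isin(nm.cell_ids, np.asarray(group_a, dtype=object)))
    ib = np.flatnonzero(np.isin(nm.cell_ids, np.asarray(group_b, dtype=object)))
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 cells")
    xa = np.asarray(nm.values[:, ia].todense())
    xb = np.asarray(nm.values[:, ib].todense())
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    t[degenerate] = 0.0
    p = np.ones(nm.n_genes)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return pd.DataFrame(
        {
            "gene": nm.gene_ids,
            "effect": ma - mb,
            "stat": t,
            "pvalue": p,
            "padj": bh_adjust(p),
        }
    )


def _mom_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion: var = mu + alpha mu^2."""
    resid2 = (y - mu) ** 2 - mu
    denom = (mu ** 2).sum()
    return float(np.clip(resid2.sum() / max(denom, 1e-12), 1e-6, 100.0))


def _fit_gene_nb(y: np.ndarray, X: np.ndarray):
    """NB regression for one gene: ML over (beta, alpha), MoM-dispersion GLM fallback.

    Returns (coefficients, covariance) or None on failure.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        except Exception:
            return None
        try:
            start = np.append(pois.params, 0.1)
            res = sm.NegativeBinomial(y, X).fit(
                start_params=start, method="bfgs", maxiter=200, disp=0
            )
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(res.bse[:-1])
            ):
                k = X.shape[1]
                return res.params[:k], res.cov_params()[:k, :k]
        except Exception:
            pass
        try:  # fallback: plug-in dispersion
            alpha = _mom_alpha(y, pois.fittedvalues)
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            if np.all(np.isfinite(glm.bse)):
                return glm.params, glm.cov_params()
        except Exception:
            pass
    return None


def nb_glm_de(
    raw: CountMatrix,
    subsets: np.ndarray,
    contrast: tuple,
    offset_mode: bool = False,
) -> pd.DataFrame:
    """Averaged-coefficient NB regression over all genes.

    ``subsets`` gives one label per cell, e.g. "XEG_rep1"; ``contrast`` is
    (side1_labels, side2_labels); the tested quantity is
    mean(coef[side1]) - mean(coef[side2]). For the one-vs-rest cell-type
    test pass all remaining subset labels as side2. The log total count per
    cell enters as a covariate by default; ``offset_mode`` moves it to a
    fixed offset instead.
    """
    subsets = np.asarray(subsets, dtype=object)
    side1, side2 = [list(s) for s in contrast]
    levels = sorted(set(subsets.tolist()))
    for lab in side1 + side2:
        if lab not in levels:
            raise ValueError(f"contrast references unknown subset {lab!r}")
    if len(side1) < 1 or len(side2) < 1:
        raise ValueError("each contrast side needs at least one subset")
    dummies = np.stack([(subsets == lev).astype(float) for lev in levels], axis=1)
    log_total = np.log(raw.cell_totals().astype(float))
    if offset_mode:
        X = dummies
        offset = log_total
    else:
        X = np.column_stack([dummies, log_total - log_total.mean()])
        offset = None

    c = np.zeros(X.shape[1])
    for lab in side1:
        c[levels.index(lab)] += 1.0 / len(side1)
    for lab in side2:
        c[levels.index(lab)] -= 1.0 / len(side2)

    counts = np.asarray(raw.values.todense())
    rows = []
    for gi in range(raw.n_genes):
        y = counts[gi].astype(float)
        fit = None
        if y.sum() > 0:
            if offset is None:
                fit = _fit_gene_nb(y, X)
            else:  # offset mode: absorb exposure into the fallback GLM route only
                fit = _fit_gene_nb_offset(y, X, offset)
        if fit is None:
            rows.append((raw.gene_ids[gi], np.nan, np.nan, np.nan, False))
            continue
        beta, cov = fit
        est = float(c @ beta)
        var = float(c @ cov @ c)
        if var <= 0 or not np.isfinite(var):
            rows.append((raw.gene_ids[gi], np.nan, np.nan, np.nan, False))
            continue
        z = est / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((raw.gene_ids[gi], est / LN2, z, p, True))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "stat", "pvalue", "converged"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def _fit_gene_nb_offset(y: np.ndarray, X: np.ndarray, offset: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            alpha = _mom_alpha(y, pois.fittedvalues)
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            if np.all(np.isfinite(glm.bse)):
                return glm.params, glm.cov_params()
        except Exception:
            pass
    return None
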