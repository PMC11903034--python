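"""Allele-specific expression and expression-noise effects in F1 hybrids.

F1 diploids are isogenic and share all trans-acting factors, so allelic
differences in count distributions isolate cis effects.  Counts from the
two alleles of a gene are stacked (two rows per cell) and fit jointly
with an NB model whose mean carries the allele effect (and optional
stage / batch / depth terms) and whose dispersion is allele-specific:

    ln theta(row) = tau0 + Xk * tau1

with Xk the allele indicator.  "Noise" is 1/theta; the noise fold-change
between alleles is exp(-tau1).  The t-statistic of tau1 identifies
allele-specific noise effects; the mean and noise families are BH
adjusted separately.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import eqtl_scan, simdata
from .io_formats import AlleleCountMatrix

logger = logging.getLogger("onepot")

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# cell classification to input diploids


def classify_f1_cells(ac: AlleleCountMatrix, diploids: dict[str, np.ndarray],
                      error_rate: float = 0.005,
                      margin_threshold: float = 2.0) -> pd.DataFrame:
    """Assign each cell to one of the pooled F1 diploids by likelihood.

    ``diploids`` maps name -> per-site parent-A allele dosage in {0,1,2}
    for that diploid.  Per cell, the log-likelihood under a diploid is
    the sum over sites of log Binomial(rA | D, p) with p = e, 0.5 or
    1 - e for dosage 0, 1, 2.  Cells are assigned to the argmax diploid;
    cells whose best-vs-second margin falls below ``margin_threshold``
    log-units (or with no reads) stay unassigned.
    """
    if len(diploids) < 2:
        raise ValueError("need >= 2 candidate diploids")
    names = list(diploids)
    dosages = np.array([np.asarray(diploids[n]) for n in names])
    if any(np.array_equal(dosages[i], dosages[j])
           for i in range(len(names)) for j in range(i + 1, len(names))):
        raise ValueError("two candidate diploids have identical genotypes; "
                         "no distinguishing sites")
    e = error_rate
    p_by_dosage = np.array([e, 0.5, 1.0 - e])
    A = ac.countsA.toarray().astype(float)
    D = (ac.countsA + ac.countsB).toarray().astype(float)
    loglik = np.zeros((ac.n_cells, len(names)))
    for k in range(len(names)):
        p = p_by_dosage[dosages[k]]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = A * np.log(p)[None, :] + (D - A) * np.log(1 - p)[None, :]
        loglik[:, k] = np.where(D > 0, ll, 0.0).sum(axis=1)
    order = np.argsort(loglik, axis=1)
    best = order[:, -1]
    margin = (loglik[np.arange(ac.n_cells), best]
              - loglik[np.arange(ac.n_cells), order[:, -2]])
    has_reads = D.sum(axis=1) > 0
    assigned = has_reads & (margin >= margin_threshold)
    return pd.DataFrame({
        "cell": ac.cells,
        "diploid": [names[b] if a else None for b, a in zip(best, assigned)],
        "margin": np.where(has_reads, margin, np.nan),
    })


# ---------------------------------------------------------------------------
# filters


def filter_ase(allelic_total: np.ndarray, total_umis: np.ndarray,
               min_cells: int = 64, max_umis: int = 20_000
               ) -> tuple[np.ndarray, np.ndarray]:
    """Analysis set for ASE: cell mask and gene mask.

    Cells with total UMIs >= ``max_umis`` are dropped (strict "<" keeps
    cells below the bound); genes must have an allelic count observed in
    at least ``min_cells`` of the remaining cells.  ``allelic_total`` is
    cells x genes total allelic counts (both alleles summed).
    """
    cell_keep = np.asarray(total_umis) < max_umis
    observed = (np.asarray(allelic_total)[cell_keep] > 0).sum(axis=0)
    gene_keep = observed >= min_cells
    return cell_keep, gene_keep


# ---------------------------------------------------------------------------
# joint NB fit with allele-specific dispersion


def _ase_design(data: simdata.AseGeneData) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the stacked allelic counts.

    Columns: intercept, allele indicator, then (per cell, replicated to
    both rows) ln total UMIs, batch indicators, stage indicators and
    allele x stage interactions when the metadata is present.
    """
    rows = len(data.counts)
    cols = [np.ones(rows), data.allele.astype(float)]
    names = ["intercept", "allele"]
    if data.total_umis is not None:
        cols.append(np.log(np.maximum(data.total_umis[data.cell], 1.0)))
        names.append("ln_umis")
    if data.batch is not None:
        b = pd.Categorical(data.batch[data.cell])
        for level in b.categories[1:]:
            cols.append((b == level).astype(float))
            names.append(f"batch[{level}]")
    if data.stage is not None:
        s = pd.Categorical(data.stage[data.cell])
        levels = [lv for lv in s.categories][1:]
        for lv in levels:
            ind = (s == lv).astype(float)
            if ind.sum() == 0:
                logger.warning("stage level %s empty; dropped", lv)
                continue
            cols.append(ind)
            names.append(f"stage[{lv}]")
            cols.append(ind * data.allele)
            names.append(f"allele:stage[{lv}]")
    return np.column_stack(cols), names


def _ase_negll_grad(params: np.ndarray, y: np.ndarray, X: np.ndarray,
                    a: np.ndarray) -> tuple[float, np.ndarray]:
    p = X.shape[1]
    beta, tau0, tau1 = params[:p], params[p], params[p + 1]
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    theta = np.exp(np.clip(tau0 + a * tau1, -20.0, 20.0))
    ll = np.sum(special.gammaln(y + theta) - special.gammaln(theta)
                - special.gammaln(y + 1.0) + theta * np.log(theta)
                + y * eta - (y + theta) * np.log(mu + theta))
    dl_deta = y - (y + theta) * mu / (mu + theta)
    g_beta = X.T @ dl_deta
    dl_dtheta = (special.digamma(y + theta) - special.digamma(theta)
                 + np.log(theta) + 1.0 - np.log(mu + theta)
                 - (y + theta) / (mu + theta))
    g_tau = theta * dl_dtheta
    grad = np.concatenate([g_beta, [g_tau.sum(), (g_tau * a).sum()]])
    return -ll, -grad


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclasses.dataclass
class AseFit:
    """Joint ASE fit for one gene."""

    coef_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    tau0: float
    tau1: float
    tau1_se: float
    loglik: float
    converged: bool

    @property
    def allele_log_fc(self) -> float:
        return float(self.beta[self.coef_names.index("allele")])

    @property
    def allele_log_fc_se(self) -> float:
        return float(self.beta_se[self.coef_names.index("allele")])

    @property
    def noise_log_fc(self) -> float:
        """ln of the allele noise fold-change, -tau1 (noise = 1/theta)."""
        return -self.tau1

    @property
    def t_noise(self) -> float:
        return self.tau1 / self.tau1_se if self.tau1_se > 0 else np.nan

    @property
    def p_noise(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.t_noise)))

    @property
    def z_mean(self) -> float:
        se = self.allele_log_fc_se
        return self.allele_log_fc / se if se > 0 else np.nan

    @property
    def p_mean(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z_mean)))


def fit_ase_model(data: simdata.AseGeneData,
                  allele_specific_dispersion: bool = True) -> AseFit:
    """Joint ML fit of the stacked-allele NB model for one gene.

    Warm-starts from an IRLS fit with a common dispersion, then runs a
    quasi-Newton (L-BFGS-B) maximisation over (beta, tau0, tau1); SEs
    come from a central-difference observed-information matrix.  With
    ``allele_specific_dispersion`` False, tau1 is pinned at 0 and the
    fit reduces to an ordinary NB regression on the stacked design.
    """
    y = np.asarray(data.counts, float)
    if (y[data.allele == 0].sum() == 0) or (y[data.allele == 1].sum() == 0):
        raise ValueError("both alleles must be observed")
    X, names = _ase_design(data)
    a = data.allele.astype(float)
    warm = eqtl_scan.fit_nb_glm(y, X, theta=None)
    x0 = np.concatenate([warm.beta, [np.log(warm.theta), 0.0]])

    if not allele_specific_dispersion:
        def f0(params):
            full = np.concatenate([params, [0.0]])
            return _ase_negll_grad(full, y, X, a)[0]

        def fg0(params):
            nll, g = _ase_negll_grad(np.concatenate([params, [0.0]]), y, X, a)
            return nll, g[:-1]

        res = optimize.minimize(fg0, x0[:-1], jac=True, method="L-BFGS-B",
                                options={"maxiter": 500})
        H = _numerical_hessian(f0, res.x)
        se = _safe_se(H)
        p = X.shape[1]
        return AseFit(coef_names=names, beta=res.x[:p], beta_se=se[:p],
                      tau0=float(res.x[p]), tau1=0.0, tau1_se=np.nan,
                      loglik=-res.fun, converged=bool(res.success))

    res = optimize.minimize(_ase_negll_grad, x0, args=(y, X, a), jac=True,
                            method="L-BFGS-B", options={"maxiter": 500})
    if not res.success:
        logger.warning("ASE optimiser did not converge: %s", res.message)
    H = _numerical_hessian(lambda p_: _ase_negll_grad(p_, y, X, a)[0], res.x)
    se = _safe_se(H)
    p = X.shape[1]
    return AseFit(coef_names=names, beta=res.x[:p], beta_se=se[:p],
                  tau0=float(res.x[p]), tau1=float(res.x[p + 1]),
                  tau1_se=float(se[p + 1]), loglik=-res.fun,
                  converged=bool(res.success))


def _safe_se(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(H.shape[0], np.nan)


def summarize_ase(fits: dict[str, AseFit]) -> pd.DataFrame:
    """Per-gene ASE table with separate BH families for mean and noise."""
    from statsmodels.stats.multitest import multipletests
    rows = []
    for gene, fit in fits.items():
        rows.append({
            "gene": gene,
            "allele_log_fc": fit.allele_log_fc,
            "allele_log_fc_se": fit.allele_log_fc_se,
            "p_mean": fit.p_mean,
            "noise_log_fc": fit.noise_log_fc,
            "noise_log_fc_se": fit.tau1_se,
            "t_noise": fit.t_noise,
            "p_noise": fit.p_noise,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q_mean"] = multipletests(df["p_mean"].to_numpy(), method="fdr_bh")[1]
        df["q_noise"] = multipletests(df["p_noise"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# bias / calibration simulation


def bias_simulation(design: simdata.AseSimDesign) -> pd.DataFrame:
    """Simulate the fold-change grid and refit; returns the long table.

    One row per (fc, dfc, rep): estimated allele log2 FC, estimated
    dispersion log2 FC (= -tau1/ln 2) and the noise-test p-value.  The
    refit model matches the generating one: intercept and allele effect
    only, with allele-specific dispersion.
    """
    rows = []
    for data in simdata.simulate_f1_hybrid(design):
        truth = data.truth
        try:
            fit = fit_ase_model(data)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rows.append({
            "fc_log2": truth["fc_log2"], "dfc_log2": truth["dfc_log2"],
            "rep": truth["rep"],
            "est_fc_log2": fit.allele_log_fc / np.log(2.0),
            "est_dfc_log2": -fit.tau1 / np.log(2.0),
            "p_noise": fit.p_noise, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def summarize_bias(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate the bias table per grid point: mean estimates, bias,
    rejection rate of the noise test at ``alpha``."""
    grp = table.groupby(["fc_log2", "dfc_log2"])
    out = grp.agg(
        mean_est_fc_log2=("est_fc_log2", "mean"),
        mean_est_dfc_log2=("est_dfc_log2", "mean"),
        rejection_rate=("p_noise", lambda p: float((p < alpha).mean())),
        n=("rep", "size"),
    ).reset_index()
    out["bias_fc_log2"] = out["mean_est_fc_log2"] - out["fc_log2"]
    out["bias_dfc_log2"] = out["mean_est_dfc_log2"] - out["dfc_log2"]
    return out


# ---------------------------------------------------------------------------
# global noise-expression trend


def noise_trend(results: pd.DataFrame, z: float = 1.959964) -> pd.DataFrame:
    """Robust trend of noise change on expression change, with violations.

    ``results`` must carry ``noise_log_fc``, ``noise_log_fc_se`` and
    ``allele_log_fc`` for the genes significant in either the mean or
    noise family.  A Huber M-estimated line is fit (noise change on
    expression change); a gene violates the trend iff its noise-effect
    95% CI and the pointwise 95% CI of the fitted line at its expression
    change are disjoint.
    """
    if len(results) < 10:
        raise ValueError("trend fit needs >= 10 significant genes")
    x = results["allele_log_fc"].to_numpy(float)
    y = results["noise_log_fc"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("expression changes are constant; trend undefined")
    import statsmodels.api as sm
    X = sm.add_constant(x)
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    pred = rlm.predict(X)
    cov = rlm.cov_params()
    se_fit = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    lo_line, hi_line = pred - z * se_fit, pred + z * se_fit
    se_g = results["noise_log_fc_se"].to_numpy(float)
    lo_g, hi_g = y - z * se_g, y + z * se_g
    violates = (lo_g > hi_line) | (hi_g < lo_line)
    out = results.copy()
    out["trend_fit"] = pred
    out["trend_lo"] = lo_line
    out["trend_hi"] = hi_line
    out["violates_trend"] = violates
    out.attrs["trend_intercept"] = float(rlm.params[0])
    out.attrs["trend_slope"] = float(rlm.params[1])
    return out
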