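"""Differential-methylation pipeline: normalization, dispersion estimation,
per-peak GLM likelihood-ratio tests, fold-change decomposition, FDR control,
ensemble combination and filtering.

The test asks, per peak, whether IP-over-input enrichment differs between
conditions beyond any change in the underlying gene's expression.  Two
pipeline variants share everything except how they estimate the NB
dispersion:

* ``trend_shrink`` — per-peak Cox–Reid adjusted profile-likelihood estimates
  shrunk on the log scale toward a fitted mean–dispersion trend
  phi(mu) = a0 + a1/mu.
* ``common_tagwise`` — per-peak estimates shrunk toward a single common
  dispersion with a prior weight equivalent to 10 observations.

Running both and taking the union or intersect of significant peaks mirrors
the practice of cross-checking differential calls between independent
NB-based implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.multitest import multipletests

from .glm import fit_nb_glm, lrt_interaction
from .model import CountExperiment, SampleInfo, ValidationError, design_matrix

logger = logging.getLogger(__name__)

VARIANTS = ("trend_shrink", "common_tagwise")

_PHI_MIN = 1e-8
_PHI_MAX = 10.0
_PRIOR_OBS = 10.0  # prior weight (in observations) for dispersion shrinkage


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def estimate_size_factors(
    counts: pd.DataFrame,
    samples: list[SampleInfo],
    method: str = "median_of_ratios",
) -> pd.Series:
    """Per-sample size factors, computed separately within the IP group and
    the input group and rescaled to geometric mean 1 within each group.

    Within-fraction normalization keeps global IP enrichment out of the input
    size factors; the GLM's beta_ip term absorbs the mean IP/input ratio.
    """
    if method not in {"median_of_ratios", "total_count"}:
        raise ValueError(f"unknown method {method!r}")
    ids = [s.sample_id for s in samples]
    arr = counts[ids].to_numpy(dtype=float)
    zero = arr.sum(axis=0) == 0
    if zero.any():
        bad = [ids[i] for i in np.flatnonzero(zero)]
        raise ValidationError(f"all-zero sample(s): {bad}")
    factors = np.ones(len(ids))
    for fraction in ("IP", "input"):
        idx = [i for i, s in enumerate(samples) if s.fraction == fraction]
        if not idx:
            continue
        sub = arr[:, idx]
        if method == "total_count":
            f = sub.sum(axis=0)
        else:
            pos = (sub > 0).all(axis=1)
            if not pos.any():
                raise ValidationError(
                    f"median_of_ratios needs >=1 peak with nonzero counts in "
                    f"every {fraction} sample"
                )
            logref = np.log(sub[pos]).mean(axis=1)
            f = np.exp(np.median(np.log(sub[pos]) - logref[:, None], axis=0))
        f = f / np.exp(np.mean(np.log(f)))  # geometric mean 1 within group
        factors[idx] = f
    return pd.Series(factors, index=ids, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _profile_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float) -> float:
    """Cox–Reid adjusted profile log-likelihood of phi (beta profiled out)."""
    fit = fit_nb_glm(y, X, phi, offset=offset)
    if fit.degenerate:
        return -np.inf
    w = fit.mu / (1.0 + phi * fit.mu)
    xtwx = X.T @ (w[:, None] * X)
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return fit.loglik - 0.5 * logdet


def _golden_max(f, lo: float, hi: float, n_iter: int = 25) -> float:
    """Golden-section maximum of f over log-phi in [lo, hi]."""
    g = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(np.exp(d))
    return float(np.exp((a + b) / 2.0))


def _per_peak_dispersion(
    counts: np.ndarray, X: np.ndarray, offset: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak CR-APL dispersion estimates plus the APL evaluated on a shared
    grid (returned for the common-dispersion estimate)."""
    n_peaks = counts.shape[0]
    phi_hat = np.zeros(n_peaks)
    apl_grid = np.full((n_peaks, grid.size), -np.inf)
    for i in range(n_peaks):
        y = counts[i]
        f = lambda phi: _profile_apl(y, X, offset, phi)  # noqa: E731
        vals = np.array([f(g) for g in grid])
        apl_grid[i] = vals
        if not np.isfinite(vals).any():
            phi_hat[i] = 0.0
            continue
        j = int(np.nanargmax(vals))
        if j == 0 and vals[0] >= vals[1]:
            phi_hat[i] = 0.0  # boundary: no evidence of overdispersion
            continue
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, grid.size - 1)]
        phi_hat[i] = _golden_max(f, lo, hi)
    return phi_hat, apl_grid


def fit_dispersion_trend(phi_hat: np.ndarray, mean_counts: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of phi = a0 + a1/mu with non-negative coefficients."""
    ok = np.isfinite(phi_hat) & (mean_counts > 0)
    if ok.sum() < 2:
        return max(float(np.nanmedian(phi_hat)), _PHI_MIN), 0.0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_counts[ok]])
    coef, _ = optimize.nnls(A, phi_hat[ok])
    if coef[0] <= 0 and coef[1] <= 0:
        coef[0] = max(float(np.median(phi_hat[ok])), _PHI_MIN)
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    samples: list[SampleInfo],
    size_factors: pd.Series | np.ndarray,
    variant: str = "trend_shrink",
) -> np.ndarray:
    """Per-peak NB dispersion under the full model.

    Both variants start from per-peak Cox–Reid adjusted profile-likelihood
    maximization, then regularize: ``trend_shrink`` shrinks log-dispersions
    toward a fitted trend phi(mu) = a0 + a1/mu, leaving far-above-trend
    outliers (>4x trend) at their own estimates; ``common_tagwise`` shrinks
    toward the common (all-peak) dispersion with prior weight equivalent to
    10 observations.  Estimated once under the full model and shared between
    full and reduced fits, standard LRT practice.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    X = design_matrix(samples, "full")
    n, p = X.shape
    if n - p < 2:
        raise ValidationError(
            "dispersion estimation needs >=2 residual degrees of freedom: "
            "provide >=2 replicates per condition in at least one fraction"
        )
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    offset = np.log(sf)
    grid = np.exp(np.linspace(np.log(1e-4), np.log(_PHI_MAX), 12))
    phi_hat, apl_grid = _per_peak_dispersion(arr, X, offset, grid)

    resid_df = float(n - p)
    log_phi = np.log(np.maximum(phi_hat, _PHI_MIN))
    norm_mean = (arr / sf).mean(axis=1)

    if variant == "trend_shrink":
        a0, a1 = fit_dispersion_trend(phi_hat, norm_mean)
        trend = np.maximum(a0 + a1 / np.maximum(norm_mean, 1e-6), _PHI_MIN)
        # empirical-Bayes weight: the spread of log residuals around the
        # trend in excess of the known sampling variance of a log-dispersion
        # estimate (trigamma of half the residual df) estimates the prior
        # variance; when peaks scatter no more than sampling noise predicts,
        # nearly all weight goes to the trend.
        resid = log_phi - np.log(trend)
        sampling_var = float(special.polygamma(1, resid_df / 2.0))
        s_lr = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        prior_var = max(s_lr ** 2 - sampling_var, 0.01)
        w = prior_var / (prior_var + sampling_var)
        shrunk = np.exp(w * log_phi + (1.0 - w) * np.log(trend))
        outlier = phi_hat > 4.0 * trend
        shrunk[outlier] = phi_hat[outlier]
        logger.info(
            "dispersion trend: a0=%.4g a1=%.4g; prior var %.3g, weight %.2f; "
            "%d outliers unshrunk", a0, a1, prior_var, w, int(outlier.sum()))
        return shrunk
    # common_tagwise: common phi maximizes the summed per-peak APL on the grid
    total = apl_grid.sum(axis=0)
    finite = np.isfinite(total)
    common = float(grid[int(np.argmax(np.where(finite, total, -np.inf)))]) if finite.any() else _PHI_MIN
    common = max(common, _PHI_MIN)
    w = resid_df / (resid_df + _PRIOR_OBS)
    return np.exp(w * log_phi + (1.0 - w) * np.log(common))


# ---------------------------------------------------------------------------
# per-peak GLM + LRT
# ---------------------------------------------------------------------------

def run_glm_lrt(
    experiment: CountExperiment,
    variant: str = "trend_shrink",
    size_factors: pd.Series | None = None,
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit full and reduced NB GLMs per peak and test the interaction term.

    Returns one row per peak with coefficients (natural-log scale),
    dispersion, deviances, LRT statistic, p-value, BH-adjusted FDR and a
    convergence flag.  Degenerate (all-zero) or non-converged peaks get
    missing p/fdr and are never significant.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(experiment.peak_counts, experiment.samples)
    sf = size_factors.loc[experiment.sample_ids].to_numpy()
    if dispersions is None:
        dispersions = estimate_dispersions(
            experiment.peak_counts, experiment.samples, sf, variant=variant
        )
    X_full = design_matrix(experiment.samples, "full")
    X_red = design_matrix(experiment.samples, "reduced")
    offset = np.log(sf)
    arr = experiment.peak_counts.to_numpy(dtype=float)
    rows = []
    for i, peak_id in enumerate(experiment.peak_counts.index):
        y = arr[i]
        phi = float(dispersions[i])
        full = fit_nb_glm(y, X_full, phi, offset=offset)
        red = fit_nb_glm(y, X_red, phi, offset=offset)
        stat, p = lrt_interaction(full, red)
        rows.append({
            "peak_id": peak_id,
            "beta0": full.beta[0],
            "beta_ip": full.beta[1],
            "beta_stim": full.beta[2],
            "beta_interaction": full.beta[3],
            "dispersion": phi,
            "deviance_full": full.deviance,
            "deviance_reduced": red.deviance,
            "lrt_stat": stat,
            "p_value": p,
            "converged": bool(full.converged and red.converged and not full.degenerate),
        })
    df = pd.DataFrame(rows)
    df["fdr"] = adjust_fdr(df["p_value"].to_numpy())
    return df


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up over non-missing p-values; missing stays missing."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# fold changes, combination, filters
# ---------------------------------------------------------------------------

def compute_fold_changes(
    experiment: CountExperiment,
    size_factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Decompose each peak's change into peak-IP and gene-input log2 fold
    changes (treated vs control, means of size-factor-normalized counts with
    a pseudocount) and their absolute difference ``delta_log2fc``.

    ``min_peak_count`` is the minimum raw peak count across all samples
    (replicates and conditions), the quantity gated at >=10 downstream.
    Genes with zero input counts throughout a condition are flagged
    ``low_expression`` (the pseudocount still yields a finite value).
    """
    if size_factors is None:
        size_factors = estimate_size_factors(experiment.peak_counts, experiment.samples)
    sf = size_factors.loc[experiment.sample_ids].to_numpy()
    peak_norm = experiment.peak_counts.to_numpy(dtype=float) / sf
    gene_norm = experiment.gene_counts.to_numpy(dtype=float) / sf

    m_ip_t = experiment.mask("IP", "treated")
    m_ip_c = experiment.mask("IP", "control")
    m_in_t = experiment.mask("input", "treated")
    m_in_c = experiment.mask("input", "control")
    for m, what in ((m_ip_t, "treated IP"), (m_ip_c, "control IP"),
                    (m_in_t, "treated input"), (m_in_c, "control input")):
        if not m.any():
            raise ValidationError(f"no {what} samples")

    peak_fc = np.log2((peak_norm[:, m_ip_t].mean(axis=1) + pseudocount)
                      / (peak_norm[:, m_ip_c].mean(axis=1) + pseudocount))
    gene_in_t = gene_norm[:, m_in_t].mean(axis=1)
    gene_in_c = gene_norm[:, m_in_c].mean(axis=1)
    gene_fc = np.log2((gene_in_t + pseudocount) / (gene_in_c + pseudocount))
    gene_fc_by_id = pd.Series(gene_fc, index=experiment.gene_counts.index)
    gene_raw = experiment.gene_counts.to_numpy(dtype=float)
    low = ((gene_raw[:, m_in_t].sum(axis=1) == 0) | (gene_raw[:, m_in_c].sum(axis=1) == 0))
    low_by_id = pd.Series(low, index=experiment.gene_counts.index)

    p2g = experiment.peak_to_gene
    genes = [p2g[pid] for pid in experiment.peak_counts.index]
    gene_input_fc = gene_fc_by_id.loc[genes].to_numpy()
    return pd.DataFrame({
        "peak_id": experiment.peak_counts.index,
        "gene_id": genes,
        "peak_ip_log2fc": peak_fc,
        "gene_input_log2fc": gene_input_fc,
        "delta_log2fc": np.abs(peak_fc - gene_input_fc),
        "min_peak_count": experiment.peak_counts.min(axis=1).to_numpy(),
        "low_expression": low_by_id.loc[genes].to_numpy(),
    })


def combine_calls(
    results: dict[str, pd.DataFrame],
    rule: str = "union",
    alpha: float = 0.05,
) -> set[str]:
    """Set algebra over per-variant significant peaks (fdr < alpha)."""
    if not results:
        raise ValueError("need results from >=1 variant")
    if rule not in {"union", "intersect"}:
        raise ValueError(f"rule must be union or intersect, got {rule!r}")
    sets = []
    for df in results.values():
        sig = df.loc[df["fdr"].notna() & (df["fdr"] < alpha), "peak_id"]
        sets.append(set(sig))
    out = set.union(*sets) if rule == "union" else set.intersection(*sets)
    return out


def apply_filters(
    calls: pd.DataFrame,
    min_delta: float = 1.0,
    min_count: int = 10,
    exonic_only: bool = False,
    exon_peak_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Retain calls meeting all enabled thresholds (order-independent).

    Defaults follow the published filter set: significance by the combine
    rule, |difference between peak and gene log2 fold change| >= 1, and a
    minimum peak read count of 10 across all replicates and conditions.
    ``exonic_only`` additionally requires membership in ``exon_peak_ids``
    (peaks intersecting a user-supplied exon BED).
    """
    keep = calls["delta_log2fc"] >= min_delta
    keep &= calls["min_peak_count"] >= min_count
    if "significant" in calls.columns:
        keep &= calls["significant"].astype(bool)
    if exonic_only:
        if exon_peak_ids is None:
            raise ValueError("exonic_only requires exon_peak_ids")
        keep &= calls["peak_id"].isin(exon_peak_ids)
    return calls.loc[keep].reset_index(drop=True)


@dataclass
class PipelineResult:
    glm_results: dict[str, pd.DataFrame]
    calls: pd.DataFrame
    filtered: pd.DataFrame
    size_factors: pd.Series


def run_pipeline(
    experiment: CountExperiment,
    variants: tuple[str, ...] = VARIANTS,
    rule: str = "union",
    alpha: float = 0.05,
    min_delta: float = 1.0,
    min_count: int = 10,
    exonic_only: bool = False,
    exon_peak_ids: set[str] | None = None,
) -> PipelineResult:
    """Full analysis: normalization -> dispersions -> GLM/LRT per variant ->
    FDR -> fold changes -> combine -> filters."""
    size_factors = estimate_size_factors(experiment.peak_counts, experiment.samples)
    glm_results = {
        v: run_glm_lrt(experiment, variant=v, size_factors=size_factors)
        for v in variants
    }
    calls = compute_fold_changes(experiment, size_factors)
    sig = combine_calls(glm_results, rule=rule, alpha=alpha)
    per_variant_sig = {
        v: set(df.loc[df["fdr"].notna() & (df["fdr"] < alpha), "peak_id"])
        for v, df in glm_results.items()
    }
    calls["significant_by"] = [
        ",".join(sorted(v for v in variants if pid in per_variant_sig[v]))
        for pid in calls["peak_id"]
    ]
    calls["significant"] = calls["peak_id"].isin(sig)
    for v, df in glm_results.items():
        calls = calls.merge(
            df[["peak_id", "p_value", "fdr"]].rename(
                columns={"p_value": f"p_{v}", "fdr": f"fdr_{v}"}),
            on="peak_id", how="left",
        )
    filtered = apply_filters(calls, min_delta=min_delta, min_count=min_count,
                             exonic_only=exonic_only, exon_peak_ids=exon_peak_ids)
    calls["passes_filters"] = calls["peak_id"].isin(set(filtered["peak_id"]))
    return PipelineResult(glm_results, calls, filtered, size_factors)
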