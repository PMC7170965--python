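"""Replicate-subsampling power analysis.

How many replicates does statistical detection of a peak change need?  For
each candidate replicate number k, replicates are randomly subsampled
(without replacement, independently per condition, IP/input pairs kept
together), the full differential pipeline re-run on the reduced design —
including re-estimation of size factors and dispersions, as a real
k-replicate study would — and the fraction of subsamples in which each peak
is called significant recorded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffmeth import combine_calls, run_glm_lrt
from .model import CountExperiment

logger = logging.getLogger(__name__)


def _subsample_experiment(
    experiment: CountExperiment, k: int, rng: np.random.Generator
) -> CountExperiment:
    """Keep k random replicates per condition, both fractions of each."""
    keep_ids = []
    for cond in ("control", "treated"):
        reps = sorted({s.replicate for s in experiment.samples if s.condition == cond})
        chosen = set(rng.choice(reps, size=k, replace=False).tolist())
        keep_ids.extend(
            s.sample_id for s in experiment.samples
            if s.condition == cond and s.replicate in chosen
        )
    return experiment.subset_samples(keep_ids)


def subsample_power(
    experiment: CountExperiment,
    k_grid: tuple[int, ...],
    n_subsamples: int = 10,
    alpha: float = 0.05,
    rule: str = "union",
    variants: tuple[str, ...] = ("trend_shrink",),
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of random k-replicate subsamples in which each peak is called
    significant (FDR < alpha, combined across ``variants`` by ``rule``).

    When k equals the full replicate count there is a single deterministic
    run, so the fraction is exactly 0 or 1.  k values below the GLM minimum
    (2 per condition) are skipped with a warning.
    """
    reps_per_cond = experiment.n_replicates_per_condition
    n_full = min(reps_per_cond.values())
    rng = np.random.default_rng(seed)
    peak_ids = list(experiment.peak_counts.index)
    records = []
    for k in k_grid:
        if k < 2:
            logger.warning("k=%d below the GLM minimum of 2 replicates; skipped", k)
            continue
        if k > n_full:
            logger.warning("k=%d exceeds available replicates (%d); skipped", k, n_full)
            continue
        draws = 1 if k == n_full else n_subsamples
        hits = pd.Series(0.0, index=peak_ids)
        for _ in range(draws):
            sub = (experiment if k == n_full
                   else _subsample_experiment(experiment, k, rng))
            results = {v: run_glm_lrt(sub, variant=v) for v in variants}
            sig = combine_calls(results, rule=rule, alpha=alpha)
            hits.loc[list(sig & set(peak_ids))] += 1.0
        frac = hits / draws
        for pid in peak_ids:
            records.append({
                "peak_id": pid, "k": k, "n_subsamples": draws,
                "fraction_detected": float(frac.loc[pid]),
            })
    return pd.DataFrame(records)


def consistent_detection_threshold(
    power_table: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Smallest k at which each peak is detected in >= ``min_fraction`` of
    subsamples ("consistent detection"); NaN when never reached.  Includes a
    quartile summary of the k* distribution in the DataFrame attrs."""
    rows = []
    for pid, sub in power_table.groupby("peak_id", sort=False):
        sub = sub.sort_values("k")
        ok = sub.loc[sub["fraction_detected"] >= min_fraction, "k"]
        rows.append({"peak_id": pid,
                     "k_star": float(ok.iloc[0]) if len(ok) else float("nan")})
    out = pd.DataFrame(rows)
    reached = out["k_star"].dropna()
    out.attrs["summary"] = {
        "n_peaks": len(out),
        "n_reached": int(reached.size),
        "q1": float(reached.quantile(0.25)) if reached.size else float("nan"),
        "median": float(reached.median()) if reached.size else float("nan"),
        "q3": float(reached.quantile(0.75)) if reached.size else float("nan"),
    }
    return out
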