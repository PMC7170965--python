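"""Peak-level reproducibility metrics.

Peak identity across replicates and experiments is positional: two peaks are
"the same" when their intervals share at least one base, the bedtools-style
convention used throughout MeRIP-seq comparisons.  Metrics: cross-experiment
overlap percentages gated on expressed genes, replicate saturation and
recurrence curves, coverage-threshold saturation, DRAC-motif enrichment
against shuffled intervals, and mean +/- SD coverage summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CoverageTrack, PeakInterval

DRAC_RE = re.compile("[AGT][AG]AC")


@dataclass
class OverlapResult:
    n_considered: int
    n_overlapping: int
    percent_overlap: float | None  # None when no peak passes the gate
    expression_gate: float


@dataclass
class SaturationCurve:
    x: list
    y: list
    subsample_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def merge_intervals(peaks: list[PeakInterval]) -> list[PeakInterval]:
    """Union of intervals: maximal covered runs, sorted by (chrom, start).

    Equivalent to a per-base union (bedtools-merge semantics): overlapping
    and bookended intervals join into one run.
    """
    by_chrom: dict[str, list[PeakInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[PeakInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        genes = {ivs[0].gene_id} if ivs[0].gene_id else set()
        for p in ivs[1:]:
            if p.start <= cur_end:  # overlapping or bookended
                cur_end = max(cur_end, p.end)
                if p.gene_id:
                    genes.add(p.gene_id)
            else:
                out.append(PeakInterval(chrom, cur_start, cur_end,
                                        peak_id=f"merged_{chrom}_{cur_start}",
                                        gene_id=min(genes) if genes else ""))
                cur_start, cur_end = p.start, p.end
                genes = {p.gene_id} if p.gene_id else set()
        out.append(PeakInterval(chrom, cur_start, cur_end,
                                peak_id=f"merged_{chrom}_{cur_start}",
                                gene_id=min(genes) if genes else ""))
    return out


def merge_replicate_peaks(peak_sets: list[list[PeakInterval]]) -> list[PeakInterval]:
    """Merged union peak set across replicates."""
    return merge_intervals([p for ps in peak_sets for p in ps])


def _overlaps_any(peak: PeakInterval, sorted_peaks: list[PeakInterval]) -> bool:
    """>=1 base overlap against a chrom-sorted list (linear scan is fine at
    the set sizes these metrics see)."""
    return any(peak.overlaps(q) for q in sorted_peaks)


def _membership_matrix(
    union: list[PeakInterval], peak_sets: list[list[PeakInterval]]
) -> np.ndarray:
    """bool matrix union-peaks x replicates: union peak hit (>=1 base) by a
    peak of that replicate."""
    m = np.zeros((len(union), len(peak_sets)), dtype=bool)
    for j, ps in enumerate(peak_sets):
        for i, u in enumerate(union):
            m[i, j] = _overlaps_any(u, ps)
    return m


# ---------------------------------------------------------------------------
# cross-experiment overlap
# ---------------------------------------------------------------------------

def overlap_percent(
    peaks1: list[PeakInterval],
    peaks2: list[PeakInterval],
    coverage1: dict[str, float],
    coverage2: dict[str, float],
    min_cov: float = 10.0,
) -> OverlapResult:
    """Percent of experiment-1 peaks sharing >= 1 base with an experiment-2
    peak, counting only peaks on genes with mean input coverage >= ``min_cov``
    in BOTH experiments (the gate applies symmetrically to numerator and
    denominator).  Asymmetric by construction: swap arguments for the
    reverse direction.
    """
    def expressed(p: PeakInterval) -> bool:
        return (coverage1.get(p.gene_id, 0.0) >= min_cov
                and coverage2.get(p.gene_id, 0.0) >= min_cov)

    considered = [p for p in peaks1 if expressed(p)]
    targets = [p for p in peaks2 if expressed(p)]
    n_over = sum(_overlaps_any(p, targets) for p in considered)
    pct = 100.0 * n_over / len(considered) if considered else None
    return OverlapResult(len(considered), n_over, pct, min_cov)


# ---------------------------------------------------------------------------
# replicate saturation / recurrence
# ---------------------------------------------------------------------------

def replicate_saturation(
    peak_sets: list[list[PeakInterval]],
    n_subsamples_per_k: int = 6,
    seed: int = 0,
) -> SaturationCurve:
    """Unique (merged-union) peaks captured by random k-replicate subsets.

    For each k in 1..n, ``n_subsamples_per_k`` random subsets are drawn (a
    single draw when k = n) and the number of union peaks hit by at least one
    member recorded.  One (x, y) pair per subsample.
    """
    n = len(peak_sets)
    if n < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    union = merge_replicate_peaks(peak_sets)
    member = _membership_matrix(union, peak_sets)
    xs, ys, ids = [], [], []
    for k in range(1, n + 1):
        draws = 1 if k == n else n_subsamples_per_k
        for d in range(draws):
            subset = rng.choice(n, size=k, replace=False)
            xs.append(k)
            ys.append(int(member[:, subset].any(axis=1).sum()))
            ids.append(f"k{k}_s{d}:" + ",".join(map(str, sorted(subset))))
    return SaturationCurve(xs, ys, ids)


def recurrence_curve(peak_sets: list[list[PeakInterval]]) -> SaturationCurve:
    """Percent of merged-union peaks present (>=1 base overlap) in at least r
    replicates, for r = 1..n.  Monotone non-increasing; r = 1 gives 100%."""
    n = len(peak_sets)
    if n < 2:
        raise ValueError("need >= 2 replicates")
    union = merge_replicate_peaks(peak_sets)
    counts = _membership_matrix(union, peak_sets).sum(axis=1)
    total = len(union)
    xs = list(range(1, n + 1))
    ys = [100.0 * float(np.sum(counts >= r)) / total if total else 0.0 for r in xs]
    return SaturationCurve(xs, ys)


def coverage_saturation(
    gene_coverage: dict[str, float],
    peak_sets: list[list[PeakInterval]],
    thresholds: tuple[int, ...] = (1, 2, 3),
    n_bins: int = 20,
) -> dict[int, SaturationCurve]:
    """Percent of genes with >= k merged peaks, per log-spaced mean input
    coverage bin, one curve per threshold k.

    Genes at zero coverage go to the lowest bin.  As a scalar operating point
    the smallest bin where a curve first reaches 90% of its plateau is a
    practical read-out of the coverage needed to avoid missing peaks.
    """
    merged = merge_replicate_peaks(peak_sets)
    peaks_per_gene: dict[str, int] = {}
    for p in merged:
        if p.gene_id:
            peaks_per_gene[p.gene_id] = peaks_per_gene.get(p.gene_id, 0) + 1
    genes = sorted(gene_coverage)
    cov = np.array([gene_coverage[g] for g in genes], dtype=float)
    npk = np.array([peaks_per_gene.get(g, 0) for g in genes])
    pos = cov[cov > 0]
    if pos.size == 0:
        edges = np.array([0.0, 1.0])
    else:
        lo, hi = pos.min(), max(pos.max(), pos.min() * 1.001)
        edges = np.exp(np.linspace(np.log(lo), np.log(hi), n_bins + 1))
    which = np.clip(np.searchsorted(edges, cov, side="right") - 1, 0, len(edges) - 2)
    out: dict[int, SaturationCurve] = {}
    for k in thresholds:
        xs, ys = [], []
        for b in range(len(edges) - 1):
            sel = which == b
            if not sel.any():
                continue
            xs.append(float(np.sqrt(edges[b] * edges[b + 1])))  # bin geometric center
            ys.append(100.0 * float(np.mean(npk[sel] >= k)))
        out[k] = SaturationCurve(xs, ys)
    return out


def plateau_threshold(curve: SaturationCurve, plateau_fraction: float = 0.9) -> float | None:
    """Smallest bin center where the curve reaches ``plateau_fraction`` of its
    plateau (its maximum); None if never reached."""
    if not curve.y:
        return None
    target = plateau_fraction * max(curve.y)
    for x, y in zip(curve.x, curve.y):
        if y >= target:
            return x
    return None


# ---------------------------------------------------------------------------
# DRAC motif enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    observed_fraction: float
    background_fraction: float
    enrichment_ratio: float | None  # None when 0/0; capped when inf
    empirical_p: float
    capped: bool
    n_shuffles: int


RATIO_CAP = 1e6


def drac_enrichment(
    peaks: list[PeakInterval],
    sequences: dict[str, str],
    n_shuffles: int = 100,
    seed: int = 0,
) -> MotifEnrichment:
    """DRAC ([AGT][AG]AC on DNA, U mapped to T) presence in peaks versus
    shuffled same-length intervals within the same gene's sequence.

    Background intervals preserve length and gene of origin (composition
    control).  empirical p = (1 + #shuffled fractions >= observed) /
    (n_shuffles + 1).  A zero background with nonzero observed fraction caps
    the ratio and sets ``capped``; all-zero observed and background leaves
    the ratio missing.
    """
    rng = np.random.default_rng(seed)
    gene_seq = {g: s.upper().replace("U", "T") for g, s in sequences.items()}

    def gene_origin(p: PeakInterval) -> int:
        # genes laid out by the simulator start at multiples of 10 kb; for
        # user-supplied sequences the sequence is assumed to start at 0
        return (p.start // 10_000) * 10_000 if p.start >= 10_000 else 0

    usable = [p for p in peaks if p.gene_id in gene_seq]
    if not usable:
        raise ValueError("no peak has a sequence for its gene")

    def has_motif(p: PeakInterval, start_override: int | None = None) -> bool:
        seq = gene_seq[p.gene_id]
        origin = gene_origin(p)
        a = (p.start if start_override is None else start_override) - origin
        a = max(a, 0)
        b = min(a + len(p), len(seq))
        return DRAC_RE.search(seq[a:b]) is not None

    observed = float(np.mean([has_motif(p) for p in usable]))
    bg_fracs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        hits = []
        for p in usable:
            seq = gene_seq[p.gene_id]
            origin = gene_origin(p)
            span = max(len(seq) - len(p), 1)
            a = origin + int(rng.integers(0, span))
            hits.append(has_motif(p, start_override=a))
        bg_fracs[s] = float(np.mean(hits))
    bg_mean = float(bg_fracs.mean())
    capped = False
    if bg_mean > 0:
        ratio: float | None = observed / bg_mean
    elif observed > 0:
        ratio, capped = RATIO_CAP, True
    else:
        ratio = None
    p_emp = (1.0 + float(np.sum(bg_fracs >= observed))) / (n_shuffles + 1.0)
    return MotifEnrichment(observed, bg_mean, ratio, p_emp, capped, n_shuffles)


# ---------------------------------------------------------------------------
# coverage summaries
# ---------------------------------------------------------------------------

def coverage_summary(tracks: list[CoverageTrack]) -> pd.DataFrame:
    """Per-position mean and sample SD (n-1 denominator; 0 when n = 1) of
    depth across replicates, per gene x fraction x condition — the numeric
    form of mean +/- SD coverage plots."""
    rows = []
    for t in tracks:
        nrep = t.per_replicate_depth.shape[0]
        mean = t.per_replicate_depth.mean(axis=0)
        sd = (t.per_replicate_depth.std(axis=0, ddof=1) if nrep > 1
              else np.zeros_like(mean))
        rows.append(pd.DataFrame({
            "gene_id": t.gene_id, "fraction": t.fraction,
            "condition": t.condition, "position": t.positions,
            "mean_depth": mean, "sd_depth": sd, "n_replicates": nrep,
        }))
    return pd.concat(rows, ignore_index=True)


def plot_coverage_summary(summary: pd.DataFrame, gene_id: str, path,
                          scale_per_condition: bool = False) -> None:
    """Mean line with +/- SD shading per fraction x condition for one gene;
    optionally an independent y scale per condition (which makes changes
    proportional to expression visually obvious)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["gene_id"] == gene_id]
    conditions = sorted(sub["condition"].unique())
    fig, axes = plt.subplots(len(conditions), 1, figsize=(8, 3 * len(conditions)),
                             sharey=not scale_per_condition, squeeze=False)
    for ax, cond in zip(axes[:, 0], conditions):
        for fraction, color in (("input", "0.2"), ("IP", "crimson")):
            s = sub[(sub["condition"] == cond) & (sub["fraction"] == fraction)]
            if s.empty:
                continue
            ax.plot(s["position"], s["mean_depth"], color=color, label=fraction)
            ax.fill_between(s["position"], s["mean_depth"] - s["sd_depth"],
                            s["mean_depth"] + s["sd_depth"], color=color, alpha=0.3)
        ax.set_title(f"{gene_id} — {cond}")
        ax.set_ylabel("depth")
        ax.legend()
    axes[-1, 0].set_xlabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
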