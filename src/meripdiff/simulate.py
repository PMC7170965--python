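"""Synthetic MeRIP-seq experiments with known ground truth.

The generator emulates the count structure the differential-methylation
model assumes: paired IP/input libraries per replicate, negative-binomial
counts with a mean-dependent dispersion trend phi(mu) = a0 + a1/mu, unequal
library sizes, condition effects on gene expression (visible in input
counts) and on IP enrichment (the true methylation change, i.e. the
interaction the GLM tests).  Expected counts follow

    input  peak/gene, sample j: s_j * r_j * baseline * 2^(expr_lfc * treated_j)
    IP     peak,       sample j: the input mean * ip_enrichment
                                 * 2^(meth_lfc * treated_j)

with s_j a library size factor and r_j a lognormal replicate-pair scale
shared by each replicate's IP and input libraries (biological pairing).

All draws come from one `numpy.random.default_rng(seed)`; identical seeds
give identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_fasta, write_peaks_bed
from .model import CountExperiment, CoverageTrack, PeakInterval, SampleInfo


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror a well-powered two-condition MeRIP-seq comparison used
    as the calibration setting throughout: ~2000 peaks (one per gene), six
    paired IP/input replicates per condition, input means log-uniform over
    50–500 reads, dispersion trend a0=0.05, a1=5 (typical bulk RNA-seq
    magnitudes), four-fold IP enrichment at methylated peaks, and modest
    library-size variation.
    """

    n_genes: int = 2000
    peaks_per_gene: int = 1
    n_replicates_per_condition: int = 6
    baseline_gene_mean: float = 158.0  # geometric center of baseline_range
    baseline_range: tuple[float, float] = (50.0, 500.0)  # log-uniform draw
    ip_enrichment: float = 4.0
    dispersion_model: tuple[float, float] = (0.05, 5.0)  # phi(mu) = a0 + a1/mu
    expression_log2fc: float = 1.0
    fraction_expression_changed: float = 0.0
    methylation_log2fc: float = 1.0
    fraction_changed: float = 0.0
    gene_length_factor: float = 3.0  # gene input mean / peak input mean
    library_size_sigma: float = 0.2  # lognormal sigma of per-library factors
    library_size_factors: list[float] | None = None
    pair_sigma: float = 0.1  # lognormal sigma of replicate-pair scale
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.baseline_range
        if lo <= 0 or hi < lo:
            raise ValueError("baseline_range must be positive and ordered")
        if self.ip_enrichment <= 0 or self.baseline_gene_mean <= 0:
            raise ValueError("mean parameters must be positive")
        if not (0.0 <= self.fraction_changed <= 1.0):
            raise ValueError("fraction_changed must be in [0, 1]")
        if not (0.0 <= self.fraction_expression_changed <= 1.0):
            raise ValueError("fraction_expression_changed must be in [0, 1]")
        a0, a1 = self.dispersion_model
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend coefficients must be >= 0")

    def dispersion(self, mu: np.ndarray) -> np.ndarray:
        a0, a1 = self.dispersion_model
        return a0 + a1 / np.maximum(np.asarray(mu, dtype=float), 1e-8)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated experiment."""

    peak_truth: pd.DataFrame   # peak_id, gene_id, methylation_log2fc, changed
    gene_truth: pd.DataFrame   # gene_id, expression_log2fc

    @property
    def n_changed(self) -> int:
        return int(self.peak_truth["changed"].sum())


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi*mu^2; phi -> 0 degenerates to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _sample_layout(n_reps: int) -> list[SampleInfo]:
    samples = []
    for cond in ("control", "treated"):
        for rep in range(1, n_reps + 1):
            for frac in ("input", "IP"):
                samples.append(SampleInfo(
                    sample_id=f"{cond}_{rep}_{frac}",
                    fraction=frac, condition=cond, replicate=rep,
                ))
    return samples


def simulate_experiment(config: SimulationConfig) -> tuple[CountExperiment, SimTruth]:
    """Draw a paired IP/input NB count experiment with known effects.

    A ``fraction_changed`` share of peaks receives the methylation effect
    (|log2FC| = ``methylation_log2fc``, random sign) on IP counts in the
    treated condition only; a ``fraction_expression_changed`` share of genes
    similarly receives an expression effect on all counts of the gene.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_peaks = n_genes * config.peaks_per_gene
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    lo, hi = config.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    # per-gene expression effects (signed), per-peak methylation effects
    expr_lfc = np.zeros(n_genes)
    n_de = int(round(config.fraction_expression_changed * n_genes))
    if n_de:
        idx = rng.choice(n_genes, size=n_de, replace=False)
        expr_lfc[idx] = config.expression_log2fc * rng.choice([-1.0, 1.0], size=n_de)
    meth_lfc = np.zeros(n_peaks)
    n_ch = int(round(config.fraction_changed * n_peaks))
    if n_ch:
        idx = rng.choice(n_peaks, size=n_ch, replace=False)
        meth_lfc[idx] = config.methylation_log2fc * rng.choice([-1.0, 1.0], size=n_ch)

    samples = _sample_layout(config.n_replicates_per_condition)
    n_samples = len(samples)
    if config.library_size_factors is not None:
        sf = np.asarray(config.library_size_factors, dtype=float)
        if sf.size != n_samples or (sf <= 0).any():
            raise ValueError(f"need {n_samples} positive library size factors")
    else:
        sf = np.exp(rng.normal(0.0, config.library_size_sigma, size=n_samples))
    sf = sf / np.exp(np.mean(np.log(sf)))
    pair_scale = {
        (cond, rep): float(np.exp(rng.normal(0.0, config.pair_sigma)))
        for cond in ("control", "treated")
        for rep in range(1, config.n_replicates_per_condition + 1)
    }

    treated = np.array([1.0 if s.condition == "treated" else 0.0 for s in samples])
    is_ip = np.array([s.fraction == "IP" for s in samples])
    scale_j = sf * np.array([pair_scale[(s.condition, s.replicate)] for s in samples])

    # peaks: gene baseline scaled; peak input mean == gene baseline
    peak_gene_idx = np.repeat(np.arange(n_genes), config.peaks_per_gene)
    peak_base = baseline[peak_gene_idx]
    peak_mu = (peak_base[:, None]
               * 2.0 ** (expr_lfc[peak_gene_idx][:, None] * treated[None, :])
               * scale_j[None, :])
    ip_factor = (config.ip_enrichment
                 * 2.0 ** (meth_lfc[:, None] * treated[None, :]))
    peak_mu[:, is_ip] *= ip_factor[:, is_ip]
    peak_counts = _nb_draw(rng, peak_mu, config.dispersion(peak_mu))

    gene_mu = (config.gene_length_factor * baseline[:, None]
               * 2.0 ** (expr_lfc[:, None] * treated[None, :])
               * scale_j[None, :])
    gene_mu[:, is_ip] *= config.ip_enrichment  # gene-body IP coverage scale
    gene_counts = _nb_draw(rng, gene_mu, config.dispersion(gene_mu))

    sample_ids = [s.sample_id for s in samples]
    peak_ids = [f"peak{i:05d}" for i in range(n_peaks)]
    peaks = []
    for i, pid in enumerate(peak_ids):
        gstart = 10_000 * peak_gene_idx[i]
        offset = 1_000 * (i % config.peaks_per_gene)
        peaks.append(PeakInterval(
            chrom="chrS", start=gstart + 200 + offset, end=gstart + 400 + offset,
            strand="+", peak_id=pid, gene_id=gene_ids[peak_gene_idx[i]],
        ))
    experiment = CountExperiment(
        peak_counts=pd.DataFrame(peak_counts, index=peak_ids, columns=sample_ids),
        gene_counts=pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids),
        peaks=peaks,
        samples=samples,
    )
    truth = SimTruth(
        peak_truth=pd.DataFrame({
            "peak_id": peak_ids,
            "gene_id": [gene_ids[g] for g in peak_gene_idx],
            "methylation_log2fc": meth_lfc,
            "changed": meth_lfc != 0.0,
        }),
        gene_truth=pd.DataFrame({
            "gene_id": gene_ids,
            "expression_log2fc": expr_lfc,
        }),
    )
    return experiment, truth


def simulate_null(config: SimulationConfig) -> tuple[CountExperiment, SimTruth]:
    """Negative control: the same design with all effect sizes zero, as in a
    many-replicate baseline experiment split into two arbitrary groups."""
    null_cfg = dataclasses.replace(
        config, fraction_changed=0.0, fraction_expression_changed=0.0,
    )
    return simulate_experiment(null_cfg)


def simulate_peak_sets(
    n_replicates: int,
    n_true_sites: int,
    detection_prob: float,
    seed: int = 0,
    peak_length: int = 200,
    spacing: int = 500,
) -> list[list[PeakInterval]]:
    """Independent per-replicate detection of a fixed universe of sites.

    Each of ``n_true_sites`` (disjoint intervals on one synthetic chromosome)
    is detected independently in each replicate with probability
    ``detection_prob``; every replicate's set is a subset of the universe.
    """
    if not (0.0 < detection_prob <= 1.0):
        raise ValueError("detection_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = [
        PeakInterval("chrS", i * spacing, i * spacing + peak_length,
                     strand="+", peak_id=f"site{i:05d}", gene_id=f"gene{i:05d}")
        for i in range(n_true_sites)
    ]
    out = []
    for _ in range(n_replicates):
        detected = rng.random(n_true_sites) < detection_prob
        out.append([universe[i] for i in np.flatnonzero(detected)])
    return out


_BASES = np.array(list("ACGT"))


def simulate_sequences_and_coverage(
    experiment: CountExperiment,
    truth: SimTruth,
    seed: int = 0,
    read_length: int = 50,
    motif_planting_rate: float = 1.0,
    gene_length: int = 1000,
    background_alphabet: str = "ACGT",
) -> tuple[dict[str, str], list[CoverageTrack]]:
    """Per-gene sequences with DRAC motifs planted in methylated peaks, plus
    per-replicate coverage tracks consistent with the simulated counts.

    Methylated (changed) peaks receive a GGACT motif at the peak center with
    probability ``motif_planting_rate``.  IP coverage is piecewise constant
    over each peak such that the track sum over the peak equals
    count * read_length (within rounding); input coverage is flat over the
    gene at the gene's per-base rate.
    """
    if not (0.0 <= motif_planting_rate <= 1.0):
        raise ValueError("motif planting rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list(background_alphabet.upper().replace("U", "T")))
    changed = dict(zip(truth.peak_truth["peak_id"], truth.peak_truth["changed"]))
    peaks_by_gene: dict[str, list[PeakInterval]] = {}
    for p in experiment.peaks:
        peaks_by_gene.setdefault(p.gene_id, []).append(p)

    seqs: dict[str, str] = {}
    gene_start: dict[str, int] = {}
    for gene_id in experiment.gene_counts.index:
        seq = rng.choice(bases, size=gene_length)
        start = min((p.start for p in peaks_by_gene.get(gene_id, [])), default=0)
        start = (start // 10_000) * 10_000  # gene origin on the synthetic chrom
        gene_start[gene_id] = start
        for p in peaks_by_gene.get(gene_id, []):
            if changed.get(p.peak_id) and rng.random() < motif_planting_rate:
                mid = (p.start + p.end) // 2 - start
                mid = min(max(mid, 0), gene_length - 5)
                seq[mid:mid + 5] = list("GGACT")
        seqs[gene_id] = "".join(seq)

    tracks: list[CoverageTrack] = []
    counts = experiment.peak_counts
    positions = np.arange(gene_length)
    for gene_id in experiment.gene_counts.index:
        start = gene_start[gene_id]
        for fraction in ("input", "IP"):
            for condition in ("control", "treated"):
                reps = sorted({s.replicate for s in experiment.samples
                               if s.fraction == fraction and s.condition == condition})
                depth = np.zeros((len(reps), gene_length))
                for ri, rep in enumerate(reps):
                    sid = next(s.sample_id for s in experiment.samples
                               if (s.fraction, s.condition, s.replicate)
                               == (fraction, condition, rep))
                    gcount = int(experiment.gene_counts.loc[gene_id, sid])
                    depth[ri, :] = gcount * read_length / gene_length
                    if fraction == "IP":
                        for p in peaks_by_gene.get(gene_id, []):
                            c = int(counts.loc[p.peak_id, sid])
                            a, b = p.start - start, p.end - start
                            width = b - a
                            total = c * read_length
                            base_d, rem = divmod(total, width)
                            depth[ri, a:b] = base_d
                            depth[ri, a:a + rem] += 1
                tracks.append(CoverageTrack(
                    gene_id=gene_id, fraction=fraction, condition=condition,
                    positions=positions + start, per_replicate_depth=depth,
                ))
    return seqs, tracks


# ---------------------------------------------------------------------------
# fixture directory emission (exact dialects data_model_io reads)
# ---------------------------------------------------------------------------

def write_fixture_dir(
    outdir: str | Path,
    config: SimulationConfig,
    with_sequences: bool = False,
) -> Path:
    """Simulate and write counts, sample sheet, peak BED and truth tables
    (optionally FASTA + coverage) in the dialects the readers consume.
    Data files carry '#'-prefixed provenance headers including the seed, and
    are byte-identical across runs with the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiment, truth = (simulate_null(config) if config.fraction_changed == 0
                         and config.fraction_expression_changed == 0
                         else simulate_experiment(config))
    header = f"# meripdiff simulation; seed: {config.seed}\n"

    def _write_table(df: pd.DataFrame, name: str, index_label: str | None) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index_label is not None,
                      index_label=index_label)

    _write_table(experiment.peak_counts, "peak_counts.tsv", "peak_id")
    _write_table(experiment.gene_counts, "gene_counts.tsv", "gene_id")
    sheet = pd.DataFrame([dataclasses.asdict(s) for s in experiment.samples])
    sheet = sheet.drop(columns=["library_size"])
    _write_table(sheet, "samples.tsv", None)
    write_peaks_bed(experiment.peaks, outdir / "peaks.bed")
    p2g = pd.DataFrame({"peak_id": [p.peak_id for p in experiment.peaks],
                        "gene_id": [p.gene_id for p in experiment.peaks]})
    _write_table(p2g, "peak_to_gene.tsv", None)
    _write_table(truth.peak_truth, "truth_peaks.tsv", None)
    _write_table(truth.gene_truth, "truth_genes.tsv", None)
    with open(outdir / "config.yaml", "w") as fh:
        import yaml

        cfg = dataclasses.asdict(config)
        cfg["baseline_range"] = list(config.baseline_range)
        cfg["dispersion_model"] = list(config.dispersion_model)
        yaml.safe_dump(cfg, fh, sort_keys=True)
    if with_sequences:
        seqs, tracks = simulate_sequences_and_coverage(
            experiment, truth, seed=config.seed)
        write_fasta(seqs, outdir / "sequences.fasta")
        rows = []
        for t in tracks:
            for ri in range(t.per_replicate_depth.shape[0]):
                rows.append(pd.DataFrame({
                    "gene_id": t.gene_id, "fraction": t.fraction,
                    "condition": t.condition, "replicate": ri + 1,
                    "position": t.positions,
                    "depth": t.per_replicate_depth[ri],
                }))
        _write_table(pd.concat(rows, ignore_index=True), "coverage.tsv", None)
    return outdir


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file; unknown keys are an error."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown simulation config key(s): {sorted(unknown)}")
    if "baseline_range" in raw:
        raw["baseline_range"] = tuple(raw["baseline_range"])
    if "dispersion_model" in raw:
        raw["dispersion_model"] = tuple(raw["dispersion_model"])
    return SimulationConfig(**raw)
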