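"""Shared data model for MeRIP-seq count analysis.

A MeRIP-seq experiment measures RNA methylation as peaks of coverage in an
immunoprecipitated (IP) library relative to an input (non-IP) library from
the same biological replicate.  The analysis here operates on two count
matrices — reads in peaks and reads in genes, each peaks/genes x samples —
plus a sample sheet assigning every library a fraction (IP or input), a
condition (treated or control) and a replicate number.

Coordinates are 0-based half-open throughout (BED convention); any 1-based
display is formatting only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}
VALID_FRACTIONS = {"IP", "input"}
VALID_CONDITIONS = {"treated", "control"}


class ValidationError(ValueError):
    """Raised when inputs violate the data-model invariants."""


@dataclass(frozen=True)
class PeakInterval:
    """A genomic interval (0-based, half-open) with optional gene assignment."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    peak_id: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "PeakInterval") -> bool:
        """True if the two intervals share >= 1 base on the same chromosome."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SampleInfo:
    """One sequencing library: fraction (IP/input), condition, replicate."""

    sample_id: str
    fraction: str
    condition: str
    replicate: int
    library_size: float = float("nan")

    def __post_init__(self) -> None:
        if self.fraction not in VALID_FRACTIONS:
            raise ValidationError(
                f"{self.sample_id}: fraction must be IP or input, got {self.fraction!r}"
            )
        if self.condition not in VALID_CONDITIONS:
            raise ValidationError(
                f"{self.sample_id}: condition must be treated or control, got {self.condition!r}"
            )


@dataclass
class CoverageTrack:
    """Per-base depth for one gene, one fraction x condition, replicates x positions."""

    gene_id: str
    fraction: str
    condition: str
    positions: np.ndarray
    per_replicate_depth: np.ndarray  # replicates x positions

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.per_replicate_depth = np.atleast_2d(
            np.asarray(self.per_replicate_depth, dtype=float)
        )
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError(f"{self.gene_id}: positions must be strictly increasing")
        if np.any(self.per_replicate_depth < 0):
            raise ValidationError(f"{self.gene_id}: depth must be non-negative")
        if self.per_replicate_depth.shape[1] != self.positions.size:
            raise ValidationError(
                f"{self.gene_id}: depth matrix columns must match positions"
            )


@dataclass
class CountExperiment:
    """Peak and gene count matrices plus sample annotations.

    peak_counts / gene_counts are DataFrames indexed by peak_id / gene_id with
    one column per sample, column order matching ``samples``.
    """

    peak_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    peaks: list[PeakInterval]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("sample_id")

    @property
    def peak_to_gene(self) -> dict[str, str]:
        return {p.peak_id: p.gene_id for p in self.peaks}

    @property
    def n_replicates_per_condition(self) -> dict[str, int]:
        reps: dict[str, set[int]] = {}
        for s in self.samples:
            reps.setdefault(s.condition, set()).add(s.replicate)
        return {cond: len(v) for cond, v in reps.items()}

    def mask(self, fraction: str | None = None, condition: str | None = None) -> np.ndarray:
        """Boolean mask over samples (in column order)."""
        out = np.ones(len(self.samples), dtype=bool)
        if fraction is not None:
            out &= np.array([s.fraction == fraction for s in self.samples])
        if condition is not None:
            out &= np.array([s.condition == condition for s in self.samples])
        return out

    def subset_samples(self, sample_ids: list[str]) -> "CountExperiment":
        """Column subset preserving the given sample order."""
        keep = {sid: s for s in self.samples for sid in [s.sample_id]}
        missing = [sid for sid in sample_ids if sid not in keep]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return CountExperiment(
            peak_counts=self.peak_counts[sample_ids].copy(),
            gene_counts=self.gene_counts[sample_ids].copy(),
            peaks=list(self.peaks),
            samples=[keep[sid] for sid in sample_ids],
        )

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        for df, what in ((self.peak_counts, "peak"), (self.gene_counts, "gene")):
            if list(df.columns) != ids:
                raise ValidationError(
                    f"{what} count columns {list(df.columns)} do not match sample order {ids}"
                )
            arr = df.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValidationError(f"non-integer {what} counts")
            if (arr < 0).any():
                raise ValidationError(f"negative {what} counts")
        triples = [(s.fraction, s.condition, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValidationError("duplicate (fraction, condition, replicate) triple")
        # every IP library must have a paired input library
        inputs = {(s.condition, s.replicate) for s in self.samples if s.fraction == "input"}
        for s in self.samples:
            if s.fraction == "IP" and (s.condition, s.replicate) not in inputs:
                raise ValidationError(
                    f"IP sample {s.sample_id} has no matching input library "
                    f"(condition={s.condition}, replicate={s.replicate})"
                )
        peak_ids = [p.peak_id for p in self.peaks]
        if len(set(peak_ids)) != len(peak_ids):
            raise ValidationError("duplicate peak ids")
        if set(self.peak_counts.index) != set(peak_ids):
            raise ValidationError("peak_counts index does not match peak list")
        for p in self.peaks:
            if not p.gene_id:
                raise ValidationError(f"peak {p.peak_id} has no gene assignment")
            if p.gene_id not in self.gene_counts.index:
                raise ValidationError(
                    f"peak {p.peak_id} maps to gene {p.gene_id} absent from gene_counts"
                )


def design_matrix(samples: list[SampleInfo], model: str = "full") -> np.ndarray:
    """GLM design for log mean count: intercept, IP, condition, and (full only)
    their interaction.  Columns: beta0, beta_ip, beta_stim[, beta_interaction].
    """
    ip = np.array([1.0 if s.fraction == "IP" else 0.0 for s in samples])
    stim = np.array([1.0 if s.condition == "treated" else 0.0 for s in samples])
    cols = [np.ones(len(samples)), ip, stim]
    if model == "full":
        cols.append(ip * stim)
    elif model != "reduced":
        raise ValueError(f"model must be 'full' or 'reduced', got {model!r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient: need >=1 sample in every "
            "fraction x condition cell"
        )
    return X
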