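"""Shared in-memory containers for expression and translatome data.

Matrices are stored genes x samples (the orientation expression compendia
are usually distributed in); estimator-style APIs that follow scikit-learn
conventions transpose to samples x features at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("count", "tpm", "log_tpm")


@dataclass
class ExpressionCompendium:
    """A genes x samples expression matrix with per-sample condition labels.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values in the declared ``unit``.
    gene_ids, sample_ids : sequences of str
        Row and column labels; sample ids must be unique.
    condition_of_sample : dict
        Maps each sample id to its condition label.
    unit : {"count", "tpm", "log_tpm"}
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition_of_sample: dict[str, str]
    unit: str = "log_tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing = [s for s in self.sample_ids if s not in self.condition_of_sample]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        if self.unit == "count" and (np.any(self.values < 0) or np.any(self.values % 1 != 0)):
            raise ValueError("unit 'count' requires non-negative integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of_sample[s], None)
        return list(seen)

    def samples_of_condition(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of_sample[s] == condition]

    def column_indices(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def tpm_view(self) -> np.ndarray:
        """Linear-scale TPM view of a log2-TPM matrix (pseudocount removed)."""
        if self.unit != "log_tpm":
            raise ValueError("tpm_view is only defined for unit='log_tpm'")
        return np.maximum(2.0 ** self.values - 1.0, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ScaledCompendium:
    """Per-gene min-max scaled expression in [0, 1].

    Holds the scaled matrix plus the (min, max) recorded on the fitting
    partition so held-out samples can be projected and scaling inverted.
    """

    values: np.ndarray  # genes x samples, in [0, 1]
    gene_ids: list[str]
    sample_ids: list[str]
    condition_of_sample: dict[str, str]
    gene_min: np.ndarray
    gene_max: np.ndarray
    fitting_partition: list[str]
    constant_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def samples_of_condition(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of_sample[s] == condition]

    def column_indices(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)


@dataclass
class PairedCountExperiment:
    """Matched Ribo-Seq and RNA-Seq count matrices over a shared design.

    Both assays share the gene universe, condition labels and replicate
    structure; column ``j`` of either matrix is the same biological sample
    measured by the respective assay.
    """

    ribo_counts: np.ndarray  # genes x samples, integers
    rna_counts: np.ndarray
    gene_ids: list[str]
    sample_conditions: list[str]  # condition label per column
    sample_replicates: list[int]  # replicate index per column
    gene_lengths: np.ndarray  # nt

    def __post_init__(self) -> None:
        self.ribo_counts = np.asarray(self.ribo_counts)
        self.rna_counts = np.asarray(self.rna_counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=int)
        n_g, n_s = self.ribo_counts.shape
        if self.rna_counts.shape != (n_g, n_s):
            raise ValueError("ribo and rna count matrices must share shape")
        if len(self.gene_ids) != n_g or len(self.gene_lengths) != n_g:
            raise ValueError("gene ids/lengths do not match matrix rows")
        if len(self.sample_conditions) != n_s or len(self.sample_replicates) != n_s:
            raise ValueError("sample annotations do not match matrix columns")
        for m in (self.ribo_counts, self.rna_counts):
            if np.any(m < 0):
                raise ValueError("counts must be non-negative")
        if np.any(self.gene_lengths < 30):
            raise ValueError("gene lengths below 30 nt are not supported")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.sample_conditions:
            seen.setdefault(c, None)
        return list(seen)

    def columns_of_condition(self, condition: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.sample_conditions) if c == condition], dtype=int)

    def counts(self, assay: str) -> np.ndarray:
        if assay == "ribo":
            return self.ribo_counts
        if assay == "rna":
            return self.rna_counts
        raise ValueError(f"unknown assay {assay!r}")

    def to_tsv(self, path_prefix) -> None:
        """Write one counts TSV per assay, a sample sheet, and gene lengths."""
        for assay in ("ribo", "rna"):
            pd.DataFrame(
                self.counts(assay), index=self.gene_ids,
                columns=[f"{c}_rep{r}" for c, r in zip(self.sample_conditions, self.sample_replicates)],
            ).to_csv(f"{path_prefix}.{assay}.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(
            {
                "sample": [f"{c}_rep{r}" for c, r in zip(self.sample_conditions, self.sample_replicates)],
                "condition": self.sample_conditions,
                "replicate": self.sample_replicates,
            }
        ).to_csv(f"{path_prefix}.samples.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": self.gene_ids, "length_nt": self.gene_lengths}
                     ).to_csv(f"{path_prefix}.lengths.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_prefix) -> "PairedCountExperiment":
        """Read the matrices written by :meth:`to_tsv` back into memory."""
        ribo = pd.read_csv(f"{path_prefix}.ribo.tsv", sep="\t", index_col="gene_id")
        rna = pd.read_csv(f"{path_prefix}.rna.tsv", sep="\t", index_col="gene_id")
        sheet = pd.read_csv(f"{path_prefix}.samples.tsv", sep="\t")
        lengths = pd.read_csv(f"{path_prefix}.lengths.tsv", sep="\t")
        return cls(
            ribo_counts=ribo.to_numpy(),
            rna_counts=rna.to_numpy(),
            gene_ids=list(ribo.index),
            sample_conditions=list(sheet["condition"]),
            sample_replicates=list(sheet["replicate"]),
            gene_lengths=lengths["length_nt"].to_numpy(),
        )
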