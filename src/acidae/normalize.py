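"""Expression-unit conversions and scaling.

Counts are converted to CPM, RPKM or log2-TPM; count matrices get
median-of-ratios size factors; and compendia are min-max scaled per gene
before autoencoder training. The scaler follows scikit-learn conventions
(samples x features) and records per-gene (min, max) from the fitting
partition so held-out samples are projected with the same map.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionCompendium, ScaledCompendium

__all__ = [
    "counts_to_cpm",
    "counts_to_rpkm",
    "counts_to_log_tpm",
    "median_of_ratios_size_factors",
    "GeneMinMaxScaler",
    "fit_minmax_scaler",
]


def counts_to_cpm(counts, sample_id: str = "sample") -> np.ndarray:
    """Counts-per-million: each count divided by the sample total, x 1e6."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total count; CPM undefined")
    return counts / total * 1e6


def counts_to_rpkm(count, gene_length_nt, total_mapped) -> float | np.ndarray:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count / (length/1000) / (total/1e6). Accepts scalars or arrays.
    """
    count = np.asarray(count, dtype=float)
    gene_length_nt = np.asarray(gene_length_nt, dtype=float)
    if np.any(gene_length_nt < 1):
        raise ValueError("gene length must be >= 1 nt")
    if total_mapped < 1:
        raise ValueError("total mapped reads must be >= 1")
    out = count / (gene_length_nt / 1e3) / (total_mapped / 1e6)
    return float(out) if out.ndim == 0 else out


def counts_to_log_tpm(counts, lengths, pseudocount: float = 1.0,
                      sample_id: str = "sample") -> np.ndarray:
    """log2 transcripts-per-million for one sample.

    TPM first length-normalizes each count, then scales rates to sum to 1e6;
    the log is base 2 with an additive pseudocount (default 1, so a TPM of
    zero maps to exactly 0).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 1):
        raise ValueError("gene lengths must be >= 1 nt")
    rates = counts / lengths
    denom = rates.sum()
    if denom <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total count; TPM undefined")
    tpm = rates / denom * 1e6
    return np.log2(tpm + pseudocount)


def median_of_ratios_size_factors(counts, allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios size factors for a genes x samples count matrix.

    The reference per gene is its geometric mean across samples, computed on
    genes with all-positive counts; a sample's factor is the median ratio of
    its counts to the reference over those genes.

    With ``allow_pseudo_reference=True``, genes with at least one positive
    count in every sample are not required; the geometric mean is instead
    taken over positive entries only (the "poscounts" fallback for sparse
    matrices).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a genes x samples matrix")
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; rerun with "
                "allow_pseudo_reference=True to use the positive-count fallback"
            )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        log_gm = np.nanmean(logc, axis=1)
        usable = np.isfinite(log_gm)
    else:
        log_gm = np.full(counts.shape[0], np.nan)
        log_gm[all_positive] = np.log(counts[all_positive]).mean(axis=1)
        usable = all_positive
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratios = np.log(counts[usable]) - log_gm[usable][:, None]
    factors = np.exp(np.nanmedian(np.where(np.isfinite(log_ratios), log_ratios, np.nan), axis=0))
    return factors


class GeneMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-gene min-max scaling to [0, 1], fitted on a declared partition.

    X is samples x genes. Held-out samples transformed after fitting are
    clipped into [0, 1]; genes constant on the fitting partition map to
    ``constant_fill`` (default 0.5, the center of the sigmoid output range)
    and are flagged in ``constant_genes_``.
    """

    def __init__(self, constant_fill: float = 0.5, clip: bool = True):
        self.constant_fill = constant_fill
        self.clip = clip

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty samples x genes matrix")
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.range_ = self.data_max_ - self.data_min_
        self.constant_genes_ = self.range_ == 0
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = np.asarray(X, dtype=float)
        rng = np.where(self.constant_genes_, 1.0, self.range_)
        out = (X - self.data_min_) / rng
        out[:, self.constant_genes_] = self.constant_fill
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "data_min_")
        X = np.asarray(X, dtype=float)
        out = X * self.range_ + self.data_min_
        # constant genes carry no range information; restore the fitted value
        out[:, self.constant_genes_] = self.data_min_[self.constant_genes_]
        return out

    def to_json(self, path) -> None:
        check_is_fitted(self, "data_min_")
        with open(path, "w") as fh:
            json.dump(
                {
                    "data_min": self.data_min_.tolist(),
                    "data_max": self.data_max_.tolist(),
                    "constant_fill": self.constant_fill,
                    "clip": self.clip,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GeneMinMaxScaler":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(constant_fill=d["constant_fill"], clip=d["clip"])
        obj.data_min_ = np.asarray(d["data_min"], dtype=float)
        obj.data_max_ = np.asarray(d["data_max"], dtype=float)
        obj.range_ = obj.data_max_ - obj.data_min_
        obj.constant_genes_ = obj.range_ == 0
        obj.n_features_in_ = obj.data_min_.size
        return obj


def fit_minmax_scaler(compendium: ExpressionCompendium,
                      fitting_partition) -> tuple[ScaledCompendium, GeneMinMaxScaler]:
    """Scale a compendium gene-wise to [0, 1] using only the fitting samples.

    Returns the scaled compendium (all samples transformed, held-out samples
    clipped) together with the fitted scaler for later inversion.
    """
    fitting_partition = list(fitting_partition)
    if not fitting_partition:
        raise ValueError("fitting partition is empty")
    unknown = [s for s in fitting_partition if s not in compendium.sample_ids]
    if unknown:
        raise ValueError(f"fitting partition contains unknown samples: {unknown}")
    cols = compendium.column_indices(fitting_partition)
    scaler = GeneMinMaxScaler().fit(compendium.values[:, cols].T)
    scaled = scaler.transform(compendium.values.T).T
    return (
        ScaledCompendium(
            values=scaled,
            gene_ids=compendium.gene_ids,
            sample_ids=compendium.sample_ids,
            condition_of_sample=dict(compendium.condition_of_sample),
            gene_min=scaler.data_min_.copy(),
            gene_max=scaler.data_max_.copy(),
            fitting_partition=fitting_partition,
            constant_genes=scaler.constant_genes_.copy(),
        ),
        scaler,
    )
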