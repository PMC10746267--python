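"""From condition-specific nodes to gene signatures and enrichment.

A specific bottleneck node is turned on alone (one-hot bottleneck vector)
and propagated through the decoder to give a per-gene output profile; the
all-off bottleneck decodes to a baseline profile, and the signed difference
(node output minus baseline) ranks genes by how strongly the node pushes
them up or down. Averaging node outputs across all identified nodes and
taking the top of the sorted vector defines the condition's signature gene
set. Gene sets are tested for enrichment by gene-label permutation of the
signed ranking, with Benjamini-Hochberg adjustment across terms, and the
final candidate-gene rule keeps signature genes whose expression beats
every other stress condition by at least ``lfc_min`` log2 units in at least
``frac_min`` of pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionCompendium
from .dae import DenoisingAutoencoder

__all__ = [
    "read_gmt",
    "write_gmt",
    "NodeGeneVector",
    "node_gene_vector",
    "SignatureGeneSet",
    "extract_gene_set",
    "EnrichmentResult",
    "permutation_gsea",
    "bh_adjust",
    "tally_term_directions",
    "CandidateGene",
    "select_candidates",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: term, description, genes per line."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gmt(path, term_genes: dict, description: str = "") -> None:
    with open(path, "w") as fh:
        for term, genes in term_genes.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


@dataclass
class NodeGeneVector:
    """Decoder output for a one-hot-activated bottleneck node.

    ``output`` is the decoded per-gene profile with only this node active;
    ``baseline`` is the all-off decode of the same member. Their difference
    is the node's signed effect on each gene.
    """

    member: int
    node: int
    output: np.ndarray
    baseline: np.ndarray

    @property
    def signed_score(self) -> np.ndarray:
        return self.output - self.baseline


def node_gene_vector(dae: DenoisingAutoencoder, node_index: int,
                     member: int = 0) -> NodeGeneVector:
    """Activate one bottleneck node and propagate it through the decoder."""
    if not 0 <= node_index < dae.bottleneck:
        raise IndexError(
            f"node index {node_index} out of range for bottleneck of {dae.bottleneck}")
    onehot = np.zeros((1, dae.bottleneck))
    onehot[0, node_index] = 1.0
    output = dae.inverse_transform(onehot)[0]
    baseline = dae.inverse_transform(np.zeros((1, dae.bottleneck)))[0]
    return NodeGeneVector(member=member, node=node_index, output=output, baseline=baseline)


@dataclass
class SignatureGeneSet:
    pattern: str
    ranked_genes: list[str]
    scores: np.ndarray  # mean node output per ranked gene
    cutoff: int
    genes: frozenset[str]


def extract_gene_set(vectors: list[NodeGeneVector], gene_ids, cutoff=100,
                     tie_rule: str = "gene_id", pattern: str = "",
                     baseline_correction: bool = True) -> SignatureGeneSet:
    """Rank genes by mean decoder output across nodes; keep the top slice.

    With ``baseline_correction`` (default) each node's output has the
    member's all-off decode subtracted first, so the ranking reflects what
    the node *adds* rather than each gene's decoder resting level — the
    resting level otherwise dominates and buries the node's program. Set
    it to False to rank on the uncorrected decoder output.

    ``cutoff`` may be an integer count or a fraction of the gene universe.
    Ties are broken lexicographically by gene id (the only rule currently
    implemented), making the ranking fully deterministic.
    """
    if not vectors:
        raise ValueError("need at least one node gene vector")
    gene_ids = list(gene_ids)
    mat = np.stack([v.signed_score if baseline_correction else v.output
                    for v in vectors])
    if mat.shape[1] != len(gene_ids):
        raise ValueError("node vectors and gene universe differ in length")
    mean_output = mat.mean(axis=0)
    if tie_rule != "gene_id":
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    order = np.lexsort((np.array(gene_ids), -mean_output))
    if isinstance(cutoff, float):
        if not 0 < cutoff <= 1:
            raise ValueError("fractional cutoff must be in (0, 1]")
        k = max(1, int(round(cutoff * len(gene_ids))))
    else:
        k = int(cutoff)
    k = min(k, len(gene_ids))
    ranked = [gene_ids[i] for i in order]
    return SignatureGeneSet(
        pattern=pattern,
        ranked_genes=ranked,
        scores=mean_output[order],
        cutoff=k,
        genes=frozenset(ranked[:k]),
    )


@dataclass
class EnrichmentResult:
    term: str
    statistic: float
    direction: str  # "up" | "down"
    p_value: float
    n_permutations: int
    n_term_genes: int
    member: int | None = None
    node: int | None = None
    p_adjusted: float | None = None
    skipped: str | None = None


def _null_means(scores: np.ndarray, k: int, n_perm: int, rng,
                chunk: int = 2000) -> np.ndarray:
    """Means of ``n_perm`` independent without-replacement draws of size k.

    Draws are realised by ranking random keys per permutation (exact
    uniform sampling without replacement), chunked to bound memory.
    """
    n = scores.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n), dtype=np.float32)
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[done:done + b] = scores[idx].mean(axis=1)
        done += b
    return out


def _enrichment_score(order_rank: np.ndarray, abs_scores_sorted: np.ndarray,
                      member_mask_sorted: np.ndarray) -> float:
    """Signed weighted Kolmogorov-Smirnov-style enrichment score.

    Genes are sorted by descending signed score; the running sum gains the
    term genes' normalized absolute scores and loses 1/(N-k) for the rest;
    the score is the deviation of largest magnitude.
    """
    k_weights = abs_scores_sorted * member_mask_sorted
    total = k_weights.sum()
    n = member_mask_sorted.size
    k = int(member_mask_sorted.sum())
    if total == 0:  # degenerate: fall back to uniform hit weights
        hit = member_mask_sorted / max(k, 1)
    else:
        hit = k_weights / total
    miss = (~member_mask_sorted.astype(bool)).astype(float) / max(n - k, 1)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def permutation_gsea(scores, gene_ids, term_genes, n_perm: int = 10_000,
                     seed: int = 0, min_size: int = 5, max_size: int = 30,
                     statistic: str = "mean", term: str = "term",
                     member=None, node=None) -> EnrichmentResult:
    """Gene-label permutation test of a term's enrichment in a signed score.

    With ``statistic="mean"`` (default, fully vectorised) the statistic is
    the mean signed score (node output minus baseline) of the term's
    genes; ``statistic="ks"`` uses a weighted running-sum enrichment score
    instead (slower; the null loops over permutations). Either way the
    null redraws same-size gene sets at random from the universe, and the
    two-sided p-value uses the plus-one correction
    ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``, so its minimum is
    ``1/(n_perm+1)``. Terms outside the [min_size, max_size] overlap bounds
    are skipped with a reason code.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("mean", "ks"):
        raise ValueError(f"unknown statistic {statistic!r}")
    scores = np.asarray(scores, dtype=float)
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([pos[g] for g in term_genes if g in pos], dtype=int)
    k = idx.size
    if not min_size <= k <= max_size:
        return EnrichmentResult(term=term, statistic=np.nan, direction="up",
                                p_value=np.nan, n_permutations=0, n_term_genes=k,
                                member=member, node=node,
                                skipped=f"term size {k} outside [{min_size}, {max_size}]")
    rng = np.random.default_rng(seed)
    if statistic == "mean":
        obs = scores[idx].mean()
        null = _null_means(scores, k, n_perm, rng)
    else:
        order = np.argsort(-scores, kind="stable")
        abs_sorted = np.abs(scores[order])
        rank_of = np.empty(scores.size, dtype=int)
        rank_of[order] = np.arange(scores.size)
        mask = np.zeros(scores.size)
        mask[rank_of[idx]] = 1.0
        obs = _enrichment_score(order, abs_sorted, mask)
        null = np.empty(n_perm)
        for b in range(n_perm):
            m = np.zeros(scores.size)
            m[rng.choice(scores.size, size=k, replace=False)] = 1.0
            null[b] = _enrichment_score(order, abs_sorted, m)
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return EnrichmentResult(
        term=term, statistic=float(obs),
        direction="up" if obs >= 0 else "down",
        p_value=float(p), n_permutations=n_perm, n_term_genes=k,
        member=member, node=node,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tally_term_directions(results: list[EnrichmentResult],
                          padj_threshold: float = 0.0005) -> pd.DataFrame:
    """Per-term counts of nodes significantly enriched up vs down.

    Expects results whose ``p_adjusted`` has been filled (one BH family per
    analysis); unadjusted results fall back to their raw p-value.
    """
    if not 0 < padj_threshold < 1:
        raise ValueError("padj threshold must be in (0, 1)")
    tally: dict[str, list[int]] = {}
    for r in results:
        if r.skipped is not None:
            continue
        padj = r.p_adjusted if r.p_adjusted is not None else r.p_value
        if padj is None or not np.isfinite(padj) or padj > padj_threshold:
            continue
        up_down = tally.setdefault(r.term, [0, 0])
        up_down[0 if r.direction == "up" else 1] += 1
    return pd.DataFrame(
        [(t, u, d) for t, (u, d) in sorted(tally.items())],
        columns=["term", "n_nodes_up", "n_nodes_down"],
    )


@dataclass
class CandidateGene:
    gene_id: str
    log2_fcs: np.ndarray  # one per (acid condition, other condition) pair
    fraction_passing: float
    mean_acid_expression: float
    selected: bool


def select_candidates(compendium: ExpressionCompendium, signature_genes,
                      acid_conditions, other_conditions, lfc_min: float = 0.5,
                      frac_min: float = 0.95, top_n: int | None = None) -> list[CandidateGene]:
    """Acid-specific candidate genes from a signature set.

    For each signature gene, every (acid condition, other condition) pair
    contributes one log2 fold change — the difference of the gene's mean
    log2 expression under the two conditions. A gene is selected when at
    least ``frac_min`` of these comparisons reach ``lfc_min``. All evaluated
    signature genes are returned (with their ``selected`` flag), sorted by
    mean expression under the acid conditions, descending; ``top_n``
    optionally caps the list.
    """
    acid_conditions = list(acid_conditions)
    other_conditions = list(other_conditions)
    if set(acid_conditions) & set(other_conditions):
        raise ValueError("acid and other condition sets must be disjoint")
    known = set(compendium.conditions)
    missing = [c for c in acid_conditions + other_conditions if c not in known]
    if missing:
        raise ValueError(f"conditions absent from compendium: {missing}")
    if compendium.unit != "log_tpm":
        raise ValueError("candidate selection expects a log-TPM compendium")

    cond_mean = {}
    for c in acid_conditions + other_conditions:
        cols = compendium.column_indices(compendium.samples_of_condition(c))
        cond_mean[c] = compendium.values[:, cols].mean(axis=1)
    gene_pos = {g: i for i, g in enumerate(compendium.gene_ids)}
    acid_stack = np.stack([cond_mean[a] for a in acid_conditions])

    out = []
    for g in sorted(signature_genes):
        if g not in gene_pos:
            continue
        i = gene_pos[g]
        lfcs = np.array([cond_mean[a][i] - cond_mean[o][i]
                         for a in acid_conditions for o in other_conditions])
        frac = float(np.mean(lfcs >= lfc_min))
        out.append(CandidateGene(
            gene_id=g,
            log2_fcs=lfcs,
            fraction_passing=frac,
            mean_acid_expression=float(acid_stack[:, i].mean()),
            selected=frac >= frac_min,
        ))
    out.sort(key=lambda c: (-c.mean_acid_expression, c.gene_id))
    if top_n is not None:
        out = out[:top_n]
    return out
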