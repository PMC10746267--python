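"""Small-ORF candidate filtering.

Ribosome-profiling-based sORF discovery produces large candidate tables
with many false positives; this module applies the standard exclusion
cascade: minimum Ribo-Seq coverage (mean rpkm >= 30), codon-count range
(10-70 amino acids, with an explicit per-candidate exception flag for
manually curated longer ORFs), induction significance (Ribo and RNA log2
FC >= 2 with adjusted p <= 0.05 in at least one stress contrast), and
exclusion of candidates that share nucleotides with an annotated gene on
the same strand (antisense overlap is fine — the signals are
distinguishable). Every discarded candidate is attributed to the first
rule it fails, in the fixed order rpkm -> length -> significance ->
overlap, and a census of those attributions is returned.

Coordinates are 1-based inclusive (GFF3 convention) on the public surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

__all__ = [
    "GeneFeature",
    "SorfCandidate",
    "FilterParams",
    "same_strand_overlap",
    "filter_candidates",
    "write_gff3",
    "read_gff3_features",
]

RULES = ("rpkm", "length", "significance", "overlap")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene interval, 1-based inclusive."""

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.feature_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: malformed strand {self.strand!r}")


@dataclass
class SorfCandidate:
    """A predicted small ORF with its expression statistics.

    ``contrasts`` maps a contrast label (e.g. "mild", "severe") to a
    (lfc_ribo, padj_ribo, lfc_rna, padj_rna) tuple. ``codon_count`` is in
    amino acids; for a stop-inclusive ORF the nucleotide span should be
    3 * (codon_count + 1), and a mismatch is warned about (annotation
    dialects that exclude the stop codon are tolerated).
    """

    candidate_id: str
    contig: str
    start: int
    end: int
    strand: str
    codon_count: int
    mean_ribo_rpkm: float
    contrasts: dict[str, tuple[float, float, float, float]]
    length_exception: bool = False
    decision: str | None = None
    first_failed_rule: str | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.candidate_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.candidate_id}: malformed strand {self.strand!r}")
        span = self.end - self.start + 1
        if span != 3 * (self.codon_count + 1) and span != 3 * self.codon_count:
            warnings.warn(
                f"{self.candidate_id}: span {span} nt inconsistent with "
                f"{self.codon_count} codons (stop included or excluded)",
                stacklevel=2)


@dataclass(frozen=True)
class FilterParams:
    rpkm_min: float = 30.0
    codon_min: int = 10
    codon_max: int = 70
    lfc_min: float = 2.0
    padj_max: float = 0.05
    require_both_assays: bool = True  # non-default: either assay suffices


def _annotation_trees(annotation) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation:
        # half-open internal coordinates for the tree
        trees.setdefault((g.contig, g.strand), IntervalTree()).addi(g.start, g.end + 1, g.feature_id)
    return trees


def same_strand_overlap(candidate, annotation) -> bool:
    """True iff the candidate shares >= 1 nt with a same-strand gene."""
    trees = annotation if isinstance(annotation, dict) else _annotation_trees(annotation)
    tree = trees.get((candidate.contig, candidate.strand))
    if tree is None:
        return False
    return bool(tree.overlap(candidate.start, candidate.end + 1))


def _significant(cand: SorfCandidate, p: FilterParams) -> bool:
    for lfc_r, padj_r, lfc_n, padj_n in cand.contrasts.values():
        ribo_ok = lfc_r >= p.lfc_min and padj_r <= p.padj_max
        rna_ok = lfc_n >= p.lfc_min and padj_n <= p.padj_max
        if (ribo_ok and rna_ok) if p.require_both_assays else (ribo_ok or rna_ok):
            return True
    return False


def filter_candidates(candidates, annotation, params: FilterParams | None = None
                      ) -> tuple[list[SorfCandidate], dict[str, int]]:
    """Apply the exclusion cascade; return kept candidates and a census.

    Each returned candidate carries ``decision`` ("keep"/"discard") and,
    for discards, ``first_failed_rule``; the census counts discards per
    rule. The input list is not mutated. Known contigs are those of the
    annotation; a candidate on an unknown contig is an error.
    """
    p = params or FilterParams()
    annotation = list(annotation)
    trees = _annotation_trees(annotation)
    known_contigs = {g.contig for g in annotation}
    kept: list[SorfCandidate] = []
    census = {r: 0 for r in RULES}
    decided = []
    for cand in candidates:
        if known_contigs and cand.contig not in known_contigs:
            raise ValueError(f"{cand.candidate_id}: unknown contig {cand.contig!r}")
        failed = None
        if cand.mean_ribo_rpkm < p.rpkm_min:
            failed = "rpkm"
        elif not (p.codon_min <= cand.codon_count <= p.codon_max) and not cand.length_exception:
            failed = "length"
        elif not _significant(cand, p):
            failed = "significance"
        elif same_strand_overlap(cand, trees):
            failed = "overlap"
        if failed is None:
            decided.append(replace(cand, decision="keep", first_failed_rule=None))
            kept.append(decided[-1])
        else:
            census[failed] += 1
            decided.append(replace(cand, decision="discard", first_failed_rule=failed))
    return kept, {r: n for r, n in census.items() if n > 0}


# -- GFF3 I/O (1-based inclusive coordinates) -----------------------------

def write_gff3(path, features, source: str = "acidae") -> None:
    """Write gene features and/or sORF candidates as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if isinstance(f, SorfCandidate):
                ftype, fid = "ORF", f.candidate_id
                attrs = [f"ID={fid}", f"codon_count={f.codon_count}",
                         f"mean_ribo_rpkm={f.mean_ribo_rpkm:g}"]
                if f.decision:
                    attrs.append(f"decision={f.decision}")
                if f.first_failed_rule:
                    attrs.append(f"first_failed_rule={f.first_failed_rule}")
            else:
                ftype, fid = "gene", f.feature_id
                attrs = [f"ID={fid}"]
            fh.write("\t".join([
                f.contig, source, ftype, str(f.start), str(f.end),
                ".", f.strand, ".", ";".join(attrs)]) + "\n")


def read_gff3_features(path) -> list[GeneFeature]:
    """Read gene-like records from a GFF3 file into GeneFeature objects."""
    import gffutils

    out = []
    for feat in gffutils.DataIterator(str(path)):
        fid = feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        out.append(GeneFeature(fid, feat.seqid, feat.start, feat.end, feat.strand))
    return out
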