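"""Synthetic data with planted ground truth.

Three generators cover the inputs of the two analysis pipelines:

* :func:`simulate_compendium` builds a log2-scale expression compendium in
  which latent co-expression programs (gene sets with a shared log2
  loading) switch on in declared condition subsets, on top of per-gene
  baselines and Gaussian noise — the structure a stress-augmented
  expression compendium presents to an autoencoder.
* :func:`simulate_paired_counts` draws matched Ribo-Seq/RNA-Seq negative-
  binomial counts with planted transcriptional effects (both assays),
  translational effects (Ribo only), buffered RNA-exclusive effects and
  opposite-direction effects, plus per-sample library size factors.
* :func:`simulate_annotation_and_orfs` lays out a toy genome annotation and
  an sORF candidate table containing, by construction, one violator of each
  filtering rule and an antisense-overlapping survivor.

All generators are deterministic given their seed, and each returns (or
records) the planted truth so downstream stages can be scored against it.
The default scenario sizes are desk-scale: 2,000 genes over eight stress
conditions x 3 replicates for the compendium, 1,500 genes x 2 conditions
x 3 replicates for the paired counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionCompendium, PairedCountExperiment
from .sorf import GeneFeature, SorfCandidate

__all__ = [
    "ExpressionProgram",
    "CompendiumTruth",
    "TranslatomeTruth",
    "simulate_compendium",
    "simulate_paired_counts",
    "simulate_annotation_and_orfs",
    "simulate_start_coverage",
    "default_conditions",
    "default_programs",
    "default_compendium",
    "default_translatome_truth",
    "nb_counts",
]

#: The stress-contrast universe used throughout the default scenario:
#: two acid intensities against a panel of unrelated stressors.
DEFAULT_CONDITIONS = ("acid_mild", "acid_severe", "control", "heat",
                      "ethanol", "osmotic", "oxidative", "antibiotic")


def default_conditions() -> tuple[str, ...]:
    return DEFAULT_CONDITIONS


@dataclass(frozen=True)
class ExpressionProgram:
    """A latent co-expression program: genes, loading, active conditions."""

    program_id: str
    member_genes: frozenset[str]
    loading: float
    active_conditions: frozenset[str]

    def __post_init__(self):
        if not self.member_genes:
            raise ValueError(f"program {self.program_id}: empty gene set")
        if not np.isfinite(self.loading):
            raise ValueError(f"program {self.program_id}: non-finite loading")


@dataclass
class CompendiumTruth:
    """Ground truth serialized alongside a simulated compendium."""

    programs: list[ExpressionProgram]
    baseline_mean: np.ndarray
    noise_sd: float
    condition_design: list[str]
    seed: int

    def program_genes(self, program_id: str) -> frozenset[str]:
        for p in self.programs:
            if p.program_id == program_id:
                return p.member_genes
        raise KeyError(program_id)

    def to_json(self, path) -> None:
        d = {
            "programs": [
                {"program_id": p.program_id,
                 "member_genes": sorted(p.member_genes),
                 "loading": p.loading,
                 "active_conditions": sorted(p.active_conditions)}
                for p in self.programs
            ],
            "baseline_mean": np.asarray(self.baseline_mean).tolist(),
            "noise_sd": self.noise_sd,
            "condition_design": self.condition_design,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_compendium(n_genes: int, condition_design, programs=(),
                        baseline_mean=5.0, noise_sd: float = 0.5,
                        seed: int = 0) -> tuple[ExpressionCompendium, CompendiumTruth]:
    """Simulate a log2-scale compendium with planted programs.

    Each entry is baseline + the summed loadings of programs active in the
    sample's condition (for member genes) + Gaussian(0, noise_sd) noise.
    ``condition_design`` is the condition label per sample, in column
    order; sample ids are ``<condition>_rep<k>``.
    """
    condition_design = list(condition_design)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conditions = set(condition_design)
    gene_ids = _gene_ids(n_genes)
    known_genes = set(gene_ids)
    for p in programs:
        bad_cond = p.active_conditions - conditions
        if bad_cond:
            raise ValueError(
                f"program {p.program_id} references unknown condition(s): {sorted(bad_cond)}")
        bad_genes = p.member_genes - known_genes
        if bad_genes:
            raise ValueError(
                f"program {p.program_id} references unknown gene(s): {sorted(bad_genes)[:5]}")

    baseline = np.broadcast_to(np.asarray(baseline_mean, dtype=float), (n_genes,)).copy()
    rng = np.random.default_rng(seed)
    values = np.tile(baseline[:, None], (1, len(condition_design)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for p in programs:
        rows = [gene_pos[g] for g in sorted(p.member_genes)]
        cols = [j for j, c in enumerate(condition_design) if c in p.active_conditions]
        if cols:
            values[np.ix_(rows, cols)] += p.loading
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    counts: dict[str, int] = {}
    sample_ids = []
    for c in condition_design:
        counts[c] = counts.get(c, 0) + 1
        sample_ids.append(f"{c}_rep{counts[c]}")
    compendium = ExpressionCompendium(
        values=values, gene_ids=gene_ids, sample_ids=sample_ids,
        condition_of_sample=dict(zip(sample_ids, condition_design)),
        unit="log_tpm")
    truth = CompendiumTruth(programs=list(programs), baseline_mean=baseline,
                            noise_sd=noise_sd, condition_design=condition_design,
                            seed=seed)
    return compendium, truth


def default_programs(gene_ids) -> list[ExpressionProgram]:
    """The default planted-program scenario.

    Cross-condition structure: one acid-only program (20 genes, +3 log2),
    one program shared between acid and ethanol (15 genes, +2.5) — the
    membrane-permeability overlap between the two stressors — and one
    general stress program active under every stressor (25 genes, +2).
    On top of that, every condition carries a private 30-gene program
    (+2), mimicking the condition-specific regulons that dominate real
    stress compendia; without them the matrix would be mostly replicate
    noise, which no compendium is.
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) < 300:
        raise ValueError("the default program scenario needs >= 300 genes")
    programs = [
        ExpressionProgram("acid_only", frozenset(gene_ids[0:20]), 3.0,
                          frozenset({"acid_mild", "acid_severe"})),
        ExpressionProgram("acid_ethanol", frozenset(gene_ids[20:35]), 2.5,
                          frozenset({"acid_mild", "acid_severe", "ethanol"})),
        ExpressionProgram("general_stress", frozenset(gene_ids[35:60]), 2.0,
                          frozenset(set(DEFAULT_CONDITIONS) - {"control"})),
    ]
    start = 60
    for cond in DEFAULT_CONDITIONS:
        programs.append(ExpressionProgram(
            f"{cond}_private", frozenset(gene_ids[start:start + 30]), 2.0,
            frozenset({cond})))
        start += 30
    return programs


def default_compendium(n_genes: int = 2000, replicates: int = 3,
                       noise_sd: float = 0.5, seed: int = 0
                       ) -> tuple[ExpressionCompendium, CompendiumTruth]:
    """The default desk-scale compendium: 8 conditions x 3 replicates.

    Per-gene baselines are drawn N(7, 1.5) on the log2 scale (seeded
    separately from the noise so truth is stable across noise settings).
    """
    design = [c for c in DEFAULT_CONDITIONS for _ in range(replicates)]
    base_rng = np.random.default_rng(seed + 1_000_003)
    baseline = base_rng.normal(7.0, 1.5, size=n_genes)
    programs = default_programs(_gene_ids(n_genes))
    return simulate_compendium(n_genes, design, programs, baseline, noise_sd, seed)


# -- paired Ribo/RNA counts -----------------------------------------------

def nb_counts(mu, alpha, rng) -> np.ndarray:
    """Negative binomial draws with mean mu and dispersion alpha.

    Var = mu + alpha * mu^2; alpha = 0 is the Poisson limit. ``mu`` and
    ``alpha`` broadcast against each other.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    if np.any(alpha < 0):
        raise ValueError("NB dispersion alpha must be >= 0")
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha == 0
    out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        r = 1.0 / alpha[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


@dataclass
class TranslatomeTruth:
    """Planted effects for a paired Ribo/RNA experiment.

    Effects are log2 and act multiplicatively on condition means:
    RNA mean carries ``transcriptional_effect``; Ribo mean carries
    ``transcriptional_effect + translational_effect``. The named sets map
    onto the four regulatory classes: ``de_both_genes`` (transcriptional
    only -> concordant), ``de_rna_genes`` (transcriptional effect exactly
    cancelled in Ribo by an opposite translational effect -> RNA-
    exclusive), ``de_ribo_genes`` (translational only -> Ribo-exclusive),
    ``opposite_genes`` (translational effect of -2x the transcriptional
    one, so the two assays move in opposite directions). ``te_genes`` is
    every gene with a non-zero translational effect.
    """

    gene_ids: list[str]
    transcriptional_effect: np.ndarray
    translational_effect: np.ndarray
    de_both_genes: frozenset[str]
    de_rna_genes: frozenset[str]
    de_ribo_genes: frozenset[str]
    opposite_genes: frozenset[str]
    dispersion: np.ndarray
    gene_lengths: np.ndarray
    library_size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=int)
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion must be >= 0")
        if np.any(self.gene_lengths < 30):
            raise ValueError("gene lengths must be >= 30 nt")

    @property
    def te_genes(self) -> frozenset[str]:
        return frozenset(g for g, t in zip(self.gene_ids, self.translational_effect) if t != 0)

    def expected_class(self) -> dict[str, str]:
        """Planted regulatory class per gene (the recovery target)."""
        out = {}
        for g in self.gene_ids:
            if g in self.de_both_genes:
                out[g] = "both_concordant"
            elif g in self.de_rna_genes:
                out[g] = "rna_exclusive"
            elif g in self.de_ribo_genes:
                out[g] = "ribo_exclusive"
            elif g in self.opposite_genes:
                out[g] = "opposite"
            else:
                out[g] = "neither"
        return out


def default_translatome_truth(n_genes: int = 1500, effect: float = 2.0,
                              n_per_class: int = 50, alpha: float = 0.05,
                              seed: int = 0) -> TranslatomeTruth:
    """Planted truth with ``n_per_class`` genes in each regulatory class.

    ``effect`` is the planted log2 magnitude (default +2, a fourfold
    change); dispersion is constant ``alpha`` (default 0.05, typical of
    bacterial bulk libraries with biological triplicates).
    """
    if 4 * n_per_class > n_genes:
        raise ValueError("not enough genes for the requested class sizes")
    gene_ids = _gene_ids(n_genes)
    rng = np.random.default_rng(seed + 7)
    tx = np.zeros(n_genes)
    tl = np.zeros(n_genes)
    blocks = {
        "both": slice(0, n_per_class),
        "rna": slice(n_per_class, 2 * n_per_class),
        "ribo": slice(2 * n_per_class, 3 * n_per_class),
        "opposite": slice(3 * n_per_class, 4 * n_per_class),
    }
    tx[blocks["both"]] = effect
    tx[blocks["rna"]] = effect
    tl[blocks["rna"]] = -effect  # buffered: Ribo stays flat
    tl[blocks["ribo"]] = effect
    tx[blocks["opposite"]] = effect
    tl[blocks["opposite"]] = -2 * effect  # Ribo moves opposite to RNA
    lengths = rng.integers(150, 2400, size=n_genes)
    return TranslatomeTruth(
        gene_ids=gene_ids,
        transcriptional_effect=tx,
        translational_effect=tl,
        de_both_genes=frozenset(gene_ids[blocks["both"]]),
        de_rna_genes=frozenset(gene_ids[blocks["rna"]]),
        de_ribo_genes=frozenset(gene_ids[blocks["ribo"]]),
        opposite_genes=frozenset(gene_ids[blocks["opposite"]]),
        dispersion=np.full(n_genes, alpha),
        gene_lengths=lengths,
    )


def simulate_paired_counts(truth: TranslatomeTruth, conditions=("control", "acid"),
                           replicates: int = 3, baseline_mu=200.0,
                           size_factor_range=(0.5, 2.0), seed: int = 0
                           ) -> PairedCountExperiment:
    """Draw paired NB counts for a control/stress contrast.

    The first condition is the reference; planted effects apply to the
    second. Per-sample size factors are drawn log-uniform over
    ``size_factor_range`` (shared between the two assays of a sample) and
    recorded on the truth object.
    """
    conditions = list(conditions)
    if len(conditions) != 2:
        raise ValueError("expected exactly two conditions (reference, stress)")
    if replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    n_genes = len(truth.gene_ids)
    mu0 = np.broadcast_to(np.asarray(baseline_mu, dtype=float), (n_genes,))
    if np.any(mu0 <= 0):
        raise ValueError("baseline_mu must be positive")
    rng = np.random.default_rng(seed)
    n_samples = 2 * replicates
    lo, hi = size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    sample_conditions = [conditions[0]] * replicates + [conditions[1]] * replicates
    sample_replicates = list(range(1, replicates + 1)) * 2

    rna_mu = np.tile(mu0[:, None], (1, n_samples))
    ribo_mu = np.tile(mu0[:, None], (1, n_samples))
    stress_cols = np.arange(replicates, n_samples)
    rna_mu[:, stress_cols] *= 2.0 ** truth.transcriptional_effect[:, None]
    ribo_mu[:, stress_cols] *= 2.0 ** (truth.transcriptional_effect
                                       + truth.translational_effect)[:, None]
    rna_mu *= sf[None, :]
    ribo_mu *= sf[None, :]
    alpha = truth.dispersion[:, None]
    rna = nb_counts(rna_mu, np.broadcast_to(alpha, rna_mu.shape), rng)
    ribo = nb_counts(ribo_mu, np.broadcast_to(alpha, ribo_mu.shape), rng)
    truth.library_size_factors = sf
    return PairedCountExperiment(
        ribo_counts=ribo, rna_counts=rna, gene_ids=list(truth.gene_ids),
        sample_conditions=sample_conditions, sample_replicates=sample_replicates,
        gene_lengths=truth.gene_lengths)


# -- annotation + sORF fixtures -------------------------------------------

def simulate_annotation_and_orfs(genome_length: int = 50_000, n_genes: int = 20,
                                 n_candidates: int = 6, seed: int = 0
                                 ) -> tuple[list[GeneFeature], list[SorfCandidate], dict[str, str]]:
    """A toy annotation plus an sORF candidate fixture with planted labels.

    The first six candidates are canonical: one violator of each filter
    rule (low rpkm, too short, too long, non-significant, same-strand
    overlap with a gene) and one survivor placed *antisense* within an
    annotated gene (same-strand exclusion must not fire). Additional
    candidates alternate between clean intergenic survivors and extra
    low-coverage violators. Returns (annotation, candidates, truth) where
    truth maps candidate id -> "keep" / the rule it should fail.
    """
    if n_candidates < 6:
        raise ValueError("need at least 6 candidates for full rule coverage")
    rng = np.random.default_rng(seed)
    gene_len = 900
    gap = 600
    span = n_genes * (gene_len + gap) + (n_candidates + 2) * 400
    if genome_length < span:
        raise ValueError(
            f"genome_length {genome_length} too small; need >= {span} "
            f"for {n_genes} genes and {n_candidates} candidates")
    annotation = []
    pos = 1
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        annotation.append(GeneFeature(f"gene{i:03d}", "chr", pos, pos + gene_len - 1, strand))
        pos += gene_len + gap

    sig = {"stress": (3.0, 1e-4, 2.5, 1e-3)}
    nonsig = {"stress": (0.5, 0.5, 0.3, 0.6)}

    def intergenic_start(idx: int) -> int:
        # middle of the gap after gene idx
        g = annotation[idx % n_genes]
        return g.end + gap // 2

    def cand(cid, start, codons, strand="+", rpkm=50.0, contrasts=sig, exc=False):
        end = start + 3 * (codons + 1) - 1
        return SorfCandidate(cid, "chr", start, end, strand, codons, rpkm,
                             dict(contrasts), length_exception=exc)

    host = annotation[2]  # '+' gene hosting the antisense survivor
    overlap_host = annotation[4]
    candidates = [
        cand("cand_keep_antisense", host.start + 150, 20, strand="-"),
        cand("cand_low_rpkm", intergenic_start(0), 20, rpkm=10.0),
        cand("cand_too_short", intergenic_start(1), 8),
        cand("cand_too_long", intergenic_start(3), 80),
        cand("cand_nonsig", intergenic_start(5), 20, contrasts=nonsig),
        cand("cand_overlap", overlap_host.start + 90, 20, strand=overlap_host.strand),
    ]
    truth = {
        "cand_keep_antisense": "keep",
        "cand_low_rpkm": "rpkm",
        "cand_too_short": "length",
        "cand_too_long": "length",
        "cand_nonsig": "significance",
        "cand_overlap": "overlap",
    }
    for j in range(6, n_candidates):
        start = intergenic_start(6 + j)
        if j % 2 == 0:
            c = cand(f"cand_extra{j}", start, int(rng.integers(10, 70)))
            truth[c.candidate_id] = "keep"
        else:
            c = cand(f"cand_extra{j}", start, int(rng.integers(10, 70)),
                     rpkm=float(rng.uniform(0, 29)))
            truth[c.candidate_id] = "rpkm"
        candidates.append(c)
    return annotation, candidates, truth


def simulate_start_coverage(n_genes: int = 50, region_length: int = 400,
                            start_index: int = 120, spike: float = 3.0,
                            spike_codons: int = 10, noise: float = 0.1,
                            seed: int = 0):
    """Per-gene coverage vectors with an occupancy spike after the start.

    Yields (coverage, start, strand) records suitable for
    :func:`acidae.translatome.metagene_profile`: flat unit coverage with
    multiplicative noise, times ``spike`` over the first ``spike_codons``
    codons of the ORF. Strands alternate, with minus-strand coverage laid
    out genome-oriented (reversed).
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        cov = 1.0 + noise * rng.standard_normal(region_length)
        cov = np.clip(cov, 0.05, None)
        cov[start_index:start_index + 3 * spike_codons] *= spike
        strand = "+" if i % 2 == 0 else "-"
        if strand == "-":
            cov = cov[::-1]
            start = region_length - 1 - start_index
        else:
            start = start_index
        records.append((cov, start, strand))
    return records
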