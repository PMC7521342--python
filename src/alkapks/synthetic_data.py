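"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study design of a two-species comparative
transcriptome experiment: two species (an alkamide producer, `Hl`, and a
non-producer, `Ha`) by two tissues (root, leaf) with two biological
replicates each.  A configurable subset of genes is planted as upregulated
in the producer-root group and assigned PKS/FAS domain motifs; KS-domain
protein sequences are drawn from four clades (plant FAS, plant type-III
PKS, microbial type-I PKS and an "alkamide" clade); qPCR Ct tables encode
known expression ratios.  Every generator is deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .domain_profiles import AA_ALPHABET, DOMAIN_LABELS
from .expression_screen import CountMatrix

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "CladeSimSpec",
    "simulate_counts",
    "simulate_domain_transcripts",
    "simulate_clade_sequences",
    "simulate_ct_table",
    "write_fasta",
    "read_fasta",
    "CLADE_NAMES",
    "REVERSE_CODON",
]

DEFAULT_GROUPS = ("Hl-root", "Hl-leaf", "Ha-root", "Ha-leaf")
PRODUCER_GROUP = "Hl-root"

#: The four KS-domain clades the phylogenetic stage distinguishes.
CLADE_NAMES = ("FAS", "PKS-III", "microbial-PKS-I", "alkamide")

#: One fixed codon per amino acid for reverse translation (codon usage is
#: irrelevant to motif planting and scanning).
REVERSE_CODON: Mapping[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the count simulator.

    Defaults mirror the experimental layout (4 groups x 2 replicates) with
    100 of 2,000 genes planted as 8-fold (log2FC = 3) upregulated in the
    producer-root group, negative-binomial noise with dispersion
    ``nb_dispersion`` (variance mu + phi mu^2) and log-normal baseline
    expression.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 2
    planted_up: int = 100
    effect_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    mean_log_mu: float = 4.6  # baseline median expression ~ exp(4.6) ~ 100
    sd_log_mu: float = 1.0
    gene_length_range: tuple[int, int] = (300, 3000)
    libsize_variation: float = 0.3  # library-size factors in [1-v, 1+v]
    producer_group: str = PRODUCER_GROUP
    seed: int = 0

    def __post_init__(self):
        if self.planted_up > self.n_genes:
            raise ValueError("planted_up exceeds n_genes")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.producer_group not in self.groups:
            raise ValueError(f"{self.producer_group!r} not among groups")
        if not (0 <= self.libsize_variation < 1):
            raise ValueError("libsize_variation must be in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: which genes are differentially
    expressed (and by how much), which carry which domain motif, and the
    clade of every simulated KS sequence."""

    all_gene_ids: list[str]
    de_gene_ids: list[str]
    true_log2fc: dict[str, float]
    domain_assignments: dict[str, str] = field(default_factory=dict)
    clade_labels: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB with mean mu and variance mu + phi mu^2; Poisson in the phi->0 limit."""
    if phi < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / phi
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Draw a gene x sample count matrix with planted producer-root effects.

    Baseline means are log-normal per gene; planted genes are multiplied by
    ``2**effect_log2fc`` in the producer-root group only; per-sample
    library-size factors vary by ``±libsize_variation``; counts are
    negative binomial with common dispersion.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples, sample_groups = [], []
    for g in config.groups:
        for r in range(1, config.replicates_per_group + 1):
            samples.append(f"{g}_{r}")
            sample_groups.append(g)

    base_mu = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, config.n_genes))
    planted_idx = rng.choice(config.n_genes, size=config.planted_up, replace=False)
    planted_idx.sort()
    planted = set(planted_idx.tolist())

    factors = rng.uniform(
        1 - config.libsize_variation, 1 + config.libsize_variation, len(samples)
    )
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    fold = 2.0 ** config.effect_log2fc
    for j, (sample, group) in enumerate(zip(samples, sample_groups)):
        mu = base_mu.copy()
        if group == config.producer_group and planted:
            mu[planted_idx] *= fold
        counts[:, j] = _nb_draw(rng, mu * factors[j], config.nb_dispersion)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    # record the generative sequencing depths as library sizes: realized
    # column sums also reflect the planted composition shift, which is a
    # depth-normalization artifact, not depth
    library_sizes = pd.Series(
        factors * base_mu.sum(), index=samples, name="library_size"
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=pd.Series(sample_groups, index=samples, name="group"),
        lengths=pd.Series(lengths, index=genes, name="length"),
        library_sizes=library_sizes,
    )
    de_ids = [genes[i] for i in planted_idx]
    # planted domain labels cycle through the PKS/FAS vocabulary
    domains = {
        gid: DOMAIN_LABELS[k % len(DOMAIN_LABELS)] for k, gid in enumerate(de_ids)
    }
    truth = PlantedTruth(
        all_gene_ids=genes,
        de_gene_ids=de_ids,
        true_log2fc={gid: config.effect_log2fc for gid in de_ids},
        domain_assignments=domains,
    )
    return cm, truth


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_domain_transcripts(
    truth: PlantedTruth,
    seed: int = 0,
    transcript_length: int = 600,
    consensus: Optional[Mapping[str, str]] = None,
) -> list[tuple[str, str]]:
    """Nucleotide transcripts: planted genes embed the reverse-translated
    motif of their assigned domain in a random frame on a random strand,
    flanked by random sequence; all other genes are random sequence.

    Returns ``(gene_id, sequence)`` pairs in gene order.
    """
    if consensus is None:
        from .domain_profiles import DOMAIN_CONSENSUS as consensus  # type: ignore
    rng = np.random.default_rng([seed, 2])
    bases = np.array(list("ACGT"))
    records = []
    for gid in truth.all_gene_ids:
        seq = "".join(rng.choice(bases, transcript_length))
        domain = truth.domain_assignments.get(gid)
        if domain is not None:
            motif_nt = "".join(REVERSE_CODON[aa] for aa in consensus[domain])
            if len(motif_nt) > transcript_length:
                raise ValueError(
                    f"motif for {domain} ({len(motif_nt)} nt) exceeds "
                    f"transcript length {transcript_length}"
                )
            start = int(rng.integers(0, transcript_length - len(motif_nt) + 1))
            seq = seq[:start] + motif_nt + seq[start + len(motif_nt):]
            if rng.random() < 0.5:
                seq = _revcomp(seq)
        records.append((gid, seq))
    return records


@dataclass(frozen=True)
class CladeSimSpec:
    """Star-shaped clade simulation: per clade, descendants arise from the
    clade ancestor by independent per-site substitution toward a uniform
    random residue (so a site changes with probability 19/20 x rate).

    Clade ancestors themselves derive from one synthetic root sequence by
    substitution at ``ancestor_divergence`` per site, keeping between-clade
    distances large relative to within-clade distances but below the
    saturation regime of the distance correction (KS domains are conserved
    enough to align, however divergent the clades).
    """

    clades: tuple[str, ...] = CLADE_NAMES
    sequences_per_clade: int = 5
    alignment_length: int = 120
    substitution_rate: float = 0.15
    ancestor_divergence: float = 0.5
    ancestor_seed: int = 77

    def __post_init__(self):
        if not (0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5)")
        if not (0 <= self.ancestor_divergence <= 1):
            raise ValueError("ancestor_divergence must be in [0, 1]")

    def ancestors(self) -> dict[str, str]:
        """Deterministic, pairwise-divergent synthetic clade ancestors."""
        rng = np.random.default_rng([self.ancestor_seed, 3])
        alphabet = np.array(list(AA_ALPHABET))
        root = rng.choice(alphabet, self.alignment_length)
        out = {}
        for clade in self.clades:
            chars = root.copy()
            hit = rng.random(self.alignment_length) < self.ancestor_divergence
            chars[hit] = rng.choice(alphabet, hit.sum())
            out[clade] = "".join(chars)
        return out


def simulate_clade_sequences(
    spec: CladeSimSpec, seed: int = 0, n_queries_per_clade: int = 0
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Aligned protein sequences per clade, plus optional query sequences.

    Returns ``(records, labels)`` where records are ``(id, sequence)``
    (references named ``<clade>_r<k>``, queries ``q<k>``) and labels map
    every id to its true clade.
    """
    rng = np.random.default_rng([seed, 4])
    alphabet = np.array(list(AA_ALPHABET))
    ancestors = spec.ancestors()

    def descend(ancestor: str) -> str:
        chars = np.array(list(ancestor))
        hit = rng.random(len(chars)) < spec.substitution_rate
        chars[hit] = rng.choice(alphabet, hit.sum())
        return "".join(chars)

    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for clade in spec.clades:
        for k in range(spec.sequences_per_clade):
            sid = f"{clade}_r{k + 1}"
            records.append((sid, descend(ancestors[clade])))
            labels[sid] = clade
    qi = 0
    for clade in spec.clades:
        for _ in range(n_queries_per_clade):
            qi += 1
            sid = f"q{qi:03d}"
            records.append((sid, descend(ancestors[clade])))
            labels[sid] = clade
    return records, labels


def simulate_ct_table(
    expression_ratios: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    biological_replicates: int = 3,
    technical_replicates: int = 3,
    reference_gene: str = "ACT",
    base_ct_target: float = 25.0,
    base_ct_reference: float = 18.0,
) -> pd.DataFrame:
    """qPCR Ct table encoding known expression ratios.

    ``expression_ratios[gene][group]`` is the true expression of ``gene``
    in ``group`` relative to the calibrator group (whose ratio should be
    1).  A gene expressed R-fold higher amplifies log2(R) cycles earlier,
    so ``Ct = base - log2(R) + noise``; the reference gene is flat across
    samples.  Gaussian technical noise is added per measurement.
    """
    rng = np.random.default_rng([seed, 5])
    rows = []
    groups = sorted({g for per_gene in expression_ratios.values() for g in per_gene})
    for group in groups:
        for b in range(1, biological_replicates + 1):
            sample = f"{group}_b{b}"
            for gene, per_group in expression_ratios.items():
                ratio = per_group[group]
                if ratio <= 0:
                    raise ValueError(f"ratio for {gene}/{group} must be > 0")
                ct_true = base_ct_target - np.log2(ratio)
                for t in range(1, technical_replicates + 1):
                    rows.append(
                        (sample, group, gene, t,
                         ct_true + rng.normal(0.0, noise_sd) if noise_sd else ct_true)
                    )
            for t in range(1, technical_replicates + 1):
                rows.append(
                    (sample, group, reference_gene, t,
                     base_ct_reference + rng.normal(0.0, noise_sd) if noise_sd
                     else base_ct_reference)
                )
    return pd.DataFrame(
        rows, columns=["sample", "group", "gene", "replicate", "ct"]
    )


# --- plain-text I/O -------------------------------------------------------

def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
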