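"""Differential-expression screen: FPKM normalization, a per-gene
negative-binomial exact test between two groups, Benjamini-Hochberg FDR
control and the up/down call at FDR <= alpha and |log2FC| >= tau.

The exact test conditions on each gene's total count after equalizing
library sizes: if per-sample counts are NB(mu, phi) with variance
mu + phi mu^2, the group sums are NB with sizes n_A/phi and n_B/phi and a
shared success probability, so the group-A sum given the total follows a
beta-binomial(t, n_A/phi, n_B/phi) that is free of mu.  The two-sided
p-value accumulates all outcomes no more probable than the observed split;
at phi = 0 the conditional law is Binomial(t, n_A/(n_A+n_B)), which serves
as an enumeration oracle in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "fpkm",
    "log2_fold_change",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "run_de",
    "write_counts",
    "read_counts",
]

UP, DOWN, NS = "up", "down", "ns"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample group labels, gene lengths
    (bp) and library sizes (column sums unless supplied)."""

    counts: pd.DataFrame
    groups: pd.Series
    lengths: pd.Series
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        missing_len = set(self.counts.index) - set(self.lengths.index)
        if missing_len:
            raise ValueError(f"genes without a length: {len(missing_len)} ids")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)

    def samples_in(self, group: str) -> list[str]:
        sel = [s for s in self.counts.columns if self.groups[s] == group]
        if not sel:
            raise ValueError(f"no samples in group {group!r}")
        return sel


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads:
    counts x 1e9 / (length x library size)."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    if (np.asarray(library_sizes) <= 0).any():
        raise ValueError("library sizes must be positive")
    if (lengths.loc[counts.index] <= 0).any():
        raise ValueError("gene lengths must be positive")
    return counts * 1e9 / np.outer(lengths.loc[counts.index], library_sizes)


def _scale_to_common(
    counts: pd.DataFrame, library_sizes: pd.Series, round_int: bool = False
) -> pd.DataFrame:
    """Rescale every sample to the geometric-mean library size."""
    target = float(np.exp(np.mean(np.log(library_sizes.loc[counts.columns]))))
    scaled = counts * (target / library_sizes.loc[counts.columns])
    return scaled.round().astype(np.int64) if round_int else scaled


def log2_fold_change(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-gene log2((mean_A + c) / (mean_B + c)) on library-size-scaled
    counts; the pseudocount guards all-zero genes."""
    mean_a = np.asarray(group_a, dtype=float).mean(axis=1)
    mean_b = np.asarray(group_b, dtype=float).mean(axis=1)
    return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> float:
    """Method-of-moments common dispersion on library-size-scaled counts.

    Per gene, the within-group pooled variance s2 and grand mean m give
    phi_g = (s2 - m) / m^2; the common estimate is the median over genes,
    clipped at 0.  Pooling within groups keeps real group differences out
    of the variance.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 samples")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    scaled = _scale_to_common(counts, library_sizes).values
    labels = groups.loc[counts.columns].values
    ss = np.zeros(len(counts))
    dof = 0
    for g in pd.unique(labels):
        block = scaled[:, labels == g]
        if block.shape[1] < 2:
            continue
        ss += block.var(axis=1, ddof=1) * (block.shape[1] - 1)
        dof += block.shape[1] - 1
    if dof == 0:
        raise ValueError("no group has >= 2 replicates")
    s2 = ss / dof
    m = scaled.mean(axis=1)
    ok = m > 0
    phi_g = (s2[ok] - m[ok]) / m[ok] ** 2
    if phi_g.size == 0:
        return 0.0
    return float(max(0.0, np.median(phi_g)))


def nb_exact_test(
    group_a: Sequence[int] | np.ndarray,
    group_b: Sequence[int] | np.ndarray,
    phi: float,
) -> float:
    """Two-sided exact test of equal means from library-size-equalized
    counts, conditioning on the gene's total (see module docstring)."""
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = len(a), len(b)
    sa, sb = int(a.sum()), int(b.sum())
    t = sa + sb
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi < 1e-12:
        logpmf = stats.binom.logpmf(x, t, n_a / (n_a + n_b))
    else:
        logpmf = stats.betabinom.logpmf(x, t, n_a / phi, n_b / phi)
    obs = logpmf[sa]
    # count outcomes no more probable than the observed split, ties once
    p = float(np.exp(logpmf[logpmf <= obs + 1e-10]).sum())
    return min(1.0, p)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 2.0
) -> pd.DataFrame:
    """Attach up/down/ns calls: up iff q <= alpha and log2FC >= tau, down
    iff q <= alpha and log2FC <= -tau (the threshold is applied to both
    directions symmetrically)."""
    out = results.copy()
    sig = out["qvalue"] <= alpha
    out["call"] = NS
    out.loc[sig & (out["log2fc"] >= lfc_threshold), "call"] = UP
    out.loc[sig & (out["log2fc"] <= -lfc_threshold), "call"] = DOWN
    return out


def run_de(
    cm: CountMatrix,
    group_a: str,
    group_b: str = "rest",
    alpha: float = 0.05,
    lfc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    phi: Optional[float] = None,
) -> pd.DataFrame:
    """Full screen of ``group_a`` against ``group_b`` (or all other samples
    when ``group_b="rest"``): dispersion estimation, per-gene exact test,
    BH adjustment and threshold calls.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b,
    log2fc, pvalue, qvalue, call.
    """
    samples_a = cm.samples_in(group_a)
    if group_b == "rest":
        samples_b = [s for s in cm.counts.columns if s not in samples_a]
    else:
        samples_b = cm.samples_in(group_b)
    if not samples_b:
        raise ValueError("contrast group is empty")
    if phi is None:
        phi = estimate_dispersion(
            cm.counts[samples_a + samples_b],
            cm.groups,
            cm.library_sizes[samples_a + samples_b],
        )
    sub = cm.counts[samples_a + samples_b]
    equalized = _scale_to_common(
        sub, cm.library_sizes[samples_a + samples_b], round_int=True
    )
    eq_a = equalized[samples_a].values
    eq_b = equalized[samples_b].values
    pvals = np.array(
        [nb_exact_test(eq_a[i], eq_b[i], phi) for i in range(len(equalized))]
    )
    lfc = log2_fold_change(eq_a, eq_b, pseudocount)
    res = pd.DataFrame(
        {
            "mean_a": eq_a.mean(axis=1),
            "mean_b": eq_b.mean(axis=1),
            "log2fc": lfc,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        },
        index=equalized.index,
    )
    res.index.name = "gene"
    res.attrs["dispersion"] = phi
    return call_de(res, alpha, lfc_threshold)


def summarize_calls(results: pd.DataFrame) -> dict[str, int]:
    c = results["call"].value_counts()
    return {k: int(c.get(k, 0)) for k in (UP, DOWN, NS)}


# --- plain-text I/O -------------------------------------------------------

def write_counts(cm: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    cm.lengths.to_frame().to_csv(outdir / "lengths.tsv", sep="\t", index_label="gene")
    cm.groups.to_frame().to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    (outdir / "library_sizes.json").write_text(
        json.dumps({k: float(v) for k, v in cm.library_sizes.items()}, indent=1)
    )


def read_counts(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene")
    lengths = pd.read_csv(indir / "lengths.tsv", sep="\t", index_col="gene")["length"]
    groups = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample")["group"]
    lib_path = indir / "library_sizes.json"
    library_sizes = None
    if lib_path.exists():
        library_sizes = pd.Series(json.loads(lib_path.read_text()), dtype=float)
    return CountMatrix(counts, groups, lengths, library_sizes)
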