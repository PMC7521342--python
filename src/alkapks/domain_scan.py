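"""Domain tagging of nucleotide transcripts by six-frame translation and
ungapped log-odds profile (PSSM) scanning, and the intersection of domain
hits with differential-expression calls into the candidate-gene table.

Profiles are position-specific log-odds matrices built from small seed
alignments with pseudocounts against a uniform background; each profile's
score threshold is calibrated empirically to a stated false-positive rate
on random protein sequence.  The composite "OR" (oxide reductase) label
used for reporting covers the KR and ER profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .domain_profiles import AA_ALPHABET, DOMAIN_LABELS, seed_alignment

__all__ = [
    "ProteinProfile",
    "DomainHit",
    "six_frame_translate",
    "build_pssm",
    "calibrate_threshold",
    "calibrate_threshold_transcripts",
    "default_profiles",
    "scan",
    "scan_transcripts",
    "select_candidates",
    "OR_DOMAINS",
]

FRAMES = (1, 2, 3, -1, -2, -3)

#: The composite reporting label "OR" expands to these two profiles.
OR_DOMAINS = frozenset({"KR", "ER"})

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class ProteinProfile:
    """Ungapped position-specific scoring matrix for one domain.

    ``matrix`` is width x 20 log2-odds (bits) against ``background``;
    ``threshold`` is the calibrated minimum reportable window score.
    """

    domain: str
    matrix: np.ndarray
    background: np.ndarray
    threshold: float = -np.inf

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[j] for j in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True)
class DomainHit:
    """Best-scoring window of one profile on one translated transcript.
    Protein coordinates are 0-based half-open."""

    transcript_id: str
    frame: int
    start: int
    end: int
    score: float
    domain: str


def six_frame_translate(sequence: str) -> dict[int, str]:
    """Standard-code translation of all six reading frames.

    Stops are rendered ``*`` and codons containing N render ``X``.  Frames
    +1..+3 read the given strand at offsets 0..2; -1..-3 read the reverse
    complement at offsets 0..2.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty nucleotide sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    out: dict[int, str] = {}
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for frame in FRAMES:
        strand = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        sub = strand[offset: offset + 3 * ((len(strand) - offset) // 3)]
        out[frame] = str(sub.translate())
    return out


def build_pssm(
    seed_rows: Sequence[str],
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    domain: str = "",
) -> ProteinProfile:
    """Log-odds profile from an ungapped, equal-length seed block:
    score[w, a] = log2(((count + pc * bg) / (n + pc)) / bg)."""
    if len(seed_rows) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    width = len(seed_rows[0])
    if any(len(r) != width for r in seed_rows):
        raise ValueError("ragged seed alignment")
    if background is None:
        background = np.full(20, 1 / 20)
    counts = np.zeros((width, 20))
    for row in seed_rows:
        for w, aa in enumerate(row):
            counts[w, _AA_INDEX[aa]] += 1
    n = len(seed_rows)
    freq = (counts + pseudocount * background) / (n + pseudocount)
    matrix = np.log2(freq / background)
    return ProteinProfile(domain=domain, matrix=matrix, background=background)


def _window_scores(protein: str, profile: ProteinProfile) -> np.ndarray:
    """Scores of every window; X/* positions contribute 0 bits."""
    width = profile.width
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in protein])
    n_win = len(idx) - width + 1
    if n_win <= 0:
        return np.empty(0)
    known = idx >= 0
    per_pos = np.zeros((n_win, width))
    for w in range(width):
        col = idx[w: w + n_win]
        ok = known[w: w + n_win]
        per_pos[ok, w] = profile.matrix[w, col[ok]]
    return per_pos.sum(axis=1)


def calibrate_threshold(
    profile: ProteinProfile,
    fpr: float = 0.05,
    n_random: int = 1000,
    length: int = 300,
    seed: int = 101,
) -> float:
    """Empirical threshold: the (1 - fpr) quantile of best-window scores on
    random proteins drawn from the profile's background."""
    rng = np.random.default_rng([seed, DOMAIN_LABELS.index(profile.domain)
                                 if profile.domain in DOMAIN_LABELS else 0])
    alphabet = np.array(list(AA_ALPHABET))
    best = np.empty(n_random)
    for i in range(n_random):
        protein = "".join(rng.choice(alphabet, length, p=profile.background))
        scores = _window_scores(protein, profile)
        best[i] = scores.max() if scores.size else -np.inf
    return float(np.quantile(best, 1 - fpr))


def calibrate_threshold_transcripts(
    profile: ProteinProfile,
    fpr: float = 0.05,
    n_random: int = 500,
    length: int = 600,
    seed: int = 101,
) -> float:
    """Empirical threshold at the unit the pipeline scans: the (1 - fpr)
    quantile of the best window score across all six frames of random
    nucleotide transcripts."""
    rng = np.random.default_rng([seed, 7, DOMAIN_LABELS.index(profile.domain)
                                 if profile.domain in DOMAIN_LABELS else 0])
    bases = np.array(list("ACGT"))
    best = np.empty(n_random)
    for i in range(n_random):
        seq = "".join(rng.choice(bases, length))
        frame_best = -np.inf
        for protein in six_frame_translate(seq).values():
            scores = _window_scores(protein, profile)
            if scores.size:
                frame_best = max(frame_best, float(scores.max()))
        best[i] = frame_best
    return float(np.quantile(best, 1 - fpr))


_PROFILE_CACHE: dict[tuple, dict[str, ProteinProfile]] = {}


def default_profiles(
    fpr: float = 0.05, calibration_seed: int = 101
) -> dict[str, ProteinProfile]:
    """Profiles for all bundled domains.

    Thresholds are calibrated per profile so that at most ``fpr`` of random
    transcripts yield any hit for that profile across the six reading
    frames (the scan's actual decision unit; per-protein calibration is
    available separately via :func:`calibrate_threshold`).
    """
    key = (fpr, calibration_seed)
    if key not in _PROFILE_CACHE:
        profiles = {}
        for domain in DOMAIN_LABELS:
            prof = build_pssm(seed_alignment(domain), domain=domain)
            prof.threshold = calibrate_threshold_transcripts(
                prof, fpr=fpr, seed=calibration_seed
            )
            profiles[domain] = prof
        _PROFILE_CACHE[key] = profiles
    return _PROFILE_CACHE[key]


def scan(
    protein: str, profile: ProteinProfile, transcript_id: str = "", frame: int = 1
) -> Optional[DomainHit]:
    """Best window at or above the profile threshold, or None.  A protein
    shorter than the profile yields None; ties break leftmost."""
    scores = _window_scores(protein, profile)
    if scores.size == 0:
        return None
    best = int(scores.argmax())
    if scores[best] < profile.threshold:
        return None
    return DomainHit(
        transcript_id=transcript_id,
        frame=frame,
        start=best,
        end=best + profile.width,
        score=float(scores[best]),
        domain=profile.domain,
    )


def scan_transcripts(
    records: Iterable[tuple[str, str]],
    profiles: Optional[Mapping[str, ProteinProfile]] = None,
) -> pd.DataFrame:
    """Scan every transcript in all six frames with every profile.

    Returns a tidy hits table (transcript, frame, start, end, score,
    domain) keeping, per transcript x domain, the single best frame.
    """
    if profiles is None:
        profiles = default_profiles()
    rows = []
    for tid, seq in records:
        translations = six_frame_translate(seq)
        for domain, profile in profiles.items():
            best: Optional[DomainHit] = None
            for frame in FRAMES:
                hit = scan(translations[frame], profile, tid, frame)
                if hit is not None and (best is None or hit.score > best.score):
                    best = hit
            if best is not None:
                rows.append(
                    (best.transcript_id, best.frame, best.start, best.end,
                     best.score, best.domain)
                )
    return pd.DataFrame(
        rows, columns=["transcript", "frame", "start", "end", "score", "domain"]
    )


def select_candidates(
    de_results: pd.DataFrame,
    hits: pd.DataFrame,
    producer_label: str = "up",
) -> pd.DataFrame:
    """Candidate genes: called ``up`` in the producer contrast and carrying
    at least one domain hit.  Domain labels are aggregated per gene, with
    KR/ER additionally reported under the composite label OR.
    """
    unknown = set(hits["transcript"]) - set(de_results.index)
    if unknown:
        raise ValueError(
            f"hits reference {len(unknown)} ids absent from the DE table, "
            f"e.g. {sorted(unknown)[:5]}"
        )
    up_genes = de_results.index[de_results["call"] == producer_label]
    sel = hits[hits["transcript"].isin(up_genes)]
    if sel.empty:
        return pd.DataFrame(
            columns=["gene", "domains", "reported", "log2fc", "qvalue"]
        ).set_index("gene")
    rows = []
    for gene, block in sel.groupby("transcript"):
        domains = sorted(set(block["domain"]))
        reported = sorted({("OR" if d in OR_DOMAINS else d) for d in domains})
        rows.append(
            (gene, ",".join(domains), ",".join(reported),
             float(de_results.loc[gene, "log2fc"]),
             float(de_results.loc[gene, "qvalue"]))
        )
    out = pd.DataFrame(
        rows, columns=["gene", "domains", "reported", "log2fc", "qvalue"]
    ).set_index("gene").sort_index()
    return out
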