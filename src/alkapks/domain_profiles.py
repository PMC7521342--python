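"""Bundled synthetic domain-motif fixtures.

Each PKS/FAS enzymatic domain (KS, AT, ACP, KR, DH, ER, TE) is represented
by a short synthetic consensus block (40-60 aa) — not a real Pfam model —
from which a small seed alignment of mutated variants is derived
deterministically.  These fixtures exist so that motif planting, profile
building and scanning can be exercised end to end without external
databases; they carry no biological sequence information.
"""

from __future__ import annotations

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Synthetic consensus blocks, one per domain label (fixed, arbitrary).
DOMAIN_CONSENSUS: dict[str, str] = {
    "KS": "RTDELNSIAFLIWKPPCRAANGIPECRYQTKAQNRPLAQELENLKNDLRWFT",
    "AT": "HKTFFIPVGHVYSNTFEQFQFMTGNPFLRQQMWDMWKAYHCEYHAPAN",
    "ACP": "PRDLMTAHKMSMSAGFNCIFWAQGVIAPETVKLPFMYFNESL",
    "KR": "SSWNMQERFPRFGKDMFACGNIFAKNQMGCNFAWMKEGMVALAPWWMMLE",
    "DH": "ARCWSKWQMVHEISPLINVWHTYDHKKQDTKEERTMICPMAKFKKG",
    "ER": "LIRSKHAVIRGSLKQEQAYKWLKIGDDAQVAITVKTPNHVFYAPTATPEL",
    "TE": "FSPIPQQITNALIFTHACFPFVCNYEYMPGPIHAIYPMPNECWD",
}

DOMAIN_LABELS = tuple(DOMAIN_CONSENSUS)

_SEED_ALIGNMENT_SEED = 20_200_925
_SEED_ALIGNMENT_DEPTH = 8
_SEED_MUTATION_RATE = 0.08


def seed_alignment(domain: str, depth: int = _SEED_ALIGNMENT_DEPTH) -> list[str]:
    """Deterministic ungapped seed alignment for ``domain``: the consensus
    plus ``depth - 1`` variants with ~8% random substitutions."""
    consensus = DOMAIN_CONSENSUS[domain]
    rng = np.random.default_rng(
        [_SEED_ALIGNMENT_SEED, DOMAIN_LABELS.index(domain)]
    )
    rows = [consensus]
    for _ in range(depth - 1):
        chars = list(consensus)
        for i in range(len(chars)):
            if rng.random() < _SEED_MUTATION_RATE:
                chars[i] = AA_ALPHABET[rng.integers(0, 20)]
        rows.append("".join(chars))
    return rows
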