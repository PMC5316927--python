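"""Small shared sequence helpers (bases, reverse complement, codon table)."""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# codon -> amino acid, with '*' for stops (standard genetic code)
CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_AA if CODON_AA[c] != "*"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the given GC fraction (AT and GC split evenly)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def gc_fraction(seq: str) -> float:
    """GC fraction over non-N bases; 0.0 for all-N or empty input."""
    s = seq.upper()
    n_gc = s.count("G") + s.count("C")
    n_at = s.count("A") + s.count("T")
    denom = n_gc + n_at
    return n_gc / denom if denom else 0.0
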