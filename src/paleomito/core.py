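"""Shared domain types for ancient-mtDNA analysis.

Coordinates are 1-based inclusive throughout, matching rCRS position
conventions. Mitochondrial references are circular; fragments may wrap the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical base order used for all encoded arrays; N encodes as 4
BASES = "ACGT"
ALPHABET = "ACGTN"
BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}
CODE_N = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    if a == b:
        raise ValueError(f"{a!r} -> {b!r} is not a substitution")
    return (a in _PURINES) == (b in _PURINES)


def transition_partner(base: str) -> str:
    return _TRANSITION_PARTNER[base]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    table = np.full(256, CODE_N, dtype=np.uint8)
    for b, c in BASE_TO_CODE.items():
        table[ord(b)] = c
    return table[out]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Haplotype:
    """A named nucleotide sequence, circular by default (mtDNA convention).

    Stands for a reference, an endogenous truth sequence, a contaminant, or
    a comparison-panel member.
    """

    id: str
    seq: str
    circular: bool = True
    #: substitution record (pos, old, new, class) when derived by mutation
    mutations: tuple = ()

    def __post_init__(self):
        if len(self.seq) == 0:
            raise ValueError(f"haplotype {self.id!r} has empty sequence")
        bad = set(self.seq) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"haplotype {self.id!r} contains disallowed symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position; wraps modulo length if circular."""
        if self.circular:
            return self.seq[(pos - 1) % len(self.seq)]
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"position {pos} outside linear haplotype")
        return self.seq[pos - 1]

    def codes(self) -> np.ndarray:
        return encode(self.seq)


@dataclass(frozen=True)
class DamageModel:
    """Terminal cytosine-deamination model for ancient DNA fragments.

    C->T substitutions accumulate from the 5' end of each molecule and G->A
    (the complementary-strand signature) from the 3' end, at rates that decay
    geometrically into the fragment:

        rate5(d) = delta5 * decay**(d - 1),   d = 1 at the terminus

    delta5/delta3 are the terminal (distance-1) rates.
    """

    delta5: float = 0.5
    delta3: float = 0.5
    decay: float = 0.5

    def __post_init__(self):
        for name in ("delta5", "delta3", "decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def rate5(self, dist):
        """C->T probability at 1-based distance `dist` from the 5' terminus."""
        d = np.asarray(dist)
        return self.delta5 * self.decay ** (d - 1)

    def rate3(self, dist):
        """G->A probability at 1-based distance `dist` from the 3' terminus."""
        d = np.asarray(dist)
        return self.delta3 * self.decay ** (d - 1)

    @classmethod
    def none(cls) -> "DamageModel":
        return cls(delta5=0.0, delta3=0.0, decay=0.0)


@dataclass
class AlignedFragment:
    """A short read placed on reference coordinates.

    `bases` are stored in reference orientation; `strand` records which
    molecule strand was sequenced, which determines where the deamination
    signature appears. `source` and `damage_flags` are simulation truth
    labels, hidden from estimators.
    """

    start: int  # 1-based reference coordinate of the leftmost aligned base
    strand: str  # '+' or '-'
    bases: str
    quals: np.ndarray  # per-base Phred scores
    source: str = "endogenous"  # or 'contaminant'
    damage_flags: np.ndarray | None = None  # per-base deamination truth

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals length mismatch")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"start {self.start} is not a 1-based coordinate")

    def __len__(self) -> int:
        return len(self.bases)

    def read_bases(self) -> str:
        """Bases in sequencing (read) orientation."""
        return self.bases if self.strand == "+" else revcomp(self.bases)
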