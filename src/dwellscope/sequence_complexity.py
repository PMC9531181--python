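"""Compositional complexity of amino-acid motifs (SEG-style, entropy form).

The score is the Shannon entropy of the residue composition of a motif,

    K = - sum_i (n_i / L) * log2(n_i / L)    [bits],

over the 20-letter amino-acid alphabet, where n_i are residue counts and L
the motif length.  This is the K1 (log-base-2) complexity measure used by
the SEG low-complexity detector.  A homopolymer scores 0; a motif whose
score exceeds 2.5 bits is conventionally classified as high complexity.
Only the compositional score is implemented — not SEG's trigger/extension
segmentation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "HIGH_COMPLEXITY_THRESHOLD",
    "Motif",
    "ComplexityResult",
    "complexity",
    "complexity_score",
    "window_complexity",
    "score_fasta",
    "results_to_dataframe",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HIGH_COMPLEXITY_THRESHOLD = 2.5


@dataclass(frozen=True)
class Motif:
    """A named amino-acid motif over the canonical 20-letter alphabet."""

    sequence: str
    name: str = ""
    allow_x: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty sequence")
        alphabet = AMINO_ACIDS + ("X" if self.allow_x else "")
        bad = sorted(set(seq) - set(alphabet))
        if bad:
            raise ValueError(f"non-amino-acid characters in {self.name or seq!r}: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(self.sequence))


@dataclass(frozen=True)
class ComplexityResult:
    name: str
    sequence: str
    length: int
    score_bits: float
    classification: str  # "low" | "high"
    threshold: float = HIGH_COMPLEXITY_THRESHOLD

    @property
    def score_display(self) -> float:
        """Score rounded to 2 decimals, as conventionally printed."""
        return round(self.score_bits, 2) + 0.0  # normalize -0.0


def complexity_score(sequence: str | Motif) -> float:
    """Unrounded entropy score in bits of a motif's residue composition."""
    motif = sequence if isinstance(sequence, Motif) else Motif(sequence)
    L = motif.length
    return -sum((n / L) * math.log2(n / L) for n in motif.counts.values())


def complexity(
    sequence: str | Motif,
    threshold: float = HIGH_COMPLEXITY_THRESHOLD,
    name: str = "",
) -> ComplexityResult:
    """Score a motif and classify it as low or high complexity.

    Classification uses the unrounded score and a strict ``> threshold``
    comparison; rounding to 2 decimals is display-only.
    """
    motif = sequence if isinstance(sequence, Motif) else Motif(sequence, name=name)
    score = complexity_score(motif)
    return ComplexityResult(
        name=motif.name or name,
        sequence=motif.sequence,
        length=motif.length,
        score_bits=score,
        classification="high" if score > threshold else "low",
        threshold=threshold,
    )


def window_complexity(
    sequence: str, window_len: int, threshold: float = HIGH_COMPLEXITY_THRESHOLD
) -> list[ComplexityResult]:
    """Score every length-``window_len`` substring (0-based half-open windows)."""
    motif = Motif(sequence)
    if window_len < 1 or window_len > motif.length:
        raise ValueError("window_len must be in [1, len(sequence)]")
    return [
        complexity(
            motif.sequence[i : i + window_len],
            threshold=threshold,
            name=f"{i}:{i + window_len}",
        )
        for i in range(motif.length - window_len + 1)
    ]


def score_fasta(path: str | Path, threshold: float = HIGH_COMPLEXITY_THRESHOLD) -> list[ComplexityResult]:
    """Score each record of a FASTA file of amino-acid motifs."""
    from Bio import SeqIO

    results = []
    for record in SeqIO.parse(str(path), "fasta"):
        results.append(complexity(str(record.seq), threshold=threshold, name=record.id))
    if not results:
        raise ValueError(f"no FASTA records in {path}")
    return results


def results_to_dataframe(results: list[ComplexityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "sequence": [r.sequence for r in results],
            "length": [r.length for r in results],
            "score_bits": [r.score_display for r in results],
            "classification": [r.classification for r in results],
        }
    )
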