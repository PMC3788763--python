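"""Labelled haplotype alignments and their on-disk formats.

Alignments are FASTA files of equal-length {A,C,G,T} sequences; the
individual-to-population assignment is a two-column tab-separated text file
(individual id, population label).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["HaplotypeAlignment", "read_alignment", "write_alignment"]

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass
class HaplotypeAlignment:
    """Aligned {A,C,G,T} sequences with a population label per individual.

    ``matrix`` holds base codes (A=0, C=1, G=2, T=3) with one row per
    individual; ``ids`` and ``populations`` are parallel to its rows.
    """

    ids: List[str]
    populations: List[str]
    matrix: np.ndarray  # (n_individuals, L) uint8 codes 0..3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        n = self.matrix.shape[0]
        if len(self.ids) != n or len(self.populations) != n:
            raise ValueError("ids/populations must match the number of rows")
        if self.matrix.size and self.matrix.max() > 3:
            raise ValueError("alignment contains codes outside {A,C,G,T}")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def population_labels(self) -> List[str]:
        """Distinct population labels in order of first appearance."""
        seen: Dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def rows_for(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, p in enumerate(self.populations) if p == population], dtype=np.int64
        )
        return idx

    def submatrix(self, population: str) -> np.ndarray:
        idx = self.rows_for(population)
        if idx.size == 0:
            raise ValueError(f"population {population!r} has no individuals")
        return self.matrix[idx]

    def sequence(self, i: int) -> str:
        return _CODE_TO_BASE[self.matrix[i]].tobytes().decode()

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        populations: Sequence[str],
        ids: Sequence[str] | None = None,
    ) -> "HaplotypeAlignment":
        if ids is None:
            ids = [f"ind{i:04d}" for i in range(len(sequences))]
        if len(set(len(s) for s in sequences)) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        mat = np.zeros((len(sequences), len(sequences[0]) if sequences else 0), dtype=np.uint8)
        for i, s in enumerate(sequences):
            row = np.frombuffer(s.upper().encode(), dtype=np.uint8)
            codes = np.full(row.shape, 255, dtype=np.uint8)
            for b, c in _BASE_TO_CODE.items():
                codes[row == ord(b)] = c
            if (codes == 255).any():
                bad = chr(row[(codes == 255).argmax()])
                raise ValueError(f"sequence {ids[i]!r} contains non-ACGT character {bad!r}")
            mat[i] = codes
        return cls(list(ids), list(populations), mat)


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> HaplotypeAlignment:
    """Read a FASTA alignment and its population map.

    Every FASTA record must appear in the popmap; popmap entries without a
    sequence are ignored.
    """
    popmap: Dict[str, str] = {}
    with open(popmap_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{popmap_path}:{lineno}: expected two columns, got {line!r}")
            popmap[parts[0]] = parts[1]

    ids, pops, seqs = [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in popmap:
            raise ValueError(f"sequence {rec.id!r} missing from population map")
        ids.append(rec.id)
        pops.append(popmap[rec.id])
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences found in {fasta_path}")
    return HaplotypeAlignment.from_sequences(seqs, pops, ids)


def write_alignment(
    aln: HaplotypeAlignment, fasta_path: str | Path, popmap_path: str | Path
) -> None:
    """Write FASTA + population map; round-trips bit-exactly with ``read_alignment``."""
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description="")
        for i in range(aln.n_individuals)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(popmap_path, "w") as fh:
        for ind, pop in zip(aln.ids, aln.populations):
            fh.write(f"{ind}\t{pop}\n")
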