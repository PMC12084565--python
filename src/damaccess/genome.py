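"""Genome sequence container.

A :class:`GenomeSequence` holds uppercase DNA strings over ``{A,C,G,T,N}``
keyed by chromosome name, preserving chromosome order. All genomic
coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


class GenomeSequence:
    """Ordered collection of chromosome sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to DNA string. Lowercase input is
        normalised to uppercase; characters outside ``ACGTN`` are rejected.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("empty genome: at least one chromosome required")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            s = str(seq).upper()
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._seqs[name] = s

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")
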