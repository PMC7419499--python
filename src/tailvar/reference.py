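"""Reference genome container with FASTA round-trip.

Sequences are held as mutable bytearrays so the cohort simulator can embed
transcript sequence and repeat tracts in place; analysis code only reads.
"""
from __future__ import annotations

from typing import Dict, Iterator, Mapping, Tuple

import pyfaidx

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


class Reference:
    """A set of named chromosome sequences (uppercase A/C/G/T)."""

    def __init__(self, seqs: Mapping[str, str | bytearray]):
        self._seqs: Dict[str, bytearray] = {
            name: bytearray(s.upper().encode() if isinstance(s, str) else bytes(s).upper())
            for name, s in seqs.items()
        }

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        ref = cls({name: str(fa[name][:]) for name in fa.keys()})
        fa.close()
        return ref

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self._seqs)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str, start0: int = 0, end0: int | None = None) -> str:
        s = self._seqs[chrom]
        return s[start0: len(s) if end0 is None else end0].decode()

    def base(self, chrom: str, pos0: int) -> str:
        s = self._seqs[chrom]
        if not (0 <= pos0 < len(s)):
            raise IndexError(f"position {pos0} outside {chrom} (len {len(s)})")
        return chr(s[pos0])

    def write(self, chrom: str, start0: int, segment: str) -> None:
        """Overwrite bases in place starting at ``start0`` (simulator use)."""
        s = self._seqs[chrom]
        end = start0 + len(segment)
        if start0 < 0 or end > len(s):
            raise IndexError(f"segment [{start0},{end}) outside {chrom}")
        s[start0:end] = segment.upper().encode()

    def gc_fraction(self, chrom: str) -> float:
        s = self._seqs[chrom]
        return (s.count(b"G"[0]) + s.count(b"C"[0])) / len(s)

    def write_fasta(self, path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, s in self._seqs.items():
                fh.write(f">{name}\n")
                text = s.decode()
                for i in range(0, len(text), line_width):
                    fh.write(text[i: i + line_width] + "\n")
        pyfaidx.Faidx(str(path), rebuild=True)  # writes the .fai index
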