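"""Raw tag read container with FASTQ round-trip.

Reads are stored as a fixed-width NumPy byte array so that cleaning and
aggregation over multi-million-read libraries stay vectorized.  Variable
read lengths (malformed reads shorter or longer than the 21-mer tag) are
representable because NumPy ``S``-dtype elements carry their own length up
to the array width.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InputError, ParseError

DEFAULT_QUALITY_CHAR = "I"  # Phred 40 at offset 33


class RawTagReads:
    """A library of raw tag reads, optionally with per-base qualities.

    Parameters
    ----------
    sequences
        NumPy ``S``-dtype array, or any iterable of ``str``/``bytes``.
    qualities
        Optional parallel array/iterable of Phred+33 quality strings, each
        the same length as its read.  ``None`` means "no quality data"
        (simulated reads); cleaning then only applies the N filter.
    library_id
        Free-text label (typically the stage name).
    """

    def __init__(
        self,
        sequences: Sequence[str] | Sequence[bytes] | np.ndarray,
        qualities: Sequence[str] | np.ndarray | None = None,
        library_id: str = "",
    ):
        if isinstance(sequences, np.ndarray) and sequences.dtype.kind == "S":
            self.sequences = sequences
        else:
            self.sequences = np.asarray(list(sequences), dtype="S")
        if self.sequences.ndim != 1:
            raise InputError("sequences must be one-dimensional")
        if qualities is None:
            self.qualities: np.ndarray | None = None
        else:
            if isinstance(qualities, np.ndarray) and qualities.dtype.kind == "S":
                self.qualities = qualities
            else:
                self.qualities = np.asarray(list(qualities), dtype="S")
            if len(self.qualities) != len(self.sequences):
                raise InputError("qualities and sequences differ in length")
        self.library_id = library_id

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        for seq in self.sequences:
            yield seq.decode()

    @classmethod
    def from_strings(
        cls, reads: Iterable[str], library_id: str = ""
    ) -> "RawTagReads":
        return cls(list(reads), library_id=library_id)

    @classmethod
    def from_fastq(cls, path: str | Path, library_id: str | None = None) -> "RawTagReads":
        """Parse a (plain-text) FASTQ file.

        Raises :class:`ParseError` with the offending record index on
        malformed input.
        """
        seqs: list[str] = []
        quals: list[str] = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines:
            raise InputError(f"{path}: empty FASTQ file")
        if len(lines) % 4 != 0:
            raise ParseError(f"{path}: truncated FASTQ (line count not divisible by 4)")
        for i in range(0, len(lines), 4):
            rec = i // 4
            header, seq, plus, qual = lines[i : i + 4]
            if not header.startswith("@"):
                raise ParseError(f"{path}: record {rec}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: record {rec}: separator line missing '+'")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {rec}: sequence and quality lengths differ"
                )
            seqs.append(seq.upper())
            quals.append(qual)
        lib = library_id if library_id is not None else Path(path).stem
        return cls(seqs, qualities=quals, library_id=lib)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            quals = self.qualities
            for i, seq in enumerate(self.sequences):
                s = seq.decode()
                q = quals[i].decode() if quals is not None else DEFAULT_QUALITY_CHAR * len(s)
                fh.write(f"@read{i}\n{s}\n+\n{q}\n")
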