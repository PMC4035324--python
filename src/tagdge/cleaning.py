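"""Read cleaning: raw tag reads -> clean-tag count table + statistics.

Cleaning applies, in fixed priority order:

1. adaptor-only / empty reads (no CATG anywhere) are dropped;
2. structurally bad reads (length != 21 or missing the CATG prefix) are
   dropped as bad-length;
3. low-quality reads (any N, or any base call below the Phred threshold when
   qualities are present) are dropped;
4. surviving reads are aggregated into tag counts, and tags seen exactly
   once in the whole library are removed as singletons.

Each raw read is counted in exactly one category, so the categories
partition the input; libraries of this design typically retain >97% of
acquired tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import InputError
from .reads import RawTagReads
from .reference import ANCHOR, TAG_LENGTH

DEFAULT_QUALITY_THRESHOLD = 10  # Phred; any base below fails the read


@dataclass
class CleaningStats:
    """Per-library cleaning tallies; categories partition ``n_raw``."""

    n_raw: int
    n_adaptor_only: int
    n_bad_length: int
    n_low_quality: int
    n_singleton_removed: int
    n_clean: int

    @property
    def clean_fraction(self) -> float:
        return self.n_clean / self.n_raw if self.n_raw else 0.0

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_adaptor_only": self.n_adaptor_only,
            "n_bad_length": self.n_bad_length,
            "n_low_quality": self.n_low_quality,
            "n_singleton_removed": self.n_singleton_removed,
            "n_clean": self.n_clean,
            "clean_fraction": self.clean_fraction,
        }


@dataclass
class TagCountTable:
    """Clean-tag counts for one library."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, tag: str) -> int:
        return self.counts[tag]

    def validate(self) -> None:
        for tag, count in self.counts.items():
            if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
                raise InputError(f"{self.library_id}: malformed tag {tag!r}")
            if count <= 0:
                raise InputError(f"{self.library_id}: non-positive count for {tag!r}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcount\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str | None = None) -> "TagCountTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag"):
                raise InputError(f"{path}: not a tag-count TSV")
            for line in fh:
                tag, count = line.rstrip("\n").split("\t")
                counts[tag] = counts.get(tag, 0) + int(count)
        lib = library_id if library_id is not None else Path(path).stem
        table = cls(library_id=lib, counts=counts)
        table.validate()
        return table


def clean_reads(
    reads: RawTagReads,
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    remove_singletons: bool = True,
) -> tuple[TagCountTable, CleaningStats]:
    """Clean a raw read library into a tag-count table.

    Parameters
    ----------
    quality_threshold
        Minimum per-base Phred score; a read with any base below it fails
        (only applied when the library carries qualities).  Any N fails
        regardless.
    remove_singletons
        Drop tags whose aggregate library-wide count is exactly 1.

    Returns the count table and a :class:`CleaningStats` whose categories
    partition the raw read count.
    """
    n_raw = len(reads)
    if n_raw == 0:
        raise InputError(f"{reads.library_id}: empty read set")

    seqs = reads.sequences
    anchor = ANCHOR.encode()

    # priority 1: adaptor-only / empty — no CATG anywhere in the read
    has_anchor = np.char.find(seqs, anchor) >= 0
    n_adaptor = int(np.sum(~has_anchor))

    # priority 2: wrong length or anchor not at the 5' end
    lengths = np.char.str_len(seqs)
    good_struct = has_anchor & (lengths == TAG_LENGTH) & np.char.startswith(seqs, anchor)
    n_bad_length = int(np.sum(has_anchor & ~good_struct))

    # priority 3: low quality — any N, or any quality char below threshold
    low_q = np.char.find(seqs, b"N") >= 0
    if reads.qualities is not None:
        qmin = np.frombuffer(
            np.char.ljust(reads.qualities, int(reads.qualities.dtype.itemsize), b"~").tobytes(),
            dtype=np.uint8,
        ).reshape(len(seqs), -1).min(axis=1)
        low_q |= qmin < (quality_threshold + 33)
    n_low_quality = int(np.sum(good_struct & low_q))
    keep = good_struct & ~low_q

    tags, counts = np.unique(seqs[keep], return_counts=True)
    if remove_singletons:
        singles = counts == 1
        n_singleton = int(np.sum(singles))
        tags, counts = tags[~singles], counts[~singles]
    else:
        n_singleton = 0
    n_clean = int(counts.sum())

    table = TagCountTable(
        library_id=reads.library_id,
        counts={t.decode(): int(c) for t, c in zip(tags, counts)},
    )
    stats = CleaningStats(
        n_raw=n_raw,
        n_adaptor_only=n_adaptor,
        n_bad_length=n_bad_length,
        n_low_quality=n_low_quality,
        n_singleton_removed=n_singleton,
        n_clean=n_clean,
    )
    assert (
        stats.n_adaptor_only
        + stats.n_bad_length
        + stats.n_low_quality
        + stats.n_singleton_removed
        + stats.n_clean
        == stats.n_raw
    ), "cleaning categories must partition the input"
    return table, stats
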