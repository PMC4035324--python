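"""In-silico tag reference construction.

A tag library is produced by an anchoring enzyme that cuts at CATG and a
tagging enzyme that cuts 17 bp downstream, so every sequenced tag is a 21-mer:
the CATG anchor plus the 17 bases immediately 3' of it.  Because the cDNA is
oligo-dT primed, the tag that reaches the sequencer is the one generated at
the 3'-most eligible CATG of each transcript; this module extracts that
canonical tag per gene and classifies reference tags as unique or ambiguous
(shared verbatim by two or more genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

ANCHOR = "CATG"
VARIABLE_LENGTH = 17
TAG_LENGTH = len(ANCHOR) + VARIABLE_LENGTH  # 21

_VALID_BASES = frozenset("ACGTN")


class GeneCatalog:
    """Ordered mapping of gene id to uppercase sense-strand DNA sequence.

    Stands in for an annotated gene catalog (transcript/CDS-like records);
    the tag index is built from it.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._genes: dict[str, str] = {}
        for gene_id, seq in records:
            if gene_id in self._genes:
                raise InputError(f"duplicate gene id {gene_id!r}")
            if not seq:
                raise InputError(f"empty sequence for gene {gene_id!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise InputError(
                    f"gene {gene_id!r} has characters outside ACGTN: {sorted(bad)}"
                )
            self._genes[gene_id] = seq

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> str:
        return self._genes[gene_id]

    def items(self) -> Iterable[tuple[str, str]]:
        return self._genes.items()

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GeneCatalog":
        records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(seq), id=gene_id, description="")
            for gene_id, seq in self._genes.items()
        )
        SeqIO.write(records, str(path), "fasta")


def extract_canonical_tag(sequence: str) -> str | None:
    """Return the canonical 21-mer tag of a transcript, or ``None``.

    The canonical tag is the CATG anchor plus the 17 bases immediately 3' of
    the 3'-most CATG occurrence that has at least 17 downstream bases.
    Occurrences whose 21-mer window contains an N are skipped.

    Raises
    ------
    InputError
        If the sequence contains characters outside ``ACGTN``.
    """
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise InputError(f"sequence has characters outside ACGTN: {sorted(bad)}")
    # scan anchor occurrences right-to-left; first eligible wins
    pos = sequence.rfind(ANCHOR)
    while pos != -1:
        tag = sequence[pos : pos + TAG_LENGTH]
        if len(tag) == TAG_LENGTH and "N" not in tag:
            return tag
        pos = sequence.rfind(ANCHOR, 0, pos + len(ANCHOR) - 1)
    return None


@dataclass
class IndexStats:
    """Bookkeeping emitted by :meth:`TagIndex.build`."""

    n_genes: int = 0
    n_with_tag: int = 0
    n_without_tag: int = 0
    n_unique_tags: int = 0
    n_ambiguous_tags: int = 0


@dataclass
class TagIndex:
    """Reference tag index: canonical 21-mer -> owning genes.

    A tag owned verbatim by two or more genes is ambiguous; observations
    matching it cannot be assigned and are excluded from counting.
    """

    tag_to_genes: dict[str, tuple[str, ...]]
    genome_size: int
    stats: IndexStats = field(default_factory=IndexStats)

    @classmethod
    def build(cls, catalog: GeneCatalog) -> "TagIndex":
        if len(catalog) == 0:
            raise InputError("cannot build a tag index from an empty catalog")
        tag_to_genes: dict[str, list[str]] = {}
        n_without = 0
        for gene_id, seq in catalog.items():
            tag = extract_canonical_tag(seq)
            if tag is None:
                n_without += 1
                continue
            tag_to_genes.setdefault(tag, []).append(gene_id)
        frozen = {tag: tuple(genes) for tag, genes in tag_to_genes.items()}
        n_ambiguous = sum(1 for genes in frozen.values() if len(genes) > 1)
        stats = IndexStats(
            n_genes=len(catalog),
            n_with_tag=len(catalog) - n_without,
            n_without_tag=n_without,
            n_unique_tags=len(frozen) - n_ambiguous,
            n_ambiguous_tags=n_ambiguous,
        )
        return cls(tag_to_genes=frozen, genome_size=len(catalog), stats=stats)

    def status(self, tag: str) -> str:
        genes = self.tag_to_genes[tag]
        return "unique" if len(genes) == 1 else "ambiguous"

    def __len__(self) -> int:
        return len(self.tag_to_genes)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tag_to_genes

    @property
    def gene_ids(self) -> list[str]:
        """Genes with an extractable canonical tag, in first-seen order."""
        seen: dict[str, None] = {}
        for genes in self.tag_to_genes.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tgene_id\tstatus\n")
            for tag, genes in self.tag_to_genes.items():
                status = "unique" if len(genes) == 1 else "ambiguous"
                for gene_id in genes:
                    fh.write(f"{tag}\t{gene_id}\t{status}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, genome_size: int | None = None) -> "TagIndex":
        tag_to_genes: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag\t"):
                raise InputError(f"{path}: not a tag index TSV")
            for line in fh:
                tag, gene_id, _status = line.rstrip("\n").split("\t")
                tag_to_genes.setdefault(tag, []).append(gene_id)
        frozen = {t: tuple(g) for t, g in tag_to_genes.items()}
        n_genes = len({g for gs in frozen.values() for g in gs})
        return cls(
            tag_to_genes=frozen,
            genome_size=genome_size if genome_size is not None else n_genes,
        )
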