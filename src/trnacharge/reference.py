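"""Custom tRNA alignment reference.

Mature tRNAs carry a post-transcriptionally added 3'-CCA, so the alignment
reference is built from genomic tRNA gene sequences by (1) collapsing genes
with identical sequence onto a single representative and (2) appending
``CCA`` to each unique sequence.  Genes are grouped into isodecoders
(isotype + anticodon, e.g. ``His-GTG``), the unit at which charging
fractions are aggregated and reported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: gtRNAdb-style gene identifier, e.g. ``tRNA-His-GTG-1-1`` or
#: ``tRNA-iMet-CAT-1-1``.  The isotype token is kept verbatim (``iMet``,
#: ``SeC`` and suppressor isotypes are all legal).
_NAME_RE = re.compile(
    r"^(?:\S*_)?tRNA-(?P<isotype>[A-Za-z]{1,5})-(?P<anticodon>[ACGT]{3})"
    r"(?:-(?P<family>\d+))?(?:-(?P<copy>\d+))?$"
)

_SEQ_ALPHABET = set("ACGTN")


class ReferenceError(ValueError):
    """Raised for malformed gene sets (bad headers, inconsistent duplicates)."""


@dataclass(frozen=True)
class TrnaGene:
    """A genomic tRNA gene: name, parsed isotype/anticodon, raw sequence (no CCA)."""

    name: str
    isotype: str
    anticodon: str
    sequence: str

    @property
    def isodecoder(self) -> str:
        return f"{self.isotype}-{self.anticodon}"


def parse_gene_name(name: str) -> tuple[str, str]:
    """Parse isotype and anticodon out of a gtRNAdb-style gene name.

    >>> parse_gene_name("tRNA-His-GTG-1-1")
    ('His', 'GTG')
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ReferenceError(
            f"cannot parse tRNA gene header {name!r}: expected "
            "tRNA-<Isotype>-<Anticodon>[-<family>[-<copy>]]"
        )
    return m.group("isotype"), m.group("anticodon")


def isodecoder_id(gene_name: str) -> str:
    """Isodecoder identifier ``<Isotype>-<Anticodon>`` for a gene name."""
    isotype, anticodon = parse_gene_name(gene_name)
    return f"{isotype}-{anticodon}"


def parse_gene_fasta(source: str | Path | TextIO) -> list[TrnaGene]:
    """Read a tRNA gene set FASTA into :class:`TrnaGene` records, order preserved.

    ``source`` may be a path or an open text handle.  Headers must carry a
    parseable gene identifier in the first whitespace-delimited token.
    """
    is_path = isinstance(source, Path) or (
        isinstance(source, str) and source != "" and ">" not in source
    )
    if is_path:
        records = list(SeqIO.parse(str(source), "fasta"))
    else:
        import io

        handle = io.StringIO(source) if isinstance(source, str) else source
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ReferenceError("empty tRNA gene FASTA")
    genes = []
    for rec in records:
        isotype, anticodon = parse_gene_name(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ReferenceError(f"gene {rec.id} has an empty sequence")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ReferenceError(f"gene {rec.id} contains non-DNA characters {bad}")
        genes.append(TrnaGene(rec.id, isotype, anticodon, seq))
    return genes


@dataclass
class ReferenceSet:
    """Deduplicated, CCA-appended tRNA reference.

    entries
        representative gene name -> CCA-appended sequence (insertion order =
        first occurrence in the input gene set).
    aliases
        duplicate gene name -> representative name, for genes whose genomic
        sequence was identical to an earlier gene.
    isodecoder_of
        representative name -> isodecoder id.
    """

    entries: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    isodecoder_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def isodecoders(self) -> list[str]:
        seen: dict[str, None] = {}
        for iso in self.isodecoder_of.values():
            seen.setdefault(iso)
        return list(seen)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.entries.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_aliases_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("alias\trepresentative\n")
            for alias, rep in self.aliases.items():
                fh.write(f"{alias}\t{rep}\n")

    def write_isodecoder_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tisodecoder\n")
            for name, iso in self.isodecoder_of.items():
                fh.write(f"{name}\t{iso}\n")


def build_reference(genes: Iterable[TrnaGene]) -> ReferenceSet:
    """Collapse duplicate gene sequences and append CCA to each unique one.

    The first-seen name of each distinct genomic sequence becomes the
    representative; later identical sequences are recorded as aliases so
    that read counts remain attributable to every gene name.  Inputs must
    be genomic (pre-CCA) sequences; a warning is logged if a genomic
    sequence already ends in CCA (the CCA is still appended).
    """
    genes = list(genes)
    if not genes:
        raise ReferenceError("cannot build a reference from zero genes")
    by_seq: dict[str, str] = {}
    by_name: dict[str, str] = {}
    ref = ReferenceSet()
    for g in genes:
        if g.name in by_name:
            if by_name[g.name] != g.sequence:
                raise ReferenceError(
                    f"duplicate gene name {g.name} with differing sequences"
                )
            # identical name+sequence record: ignore the repeat
            continue
        by_name[g.name] = g.sequence
        if g.sequence.endswith("CCA"):
            log.warning(
                "gene %s genomic sequence already ends in CCA; appending anyway",
                g.name,
            )
        rep = by_seq.get(g.sequence)
        if rep is None:
            by_seq[g.sequence] = g.name
            ref.entries[g.name] = g.sequence + "CCA"
            ref.isodecoder_of[g.name] = g.isodecoder
        else:
            ref.aliases[g.name] = rep
    return ref
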