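"""Inline-barcode demultiplexing and adapter trimming.

Pairs are assigned to samples by the five-nucleotide barcode ligated within
the 3' adapter, read as the reverse complement of R2 positions 1-5 under
the default layout.  Pairs without an identifiable barcode are discarded.
After assignment, barcode/adapter bases are trimmed from both mates and
pairs in which either mate retains fewer than 20 nt (empty adapters) are
removed.  Every stage keeps conservation accounting:
``total = Σ assigned + unassigned`` and ``assigned = retained +
discarded_short`` per sample.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .util import revcomp

BARCODE_LEN = 5
UNASSIGNED = "__unassigned__"
MIN_INSERT_LEN = 20  # pairs with <20 nt in either mate after trimming are dropped


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRow:
    sample: str
    barcode: str
    condition: str
    replicate: int


@dataclass
class BarcodeTable:
    """Sample sheet: sample name, 5-nt barcode, condition, replicate."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        names = [r.sample for r in self.rows]
        if len(set(names)) != len(names):
            raise DemuxError("sample names are not unique")
        barcodes = [r.barcode for r in self.rows]
        if len(set(barcodes)) != len(barcodes):
            dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise DemuxError(f"barcodes are not unique: {dupes}")
        for b in barcodes:
            if len(b) != BARCODE_LEN or set(b) - set("ACGT"):
                raise DemuxError(f"barcode {b!r} is not a 5-mer over ACGT")

    def barcode_to_sample(self) -> dict[str, str]:
        return {r.barcode: r.sample for r in self.rows}

    @property
    def samples(self) -> list[str]:
        return [r.sample for r in self.rows]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {col: i for i, col in enumerate(header)}
            for col in ("sample", "barcode", "condition", "replicate"):
                if col not in idx:
                    raise DemuxError(f"sample sheet missing column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append(
                    SampleRow(
                        f[idx["sample"]], f[idx["barcode"]],
                        f[idx["condition"]], int(f[idx["replicate"]]),
                    )
                )
        return cls(rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tbarcode\tcondition\treplicate\n")
            for r in self.rows:
                fh.write(f"{r.sample}\t{r.barcode}\t{r.condition}\t{r.replicate}\n")


@dataclass
class DemuxReport:
    total_pairs: int = 0
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    discarded_short: dict[str, int] = field(default_factory=dict)
    retained: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        if self.total_pairs != sum(self.assigned.values()) + self.unassigned:
            raise AssertionError("demux accounting violated: total != assigned + unassigned")
        for s, n in self.assigned.items():
            if n != self.retained.get(s, 0) + self.discarded_short.get(s, 0):
                raise AssertionError(
                    f"trim accounting violated for sample {s}: "
                    "assigned != retained + discarded_short"
                )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(
                    total_pairs=self.total_pairs,
                    assigned=self.assigned,
                    unassigned=self.unassigned,
                    discarded_short=self.discarded_short,
                    retained=self.retained,
                ),
                fh,
                indent=2,
            )


def extract_barcode(r2_seq: str) -> str | None:
    """Decode the sample barcode from R2 (reverse complement of positions 1-5)."""
    if len(r2_seq) < BARCODE_LEN:
        return None
    return revcomp(r2_seq[:BARCODE_LEN])


def demultiplex(
    pair: tuple[str, str, str, str, str],
    barcode_table: BarcodeTable,
    *,
    barcode_mismatch: int = 0,
    _lookup: dict[str, str] | None = None,
) -> str:
    """Assign one pair to a sample name, or :data:`UNASSIGNED`.

    Matching is exact by default.  With ``barcode_mismatch=1`` a barcode is
    accepted at Hamming distance 1 only when exactly one table barcode is
    that close (ambiguous assignments stay unassigned).
    """
    lookup = _lookup if _lookup is not None else barcode_table.barcode_to_sample()
    bc = extract_barcode(pair[3])
    if bc is None:
        return UNASSIGNED
    hit = lookup.get(bc)
    if hit is not None:
        return hit
    if barcode_mismatch >= 1:
        close = [
            s for b, s in lookup.items()
            if sum(x != y for x, y in zip(b, bc)) <= barcode_mismatch
        ]
        if len(close) == 1:
            return close[0]
    return UNASSIGNED


#: adapter matching uses at most this many adapter bases; a longer adapter
#: occurrence necessarily contains a valid 16 nt prefix match
MAX_ADAPTER_MATCH = 16


def find_adapter_cuts(
    reads: list[str], adapter: str, min_overlap: int = 10
) -> np.ndarray:
    """Leftmost 3' adapter trim position for every read (vectorised).

    A start position i matches when the overlap ``read[i:i+ov]`` vs
    ``adapter[:ov]`` (ov = min(len(adapter), len(read)-i, 16), ov >=
    min_overlap) has at most ``ov // 10`` mismatches — 1 per 10 nt,
    substitutions only.  Among matching positions the one with the fewest
    mismatches wins (leftmost on ties).  Reads without a match keep their
    full length (cut = len(read)).
    """
    adapter = adapter[:MAX_ADAPTER_MATCH]
    m = len(adapter)
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    cuts = np.empty(len(reads), dtype=np.int64)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(i)
    for n, idx in by_len.items():
        if n < min_overlap:
            cuts[idx] = n
            continue
        buf = np.full((len(idx), n + m), 255, dtype=np.uint8)
        for row, i in enumerate(idx):
            buf[row, :n] = np.frombuffer(reads[i].encode(), dtype=np.uint8)
        n_pos = n - min_overlap + 1
        win = np.lib.stride_tricks.sliding_window_view(buf, m, axis=1)[:, :n_pos]
        full_mm = (win != a).sum(axis=2)
        ov = np.minimum(m, n - np.arange(n_pos))
        true_mm = full_mm - (m - ov)
        valid = true_mm <= ov // 10
        # rank candidates by mismatch count, then by position
        rank = np.where(valid, true_mm * (n + 1) + np.arange(n_pos), np.iinfo(np.int64).max)
        cuts[idx] = np.where(valid.any(axis=1), rank.argmin(axis=1), n)
    return cuts


def _find_adapter(read: str, adapter: str, min_overlap: int = 10) -> int:
    """Single-read version of :func:`find_adapter_cuts`."""
    return int(find_adapter_cuts([read], adapter, min_overlap)[0])


DISCARD = None


def trim_pair(
    pair: tuple[str, str, str, str, str],
    r1_adapter: str,
    r2_adapter: str,
    min_len: int = MIN_INSERT_LEN,
) -> tuple[str, str, str, str, str] | None:
    """Trim adapter/barcode bases from an assigned pair; None = discard.

    R2 loses its first 5 bases (the barcode) plus any 3' read-through into
    the far adapter; R1 loses any 3' read-through into
    ``r1_adapter`` (the sample barcode followed by the constant 3' adapter).
    Pairs in which either mate keeps fewer than ``min_len`` bases are
    discarded as empty adapters (strictly-less-than rule: exactly
    ``min_len`` nt is retained).
    """
    name, s1, q1, s2, q2 = pair
    cut1 = _find_adapter(s1, r1_adapter)
    s1, q1 = s1[:cut1], q1[:cut1]
    s2, q2 = s2[BARCODE_LEN:], q2[BARCODE_LEN:]
    cut2 = _find_adapter(s2, r2_adapter)
    s2, q2 = s2[:cut2], q2[:cut2]
    if len(s1) < min_len or len(s2) < min_len:
        return DISCARD
    return (name, s1, q1, s2, q2)


def demux_and_trim(
    pairs: Iterable[tuple[str, str, str, str, str]],
    barcode_table: BarcodeTable,
    *,
    constant_adapter3: str,
    r2_adapter: str,
    barcode_mismatch: int = 0,
    min_len: int = MIN_INSERT_LEN,
) -> tuple[dict[str, list[tuple[str, str, str, str, str]]], DemuxReport]:
    """Partition a pooled pair stream into trimmed per-sample streams.

    ``constant_adapter3`` is the invariant adapter downstream of the sample
    barcode; the full R1 3' adapter for a sample is barcode + constant.
    ``r2_adapter`` is the sequence R2 runs into past the insert (the
    reverse complement of the 5' adapter).
    """
    lookup = barcode_table.barcode_to_sample()
    bc_of = {r.sample: r.barcode for r in barcode_table.rows}
    r1_adapters = {s: bc_of[s] + constant_adapter3 for s in bc_of}
    assigned: dict[str, list] = {s: [] for s in barcode_table.samples}
    report = DemuxReport(
        assigned={s: 0 for s in assigned},
        discarded_short={s: 0 for s in assigned},
        retained={s: 0 for s in assigned},
    )
    for pair in pairs:
        report.total_pairs += 1
        sample = demultiplex(
            pair, barcode_table, barcode_mismatch=barcode_mismatch, _lookup=lookup
        )
        if sample == UNASSIGNED:
            report.unassigned += 1
            continue
        report.assigned[sample] += 1
        assigned[sample].append(pair)

    out: dict[str, list] = {s: [] for s in assigned}
    for sample, sample_pairs in assigned.items():
        if not sample_pairs:
            continue
        cuts1 = find_adapter_cuts(
            [p[1] for p in sample_pairs], r1_adapters[sample]
        )
        r2_bodies = [p[3][BARCODE_LEN:] for p in sample_pairs]
        cuts2 = find_adapter_cuts(r2_bodies, r2_adapter)
        for (name, s1, q1, s2, q2), c1, c2 in zip(sample_pairs, cuts1, cuts2):
            if c1 < min_len or c2 < min_len:
                report.discarded_short[sample] += 1
                continue
            report.retained[sample] += 1
            out[sample].append(
                (name, s1[:c1], q1[:c1],
                 s2[BARCODE_LEN:BARCODE_LEN + c2], q2[BARCODE_LEN:BARCODE_LEN + c2])
            )
    report.check_conservation()
    return out, report


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Stream (name, r1_seq, r1_qual, r2_seq, r2_qual) from paired FASTQ(.gz)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    def _open(path):
        path = str(path)
        return gzip.open(path, "rt") if path.endswith(".gz") else open(path)

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True
        ):
            n1 = t1.split()[0]
            n2 = t2.split()[0]
            if n1 != n2:
                raise DemuxError(f"paired FASTQ out of sync: {n1!r} vs {n2!r}")
            yield (n1, s1, q1, s2, q2)


def write_fastq_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for name, s1, q1, s2, q2 in pairs:
            fh1.write(f"@{name}\n{s1}\n+\n{q1}\n")
            fh2.write(f"@{name}\n{s2}\n+\n{q2}\n")
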