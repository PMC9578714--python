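"""Synthetic CHARGE-seq library simulator.

Emulates the sequencing readout of a periodate/β-elimination tRNA charging
assay: each library molecule is a tRNA insert whose 3' end is ``CCA`` if the
molecule was aminoacylated (charged, protected from oxidation) or ``CC`` if
it was uncharged (terminal A removed by β-elimination), ligated to a
constant 3' adapter that carries a five-nucleotide sample barcode.

Read geometry (a fixture convention — the assay itself fixes chemistry, not
read layout)::

    molecule:  [5' adapter][insert (gene ± CCA/CC)][barcode 5 nt][3' adapter]
    R1: reads the insert from its 5' end, running into barcode + 3' adapter
    R2: starts at the barcode, so R2[0:5] is the reverse complement of the
        barcode followed by the reverse complement of the insert 3' end
        (the CCA/CC charging signal)

Besides well-formed pairs the simulator emits two failure classes seen in
real libraries: pairs whose barcode matches no sample (corrupted/foreign
barcodes) and empty-adapter pairs whose insert is shorter than 20 nt.
Substitution sequencing error is applied per base; the five barcode bases
are emitted error-free so the no-barcode rate is exactly the configured
parameter (real data would lose a further ~5·error_rate of pairs there).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demux import BarcodeTable, SampleRow
from .reference import TrnaGene, parse_gene_fasta
from .util import revcomp

# Constant adapters (fixture sequences, long enough to pad any read length).
ADAPTER3 = (
    "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"
    "AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
)
ADAPTER5 = (
    "GTTCAGAGTTCTACAGTCCGACGATCAACGGGCTACAGTCCGACGATCTCGGAAGAGCACACG"
    "TTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT"
)

BARCODE_LEN = 5

#: realistic isotype/anticodon combinations; His-GTG first so the default
#: perturbation target always exists.
_ISODECODER_POOL = [
    ("His", "GTG"), ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GTT"),
    ("Asp", "GTC"), ("Cys", "GCA"), ("Gln", "CTG"), ("Glu", "CTC"),
    ("Gly", "GCC"), ("Ile", "AAT"), ("Leu", "CAA"), ("Lys", "CTT"),
    ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "AGG"), ("Ser", "AGA"),
    ("Thr", "AGT"), ("Trp", "CCA"), ("Tyr", "GTA"), ("Val", "AAC"),
    ("SeC", "TCA"), ("iMet", "CAT"), ("Leu", "AAG"), ("Arg", "TCT"),
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ChargingProfile:
    """True per-isodecoder charged fractions for one experimental condition."""

    condition_name: str
    per_isodecoder_fraction: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso, f in self.per_isodecoder_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(
                    f"charging fraction for {iso} out of [0,1]: {f}"
                )


@dataclass(frozen=True)
class SimConfig:
    """Simulator knobs; defaults mirror the default study design
    (4 replicates per condition, 5,000 pairs per sample)."""

    n_replicates: int = 4
    reads_per_sample: int = 5000
    read_length: int = 75
    seq_error_rate: float = 0.002
    frac_no_barcode: float = 0.05
    frac_empty_adapter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise SimulationError("reads_per_sample must be positive")
        for name in ("seq_error_rate", "frac_no_barcode", "frac_empty_adapter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} out of [0,1]: {v}")
        if self.frac_no_barcode + self.frac_empty_adapter > 1.0:
            raise SimulationError("failure-class fractions sum to more than 1")
        if self.read_length < BARCODE_LEN + 20:
            raise SimulationError("read_length too short for barcode + minimum insert")


@dataclass
class SimulatedLibrary:
    """Pooled paired-end library plus its ground truth.

    pairs
        (name, r1_seq, r1_qual, r2_seq, r2_qual) tuples, pooled across
        samples in shuffled order (as a multiplexed sequencing run would be).
    truth
        one row per (condition, replicate, isodecoder):
        true_fraction_charged, reads_emitted (well-formed pairs only) and
        charged_emitted.
    accounting
        one row per sample: pairs_total / pairs_good / pairs_no_barcode /
        pairs_empty_adapter.
    """

    pairs: list[tuple[str, str, str, str, str]]
    truth: pd.DataFrame
    accounting: pd.DataFrame

    def to_fastq_text(self) -> tuple[str, str]:
        r1 = "".join(f"@{n}\n{s1}\n+\n{q1}\n" for n, s1, q1, _, _ in self.pairs)
        r2 = "".join(f"@{n}\n{s2}\n+\n{q2}\n" for n, _, _, s2, q2 in self.pairs)
        return r1, r2

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path) -> None:
        r1, r2 = self.to_fastq_text()
        for path, text in ((r1_path, r1), (r2_path, r2)):
            path = str(path)
            if path.endswith(".gz"):
                with gzip.open(path, "wt") as fh:
                    fh.write(text)
            else:
                with open(path, "w") as fh:
                    fh.write(text)

    def write_truth_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def make_gene_set(
    n_isodecoders: int,
    genes_per_isodecoder: int,
    length_range: tuple[int, int] = (70, 90),
    seed: int = 0,
) -> str:
    """Generate a FASTA text of synthetic tRNA genes with gtRNAdb-style names.

    Gene names follow ``tRNA-<Isotype>-<Anticodon>-<family>-<copy>``.  When
    ``genes_per_isodecoder >= 2`` the first isodecoder's second gene is an
    exact sequence duplicate of its first (named copy 2 of family 1), so
    downstream deduplication is always exercised.
    """
    lo, hi = length_range
    if not (1 <= n_isodecoders <= len(_ISODECODER_POOL)):
        raise SimulationError(
            f"n_isodecoders must be in [1, {len(_ISODECODER_POOL)}]"
        )
    if genes_per_isodecoder < 1:
        raise SimulationError("genes_per_isodecoder must be >= 1")
    if not (60 <= lo <= hi <= 95):
        raise SimulationError(f"length range {length_range} outside tRNA-like [60, 95]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    lines: list[str] = []
    for k in range(n_isodecoders):
        isotype, anticodon = _ISODECODER_POOL[k]
        first_seq = None
        for j in range(genes_per_isodecoder):
            if k == 0 and j == 1:
                # planted duplicate: same sequence, distinct name
                name = f"tRNA-{isotype}-{anticodon}-1-2"
                seq = first_seq
            else:
                family = j + 1
                name = f"tRNA-{isotype}-{anticodon}-{family}-1"
                while True:
                    length = int(rng.integers(lo, hi + 1))
                    seq = "".join(rng.choice(bases, size=length))
                    if seq not in seen:
                        break
                seen.add(seq)
                if j == 0:
                    first_seq = seq
            lines.append(f">{name}\n{seq}\n")
    return "".join(lines)


def _tiled(adapter: str, n: int) -> str:
    reps = -(-n // len(adapter))
    return (adapter * reps)[:n]


def _apply_errors(
    seqs: list[str], rng: np.random.Generator, rate: float, protect_prefix: int
) -> None:
    """In-place substitution errors; first ``protect_prefix`` bases untouched."""
    if rate <= 0 or not seqs:
        return
    length = len(seqs[0]) - protect_prefix
    counts = rng.binomial(length, rate, size=len(seqs))
    bases = "ACGT"
    for i in np.flatnonzero(counts):
        s = list(seqs[i])
        pos = rng.choice(length, size=counts[i], replace=False) + protect_prefix
        for p in pos:
            old = s[p]
            s[p] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4] \
                if old in bases else "N"
        seqs[i] = "".join(s)


def simulate_library(
    reference_fasta: str | Path,
    profiles: Mapping[str, ChargingProfile] | Sequence[ChargingProfile],
    barcode_table: BarcodeTable,
    sim_config: SimConfig,
) -> SimulatedLibrary:
    """Simulate a pooled barcoded paired-end library with known charging truth.

    ``reference_fasta`` is the *gene set* (genomic sequences, no CCA): the
    simulator appends CCA (charged) or CC (uncharged) itself.  ``profiles``
    supplies one :class:`ChargingProfile` per condition named in the barcode
    table.  Output order and content are fully determined by
    ``sim_config.seed``.
    """
    genes = parse_gene_fasta(reference_fasta)
    if isinstance(profiles, Mapping):
        prof_by_cond = dict(profiles)
    else:
        prof_by_cond = {p.condition_name: p for p in profiles}

    by_iso: dict[str, list[TrnaGene]] = {}
    for g in genes:
        by_iso.setdefault(g.isodecoder, []).append(g)

    conditions = {row.condition for row in barcode_table.rows}
    missing = conditions - set(prof_by_cond)
    if missing:
        raise SimulationError(f"no charging profile for condition(s) {sorted(missing)}")
    for cond, prof in prof_by_cond.items():
        unknown = set(prof.per_isodecoder_fraction) - set(by_iso)
        if unknown:
            raise SimulationError(
                f"profile {cond!r} names isodecoders absent from the gene set: "
                f"{sorted(unknown)}"
            )

    cfg = sim_config
    L = cfg.read_length
    qual = "I" * L
    a3_tile = _tiled(ADAPTER3, L + BARCODE_LEN + 120)
    a5_rc_tile = _tiled(revcomp(ADAPTER5), L + 120)

    known_barcodes = {row.barcode for row in barcode_table.rows}
    pairs: list[tuple[str, str, str, str, str]] = []
    truth_rows = []
    acct_rows = []

    for sample_idx, row in enumerate(barcode_table.rows):
        rng = np.random.default_rng([cfg.seed, sample_idx])
        prof = prof_by_cond[row.condition]
        isos = sorted(prof.per_isodecoder_fraction)
        fracs = np.array([prof.per_isodecoder_fraction[i] for i in isos])

        n = cfg.reads_per_sample
        n_nb, n_ea, n_good = rng.multinomial(
            n, [cfg.frac_no_barcode, cfg.frac_empty_adapter,
                1.0 - cfg.frac_no_barcode - cfg.frac_empty_adapter]
        )

        # per-(gene, charged) read templates for this sample's barcode
        bc = row.barcode
        bc_rc = revcomp(bc)

        def templates(gene: TrnaGene, charged: bool,
                      barcode: str = None) -> tuple[str, str]:
            b = bc if barcode is None else barcode
            insert = gene.sequence + ("CCA" if charged else "CC")
            r1 = (insert + b + a3_tile)[:L]
            r2 = (revcomp(b) + revcomp(insert) + a5_rc_tile)[:L]
            return r1, r2

        tmpl_cache: dict[tuple[str, bool], tuple[str, str]] = {}

        iso_idx = rng.integers(0, len(isos), size=n_good)
        charged_draw = rng.random(n_good) < fracs[iso_idx]
        gene_pick = rng.random(n_good)

        r1_list: list[str] = []
        r2_list: list[str] = []
        names: list[str] = []
        emitted = np.zeros(len(isos), dtype=int)
        charged_emitted = np.zeros(len(isos), dtype=int)

        for j in range(n_good):
            k = int(iso_idx[j])
            members = by_iso[isos[k]]
            gene = members[int(gene_pick[j] * len(members))]
            charged = bool(charged_draw[j])
            key = (gene.name, charged)
            tpl = tmpl_cache.get(key)
            if tpl is None:
                tpl = templates(gene, charged)
                tmpl_cache[key] = tpl
            r1_list.append(tpl[0])
            r2_list.append(tpl[1])
            names.append(
                f"sim:{row.sample}:{len(names)}:{gene.name}:"
                f"{'C' if charged else 'U'}"
            )
            emitted[k] += 1
            charged_emitted[k] += int(charged)

        # no-barcode pairs: real molecules carrying a barcode absent from the table
        all_genes = [g for members in by_iso.values() for g in members]
        for j in range(n_nb):
            gene = all_genes[int(rng.integers(0, len(all_genes)))]
            charged = bool(rng.random() < 0.5)
            while True:
                foreign = "".join(
                    "ACGT"[b] for b in rng.integers(0, 4, size=BARCODE_LEN)
                )
                if foreign not in known_barcodes:
                    break
            r1, r2 = templates(gene, charged, barcode=foreign)
            r1_list.append(r1)
            r2_list.append(r2)
            names.append(f"sim:{row.sample}:{len(names)}:{gene.name}:NB")

        # empty-adapter pairs: insert shorter than the 20 nt filter
        for j in range(n_ea):
            gene = all_genes[int(rng.integers(0, len(all_genes)))]
            klen = int(rng.integers(5, 16))
            insert = (gene.sequence + "CCA")[-klen:]
            r1 = (insert + bc + a3_tile)[:L]
            r2 = (bc_rc + revcomp(insert) + a5_rc_tile)[:L]
            r1_list.append(r1)
            r2_list.append(r2)
            names.append(f"sim:{row.sample}:{len(names)}:{gene.name}:EA")

        _apply_errors(r1_list, rng, cfg.seq_error_rate, protect_prefix=0)
        _apply_errors(r2_list, rng, cfg.seq_error_rate, protect_prefix=BARCODE_LEN)

        pairs.extend(
            (names[j], r1_list[j], qual, r2_list[j], qual) for j in range(len(names))
        )
        for k, iso in enumerate(isos):
            truth_rows.append(
                dict(
                    condition=row.condition,
                    replicate=row.replicate,
                    sample=row.sample,
                    isodecoder=iso,
                    true_fraction_charged=fracs[k],
                    reads_emitted=int(emitted[k]),
                    charged_emitted=int(charged_emitted[k]),
                )
            )
        acct_rows.append(
            dict(
                sample=row.sample,
                condition=row.condition,
                replicate=row.replicate,
                pairs_total=int(n),
                pairs_good=int(n_good),
                pairs_no_barcode=int(n_nb),
                pairs_empty_adapter=int(n_ea),
            )
        )

    # pool: shuffle across samples as a multiplexed run would interleave them
    shuffle_rng = np.random.default_rng([cfg.seed, 2**20])
    order = shuffle_rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    return SimulatedLibrary(
        pairs=pairs,
        truth=pd.DataFrame(truth_rows),
        accounting=pd.DataFrame(acct_rows),
    )


@dataclass
class Scenario:
    """A complete simulated experiment: gene set, samples, truth profiles."""

    genes_fasta: str
    barcode_table: BarcodeTable
    profiles: dict[str, ChargingProfile]
    sim_config: SimConfig
    perturbed_isodecoder: str = "His-GTG"


#: default charging levels for the perturbed isodecoder: depressed by GCN2
#: inhibition (condition 2) and restored by amino-acid supplementation
#: (condition 3) — the qualitative treatment pattern of a GCN2i/EAA rescue.
DEFAULT_CONDITIONS = ("vehicle", "GCN2iB", "GCN2iB_EAA")
_PERTURBED_FRACTIONS = {"vehicle": 0.92, "GCN2iB": 0.55, "GCN2iB_EAA": 0.88}


def _make_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """Distinct 5-mers with pairwise Hamming distance >= 2."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join("ACGT"[b] for b in rng.integers(0, 4, size=BARCODE_LEN))
        if all(sum(a != b for a, b in zip(cand, x)) >= 2 for x in out):
            out.append(cand)
    return out


def default_scenario(
    seed: int = 0,
    n_isodecoders: int = 12,
    genes_per_isodecoder: int = 2,
    sim_config: SimConfig | None = None,
) -> Scenario:
    """The packaged study design: 3 conditions × 4 replicates, one perturbed
    isodecoder (His-GTG), baseline charging 0.80–0.95 for all others."""
    rng = np.random.default_rng([seed, 3])
    genes_fasta = make_gene_set(
        n_isodecoders, genes_per_isodecoder, seed=int(rng.integers(2**31))
    )
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    barcodes = _make_barcodes(3 * cfg.n_replicates, rng)
    rows = []
    i = 0
    for cond in DEFAULT_CONDITIONS:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append(SampleRow(f"{cond}_{rep}", barcodes[i], cond, rep))
            i += 1
    table = BarcodeTable(rows)

    isos = [
        f"{iso}-{ac}" for iso, ac in _ISODECODER_POOL[:n_isodecoders]
    ]
    base = {
        iso: float(f)
        for iso, f in zip(isos, rng.uniform(0.80, 0.95, size=len(isos)))
    }
    profiles = {}
    for cond in DEFAULT_CONDITIONS:
        fr = dict(base)
        fr["His-GTG"] = _PERTURBED_FRACTIONS[cond]
        profiles[cond] = ChargingProfile(cond, fr)

    return Scenario(genes_fasta, table, profiles, cfg)
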