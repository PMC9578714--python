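"""Local alignment of read pairs to the CCA-appended tRNA reference and
charging classification from the fragment's 3' end.

Each mate is aligned locally (Smith–Waterman scoring: match +2, mismatch
−6, gap of length k costs 5 + 3k) against every reference entry — the
reference is tiny (tens of entries of ≤ ~100 nt), so exhaustive search is
exact and affordable.  The gene maximizing the summed pair score wins;
score ties within one isodecoder go to the lexicographically smallest
representative (counts aggregate at isodecoder level anyway), ties across
isodecoders are discarded as ambiguous.  A mate is accepted when its score
reaches ``20 + 8·ln(mate length)``, the familiar local-mode short-read
threshold shape.

The charging call reads the observed bases covering the last three aligned
reference positions of the fragment: a ``CCA`` suffix means the tRNA was
aminoacylated (3' end protected from periodate oxidation), ``CC`` means it
was uncharged (terminal A lost to β-elimination), anything else is
undetermined.  An optional end-anchored mode additionally requires the
fragment to reach the reference 3' end.

Implementation notes: exact-substring mates are scored without running the
aligner (an exact hit is the score optimum 2L), and near-exact mates are
aligned only against entries sharing one of three exact read chunks; both
shortcuts are score-exact (any entry containing no chunk is ≥ 10 score
points below a one-error candidate) and fall back to the full scan when the
margin does not hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .reference import ReferenceSet
from .util import revcomp

TERMINAL_WINDOW = 3


class ChargeCall(Enum):
    CHARGED = "charged"
    UNCHARGED = "uncharged"
    UNDETERMINED = "undetermined"


#: non-alignment outcomes of align_pair
UNMAPPED_LOW = "low_score"
UNMAPPED_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -6
    gap_open: int = -8   # first gap base (open −5 + extend −3)
    gap_extend: int = -3
    classification_mode: str = "sequence"  # or "end_anchored"

    def min_score(self, mate_len: int) -> float:
        return 20.0 + 8.0 * math.log(mate_len)


@dataclass
class MateAlignment:
    ref_start: int
    ref_end: int
    score: float
    terminal_obs: str      # read bases over the mate's last 3 aligned ref positions
    terminal_mismatches: int
    read_end_aligned: bool = True  # mate's own 3'-sense terminal base is aligned


@dataclass
class FragmentAlignment:
    """An accepted read-pair alignment to one reference gene."""

    gene: str
    isodecoder: str
    score: float
    r1: MateAlignment | None  # may be None when detail was not requested
    r2: MateAlignment
    terminal_mate: str      # "R1" or "R2": which mate supplied the 3' signal
    terminal_obs: str       # observed bases at the fragment's 3' aligned terminus
    ref_end: int            # 3'-most aligned reference position (half-open)

    @property
    def ref_span(self) -> tuple[int, int]:
        starts = [self.r2.ref_start]
        if self.r1 is not None:
            starts.append(self.r1.ref_start)
        return (min(starts), self.ref_end)


def _terminal_from_blocks(
    ref_blocks, query_blocks, read: str, ref_seq: str, k: int = TERMINAL_WINDOW
) -> tuple[str, int]:
    """Read bases covering the last ``k`` aligned ref positions + mismatch count."""
    obs_parts: list[str] = []
    ref_parts: list[str] = []
    need = k
    for (rs, re_), (qs, qe) in zip(reversed(ref_blocks), reversed(query_blocks)):
        take = min(need, re_ - rs)
        obs_parts.append(read[qe - take:qe])
        ref_parts.append(ref_seq[re_ - take:re_])
        need -= take
        if need == 0:
            break
    obs = "".join(reversed(obs_parts))
    ref = "".join(reversed(ref_parts))
    mm = sum(a != b for a, b in zip(obs, ref))
    return obs, mm


class PairAligner:
    """Aligns trimmed read pairs against a :class:`ReferenceSet`.

    R2 is reverse-complemented internally so both mates are compared on the
    tRNA sense strand (FR orientation, dovetail permitted).
    """

    def __init__(self, reference: ReferenceSet, params: AlignParams | None = None):
        self.reference = reference
        self.params = params or AlignParams()
        self.names: list[str] = list(reference.entries)
        self.seqs: list[str] = [reference.entries[n] for n in self.names]
        self.isos: list[str] = [reference.isodecoder_of[n] for n in self.names]
        p = self.params
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=p.match,
            mismatch_score=p.mismatch,
            open_gap_score=p.gap_open,
            extend_gap_score=p.gap_extend,
        )
        # trimmed template reads recur across pairs and samples; memoize
        self._cache: dict[tuple[str, str], FragmentAlignment | str] = {}
        self._cache_max = 200_000

    # -- scoring ---------------------------------------------------------

    def _sw_score(self, entry_idx: int, mate: str) -> float:
        return self._aligner.score(self.seqs[entry_idx], mate)

    def _candidates(self, mate: str) -> set[int]:
        """Entries sharing at least one of three exact read chunks."""
        L = len(mate)
        t = L // 3
        chunks = (mate[:t], mate[t:2 * t], mate[2 * t:])
        out = set()
        for i, seq in enumerate(self.seqs):
            for c in chunks:
                if c in seq:
                    out.add(i)
                    break
        return out

    def _score_vectors(self, r1: str, r2s: str) -> tuple[list[float], list[float]]:
        """Exact pair score per entry for both mates (r2s already sense-strand)."""
        n = len(self.seqs)
        exact1 = [i for i, s in enumerate(self.seqs) if r1 in s]
        exact2 = [i for i, s in enumerate(self.seqs) if r2s in s]
        cand = self._candidates(r1) | self._candidates(r2s)
        max1, max2 = 2.0 * len(r1), 2.0 * len(r2s)

        def score_set(idx: Iterable[int]) -> tuple[dict, dict]:
            s1 = {i: (max1 if i in set(exact1) else self._sw_score(i, r1)) for i in idx}
            s2 = {i: (max2 if i in set(exact2) else self._sw_score(i, r2s)) for i in idx}
            return s1, s2

        if cand and len(cand) < n:
            s1d, s2d = score_set(cand)
            best = max(s1d[i] + s2d[i] for i in cand)
            # entries sharing no chunk with either mate are at least 10 points
            # below a one-error candidate on each mate
            outside_bound = (max1 - 10.0) + (max2 - 10.0)
            if best > outside_bound:
                neg = float("-inf")
                s1 = [s1d.get(i, neg) for i in range(n)]
                s2 = [s2d.get(i, 0.0) for i in range(n)]
                return s1, s2
        # full exhaustive scan
        s1d, s2d = score_set(range(n))
        return [s1d[i] for i in range(n)], [s2d[i] for i in range(n)]

    # -- per-mate alignment details --------------------------------------

    def _mate_alignment(self, entry_idx: int, mate: str, score: float) -> MateAlignment:
        seq = self.seqs[entry_idx]
        pos = seq.find(mate)
        if pos != -1 and score == 2.0 * len(mate):
            obs = mate[-TERMINAL_WINDOW:]
            return MateAlignment(pos, pos + len(mate), score, obs, 0)
        aln = self._aligner.align(seq, mate)[0]
        ref_blocks, query_blocks = aln.aligned
        obs, mm = _terminal_from_blocks(ref_blocks, query_blocks, mate, seq)
        return MateAlignment(
            int(ref_blocks[0][0]), int(ref_blocks[-1][1]), score, obs, mm,
            read_end_aligned=int(query_blocks[-1][1]) == len(mate),
        )

    # -- public API ------------------------------------------------------

    def align_pair(
        self, r1: str, r2: str, detail: bool = True
    ) -> FragmentAlignment | str:
        """Align one trimmed pair; returns a :class:`FragmentAlignment` or one
        of :data:`UNMAPPED_LOW` / :data:`UNMAPPED_AMBIGUOUS`.

        With ``detail=False`` the non-terminal mate's alignment detail may be
        skipped (``FragmentAlignment.r1``/``r2`` = None) when it cannot affect
        the charging call; results are then memoized.
        """
        if not detail:
            hit = self._cache.get((r1, r2))
            if hit is not None:
                return hit
        res = self._align_pair_uncached(r1, r2, detail)
        if not detail and len(self._cache) < self._cache_max:
            self._cache[(r1, r2)] = res
        return res

    def _align_pair_uncached(
        self, r1: str, r2: str, detail: bool
    ) -> FragmentAlignment | str:
        r2s = revcomp(r2)
        max1, max2 = 2.0 * len(r1), 2.0 * len(r2s)

        # fast path: both mates exact substrings of a common entry — that
        # entry attains the score optimum; only other double-exact entries tie
        exact1 = {i for i, s in enumerate(self.seqs) if r1 in s}
        exact2 = {i for i, s in enumerate(self.seqs) if r2s in s}
        both = exact1 & exact2
        if both:
            tied = sorted(both)
            s1 = {i: max1 for i in tied}
            s2 = {i: max2 for i in tied}
            best = max1 + max2
        else:
            v1, v2 = self._score_vectors(r1, r2s)
            totals = [a + b for a, b in zip(v1, v2)]
            best = max(totals)
            tied = [i for i, t in enumerate(totals) if t == best]
            s1 = {i: v1[i] for i in tied}
            s2 = {i: v2[i] for i in tied}
        thr1 = self.params.min_score(len(r1))
        thr2 = self.params.min_score(len(r2))
        tied = [i for i in tied if s1[i] >= thr1 and s2[i] >= thr2]
        if not tied:
            return UNMAPPED_LOW
        if len(tied) > 1:
            tied_isos = {self.isos[i] for i in tied}
            if len(tied_isos) > 1:
                return UNMAPPED_AMBIGUOUS
            tied.sort(key=lambda i: self.names[i])
        gi = tied[0]

        m2 = self._mate_alignment(gi, r2s, s2[gi])
        m1 = None
        # R2's sense-strand 3' terminus is the adapter ligation point, so R2
        # carries the charging signal whenever that base is part of its
        # alignment; otherwise (terminal error clipped) R1 may reach further
        # and supply it (ties: fewer terminal mismatches, then R2)
        if detail or not m2.read_end_aligned:
            m1 = self._mate_alignment(gi, r1, s1[gi])
        if (not m2.read_end_aligned) and m1 is not None and (
            m1.ref_end > m2.ref_end
            or (m1.ref_end == m2.ref_end
                and m1.terminal_mismatches < m2.terminal_mismatches)
        ):
            term, obs, ref_end = "R1", m1.terminal_obs, m1.ref_end
        else:
            term, obs, ref_end = "R2", m2.terminal_obs, m2.ref_end
        return FragmentAlignment(
            gene=self.names[gi],
            isodecoder=self.isos[gi],
            score=best,
            r1=m1,
            r2=m2,
            terminal_mate=term,
            terminal_obs=obs,
            ref_end=ref_end,
        )


def classify_charge(
    alignment: FragmentAlignment,
    reference: ReferenceSet,
    mode: str = "sequence",
) -> ChargeCall:
    """Call charging status from the fragment's 3' aligned terminus.

    ``sequence`` mode applies the suffix rule alone: observed terminal bases
    ending ``CCA`` → charged, ending ``CC`` → uncharged, else undetermined.
    ``end_anchored`` additionally requires the fragment to reach the
    reference 3' end (position L for CCA, L−1 for CC), guarding against
    internal fragments that merely happen to end in CC.
    """
    obs = alignment.terminal_obs.upper()
    if mode not in ("sequence", "end_anchored"):
        raise ValueError(f"unknown classification mode {mode!r}")
    ref_len = len(reference.entries[alignment.gene])
    if obs.endswith("CCA"):
        if mode == "end_anchored" and alignment.ref_end != ref_len:
            return ChargeCall.UNDETERMINED
        return ChargeCall.CHARGED
    if obs.endswith("CC"):
        if mode == "end_anchored" and alignment.ref_end != ref_len - 1:
            return ChargeCall.UNDETERMINED
        return ChargeCall.UNCHARGED
    return ChargeCall.UNDETERMINED


@dataclass
class SampleTabulation:
    """Per-gene charged/uncharged/undetermined counts for one sample."""

    counts: dict[str, list[int]]          # gene -> [charged, uncharged, undet]
    mapped: int
    unmapped_low: int = 0
    unmapped_ambiguous: int = 0

    @property
    def classified(self) -> int:
        return sum(c[0] + c[1] for c in self.counts.values())

    @property
    def classified_fraction(self) -> float:
        return self.classified / self.mapped if self.mapped else float("nan")


def tabulate(calls: Iterable[tuple[str, ChargeCall]]) -> SampleTabulation:
    """Count charging calls by gene; ``mapped = charged+uncharged+undetermined``."""
    counts: dict[str, list[int]] = {}
    mapped = 0
    for gene, call in calls:
        row = counts.setdefault(gene, [0, 0, 0])
        idx = {ChargeCall.CHARGED: 0, ChargeCall.UNCHARGED: 1,
               ChargeCall.UNDETERMINED: 2}[call]
        row[idx] += 1
        mapped += 1
    return SampleTabulation(counts=counts, mapped=mapped)


def quantify_sample(
    pairs: Sequence[tuple[str, str, str, str, str]],
    aligner: PairAligner,
    mode: str = "sequence",
) -> SampleTabulation:
    """Align + classify every trimmed pair of one sample."""
    calls = []
    low = ambiguous = 0
    for _, s1, _, s2, _ in pairs:
        res = aligner.align_pair(s1, s2, detail=False)
        if res == UNMAPPED_LOW:
            low += 1
        elif res == UNMAPPED_AMBIGUOUS:
            ambiguous += 1
        else:
            calls.append((res.gene, classify_charge(res, aligner.reference, mode)))
    tab = tabulate(calls)
    tab.unmapped_low = low
    tab.unmapped_ambiguous = ambiguous
    return tab


def counts_frame(tabs: dict[str, SampleTabulation]) -> pd.DataFrame:
    """Long-format ChargeCountTable: sample, gene, n_charged, n_uncharged,
    n_undetermined."""
    rows = []
    for sample, tab in tabs.items():
        for gene, (c, u, d) in sorted(tab.counts.items()):
            rows.append(
                dict(sample=sample, gene=gene, n_charged=c,
                     n_uncharged=u, n_undetermined=d)
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "n_charged",
                                       "n_uncharged", "n_undetermined"])


def classify_sam(
    sam_path: str,
    reference: ReferenceSet,
    mode: str = "sequence",
) -> SampleTabulation:
    """Classify charging from pre-computed paired alignments in SAM.

    Primary alignments only; both mates must map to the same reference
    entry (aliases are resolved to representatives).  The terminal mate is
    the one whose alignment reaches the 3'-most reference position.
    """
    import pysam

    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        refseqs = dict(reference.entries)
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            by_name.setdefault(rec.query_name, []).append(rec)

    calls = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            continue
        g0 = reference.aliases.get(recs[0].reference_name, recs[0].reference_name)
        g1 = reference.aliases.get(recs[1].reference_name, recs[1].reference_name)
        if g0 != g1 or g0 not in refseqs:
            continue
        term = max(recs, key=lambda r: r.reference_end)
        seq = refseqs[g0]
        pairs_al = [
            (q, r) for q, r in term.get_aligned_pairs(matches_only=True)
        ]
        tail = pairs_al[-TERMINAL_WINDOW:]
        qseq = term.query_sequence
        obs = "".join(qseq[q] for q, _ in tail)
        ref_end = term.reference_end
        frag = FragmentAlignment(
            gene=g0,
            isodecoder=reference.isodecoder_of[g0],
            score=float("nan"),
            r1=MateAlignment(recs[0].reference_start, recs[0].reference_end,
                             float("nan"), "", 0),
            r2=MateAlignment(recs[1].reference_start, recs[1].reference_end,
                             float("nan"), "", 0),
            terminal_mate="R2" if term.is_read2 else "R1",
            terminal_obs=obs,
            ref_end=ref_end,
        )
        calls.append((g0, classify_charge(frag, reference, mode)))
    return tabulate(calls)
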