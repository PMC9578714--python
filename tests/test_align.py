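import numpy as np
import pytest

from sw_oracle import best_pair_gene, sw_scores
from trnacharge.align import (
    ChargeCall,
    FragmentAlignment,
    MateAlignment,
    PairAligner,
    UNMAPPED_AMBIGUOUS,
    UNMAPPED_LOW,
    classify_charge,
    classify_sam,
    counts_frame,
    tabulate,
)
from trnacharge.util import revcomp


def _frag(obs, gene="tRNA-His-GTG-1-1", ref_end=None, ref_len=None):
    return FragmentAlignment(
        gene=gene, isodecoder="His-GTG", score=0.0, r1=None,
        r2=MateAlignment(0, 1, 0.0, obs, 0),
        terminal_mate="R2", terminal_obs=obs,
        ref_end=ref_end if ref_end is not None else 1,
    )


class TestClassifyCharge:
    @pytest.mark.parametrize(
        "obs,call",
        [
            ("CCA", ChargeCall.CHARGED),
            ("ACC", ChargeCall.UNCHARGED),
            ("ACA", ChargeCall.UNDETERMINED),
            ("CCG", ChargeCall.UNDETERMINED),
        ],
    )
    def test_suffix_rule(self, obs, call, tiny_reference):
        frag = _frag(obs)
        assert classify_charge(frag, tiny_reference) is call

    def test_end_anchored_requires_reaching_reference_end(self, tiny_reference):
        ref_len = len(tiny_reference.entries["tRNA-His-GTG-1-1"])
        at_end = _frag("CCA", ref_end=ref_len)
        internal = _frag("CCA", ref_end=ref_len - 7)
        assert classify_charge(at_end, tiny_reference, "end_anchored") is ChargeCall.CHARGED
        assert classify_charge(internal, tiny_reference, "end_anchored") is ChargeCall.UNDETERMINED
        cc_at_end = _frag("CC", ref_end=ref_len - 1)
        assert classify_charge(cc_at_end, tiny_reference, "end_anchored") is ChargeCall.UNCHARGED


class TestAlignPair:
    @pytest.fixture(scope="class")
    def aligner(self, tiny_reference):
        return PairAligner(tiny_reference)

    def _reads_from(self, seq):
        """Error-free pair covering the 5' and 3' halves of an entry."""
        r1 = seq[:50]
        r2 = revcomp(seq[-50:])
        return r1, r2

    def test_error_free_pair_maps_full_length(self, aligner, tiny_reference):
        seq = tiny_reference.entries["tRNA-Leu-CAA-1-1"]
        r1, r2 = self._reads_from(seq)
        res = aligner.align_pair(r1, r2)
        assert res.gene == "tRNA-Leu-CAA-1-1"
        assert res.r1.ref_start == 0 and res.r1.ref_end == 50
        assert res.r2.ref_end == len(seq)
        assert res.score == 2.0 * 100
        assert res.terminal_mate == "R2"

    def test_alias_reads_map_to_representative(self, aligner, tiny_reference):
        # tRNA-His-GTG-1-2 was deduplicated into 1-1
        seq = tiny_reference.entries["tRNA-His-GTG-1-1"]
        res = aligner.align_pair(*self._reads_from(seq))
        assert res.gene == "tRNA-His-GTG-1-1"

    def test_random_non_trna_pair_unmapped(self, aligner, tiny_reference):
        rng = np.random.default_rng(123)
        r1 = "".join(np.random.default_rng(1).choice(list("ACGT"), 60))
        r2 = "".join(rng.choice(list("ACGT"), 60))
        res = aligner.align_pair(r1, r2)
        assert res == UNMAPPED_LOW
        # oracle confirms the best score is below the acceptance threshold
        seqs = list(tiny_reference.entries.values())
        thr = aligner.params.min_score(60)
        assert min(sw_scores(r1, seqs).max(), sw_scores(revcomp(r2), seqs).max()) < thr

    def test_near_identical_genes_resolved_by_best_score(self, aligner, tiny_reference):
        # His-GTG-2-1 differs from 1-1 by its terminal genomic base
        seq = tiny_reference.entries["tRNA-His-GTG-2-1"]
        res = aligner.align_pair(*self._reads_from(seq))
        assert res.gene == "tRNA-His-GTG-2-1"

    def test_cross_isodecoder_tie_is_ambiguous(self, tiny_reference):
        # identical 30-mer planted in two isodecoders forces a score tie
        from trnacharge.reference import TrnaGene, build_reference

        core = "ACGTTGCAACGGTTAACCGGTTAACCGGTA"
        g1 = TrnaGene("tRNA-Ala-AGC-1-1", "Ala", "AGC", "G" * 20 + core + "T" * 20)
        g2 = TrnaGene("tRNA-Leu-CAA-1-1", "Leu", "CAA", "C" * 20 + core + "A" * 20)
        ref = build_reference([g1, g2])
        al = PairAligner(ref)
        res = al.align_pair(core, revcomp(core))
        assert res == UNMAPPED_AMBIGUOUS

    def test_score_matches_brute_force_oracle_with_errors(self, aligner, tiny_reference):
        seq = tiny_reference.entries["tRNA-Ala-AGC-1-1"]
        r1, r2 = self._reads_from(seq)
        r1 = r1[:20] + ("A" if r1[20] != "A" else "C") + r1[21:]  # one substitution
        res = aligner.align_pair(r1, r2)
        names = list(tiny_reference.entries)
        seqs = [tiny_reference.entries[n] for n in names]
        isos = [tiny_reference.isodecoder_of[n] for n in names]
        best, tied, cross = best_pair_gene(r1, revcomp(r2), names, seqs, isos)
        assert res.score == best
        assert res.gene in tied


class TestTabulate:
    def test_direct_counts(self):
        calls = [("g1", ChargeCall.CHARGED)] * 3 + [("g1", ChargeCall.UNCHARGED)]
        tab = tabulate(calls)
        assert tab.counts["g1"] == [3, 1, 0]
        assert tab.classified_fraction == 1.0

    def test_empty_call_list(self):
        tab = tabulate([])
        assert tab.counts == {} and tab.mapped == 0

    def test_classified_fraction_excludes_undetermined(self):
        calls = (
            [("g1", ChargeCall.CHARGED)] * 5
            + [("g1", ChargeCall.UNCHARGED)] * 3
            + [("g1", ChargeCall.UNDETERMINED)] * 2
        )
        tab = tabulate(calls)
        assert tab.mapped == 10
        assert tab.classified_fraction == pytest.approx(0.8)

    def test_counts_frame_layout(self):
        tab = tabulate([("g1", ChargeCall.CHARGED)])
        df = counts_frame({"s1": tab})
        assert list(df.columns) == [
            "sample", "gene", "n_charged", "n_uncharged", "n_undetermined"
        ]
        assert df.iloc[0].tolist() == ["s1", "g1", 1, 0, 0]


def test_classify_sam_pre_aligned_pairs(tmp_path, tiny_reference):
    """Charging calls from externally aligned SAM match the suffix rule."""
    gene = "tRNA-Leu-CAA-1-1"
    seq = tiny_reference.entries[gene]
    L = len(seq)
    r1 = seq[:50]
    r2_charged = seq[-50:]          # ends ...CCA at position L
    r2_uncharged = seq[-51:-1]      # ends ...CC at position L-1
    sam = [
        "@HD\tVN:1.6",
        f"@SQ\tSN:{gene}\tLN:{L}",
    ]
    for name, r2, pos2 in [
        ("frag1", r2_charged, L - 50), ("frag2", r2_uncharged, L - 51)
    ]:
        sam.append(f"{name}\t99\t{gene}\t1\t60\t50M\t=\t{pos2 + 1}\t{L}\t{r1}\t{'I' * 50}")
        sam.append(
            f"{name}\t147\t{gene}\t{pos2 + 1}\t60\t50M\t=\t1\t-{L}\t{r2}\t{'I' * 50}"
        )
    path = tmp_path / "sample.sam"
    path.write_text("\n".join(sam) + "\n")
    tab = classify_sam(str(path), tiny_reference)
    assert tab.counts[gene] == [1, 1, 0]
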