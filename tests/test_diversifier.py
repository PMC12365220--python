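import dataclasses
import math

import numpy as np
import pytest

from abcdiv.codon_core import ProteinSequence, allowed_codons, back_translate, translate
from abcdiv.diversifier import (
    DiversificationTask,
    InfeasibleMotifError,
    MotifSet,
    _RepeatSurrogate,
    diversify,
    diversify_chain,
    motif_scan,
)
from abcdiv.energy import objective_f
from abcdiv.fixtures import make_random_protein
from abcdiv.homology import longest_common_substring


class TestMotifScan:
    def test_palindrome_reported_once_per_strand(self):
        motifs = MotifSet({"EcoRI": "GAATTC"})
        hits = motif_scan("AAGAATTCAA", motifs)
        assert hits == [("EcoRI", 2, "+"), ("EcoRI", 2, "-")]

    def test_reverse_complement_only_occurrence(self):
        # AscI site GGCGCGCC present only as reverse complement of GGCGCGCC...
        motifs = MotifSet({"probe": "AACCGGTA"})  # revcomp TACCGGTT
        hits = motif_scan("GGTACCGGTTGG", motifs)
        assert hits == [("probe", 2, "-")]

    def test_absent_motif(self):
        assert motif_scan("ACGTACGT", MotifSet({"EcoRI": "GAATTC"})) == []

    def test_forward_only_mode(self):
        motifs = MotifSet({"probe": "AACCGGTA"}, scan_both_strands=False)
        assert motif_scan("GGTACCGGTTGG", motifs) == []


def _task(protein, usage, bias=0.1, **kw):
    kw.setdefault("allowed", allowed_codons(usage, bias))
    kw.setdefault("forbidden", MotifSet.empty())
    return DiversificationTask(target=protein, **kw)


class TestDiversify:
    def test_single_methionine_forced_codon(self, usage):
        res = diversify(_task(ProteinSequence("M"), usage))
        assert res.output.seq == "ATG"
        assert res.fscore_vs_reference.log10_f == -math.inf

    def test_determinism_same_seed_byte_identical(self, usage, greedy_map, motifs):
        prot = make_random_protein(80, seed=4)
        ref = back_translate(prot, greedy_map).seq
        task = _task(prot, usage, reference_context=ref, forbidden=motifs, seed=99)
        assert diversify(task).output.seq == diversify(task).output.seq

    def test_different_seeds_explore_differently(self, usage, greedy_map):
        prot = make_random_protein(80, seed=4)
        ref = back_translate(prot, greedy_map).seq
        a = diversify(_task(prot, usage, reference_context=ref, seed=1))
        b = diversify(_task(prot, usage, reference_context=ref, seed=2))
        assert a.output.seq != b.output.seq

    def test_result_contract(self, usage, greedy_map, motifs):
        prot = make_random_protein(100, seed=6, composition="fp")
        ref = back_translate(prot, greedy_map).seq
        amap = allowed_codons(usage, 0.15)
        res = diversify(
            DiversificationTask(
                target=prot, reference_context=ref, allowed=amap,
                forbidden=motifs, seed=3,
            )
        )
        assert translate(res.output).seq == prot.seq
        for codon in res.output.codons:
            assert codon in amap[translate_codon(codon)]
        assert motif_scan(res.output.seq, motifs) == []
        pad = motifs.max_len - 1
        junction = ref[-pad:] + res.output.seq[:pad]
        for name, pos, _ in motif_scan(junction, motifs):
            if pos < pad < pos + len(motifs.motifs[name]):
                pytest.fail(f"motif {name} spans the junction at {pos}")
        assert res.max_identical_bp == longest_common_substring(res.output.seq, ref).length
        assert sum(res.codon_counts.values()) == len(prot)

    def test_improvement_over_abundance_greedy_baseline(self, usage, greedy_map):
        prot = make_random_protein(120, seed=8, composition="fp")
        ref = back_translate(prot, greedy_map).seq
        res = diversify(_task(prot, usage, bias=0.1, reference_context=ref, seed=2))
        baseline = objective_f(back_translate(prot, allowed_codons(usage, 0.1)).seq, ref)
        assert res.fscore_vs_reference.log10_f <= baseline.log10_f
        if math.isfinite(baseline.log10_f):
            assert res.fscore_vs_reference.log10_f < baseline.log10_f

    def test_stop_codon_copied_verbatim(self, usage):
        from abcdiv.codon_core import CodingSequence

        cds = CodingSequence("ATGGCTGAGTAA")
        res = diversify(_task(cds, usage))
        assert res.output.seq.endswith("TAA")
        assert translate(res.output).has_stop

    def test_unavoidable_motif_raises_with_name(self, usage):
        # every encoding of Met starts with ATG
        task = _task(ProteinSequence("MM"), usage, forbidden=MotifSet({"start": "ATGATG"}))
        with pytest.raises(InfeasibleMotifError, match="start"):
            diversify(task)

    def test_empty_protein_rejected(self, usage):
        with pytest.raises(ValueError):
            ProteinSequence("")


def translate_codon(codon):
    from abcdiv.codon_core import GENETIC_CODE

    return GENETIC_CODE[codon]


class TestChain:
    def test_chain_of_two_equals_manual_sequential_runs(self, usage, greedy_map):
        prot = make_random_protein(60, seed=10)
        ref = back_translate(prot, greedy_map).seq
        t1 = _task(prot, usage, seed=21)
        t2 = _task(prot, usage, seed=22)
        chained = diversify_chain([t1, t2], ref)

        first = diversify(dataclasses.replace(t1, reference_context=ref))
        second = diversify(
            dataclasses.replace(t2, reference_context=ref + first.output.seq)
        )
        assert chained.results[0].output.seq == first.output.seq
        assert chained.results[1].output.seq == second.output.seq

    def test_matrix_is_symmetric_with_zero_diagonal(self, usage, greedy_map):
        prot = make_random_protein(60, seed=10)
        ref = back_translate(prot, greedy_map).seq
        chained = diversify_chain(
            [_task(prot, usage, seed=31), _task(prot, usage, seed=32)], ref
        )
        m = chained.max_identical_matrix
        assert all(m[i][i] == 0 for i in range(len(m)))
        assert all(m[i][j] == m[j][i] for i in range(len(m)) for j in range(len(m)))

    def test_error_propagates_from_offending_stage(self, usage):
        tasks = [
            _task(ProteinSequence("MAGAGA"), usage, seed=1),
            _task(ProteinSequence("MM"), usage, seed=2,
                  forbidden=MotifSet({"start": "ATGATG"})),
        ]
        with pytest.raises(InfeasibleMotifError):
            diversify_chain(tasks, "")

    def test_fewer_than_two_targets_rejected(self, usage):
        with pytest.raises(ValueError):
            diversify_chain([_task(ProteinSequence("MA"), usage)], "")


class TestSurrogate:
    def test_incremental_equals_recompute(self):
        """Append/pop/replace bookkeeping matches a from-scratch rebuild."""
        rng = np.random.default_rng(17)
        ctx = "".join("ACGT"[i] for i in rng.integers(4, size=50))
        s = _RepeatSurrogate(ctx)
        for ch in "".join("ACGT"[i] for i in rng.integers(4, size=45)):
            s.append(ch)
        for _ in range(30):
            pos = int(rng.integers(50, len(s.chars) - 3))
            s.replace(pos, "".join("ACGT"[i] for i in rng.integers(4, size=3)))
        s.pop(6)
        assert s.score == pytest.approx(
            _RepeatSurrogate.recompute_score("".join(s.chars)), rel=1e-12
        )
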