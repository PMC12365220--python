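import io

import numpy as np
import pytest

from abcdiv.chimera import (
    AnchorPair,
    ChimeraSimConfig,
    DiscriminatingSites,
    ReadGroup,
    call_group,
    extract_inserts,
    group_inserts,
    recombination_profile,
    simulate_reads,
    write_fastq,
)
from abcdiv.codon_core import reverse_complement
from abcdiv.fixtures import HomologPairSpec, make_homolog_pair

A5 = "ACGGATTACCTAGGCAT"
A3 = "GTCCATGGTTAGACGTC"
ANCHORS = AnchorPair(A5, A3, max_mismatch=0)


class TestExtract:
    def test_exact_sandwich(self):
        res = extract_inserts([A5 + "ACGT" + A3], ANCHORS)
        assert res.inserts == ["ACGT"]
        assert (res.n_kept, res.n_reads) == (1, 1)

    def test_missing_anchor_dropped_and_counted(self):
        res = extract_inserts([A5 + "ACGT"], ANCHORS)
        assert res.inserts == []
        assert res.dropped["missing_anchor"] == 1

    def test_mismatch_tolerance(self):
        mutated = "T" + A5[1:]
        read = mutated + "ACGT" + A3
        assert extract_inserts([read], AnchorPair(A5, A3, 1)).inserts == ["ACGT"]
        assert extract_inserts([read], ANCHORS).inserts == []

    def test_reverse_complement_read_normalized(self):
        read = reverse_complement(A5 + "ACGT" + A3)
        assert extract_inserts([read], ANCHORS).inserts == ["ACGT"]

    def test_conservation_kept_plus_dropped(self):
        reads = [A5 + "AC" + A3, "GGGG", A5 + "T" + A3, A5]
        res = extract_inserts(reads, ANCHORS)
        assert res.n_kept + sum(res.dropped.values()) == res.n_reads == 4


class TestGroup:
    def test_counts_and_ordering(self):
        groups = group_inserts(["AA", "AA", "AT"])
        assert [(g.insert, g.count) for g in groups] == [("AA", 2), ("AT", 1)]

    def test_empty(self):
        assert group_inserts([]) == []

    def test_conservation_over_simulated_pool(self):
        rng = np.random.default_rng(0)
        inserts = ["".join("ACGT"[i] for i in rng.integers(4, size=8)) for _ in range(5000)]
        groups = group_inserts(inserts)
        assert sum(g.count for g in groups) == 5000


class TestCall:
    sites = DiscriminatingSites(donor="AAAA", acceptor="TTTT")

    def test_mixed_call(self):
        call = call_group(ReadGroup("AATT", 1), self.sites)
        assert call.letters == ("C", "C", "Y", "Y")

    def test_all_donor(self):
        assert call_group(ReadGroup("AAAA", 3), self.sites).letters == ("C",) * 4

    def test_sequencing_error_discards_group(self):
        call = call_group(ReadGroup("AAGA", 1), self.sites)
        assert call.discarded and call.discard_reason == "error"

    def test_length_mismatch_discards(self):
        call = call_group(ReadGroup("AAAAA", 1), self.sites)
        assert call.discarded and call.discard_reason == "length"

    def test_only_differing_positions_are_sites(self):
        sites = DiscriminatingSites(donor="ACGT", acceptor="AGGT")
        assert sites.positions == (1,)


class TestProfile:
    def test_hand_computed_weighted_average(self):
        sites = DiscriminatingSites(donor="AAAA", acceptor="TTTT")
        groups = [ReadGroup("AAAA", 3), ReadGroup("AATT", 1)]
        prof = recombination_profile(groups, sites)
        assert prof.frac_acceptor == pytest.approx((0.0, 0.0, 0.25, 0.25))
        assert prof.chimeric_fraction == 1.0  # all inserts are FP-length here

    def test_all_donor_pool_is_flat_zero(self):
        sites = DiscriminatingSites(donor="ACGTACGT", acceptor="TGCATGCA")
        prof = recombination_profile([ReadGroup("ACGTACGT", 50)], sites)
        assert prof.frac_acceptor == (0.0,) * 8
        assert prof.slope == pytest.approx(0.0, abs=1e-12)

    def test_no_valid_groups_rejected(self):
        sites = DiscriminatingSites(donor="AAAA", acceptor="TTTT")
        with pytest.raises(ValueError):
            recombination_profile([ReadGroup("AAGA", 1)], sites)


def _sim_config(usage, rho, n_reads, error_rate=0.0, seed=0, identity=0.95):
    donor, acceptor = make_homolog_pair(
        HomologPairSpec(length_aa=120, identity=identity, seed=7), usage
    )
    return ChimeraSimConfig(
        donor=donor.seq,
        acceptor=acceptor.seq,
        linker="GGTGGAAGCGGTGGA",
        anchors=AnchorPair(A5, A3, 1),
        n_reads=n_reads,
        rho=rho,
        error_rate=error_rate,
        seed=seed,
    )


class TestSimulator:
    def test_rho_zero_yields_only_full_constructs(self, usage):
        config = _sim_config(usage, rho=0.0, n_reads=50)
        full = len(config.full_construct)
        ext = extract_inserts(
            [r.sequence for r in simulate_reads(config)], config.anchors
        )
        assert all(len(ins) == full for ins in ext.inserts)

    def test_same_seed_identical_fastq_bytes(self, usage):
        config = _sim_config(usage, rho=0.5, n_reads=40, error_rate=0.01, seed=9)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_fastq(simulate_reads(config), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_empirical_chimeric_fraction_matches_rho(self, usage):
        config = _sim_config(usage, rho=0.75, n_reads=3000, seed=2)
        reads = simulate_reads(config)
        frac = sum(r.is_chimera for r in reads) / len(reads)
        assert frac == pytest.approx(0.75, abs=0.03)

    def test_truth_table_consistent_with_sequences(self, usage):
        config = _sim_config(usage, rho=0.6, n_reads=100, seed=3)
        n = len(config.donor)
        for r in simulate_reads(config):
            ext = extract_inserts([r.sequence], config.anchors)
            assert len(ext.inserts) == 1
            expected = (
                config.donor[: r.breakpoint] + config.acceptor[r.breakpoint :]
                if r.is_chimera
                else config.full_construct
            )
            assert ext.inserts[0] == expected


class TestEndToEnd:
    def test_uniform_breakpoints_give_linear_profile(self, usage):
        config = _sim_config(usage, rho=1.0, n_reads=2000, seed=4)
        ext = extract_inserts(
            [r.sequence for r in simulate_reads(config)], config.anchors
        )
        groups = group_inserts(ext.inserts)
        sites = DiscriminatingSites(config.donor, config.acceptor)
        prof = recombination_profile(groups, sites)
        assert prof.r2 >= 0.99
        assert prof.slope == pytest.approx(1.0 / len(config.donor), rel=0.15)

    def test_error_floor_from_pure_donor_control(self, usage):
        donor, acceptor = make_homolog_pair(
            HomologPairSpec(length_aa=120, identity=0.95, seed=7), usage
        )
        error_rate = 0.005
        rng = np.random.default_rng(6)
        from abcdiv.chimera import _mutate

        inserts = [_mutate(donor.seq, error_rate, rng) for _ in range(3000)]
        sites = DiscriminatingSites(donor.seq, acceptor.seq)
        control = recombination_profile(group_inserts(inserts), sites)
        assert max(control.frac_acceptor) <= 3 * error_rate
        # floor subtraction zeroes a clean pool
        clean = recombination_profile(
            group_inserts([donor.seq] * 100), sites, control_profile=control
        )
        assert all(f == 0.0 for f in clean.frac_acceptor_floored)
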