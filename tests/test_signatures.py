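import itertools
import re

import numpy as np
import pytest
from Bio.Seq import Seq

from clonediv import signatures
from clonediv.io import GermlineReference
from conftest import make_profile

# ---------------------------------------------------------------------------
# independent oracles


def regex_motif_oracle(sequence, position):
    """Degenerate-regex scanner, independent of the production classifier."""
    checks = [
        ("hotspot_WRC", re.compile("[AT][AG]C"), 2),   # position = the C
        ("hotspot_GYW", re.compile("G[CT][AT]"), 0),   # position = the G
        ("coldspot_SYC", re.compile("[GC][CT]C"), 2),
        ("coldspot_GRS", re.compile("G[AG][GC]"), 0),
    ]
    for label, rx, offset in checks:
        start = position - offset
        if start >= 0 and rx.fullmatch(sequence[start:start + 3]):
            return label
    return "other"


def codon_rs_oracle(codon, index, alt):
    mutated = codon[:index] + alt + codon[index + 1:]
    return ("silent" if Seq(codon).translate() == Seq(mutated).translate()
            else "replacement")


def mutation(pos, germ, obs):
    return signatures.MutationCall(position=pos, germline_base=germ,
                                   observed_base=obs)


# ---------------------------------------------------------------------------


class TestCallMutations:
    def test_identical_sequences_no_calls(self):
        assert signatures.call_mutations("ACGT", "ACGT") == []

    def test_three_substitutions_located(self):
        calls = signatures.call_mutations("TCGAACGA", "ACGAACGT")
        assert [(c.position, c.observed_base) for c in calls] == [(0, "T"), (7, "A")]

    def test_n_columns_skipped(self):
        calls = signatures.call_mutations("NCGT", "ACGT")
        assert calls == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            signatures.call_mutations("ACG", "ACGT")


class TestClassifyMotif:
    @pytest.mark.parametrize("germline,pos,expected", [
        ("TACGT", 2, "hotspot_WRC"),   # T(A)C: W=T, R=A, center C
        ("GCTAA", 0, "hotspot_GYW"),   # G C T: Y=C, W=T
        ("GCCAA", 2, "coldspot_SYC"),  # G C C: S=G, Y=C
        ("GAGAA", 0, "coldspot_GRS"),  # G A G: R=A, S=G
        ("AAAAA", 2, "other"),
        ("ACGTA", 0, "other"),         # context off the left edge
    ])
    def test_fixed_cases(self, germline, pos, expected):
        assert signatures.classify_motif(germline, pos) == expected

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            signatures.classify_motif("ACGT", 7)

    def test_agrees_with_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            for pos in range(300):
                assert signatures.classify_motif(seq, pos) == \
                    regex_motif_oracle(seq, pos), (seq[pos - 2:pos + 3], pos)

    def test_reverse_complement_duality(self):
        rng = np.random.default_rng(7)
        complement = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            rc = seq.translate(complement)[::-1]
            for pos in range(60):
                mirrored = len(seq) - 1 - pos
                fwd = signatures.classify_motif(seq, pos)
                rev = signatures.classify_motif(rc, mirrored)
                pairs = {"hotspot_WRC": "hotspot_GYW",
                         "hotspot_GYW": "hotspot_WRC",
                         "coldspot_SYC": "coldspot_GRS",
                         "coldspot_GRS": "coldspot_SYC",
                         "other": "other"}
                assert rev == pairs[fwd]

    def test_hotspot_coldspot_overlap_unreachable(self):
        # W and S are disjoint, as are R and Y: no context can satisfy both
        for a, b, c in itertools.product("ACGT", repeat=3):
            ctx = a + b + c
            wrc = c == "C" and a in "AT" and b in "AG"
            syc = c == "C" and a in "GC" and b in "CT"
            gyw = a == "G" and b in "CT" and c in "AT"
            grs = a == "G" and b in "AG" and c in "GC"
            assert not (wrc and syc)
            assert not (gyw and grs)


class TestClassifyRs:
    def test_silent_leucine(self):
        ref = GermlineReference("G", "CTGAAA", {"FR1": (0, 6)}, 0)
        call = mutation(2, "G", "A")  # CTG -> CTA, Leu -> Leu
        assert signatures.classify_rs(call, ref) == "silent"

    def test_replacement_met_to_thr(self):
        ref = GermlineReference("G", "ATGAAA", {"FR1": (0, 6)}, 0)
        call = mutation(1, "T", "C")  # ATG -> ACG, Met -> Thr
        assert signatures.classify_rs(call, ref) == "replacement"

    def test_stop_codon_counts_as_replacement(self):
        ref = GermlineReference("G", "TACAAA", {"FR1": (0, 6)}, 0)
        call = mutation(2, "C", "A")  # TAC (Tyr) -> TAA (stop)
        assert signatures.classify_rs(call, ref) == "replacement"

    def test_incomplete_codon_unclassifiable(self):
        ref = GermlineReference("G", "AATGAA", {"FR1": (0, 6)}, 1)
        assert signatures.classify_rs(mutation(0, "A", "C"), ref) is None
        assert signatures.classify_rs(mutation(5, "A", "C"), ref) is None

    def test_exhaustive_codon_oracle(self):
        """All 64 codons x 9 single-nt mutations against Biopython translation."""
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            ref = GermlineReference("G", codon + "AAA", {"FR1": (0, 6)}, 0)
            for index in range(3):
                for alt in "ACGT":
                    if alt == codon[index]:
                        continue
                    got = signatures.classify_rs(mutation(index, codon[index], alt),
                                                 ref)
                    assert got == codon_rs_oracle(codon, index, alt), \
                        (codon, index, alt)


class TestClassifySharing:
    def test_mutation_in_every_subclone_is_shared(self):
        profile = make_profile({"ACGT": 500, "ACGA": 300, "TCGA": 200})
        calls = [signatures.call_mutations(s.sequence, "GCGG")
                 for s in profile.subclones]
        signatures.classify_sharing(profile, calls)
        by_key = {}
        for cl in calls:
            for c in cl:
                by_key.setdefault((c.position, c.observed_base), set()).add(c.sharing)
        assert by_key[(0, "A")] == {"partially_shared"}  # in 2 of 3
        assert by_key[(3, "A")] == {"partially_shared"}
        assert by_key[(0, "T")] == {"unique"}
        assert by_key[(3, "T")] == {"unique"}

    def test_shared_across_all(self):
        profile = make_profile({"ACGT": 500, "ACGA": 300})
        calls = [signatures.call_mutations(s.sequence, "TCGT")
                 for s in profile.subclones]
        signatures.classify_sharing(profile, calls)
        assert all(c.sharing == "shared" for c in calls[0] if c.position == 0)
        assert all(c.sharing == "shared" for c in calls[1] if c.position == 0)

    def test_single_subclone_all_shared(self):
        profile = make_profile({"ACGT": 500})
        calls = [signatures.call_mutations("ACGT", "TCGT")]
        signatures.classify_sharing(profile, calls)
        assert calls[0][0].sharing == "shared"

    def test_sharing_partitions_all_calls(self):
        profile = make_profile({"ACGT": 5, "ACGA": 3, "TCGA": 2, "TCGG": 1})
        calls = [signatures.call_mutations(s.sequence, "GAGC")
                 for s in profile.subclones]
        signatures.classify_sharing(profile, calls)
        flat = [c for cl in calls for c in cl]
        assert all(c.sharing in ("shared", "partially_shared", "unique")
                   for c in flat)
        n_shared = sum(c.sharing == "shared" for c in flat)
        n_non = sum(c.sharing != "shared" for c in flat)
        assert n_shared + n_non == len(flat)


class TestMutabilityRates:
    def test_zero_opportunity_class_is_undefined(self):
        # all-A germline: no C or G anywhere, so no WRC/GYW/SYC/GRS contexts
        ref = GermlineReference("G", "A" * 12, {"FR1": (0, 12)}, 0)
        profile = make_profile({"A" * 12: 100})
        summary = signatures.mutability_rates(profile, ref)
        assert summary.rates["hotspot_WRC"].rate is None
        assert summary.rates["hotspot_WRC"].observed == 0

    def test_rates_bounded_and_counts_conserved(self, germline):
        seq = list(germline.sequence)
        for pos in (20, 60, 120, 200):
            seq[pos] = "A" if seq[pos] != "A" else "T"
        profile = make_profile({germline.sequence: 800, "".join(seq): 200})
        summary = signatures.mutability_rates(profile, germline)
        for cr in summary.rates.values():
            if cr.rate is not None:
                assert 0 <= cr.rate <= 1
        assert sum(cr.observed for cr in summary.rates.values()) == 4

    def test_non_shared_scope_on_single_subclone_is_zero(self, germline):
        seq = list(germline.sequence)
        seq[30] = "A" if seq[30] != "A" else "T"
        profile = make_profile({"".join(seq): 1000})
        summary = signatures.mutability_rates(profile, germline, scope="non_shared")
        assert all(cr.observed == 0 for cr in summary.rates.values())

    def test_hotspot_bias_raises_hotspot_rate(self, germline):
        from clonediv.simulate import SimulationConfig, simulate_repertoire
        from clonediv.clones import enumerate_subclones

        def mean_rates(bias, seed):
            sim = SimulationConfig(explicit_freqs=[0.7, 0.2, 0.1],
                                   aid_hotspot_bias=bias,
                                   random_error_rate=0.0, systematic_errors=[])
            reads, _ = simulate_repertoire(sim, seed=seed)
            profile = enumerate_subclones(reads)
            summary = signatures.mutability_rates(profile, germline)
            hot = np.mean([summary.rates["hotspot_WRC"].rate or 0,
                           summary.rates["hotspot_GYW"].rate or 0])
            cold = np.mean([summary.rates["coldspot_SYC"].rate or 0,
                            summary.rates["coldspot_GRS"].rate or 0])
            return hot, cold

        hot_biased = [mean_rates(8.0, s) for s in range(6)]
        hot_flat = [mean_rates(1.0, s) for s in range(6)]
        assert np.mean([h for h, _ in hot_biased]) > \
            np.mean([h for h, _ in hot_flat])

    def test_region_densities_weighted_by_frequency(self, germline):
        seq = list(germline.sequence)
        # plant one replacement in FR3 (frame 0: first codon base change)
        pos = 180
        seq[pos] = "A" if seq[pos] != "A" else "C"
        mutant = "".join(seq)
        profile = make_profile({germline.sequence: 900, mutant: 100})
        summary = signatures.mutability_rates(profile, germline, weighting="freq")
        start, end = germline.regions["FR3"]
        total = summary.region_r_density["FR3"] + summary.region_s_density["FR3"]
        assert total == pytest.approx(0.1 / (end - start))
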