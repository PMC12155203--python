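import numpy as np
import pytest

from tdrprofiler import classify as C
from tdrprofiler import tdr_metrics as M
from tdrprofiler.reference import MatureTRNA


def _trna(length=75, anticodon_start=34, iso="Gly-GCC"):
    anticodon = iso.split("-")[1]
    seq = list("A" * (length - 3) + "CCA")
    seq[anticodon_start - 1 : anticodon_start + 2] = list(anticodon)
    return MatureTRNA("t-test", iso, "".join(seq), anticodon_start, anticodon_start + 2)


def _assignment(read_id, label, record_id, start, length, first_nt="A", weight=1.0, gene=None):
    targets = (
        (C.AssignedTarget(record_id, start, "+", 0, weight, gene_id=gene),)
        if record_id
        else ()
    )
    return C.ReadAssignment(read_id, label, targets, length, first_nt)


class TestAssignHalf:
    def test_read_entirely_left_of_anticodon(self):
        assert M.assign_half(_trna(), 1, 20) == "five_prime"

    def test_read_near_terminus(self):
        assert M.assign_half(_trna(length=75), 50, 21) == "three_prime"

    def test_canonical_five_prime_half_spanning_anticodon(self):
        # a 36 nt 5' half ends inside the anticodon yet sits mostly left of it
        assert M.assign_half(_trna(), 1, 36) == "five_prime"

    def test_exact_tie_goes_five_prime(self):
        # split at 35: positions 30..40 put 5 on each side
        assert M.assign_half(_trna(), 30, 11) == "five_prime"

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError, match="outside"):
            M.assign_half(_trna(length=75), 60, 30)


class TestHalfFractions:
    def test_three_to_one_split(self, refset):
        t = refset.trnas[0]
        asn = [
            _assignment(f"r{i}", "tRNA", t.trna_id, 1, 20) for i in range(3)
        ] + [_assignment("r3", "tRNA", t.trna_id, t.length - 19, 20)]
        hf = M.half_fractions(asn, refset)
        assert hf.five_prime_pct == pytest.approx(75.0)
        assert hf.three_prime_pct == pytest.approx(25.0)
        assert hf.five_prime_pct + hf.three_prime_pct == pytest.approx(100.0)

    def test_all_three_prime_library(self, refset):
        t = next(t for t in refset.trnas if t.isoacceptor == "Ser-AGA")
        asn = [_assignment(f"r{i}", "tRNA", t.trna_id, t.length - 21, 22) for i in range(5)]
        hf = M.half_fractions(asn, refset)
        assert (hf.five_prime_pct, hf.three_prime_pct) == (0.0, 100.0)

    def test_no_trna_reads_reports_nan_with_zero_n(self, refset):
        hf = M.half_fractions([], refset)
        assert hf.n_reads == 0 and np.isnan(hf.five_prime_pct)


class TestLengthFirstNtMatrix:
    def test_single_entries(self, refset):
        asn = [
            _assignment("a", "miRNA", "mir-1", 1, 22, first_nt="G"),
            _assignment("b", "tRNA", refset.trnas[0].trna_id, 1, 36, first_nt="G"),
        ]
        mat = M.length_firstnt_matrix(asn, scope="all")
        assert mat.at[22, "G"] == 1 and mat.at[36, "G"] == 1
        assert mat.to_numpy().sum() == 2

    def test_empty_scope_all_zero(self):
        mat = M.length_firstnt_matrix([], scope="tRNA")
        assert (mat.to_numpy() == 0).all()

    def test_marginal_matches_length_histogram(self, small_sperm_assignments):
        mat = M.length_firstnt_matrix(small_sperm_assignments, scope="tRNA")
        lengths = np.zeros(41)
        for a in small_sperm_assignments:
            if a.class_label == "tRNA":
                lengths[a.read_length] += 1
        assert np.allclose(mat.sum(axis=1).to_numpy(), lengths[18:41])

    def test_half_mode_at_36_dominates_long_lengths(self, refset, index0):
        """A library whose fragment model centres halves near 36 nt shows the
        accumulation in the tRNA-scope length histogram."""
        from tdrprofiler.simulate import CompositionProfile, FragmentModel, simulate_small_rna_reads

        prof = CompositionProfile(
            name="halfy",
            class_fractions={"tDR": 1.0},
            fragment_model=FragmentModel(
                five_prime_fraction=0.6, half_length_mean=36.0, half_length_sd=0.7, long_mode_weight=0.9
            ),
            read_count=5000,
            seed=13,
        )
        lib = simulate_small_rna_reads(prof, refset)
        reads = [C.Read(r.read_id, r.sequence) for r in lib.reads]
        asn = C.classify_reads(reads, index0, refset)
        mat = M.length_firstnt_matrix(asn, scope="tRNA")
        assert mat.sum(axis=1).idxmax() == 36


class TestCoverage:
    def test_single_read_block(self, refset):
        t = refset.trnas[0]
        asn = [_assignment("r", "tRNA", t.trna_id, 1, 30)]
        prof = M.coverage_profile(asn, refset, t.isoacceptor)
        assert (prof.depth[:30] == 1).all() and (prof.depth[30:] == 0).all()

    def test_depth_conservation(self, small_sperm_assignments, refset, index0):
        total_depth = sum(
            M.coverage_profile(small_sperm_assignments, refset, iso, index=index0).total
            for iso in refset.isoacceptors()
        )
        expected = sum(
            t.weight * a.read_length
            for a in small_sperm_assignments
            if a.class_label == "tRNA"
            for t in a.targets
        )
        assert total_depth == pytest.approx(expected)

    def test_five_prime_dominated_gly_gcc_skews_left_of_anticodon(self, refset, index0):
        from tdrprofiler.simulate import CompositionProfile, FragmentModel, simulate_small_rna_reads

        prof = CompositionProfile(
            name="fiveprime",
            class_fractions={"tDR": 1.0},
            fragment_model=FragmentModel(
                five_prime_fraction=0.95,
                long_mode_weight=0.6,
                isoacceptor_weights={"Gly-GCC": 1.0},
            ),
            read_count=5000,
            seed=23,
        )
        lib = simulate_small_rna_reads(prof, refset)
        reads = [C.Read(r.read_id, r.sequence) for r in lib.reads]
        asn = C.classify_reads(reads, index0, refset)
        cov = M.coverage_profile(asn, refset, "Gly-GCC", index=index0)
        members = [t for t in refset.trnas if t.isoacceptor == "Gly-GCC"]
        split = members[0].anticodon_start + 1
        left = cov.depth[: split - 1].mean()
        right = cov.depth[split:].mean()
        assert left > 5 * right

    def test_unknown_isoacceptor_errors(self, refset):
        with pytest.raises(KeyError):
            M.coverage_profile([], refset, "Xxx-NNN")


class TestSizeSplit:
    def test_long_short_buckets(self, refset):
        t = refset.trnas[0]
        asn = [
            _assignment("a", "tRNA", t.trna_id, 1, 36),
            _assignment("b", "tRNA", t.trna_id, 1, 22),
        ]
        df = M.size_split(asn, refset).set_index("isodecoder")
        assert df.at[t.trna_id, "long_count"] == 1
        assert df.at[t.trna_id, "short_count"] == 1

    def test_exactly_30_nt_is_short(self, refset):
        t = refset.trnas[0]
        df = M.size_split([_assignment("a", "tRNA", t.trna_id, 1, 30)], refset)
        assert df["short_count"].sum() == 1 and df["long_count"].sum() == 0

    def test_conservation_and_rpm_denominator(self, small_sperm_assignments, refset):
        df = M.size_split(small_sperm_assignments, refset, grouping="isoacceptor")
        total = sum(
            t.weight
            for a in small_sperm_assignments
            if a.class_label == "tRNA"
            for t in a.targets
        )
        assert (df["long_count"] + df["short_count"]).sum() == pytest.approx(total)
        assert (df["long_rpm"] + df["short_rpm"]).sum() == pytest.approx(1e6)

    def test_long_mode_enrichment_between_profiles(self, refset, index0):
        """A deletion-mutant-like library (long halves dominant) shows a
        higher long:short Gly-GCC rpm ratio than a het-like library."""
        from tdrprofiler.profiles import composition_profile
        from tdrprofiler.simulate import simulate_small_rna_reads

        ratios = {}
        for name in ("rnst2_del_male", "rnst2_het_male"):
            prof = composition_profile(name, read_count=20_000, seed=17)
            lib = simulate_small_rna_reads(prof, refset)
            reads = [C.Read(r.read_id, r.sequence) for r in lib.reads]
            asn = C.classify_reads(reads, index0, refset)
            df = M.size_split(asn, refset, grouping="isoacceptor").set_index("isoacceptor")
            ratios[name] = df.at["Gly-GCC", "long_rpm"] / max(df.at["Gly-GCC", "short_rpm"], 1e-9)
        assert ratios["rnst2_del_male"] > ratios["rnst2_het_male"]

    def test_empty_errors(self, refset):
        with pytest.raises(ValueError, match="zero"):
            M.size_split([], refset)
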