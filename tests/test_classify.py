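import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import hamming_hits, random_seq
from tdrprofiler import classify as C
from tdrprofiler.reference import CLASS_ORDER, reverse_complement
from tdrprofiler.simulate import DEFAULT_ADAPTER, simulate_small_rna_reads
from tdrprofiler.profiles import composition_profile

dna = st.text(alphabet="ACGT", min_size=0, max_size=45)


def oracle_trim(seq, adapter, min_prefix=6):
    """Leftmost cut position i where seq[i:] starts with >= min_prefix adapter bases."""
    for i in range(len(seq)):
        k = min(len(adapter), len(seq) - i)
        if k >= min_prefix and seq[i : i + k] == adapter[:k]:
            return seq[:i]
    return seq


class TestTrimAndFilter:
    def test_full_adapter_after_insert_is_removed(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        reads = [C.Read("r1", insert + DEFAULT_ADAPTER)]
        out = C.trim_and_filter(reads, DEFAULT_ADAPTER)
        assert [r.sequence for r in out] == [insert]

    def test_short_insert_discarded(self):
        reads = [C.Read("r1", "ACGTACGTACGTACG" + DEFAULT_ADAPTER)]  # 15 nt insert
        assert C.trim_and_filter(reads, DEFAULT_ADAPTER) == []

    def test_untrimmed_read_kept_if_in_window(self):
        out = C.trim_and_filter([C.Read("r1", "ACGTG" * 5)], DEFAULT_ADAPTER)
        assert [r.sequence for r in out] == ["ACGTG" * 5]

    @settings(max_examples=100, derandomize=True)
    @given(insert=dna, junk=dna)
    def test_trim_equals_leftmost_prefix_oracle(self, insert, junk):
        read = insert + DEFAULT_ADAPTER + junk
        assert C.trim_adapter(read, DEFAULT_ADAPTER) == oracle_trim(read, DEFAULT_ADAPTER)

    @settings(max_examples=100, derandomize=True)
    @given(read=dna)
    def test_trim_of_arbitrary_sequence_equals_oracle(self, read):
        if not read:
            return
        assert C.trim_adapter(read, DEFAULT_ADAPTER) == oracle_trim(read, DEFAULT_ADAPTER)


def oracle_assign(seq, refset, max_mm=0):
    """Exhaustive re-statement of the priority rule for the oracle comparison."""
    for label in CLASS_ORDER:
        hits = []
        for rid, rseq in refset.classes[label].records:
            hits += [(rid, s, mm) for s, mm in hamming_hits(seq, rseq, max_mm)]
        if hits:
            return label
    genome_hits = []
    for name, cseq in refset.genome.contigs.items():
        for s, mm in hamming_hits(seq, cseq, max_mm):
            genome_hits.append((name, s, "+", mm))
        for s, mm in hamming_hits(seq, reverse_complement(cseq), max_mm):
            genome_hits.append((name, len(cseq) - s - len(seq) + 2, "-", mm))
    if not genome_hits:
        return "unassigned"
    best = min(mm for *_, mm in genome_hits)
    cats = set()
    for name, s, strand, mm in genome_hits:
        if mm != best:
            continue
        for g in refset.genes:
            if g.contig == name and g.start <= s + len(seq) - 1 and s <= g.end:
                cats.add("endo_siRNA" if g.strand != strand else "mRNA_frag")
    if "endo_siRNA" in cats:
        return "endo_siRNA"
    if "mRNA_frag" in cats:
        return "mRNA_frag"
    return "other_genomic"


class TestAssignClass:
    def test_priority_rrna_beats_trna(self, refset, index0):
        # collapse the tRNA class onto a tRNA whose 5' 20-mer also sits in an rRNA
        import dataclasses

        from tdrprofiler.index import SequenceIndex
        from tdrprofiler.reference import ClassAnnotation

        t = refset.trnas[0]
        shared = t.sequence[:20]
        classes = dict(refset.classes)
        classes["rRNA"] = ClassAnnotation(
            "rRNA", [("rrn-x", "ACGTC" * 4 + shared + "GACTG" * 4)]
        )
        rs = dataclasses.replace(refset, classes=classes)
        idx = SequenceIndex(rs, 0)
        a = C.assign_class(C.Read("r", shared), idx, rs)
        assert a.class_label == "rRNA"

    def test_no_hit_is_unassigned_with_empty_targets(self, refset, index0):
        a = C.assign_class(C.Read("r", "A" * 30), index0, refset)
        assert a.class_label == "unassigned" and a.targets == ()

    def test_multimapping_weights_sum_to_one(self, refset, index0):
        # Gly-GCC has two isodecoders; a read spanning the shared anticodon
        # context can hit both records
        t1, t2 = [t for t in refset.trnas if t.isoacceptor == "Gly-GCC"]
        probe = t1.sequence[25:45]
        hits = index0.query_class("tRNA", probe)
        a = C.assign_class(C.Read("r", probe), index0, refset)
        assert a.class_label == "tRNA"
        assert sum(t.weight for t in a.targets) == pytest.approx(1.0)
        assert len(a.targets) == len(hits)

    def test_assignments_match_bruteforce_oracle_on_synthetic_reads(self, refset, index0):
        profile = composition_profile("wt_male", read_count=300, seed=33)
        lib = simulate_small_rna_reads(profile, refset)
        reads = [C.Read(r.read_id, r.sequence) for r in lib.reads]
        assignments = C.classify_reads(reads, index0, refset)
        for read, a in zip(reads, assignments):
            assert a.class_label == oracle_assign(read.sequence, refset)

    def test_truth_label_recovery(self, small_sperm_library, small_sperm_assignments):
        truth_to_class = {
            "rRNA_frag": "rRNA",
            "tDR": "tRNA",
            "miRNA": "miRNA",
            "piRNA": "piRNA",
            "endo_siRNA": "endo_siRNA",
            "mRNA_frag": "mRNA_frag",
            "unassigned": "unassigned",
        }
        mismatches = sum(
            a.class_label != truth_to_class[r.true_class]
            for r, a in zip(small_sperm_library.reads, small_sperm_assignments)
        )
        assert mismatches == 0  # toy references are collision-free

    def test_read_order_permutation_does_not_change_assignments(self, refset, index0):
        profile = composition_profile("wt_sperm", read_count=200, seed=8)
        lib = simulate_small_rna_reads(profile, refset)
        reads = [C.Read(r.read_id, r.sequence) for r in lib.reads]
        fwd = {a.read_id: a for a in C.classify_reads(reads, index0, refset)}
        rev = {a.read_id: a for a in C.classify_reads(reads[::-1], index0, refset)}
        assert fwd == rev


class TestCountsAndNormalization:
    def test_uniform_mirna_counts(self, refset, index0):
        mid, mseq = refset.classes["miRNA"].records[0]
        reads = [C.Read(f"r{i}", mseq) for i in range(10)]
        counts = C.count_classes(C.classify_reads(reads, index0, refset))
        assert counts.counts["miRNA"] == pytest.approx(10)
        assert counts.total_genome_mapping == pytest.approx(10)

    def test_weight_conservation_across_classes(self, small_sperm_assignments):
        counts = C.count_classes(small_sperm_assignments)
        total = sum(counts.counts[label] for label in C.GENOME_MAPPING_LABELS)
        assert total == pytest.approx(counts.total_genome_mapping)
        assert counts.total_genome_mapping <= counts.total_input

    def test_rpm_definitions(self):
        counts = C.ClassCounts(
            counts={"tRNA": 100.0, "rRNA": 600_000.0}, total_genome_mapping=1_000_000.0, total_input=1_000_000.0
        )
        assert C.normalize(counts, "genome").values["tRNA"] == pytest.approx(100.0)
        nm = C.normalize(counts, "genome_minus_rRNA")
        assert nm.values["tRNA"] == pytest.approx(250.0)
        assert nm.denominator == pytest.approx(400_000.0)

    def test_zero_denominator_errors(self):
        counts = C.ClassCounts(counts={"tRNA": 0.0}, total_genome_mapping=0.0, total_input=5.0)
        with pytest.raises(ValueError, match="zero"):
            C.normalize(counts, "genome")

    def test_rrna_exclusion_never_shrinks_rpm(self, small_sperm_assignments):
        """Removing rRNA reads from the denominator can only inflate the rpm
        of every other class -- the dynamic-range argument for the
        genome-minus-rRNA normalization."""
        counts = C.count_classes(small_sperm_assignments)
        rpm_g = C.normalize(counts, "genome").values
        rpm_x = C.normalize(counts, "genome_minus_rRNA").values
        for label in C.GENOME_MAPPING_LABELS:
            if label != "rRNA":
                assert rpm_x[label] >= rpm_g[label]
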