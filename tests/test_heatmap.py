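"""Heatmap stage: primer orientation, identity matrix, cluster attribution."""

import numpy as np
import pandas as pd
import pytest

from operonscope import heatmap, synth
from operonscope._align import revcomp
from operonscope.primers import DEFAULT_PRIMERS, PrimerSet, scan_primer
from operonscope.synth import ReadRecord

from conftest import cohort_metadata, truth_frame


def _cohort_fixture(panel, seed, n_reads=8, profile=0.0, wt_sed=None, bias=(1.0, 1.0)):
    designs = synth.default_cohort(panel, n_reads=n_reads, group_sizes=(1, 1, 1, 1),
                                   wt_sed_species=wt_sed)
    em = synth.ErrorModel(strand_bias=bias, strand_profile=profile, seed=seed)
    reads = synth.simulate_reads(panel, designs, em)
    return designs, reads


class TestPrimerScan:
    def test_exact_primer_found_at_planted_position(self):
        primer = "AGAGTTTGATCATGGCTCAG"  # 27F with M resolved to A
        read = "T" * 50 + primer + "T" * 100
        hit = scan_primer(DEFAULT_PRIMERS["27F"], read, 0.85)
        assert hit is not None and hit[0] == 50 and hit[1] == 1.0

    @pytest.mark.parametrize("n_mm,expected", [(3, True), (4, False)])
    def test_85_percent_threshold_on_20mer(self, n_mm, expected):
        """3 mismatches in a 20-mer (85%) is a hit; 4 (80%) is not."""
        primer = "AGAGTTTGATCATGGCTCAG"
        mutated = list(primer)
        for i in range(n_mm):
            pos = 2 + 5 * i
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        read = "T" * 30 + "".join(mutated) + "T" * 30
        hit = scan_primer(primer, read, 0.85)
        assert (hit is not None) is expected

    def test_iupac_codes_match_their_base_sets(self):
        assert scan_primer("ARY", "TTAGC", 1.0) is not None  # A G C matches A R Y
        assert scan_primer("ARY", "TTACA", 1.0) is None  # Y cannot match A

    def test_primer_set_validation(self):
        with pytest.raises(ValueError):
            PrimerSet(min_identity=0.4)
        with pytest.raises(ValueError):
            PrimerSet(primers={"short": "ACGTACGT"})


class TestOrientation:
    def test_forward_read_annotated_fwd(self, two_species_panel):
        tmpl = two_species_panel.template("sp01", 1)
        read = ReadRecord("r", "s1", tmpl.sequence)
        oriented, ann = heatmap.annotate_and_orient(read)
        assert ann.inferred_direction == "fwd"
        assert oriented.sequence == tmpl.sequence
        assert len(ann.hits) >= 6

    def test_reverse_read_is_flipped_to_match_forward(self, two_species_panel):
        tmpl = two_species_panel.template("sp01", 1)
        fwd, _ = heatmap.annotate_and_orient(ReadRecord("f", "s1", tmpl.sequence))
        rev, ann = heatmap.annotate_and_orient(ReadRecord("r", "s1", revcomp(tmpl.sequence)))
        assert ann.inferred_direction == "rev"
        assert rev.sequence == fwd.sequence

    def test_orientation_idempotent(self, two_species_panel):
        tmpl = two_species_panel.template("sp02", 1)
        once, _ = heatmap.annotate_and_orient(ReadRecord("r", "s1", revcomp(tmpl.sequence)))
        twice, ann = heatmap.annotate_and_orient(once)
        assert ann.inferred_direction == "fwd"
        assert twice.sequence == once.sequence

    def test_primerless_read_discarded(self, rng):
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        oriented, anns = heatmap.orient_reads([ReadRecord("r", "s1", junk)])
        assert oriented == []
        assert anns[0].inferred_direction == "none"

    def test_noisy_reads_orient_correctly(self, single_species_reads):
        _, reads = single_species_reads
        oriented, _ = heatmap.orient_reads(reads[:20])
        assert len(oriented) >= 18
        assert all(r.direction == r.truth[2] for r in oriented)


class TestTopReads:
    def _records(self, n, sample="s1"):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "read_id": [f"{sample}_r{i:03d}" for i in range(n)],
            "ref_id": "taxA",
            "score": 100,
            "identity": rng.uniform(0.8, 1.0, n),
            "aln_length": rng.integers(1100, 1500, n),
            "strand": "+",
            "sample_id": sample,
        })

    def test_top_n_have_best_rank_scores(self):
        records = self._records(40)
        reads = [ReadRecord(r, "s1", "ACGT") for r in records["read_id"]]
        top = heatmap.select_top_reads(records, reads, "taxA", 15)
        assert len(top) == 15
        scores = records.set_index("read_id")
        chosen = {r.read_id for r in top}
        worst_kept = min(scores.loc[r, "identity"] * scores.loc[r, "aln_length"]
                         for r in chosen)
        best_left = max((scores.loc[r, "identity"] * scores.loc[r, "aln_length"]
                         for r in scores.index if r not in chosen), default=0)
        assert worst_kept >= best_left

    def test_short_sample_keeps_everything(self):
        records = self._records(7)
        reads = [ReadRecord(r, "s1", "ACGT") for r in records["read_id"]]
        assert len(heatmap.select_top_reads(records, reads, "taxA", 15)) == 7

    def test_absent_taxon_warns_empty(self):
        records = self._records(5)
        assert heatmap.select_top_reads(records, [], "nope", 15) == []

    def test_selected_reads_beat_overall_mean_identity(self, recovery_reads,
                                                       multicopy_panel):
        from operonscope import bbh
        _, reads = recovery_reads
        df = bbh.assign_reads(bbh.size_filter(reads)[:100], multicopy_panel.ref_16s())
        taxon = df["ref_id"].value_counts().idxmax()
        top = heatmap.select_top_reads(df, reads, taxon, 5)
        chosen = {r.read_id for r in top}
        sub = df[df["ref_id"] == taxon]
        assert sub[sub["read_id"].isin(chosen)]["identity"].mean() >= \
            sub["identity"].mean()


class TestIdentityMatrix:
    def test_duplicate_read_distance_zero(self, single_species_reads):
        _, reads = single_species_reads
        a = reads[0]
        dup = ReadRecord("dup", "s1", a.sequence)
        d = heatmap.pairwise_identity_matrix([a, dup, reads[1]])
        assert d["dup", a.read_id] == 0.0

    def test_error_free_reads_reflect_reference_divergence(self, two_species_panel):
        reads = [ReadRecord(f"r{i}", "s1", two_species_panel.template(s, 1).sequence)
                 for i, s in enumerate(["sp01", "sp01", "sp02"])]
        d = heatmap.pairwise_identity_matrix(reads)
        assert d["r0", "r1"] == 0.0
        # whole-operon divergence is close to the programmed 6%
        assert 0.04 < d["r0", "r2"] < 0.08

    def test_wildly_different_lengths_flagged(self, two_species_panel, caplog):
        t = two_species_panel.template("sp01", 1).sequence
        reads = [ReadRecord("a", "s1", t), ReadRecord("b", "s1", t),
                 ReadRecord("c", "s1", t[:1500])]
        d = heatmap.pairwise_identity_matrix(reads)
        assert d["a", "c"] > d["a", "b"]

    def test_needs_three_reads(self, two_species_panel):
        t = two_species_panel.template("sp01", 1).sequence
        with pytest.raises(ValueError):
            heatmap.pairwise_identity_matrix([ReadRecord("a", "s1", t)] * 2)


class TestClustering:
    def test_identical_reads_form_single_cluster(self, two_species_panel):
        t = two_species_panel.template("sp01", 1).sequence
        reads = [ReadRecord(f"r{i}", "s1", t) for i in range(5)]
        res = heatmap.seriate_and_cluster(heatmap.pairwise_identity_matrix(reads))
        assert len(res.clusters) == 1

    def test_blocks_partition_the_ordering(self, two_species_panel):
        _, reads = _cohort_fixture(two_species_panel, seed=2, n_reads=5)
        oriented, _ = heatmap.orient_reads(reads)
        res = heatmap.seriate_and_cluster(heatmap.pairwise_identity_matrix(oriented))
        flat = [rid for block in res.clusters for rid in block]
        assert flat == res.ordering

    def test_direction_split_appears_only_with_strand_profile(self):
        """One species, no strand asymmetry: a single cluster.  With a
        systematic reverse-strand error profile: exactly two clusters
        split 100% by read direction (all sample groups in each) — and
        the split is monotone in the profile size."""
        panel = synth.make_reference_panel(1, copies_per_species=1, seed=1)
        for profile, expected in ((0.0, 1), (0.05, 2)):
            designs, reads = _cohort_fixture(panel, seed=2, profile=profile)
            oriented, _ = heatmap.orient_reads(reads)
            res = heatmap.seriate_and_cluster(heatmap.pairwise_identity_matrix(oriented))
            assert len(res.clusters) == expected
            report = heatmap.source_composition(
                res, oriented, cohort_metadata(designs), truth_frame(reads))
            if profile > 0:
                for entry in report:
                    assert max(entry["direction_fractions"].values()) == 1.0
                    assert len(entry["group_fractions"]) == 4
                dirs = {next(iter(e["direction_fractions"])) for e in report}
                assert dirs == {"fwd", "rev"}

    def test_group_exclusive_sister_species_cluster(self, two_species_panel):
        """A 94%-identity sister species present only in WT sedentary
        produces exactly one group-exclusive cluster, pure by truth."""
        flagged_total = 0
        for seed in (1, 2):
            designs, reads = _cohort_fixture(two_species_panel, seed=seed,
                                             wt_sed="sp02")
            oriented, _ = heatmap.orient_reads(reads)
            res = heatmap.seriate_and_cluster(heatmap.pairwise_identity_matrix(oriented))
            report = heatmap.source_composition(
                res, oriented, cohort_metadata(designs), truth_frame(reads))
            flagged = [e for e in report
                       if e["exclusive_group"] == "WT_sedentary" and e["n_reads"] >= 3]
            assert len(flagged) == 1
            assert all(e["purity"] >= 0.9 for e in report if e["n_reads"] >= 3)
            flagged_total += 1
        assert flagged_total == 2

    def test_composition_fractions_sum_to_one(self, two_species_panel):
        designs, reads = _cohort_fixture(two_species_panel, seed=3, n_reads=6)
        oriented, _ = heatmap.orient_reads(reads)
        res = heatmap.seriate_and_cluster(heatmap.pairwise_identity_matrix(oriented))
        report = heatmap.source_composition(res, oriented,
                                            cohort_metadata(designs), truth_frame(reads))
        for e in report:
            assert sum(e["group_fractions"].values()) == pytest.approx(1.0)
            assert sum(e["direction_fractions"].values()) == pytest.approx(1.0)

    def test_manual_cut_threshold_respected(self, two_species_panel):
        _, reads = _cohort_fixture(two_species_panel, seed=4, n_reads=5)
        oriented, _ = heatmap.orient_reads(reads)
        d = heatmap.pairwise_identity_matrix(oriented)
        res = heatmap.seriate_and_cluster(d, cut=1.1)
        assert len(res.clusters) == 1
        res2 = heatmap.seriate_and_cluster(d, cut=1e-6)
        assert len(res2.clusters) == len(oriented)
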