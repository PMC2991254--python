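import numpy as np
import pytest

from imss import evolution as ev
from imss.motifs import MotifOccurrence
from imss.records import ProteinRecord
from imss.simulate import SyntheticConfig, generate_family, generate_ortholog_set


# ---------------------------------------------------------------------------
# pairwise alignment


def test_identical_sequences_align_without_gaps():
    a = ProteinRecord("A", "MQDKLIMN")
    aln = ev.align_pair(a, ProteinRecord("B", "MQDKLIMN"))
    assert aln.identity == 1.0
    assert "-" not in aln.aligned_a + aln.aligned_b


def test_single_gap_alignment():
    aln = ev.align_pair(ProteinRecord("A", "MQDA"), ProteinRecord("B", "MDA"))
    assert (aln.aligned_a, aln.aligned_b) == ("MQDA", "M-DA")
    assert aln.identity == 1.0  # identity over gap-free columns


def test_alignment_symmetric_identity():
    a = ProteinRecord("A", "MQDKLIWN")
    b = ProteinRecord("B", "MQEKLYWN")
    assert ev.align_pair(a, b).identity == ev.align_pair(b, a).identity


def test_ungapping_recovers_inputs():
    a = ProteinRecord("A", "MQDKLIWNAC")
    b = ProteinRecord("B", "MQKLIWNC")
    aln = ev.align_pair(a, b)
    assert aln.ungapped("a") == a.sequence
    assert aln.ungapped("b") == b.sequence


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        ev.PairwiseAlignment("A", "B", "MQ", "MQD")


# ---------------------------------------------------------------------------
# bidirectional best hits


@pytest.fixture(scope="module")
def ortholog_world():
    records, data, truth = generate_family(SyntheticConfig(seed=5, n_proteins=8))
    by_species, alignments = generate_ortholog_set(
        records, truth, motif_rate=0.02, background_rate=0.1, n_species=2, seed=9
    )
    return records, truth, by_species, alignments


def test_bbh_recovers_true_ortholog_map(ortholog_world):
    records, _, by_species, _ = ortholog_world
    family = [records[k] for k in sorted(records)]
    targets = by_species["sp00"] + by_species["sp01"]
    bbh = ev.bbh_orthologs(family, targets)
    for rec in family:
        assert bbh[rec.id]["sp00"] == f"{rec.id}_sp00"
        assert bbh[rec.id]["sp01"] == f"{rec.id}_sp01"


def test_bbh_requires_mutual_best_hit():
    # q2's best hit is t1, but t1's best hit is q1: no ortholog for q2
    q1 = ProteinRecord("q1", "MQDKLIWNACDEFGHIKLMN")
    q2 = ProteinRecord("q2", "MQDKLIWNACDEFGHIYYYY")
    t1 = ProteinRecord("t1", "MQDKLIWNACDEFGHIKLMN", species="s")
    bbh = ev.bbh_orthologs([q1, q2], [t1])
    assert bbh["q1"].get("s") == "t1"
    assert "s" not in bbh["q2"]


def test_duplicated_target_yields_single_bbh():
    q = ProteinRecord("q", "MQDKLIWNACDEFGHIKLMN")
    t1 = ProteinRecord("t1", "MQDKLIWNACDEFGHIKLMN", species="s")
    t2 = ProteinRecord("t2", "MQDKLIWNACDEFGHIKLMW", species="s")
    bbh = ev.bbh_orthologs([q], [t1, t2])
    assert bbh["q"]["s"] == "t1"


# ---------------------------------------------------------------------------
# conservation


def test_identical_ortholog_window_fully_conserved():
    aln = ev.PairwiseAlignment("A", "O", "MQDKLIWN", "MQDKLIWN")
    occ = MotifOccurrence("A", "m", 2, 5)
    assert ev.motif_conservation(occ, [aln]) == 1.0


def test_partial_window_conservation():
    aln = ev.PairwiseAlignment("A", "O", "MQDKLIWN", "MQDKAAWN")
    occ = MotifOccurrence("A", "m", 1, 8)
    assert ev.motif_conservation(occ, [aln]) == pytest.approx(6 / 8)


def test_wildcard_positions_excluded_when_pattern_given():
    aln = ev.PairwiseAlignment("A", "O", "MQDK", "MADK")
    occ = MotifOccurrence("A", "m", 1, 4)
    assert ev.motif_conservation(occ, [aln], pattern="M*DK") == 1.0


def test_gap_only_window_excluded():
    aln = ev.PairwiseAlignment("A", "O", "MQ--KL", "MQWWKL")
    # residues 1..4 of A are M,Q,K,L; occurrence of residues 3-4 maps past gap
    occ = MotifOccurrence("A", "m", 3, 4)
    assert ev.motif_conservation(occ, [aln]) == 1.0  # K,L align to K,L
    aln2 = ev.PairwiseAlignment("A", "O", "MQKL", "MQ-L")
    assert ev.window_conservation(aln2, 3, 3) == 0.0  # K aligned to a gap


def test_motif_rate_below_background_separates_distributions(ortholog_world):
    records, truth, _, alignments = ortholog_world
    by_prot = {}
    for aln in alignments:
        by_prot.setdefault(aln.id_a, []).append(aln)
    motif_vals = [
        v
        for occ in truth.occurrences
        if (v := ev.motif_conservation(occ, by_prot[occ.protein_id])) is not None
    ]
    base_vals = []
    for occ in truth.occurrences:
        free = {
            pid: by_prot[pid]
            for pid in records
            if not any(
                o.protein_id == pid and not (o.end < occ.start or o.start > occ.end)
                for o in truth.occurrences
            )
        }
        base_vals.extend(ev.nonmotif_baseline(occ.start, occ.end, free))
    assert np.mean(motif_vals) > np.mean(base_vals)


# ---------------------------------------------------------------------------
# KS test


def test_ks_identical_samples():
    stat, _ = ev.ks_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert stat == 0.0


def test_ks_disjoint_supports():
    stat, p = ev.ks_test([0.0, 0.1, 0.2, 0.3], [1.0, 1.1, 1.2, 1.3])
    assert stat == 1.0 and p < 0.05


def test_ks_undersized_samples_rejected():
    with pytest.raises(ValueError):
        ev.ks_test([1.0], [1.0, 2.0])


def manual_ks_statistic(a, b):
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return np.max(np.abs(fa - fb))


@pytest.mark.parametrize("seed", range(5))
def test_ks_statistic_matches_manual_computation(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=30), rng.normal(0.5, size=25)
    stat, _ = ev.ks_test(a, b)
    assert stat == pytest.approx(manual_ks_statistic(a, b))


# ---------------------------------------------------------------------------
# indels


def test_single_clean_indel_found():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLM", "MQD-LM")
    events = ev.scan_indels(aln)
    assert [(e.indel_column, e.gap_in) for e in events] == [(4, "b")]


def test_too_many_differences_suppress_event():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLM", "MAD-LM")
    assert ev.scan_indels(aln) == []


def test_gap_run_of_two_excluded():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLMA", "MQD--MA")
    assert ev.scan_indels(aln) == []


def test_overlapping_windows_merge_to_one_event():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLMNPQR", "MQDK-MNPQR")
    assert len(ev.scan_indels(aln)) == 1


def test_scan_invariant_under_sequence_swap():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLMNP", "MQD-LMNP")
    fwd = ev.scan_indels(aln)
    rev = ev.scan_indels(aln.swapped())
    assert [(e.indel_column) for e in fwd] == [(e.indel_column) for e in rev]
    assert fwd[0].gap_in == "b" and rev[0].gap_in == "a"


@pytest.fixture()
def indel_event():
    aln = ev.PairwiseAlignment("X", "Y", "MQDKLMNP", "MQD-LMNP")
    return ev.scan_indels(aln)[0]


def test_scenario_no_motifs(indel_event):
    assert ev.classify_indel_scenario(indel_event, [], []) == "I"


def test_scenario_both_copies(indel_event):
    occ_x = [MotifOccurrence("X", "m1", 3, 6)]
    occ_y = [MotifOccurrence("Y", "m2", 2, 5)]
    assert ev.classify_indel_scenario(indel_event, occ_x, occ_y) == "II"


def test_scenario_insertion_copy_only(indel_event):
    occ_x = [MotifOccurrence("X", "m1", 3, 6)]  # X holds the extra residue
    assert ev.classify_indel_scenario(indel_event, occ_x, []) == "III"


def test_scenario_deletion_copy_only(indel_event):
    occ_y = [MotifOccurrence("Y", "m2", 2, 5)]  # Y carries the gap
    assert ev.classify_indel_scenario(indel_event, [], occ_y) == "IV"


# ---------------------------------------------------------------------------
# duplicate pairs


def test_duplicate_pairs_require_shared_clade():
    refs = [
        ProteinRecord("R1", "MQDKLIWNACDEFGHIKLMN"),
        ProteinRecord("R2", "WWYYFFPPGGSSTTAAHHRR"),
    ]
    clades = {"R1": "cladeA", "R2": "cladeB"}
    prots = [
        ProteinRecord("x1", "MQDKLIWNACDEFGHIKLMW", species="X"),
        ProteinRecord("x2", "MQDKLIWNACDEFGHIKLMY", species="X"),
        ProteinRecord("x3", "WWYYFFPPGGSSTTAAHHRK", species="X"),
    ]
    pairs = ev.find_duplicate_pairs(prots, refs, clades)
    assert pairs == [("x1", "x2", "cladeA")]


# ---------------------------------------------------------------------------
# SNP overlap


def test_no_occurrences_gives_zero_overlap():
    snps = [ev.SNPRecord("P", 5, "M", "T")]
    assert ev.snp_motif_overlap(snps, []) == 0


def test_tiling_occurrences_capture_total_weight():
    snps = [ev.SNPRecord("P", 3, "M", "T", count=4), ev.SNPRecord("P", 9, "K", "R")]
    occs = [MotifOccurrence("P", "m", 1, 10)]
    assert ev.snp_motif_overlap(snps, occs) == 5


def test_null_trials_preserve_occurrence_geometry():
    snps = [ev.SNPRecord("P", i, "M", "T") for i in range(1, 31)]
    occs = [MotifOccurrence("P", "m", 1, 30)]  # tiles the whole protein
    null = ev.randomized_motif_null(snps, occs, {"P": 30}, seed=0, trials=20)
    assert null == [30] * 20  # every placement still covers everything


def test_snp_depletion_detected(family):
    from imss.scoring import empirical_pvalue

    records, _, truth = family
    rng = np.random.default_rng(3)
    in_motif = {pid: set() for pid in records}
    for o in truth.occurrences:
        in_motif[o.protein_id].update(range(o.start, o.end + 1))
    snps = []
    for pid in sorted(records):
        free = [i for i in range(1, len(records[pid]) + 1) if i not in in_motif[pid]]
        for pos in rng.choice(free, size=3, replace=False):
            ref = records[pid].sequence[pos - 1]
            snps.append(ev.SNPRecord(pid, int(pos), ref, "A" if ref != "A" else "G"))
    observed = ev.snp_motif_overlap(snps, truth.occurrences)
    null = ev.randomized_motif_null(
        snps, truth.occurrences, {k: len(v) for k, v in records.items()},
        seed=11, trials=200,
    )
    assert empirical_pvalue(observed, null, "less") <= 0.05


# ---------------------------------------------------------------------------
# correlated mutations


def coevolving_msa(n_noise: int, seed: int):
    rng = np.random.default_rng(seed)
    groups = ["KK", "RR", "KK", "RR", "KK", "RR", "KK", "RR"]
    rows = []
    for g in groups:
        noise = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_noise))
        rows.append(g[0] + noise[: n_noise // 2] + g[1] + noise[n_noise // 2 :])
    return [(f"s{i}", row) for i, row in enumerate(rows)]


def test_perfectly_covarying_columns_score_one():
    msa = coevolving_msa(0, 0)
    hits = ev.caps_correlated_columns(msa, r_cutoff=0.4)
    assert hits and hits[0][:2] == (1, 2)
    assert hits[0][2] == pytest.approx(1.0)


def test_constant_column_excluded():
    msa = [("a", "KAD"), ("b", "KAE"), ("c", "KAD"), ("d", "KAE")]
    hits = ev.caps_correlated_columns(msa, r_cutoff=-1.1)
    cols = {i for i, j, _ in hits} | {j for i, j, _ in hits}
    assert 2 not in cols  # the invariant A column has zero variance


@pytest.mark.parametrize("seed", range(10))
def test_planted_coevolving_pair_ranks_first(seed):
    msa = coevolving_msa(20, seed)
    hits = ev.caps_correlated_columns(msa, r_cutoff=0.4)
    assert hits[0][:2] == (1, 12)  # planted pair: column 1 and the mid column


def test_low_coverage_column_skipped():
    msa = [("a", "K-D"), ("b", "K-E"), ("c", "KAD"), ("d", "-AE"), ("e", "KAD"), ("f", "KAE")]
    hits = ev.caps_correlated_columns(msa, r_cutoff=-1.1, min_coverage=0.5)
    cols = {c for i, j, _ in hits for c in (i, j)}
    assert 2 not in cols


def test_too_few_sequences_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        ev.caps_correlated_columns([("a", "KD"), ("b", "RE"), ("c", "KD")])


# ---------------------------------------------------------------------------
# exon borders


def test_occurrence_adjacent_to_border_is_near():
    occs = [MotifOccurrence("P", "m", 7, 10)]  # starts 1 residue after border
    rep = ev.exon_border_analysis(occs, [ev.ExonBorder("P", 5)], near_cutoff=3)
    assert rep.near_motifs == ["m"]
    assert rep.min_distance["m"] == 1


def test_occurrence_spanning_border_distance_zero():
    occs = [MotifOccurrence("P", "m", 4, 9)]
    rep = ev.exon_border_analysis(occs, [ev.ExonBorder("P", 5)])
    assert rep.min_distance["m"] == 0


def test_protein_without_borders_counts_as_far():
    occs = [MotifOccurrence("P", "m", 1, 5)]
    rep = ev.exon_border_analysis(occs, [], near_cutoff=3)
    assert rep.far_motifs == ["m"]
    assert rep.min_distance["m"] == float("inf")


def test_border_grouping_separates_planted_sets():
    # motif "shared" occurs in many proteins far from borders; motif "edge"
    # sits right at a border of a single protein
    occs = [MotifOccurrence(f"P{i}", "shared", 20, 25) for i in range(6)]
    occs.append(MotifOccurrence("P0", "edge", 5, 9))
    borders = [ev.ExonBorder("P0", 4)]
    rep = ev.exon_border_analysis(occs, borders, near_cutoff=3)
    assert rep.near_motifs == ["edge"] and "shared" in rep.far_motifs
    assert rep.mean_proteins_near < rep.mean_proteins_far
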