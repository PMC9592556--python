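"""Filters, secondary-structure classification, pLDDT analytics and the
study pipeline."""

import itertools

import numpy as np
import pytest

from flexscore.compare import (
    PipelineOptions,
    classify_ss,
    correlate_plddt_ansurr,
    filter_candidate,
    mean_plddt,
    partition_significance,
    score_accession,
    score_pair,
    summarize,
)
from flexscore.compare import ComparisonRecord
from flexscore.synthdata import (
    SyntheticSpec,
    build_antiparallel_sheet,
    build_structure,
    make_pair,
    simulate_shifts,
)
from flexscore.types import Atom, ChemicalShiftSet, PairCandidate, SegmentMapping

from oracles import pearson_closed_form, pearson_p_two_tailed


def _candidate(n_res=25, completeness=1.0, n_chains=1, seed=0):
    ss = "C" * 3 + "H" * (n_res - 6) + "C" * 3
    seq = "A" * n_res
    spec = SyntheticSpec(ss_string=ss, sequence=seq, seed=seed,
                         completeness_target=completeness)
    cand, _ = make_pair(spec, spec)
    if n_chains > 1:
        from flexscore.synthdata import _add_decoy_chain
        cand = _add_decoy_chain(cand)
    return cand


def _record(pair_id, diff, ss_class="alpha", plddt=70.0, plddt_wd=None,
            af2=None):
    af2 = 100.0 + diff if af2 is None else af2
    return ComparisonRecord(
        pair_id=pair_id, nmr_mean_score=af2 - diff, nmr_best_score=af2 - diff,
        af2_score=af2, ss_class=ss_class, mean_plddt_all=plddt,
        mean_plddt_well_defined=plddt_wd, n_models=1, n_residues=30)


class TestFilters:
    def test_passing_candidate(self):
        passed, reasons = filter_candidate(_candidate(25))
        assert passed and reasons == set()

    def test_nineteen_residues_too_short(self):
        passed, reasons = filter_candidate(_candidate(19))
        assert not passed and reasons == {"too_short"}

    def test_twenty_residues_inclusive(self):
        passed, reasons = filter_candidate(_candidate(20))
        assert passed

    def test_exact_threshold_completeness_passes(self):
        """75 % completeness passes (inclusive bound)."""
        cand = _candidate(24, completeness=0.75)
        passed, reasons = filter_candidate(cand)
        assert "low_completeness" not in reasons

    def test_low_completeness_fails(self):
        passed, reasons = filter_candidate(_candidate(24, completeness=0.5))
        assert reasons == {"low_completeness"}

    def test_multichain_fails(self):
        passed, reasons = filter_candidate(_candidate(25, n_chains=2))
        assert reasons == {"multichain"}

    def test_reason_codes_accumulate(self):
        passed, reasons = filter_candidate(
            _candidate(19, completeness=0.5, n_chains=2))
        assert reasons == {"too_short", "low_completeness", "multichain"}


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helical(self, helix_model):
        ss, cls = classify_ss(helix_model)
        interior = [ss[i] for i in range(4, 11)]
        assert all(v == "H" for v in interior)
        assert cls == "alpha"

    def test_antiparallel_sheet_is_beta(self):
        sheet = build_antiparallel_sheet(6)
        ss, cls = classify_ss(sheet)
        strand_residues = [v for v in ss.values()]
        assert strand_residues.count("E") >= 8
        assert cls == "beta"

    def test_helix_plus_sheet_is_mixed(self, helix_model):
        sheet = build_antiparallel_sheet(6)
        moved = []
        for a in sheet:
            b = a.copy()
            b.res_seq += 100
            b.coords = a.coords + np.array([0.0, 0.0, 40.0])
            moved.append(b)
        _, cls = classify_ss([a.copy() for a in helix_model] + moved)
        assert cls == "mixed"

    def test_missing_oxygens_raise(self, helix_model):
        stripped = [a for a in helix_model if a.name != "O"]
        with pytest.raises(ValueError, match="O atoms"):
            classify_ss(stripped)


class TestMeanPlddt:
    def _model(self):
        atoms = []
        for i in range(1, 21):
            atoms.append(Atom(name="CA", element="C", res_seq=i,
                              res_name="ALA", chain_id="A",
                              coords=np.array([3.8 * i, 0.0, 0.0]),
                              bfactor=80.0 if i <= 10 else 40.0))
        return atoms

    def test_constant(self):
        model = [a.copy() for a in self._model()]
        for a in model:
            a.bfactor = 70.0
        assert mean_plddt(model) == pytest.approx(70.0)

    def test_region_restriction(self):
        assert mean_plddt(self._model(), [(1, 10)]) == pytest.approx(80.0)

    def test_whole_model_mean(self):
        assert mean_plddt(self._model()) == pytest.approx(60.0)

    def test_disjoint_region_raises(self):
        with pytest.raises(ValueError):
            mean_plddt(self._model(), [(100, 110)])


class TestSignificance:
    def test_inclusive_positive_threshold(self):
        counts = partition_significance([_record("a", 50.0)])
        assert counts["af2_much_better"] == 1

    def test_inclusive_negative_threshold(self):
        counts = partition_significance([_record("a", -50.0)])
        assert counts["nmr_much_better"] == 1

    def test_enumeration(self):
        records = [_record("a", 60), _record("b", -60), _record("c", 10)]
        counts = partition_significance(records)
        assert counts == {"af2_much_better": 1, "nmr_much_better": 1,
                          "neither": 1}


class TestPlddtCorrelation:
    def test_perfect_linear(self):
        records = [_record(str(i), 0, plddt=p, af2=p)
                   for i, p in enumerate([50.0, 60.0, 70.0, 80.0])]
        r, p = correlate_plddt_ansurr(records)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_antitone(self):
        records = [_record(str(i), 0, plddt=x, af2=y)
                   for i, (x, y) in enumerate([(1, 3), (2, 2), (3, 1)])]
        r, _ = correlate_plddt_ansurr(records)
        assert r == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        xs, ys = [1, 2, 3, 4], [2, 1, 4, 3]
        records = [_record(str(i), 0, plddt=x, af2=y)
                   for i, (x, y) in enumerate(zip(xs, ys))]
        r, p = correlate_plddt_ansurr(records)
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(0.4, abs=1e-12)
        assert r == pytest.approx(pearson_closed_form(xs, ys), abs=1e-12)
        assert p == pytest.approx(pearson_p_two_tailed(r, 4), abs=1e-12)

    def test_constant_vector_rejected(self):
        records = [_record(str(i), 0, plddt=50.0, af2=float(i))
                   for i in range(4)]
        with pytest.raises(ValueError, match="constant"):
            correlate_plddt_ansurr(records)

    def test_well_defined_variant_uses_restricted_means(self):
        records = [_record(str(i), 0, plddt=50.0, plddt_wd=p, af2=p)
                   for i, p in enumerate([55.0, 65.0, 75.0, 85.0])]
        r, _ = correlate_plddt_ansurr(records, "well_defined")
        assert r == pytest.approx(1.0)


class TestSummarize:
    def test_singleton(self):
        s = summarize([_record("a", 17.0)])
        assert s.mean_diff_ensemble == pytest.approx(17.0)
        assert s.n_pairs == 1

    def test_symmetric_pair(self):
        s = summarize([_record("a", 30.0), _record("b", -30.0)])
        assert s.mean_diff_ensemble == pytest.approx(0.0)

    def test_fractions_sum_to_one(self):
        s = summarize([_record(str(i), d) for i, d in
                       enumerate([60, -60, 10, 20, -5])])
        assert sum(s.significance_fractions.values()) == pytest.approx(1.0)

    def test_order_permutation_stable(self):
        records = [_record(str(i), d) for i, d in
                   enumerate([60.0, -60.0, 10.0, 49.9, 50.0])]
        base = summarize(records)
        for perm in itertools.permutations(records):
            s = summarize(list(perm))
            assert s.significance_counts == base.significance_counts
            assert s.mean_diff_ensemble == pytest.approx(base.mean_diff_ensemble)

    def test_histogram_bin_width_ten(self):
        s = summarize([_record("a", 3.0), _record("b", 17.0)])
        edges = s.diff_histogram["edges"]
        assert edges[1] - edges[0] == pytest.approx(10.0)
        assert sum(s.diff_histogram["counts"]) == 2


class TestScorePair:
    def test_self_comparison_is_zero_diff(self):
        spec = SyntheticSpec(ss_string="C" * 3 + "H" * 18 + "C" * 3,
                             sequence="A" * 24, seed=4)
        cand, _ = make_pair(spec, spec)
        rec = score_pair(cand)
        assert rec.diff_mean == pytest.approx(0.0)
        assert rec.diff_best == pytest.approx(0.0)

    def test_two_segments_average(self):
        """The predicted-side score is the mean of its per-segment scores."""
        spec = SyntheticSpec(ss_string="C" * 3 + "H" * 24 + "C" * 3,
                             sequence="A" * 30, seed=9)
        cand, _ = make_pair(spec, spec, uniprot_offset=100)
        seg = cand.segments[0]
        half1 = SegmentMapping(seg.uniprot_acc, seg.pdb_id, seg.chain_id,
                               (1, 24), (101, 124))
        half2 = SegmentMapping(seg.uniprot_acc, seg.pdb_id, seg.chain_id,
                               (5, 30), (105, 130))
        two = PairCandidate(cand.uniprot_acc, cand.nmr_ensemble,
                            cand.predicted_model, cand.shifts,
                            [half1, half2], cand.well_defined)
        rec = score_pair(two)
        singles = []
        for seg_i in (half1, half2):
            one = PairCandidate(cand.uniprot_acc, cand.nmr_ensemble,
                                cand.predicted_model, cand.shifts,
                                [seg_i], cand.well_defined)
            singles.append(score_pair(one).af2_score)
        assert rec.af2_score == pytest.approx(np.mean(singles))

    def test_degraded_nmr_side_scores_lower(self):
        wins = 0
        for s in range(10):
            ss = "C" * 4 + "H" * 20 + "C" * 4
            seq = "A" * 28
            pred = SyntheticSpec(ss_string=ss, sequence=seq, seed=500 + s,
                                 hbond_retention=1.0, coil_dispersion=0.0)
            nmr = SyntheticSpec(ss_string=ss, sequence=seq, seed=500 + s,
                                n_models=2, hbond_retention=0.3,
                                shift_noise_sd=0.2)
            cand, _ = make_pair(pred, nmr)
            wins += score_pair(cand).diff_mean > 0
        assert wins >= 9


class TestTwoLevelAveraging:
    def test_mean_of_entry_means_exact(self):
        """Accession mapped to two deposited entries with overlapping
        segments (48 and 35 residues): the combined record equals the mean
        of the per-entry records on every score, exactly."""
        n = 48
        ss = "C" * 4 + "H" * 40 + "C" * 4
        seq = "A" * n
        spec_full = SyntheticSpec(ss_string=ss, sequence=seq, seed=11,
                                  first_residue=623)
        pred = build_structure(spec_full)
        entries = []
        for pdb_id, (lo, hi), seed in (("5NAM", (623, 670), 21),
                                       ("5NAO", (623, 657), 22)):
            k = hi - lo + 1
            sub = SyntheticSpec(ss_string=ss[:k], sequence=seq[:k], seed=seed,
                                n_models=2, first_residue=623,
                                shift_noise_sd=0.1, hbond_retention=[0.8, 1.0])
            entries.append(PairCandidate(
                uniprot_acc="O00206",
                nmr_ensemble=build_structure(sub),
                predicted_model=pred,
                shifts=simulate_shifts(sub),
                segments=[SegmentMapping("O00206", pdb_id, "A",
                                         (lo, hi), (lo, hi))],
            ))
        combined = score_accession(entries)
        singles = [score_pair(e) for e in entries]
        assert combined.af2_score == pytest.approx(
            np.mean([r.af2_score for r in singles]))
        assert combined.nmr_mean_score == pytest.approx(
            np.mean([r.nmr_mean_score for r in singles]))
        assert combined.nmr_best_score == pytest.approx(
            np.mean([r.nmr_best_score for r in singles]))
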