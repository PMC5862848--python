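import itertools

import numpy as np
import pytest

from probescout.digestion import PeptideInterval
from probescout.masses import MatchTolerance, peptide_mass, mz
from probescout.site_id import (
    ASCORE_UNAMBIGUOUS,
    PSM,
    Spectrum,
    assign_fdr,
    count_matched_ions,
    fragment_ions,
    localize,
    match_spectrum,
)


def make_spectrum(peak_mzs, intensities=None, precursor_mz=500.0, charge=2, **kw):
    peaks = np.column_stack(
        [np.asarray(peak_mzs, float),
         np.ones(len(peak_mzs)) if intensities is None else np.asarray(intensities)]
    ) if len(peak_mzs) else np.zeros((0, 2))
    return Spectrum(id="s1", precursor_mz=precursor_mz,
                    precursor_charge=charge, peaks=peaks, **kw)


def interval(seq, pid="P1"):
    return PeptideInterval(pid, 0, len(seq), seq)


class TestFragmentIons:
    def test_singly_charged_ion_count(self):
        ions = fragment_ions("PEPTIDE")
        assert len(ions) == 2 * (len("PEPTIDE") - 1)

    def test_b_y_pairs_conserve_peptide_mass(self):
        seq = "ACDEFGHIK"
        ions = {(lbl, z): m for lbl, z, m in fragment_ions(seq)}
        total = peptide_mass(seq)
        n = len(seq)
        for i in range(1, n):
            b = ions[(f"b{i}", 1)] - 1.007276
            y = ions[(f"y{n - i}", 1)] - 1.007276
            assert b + y == pytest.approx(total, abs=1e-9)

    def test_remnant_shifts_only_containing_fragments(self, remnant):
        plain = {(lbl, z): m for lbl, z, m in fragment_ions("ACK")}
        modded = {(lbl, z): m for lbl, z, m in fragment_ions("ACK", [(1, remnant)])}
        delta = remnant.delta_mass
        assert modded[("y1", 1)] == pytest.approx(plain[("y1", 1)])  # K only
        assert modded[("y2", 1)] == pytest.approx(plain[("y2", 1)] + delta)
        assert modded[("b1", 1)] == pytest.approx(plain[("b1", 1)])
        assert modded[("b2", 1)] == pytest.approx(plain[("b2", 1)] + delta)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fragment_ions("A")


class TestCountMatchedIons:
    def test_empty_peak_list_scores_zero(self):
        assert count_matched_ions([100.0, 200.0], [], 0.8) == 0

    def test_matches_bruteforce_bipartite_oracle(self, rng):
        def oracle(theo, obs, tol):
            # exhaustively try every injective assignment
            best = 0
            idx = range(len(obs))
            for k in range(min(len(theo), len(obs)), 0, -1):
                for theo_subset in itertools.combinations(range(len(theo)), k):
                    for perm in itertools.permutations(idx, k):
                        if all(
                            abs(theo[t] - obs[o]) <= tol
                            for t, o in zip(theo_subset, perm)
                        ):
                            return k
            return 0

        for _ in range(50):
            theo = rng.uniform(100, 110, size=rng.integers(1, 6))
            obs = rng.uniform(100, 110, size=rng.integers(1, 7))
            assert count_matched_ions(theo, obs, 1.0) == oracle(
                list(theo), list(obs), 1.0
            )


class TestMatchSpectrum:
    def test_perfect_spectrum_wins_with_max_score(self, remnant):
        seq_a, seq_b = "ACDEFK", "GHILMW"
        mods_a = ((1, remnant),)
        ions_a = [m for _, _, m in fragment_ions(seq_a, mods_a)]
        spec = make_spectrum(
            sorted(ions_a), precursor_mz=mz(peptide_mass(seq_a, mods_a), 2)
        )
        cands = [
            (interval(seq_a), mods_a, "A"),
            (interval(seq_b), (), "B"),
        ]
        tol = MatchTolerance(precursor_ppm=1e6, fragment_da=0.8)
        psm = match_spectrum(spec, cands, tol)
        assert psm.protein_id == "A"
        assert psm.score == 2 * (len(seq_a) - 1)

    def test_empty_peak_list_scores_all_zero(self, remnant):
        seq = "ACDEFK"
        mods = ((1, remnant),)
        spec = make_spectrum([], precursor_mz=mz(peptide_mass(seq, mods), 2))
        tol = MatchTolerance(precursor_ppm=10.0, fragment_da=0.8)
        psm = match_spectrum(spec, [(interval(seq), mods, "A")], tol)
        assert psm.score == 0

    def test_precursor_filter_can_reject_everything(self, remnant):
        seq = "ACDEFK"
        spec = make_spectrum([500.0], precursor_mz=100.0)
        tol = MatchTolerance(precursor_ppm=5.0, fragment_da=0.8)
        assert match_spectrum(spec, [(interval(seq), ((1, remnant),), "A")], tol) is None


class TestLocalize:
    def test_single_cys_gets_sentinel(self, remnant):
        spec = make_spectrum([300.0])
        res = localize(spec, "ACK", remnant, [1])
        assert res.ascore == ASCORE_UNAMBIGUOUS
        assert res.best_site == 2
        assert res.runner_up_site is None

    def test_closed_form_four_ion_case(self, remnant):
        # "ACGCK", sites at indices 1 and 3: the site-determining ions are
        # b2, b3, y2, y3 (4 per placement). A spectrum holding exactly the
        # four ions of placement 1 gives P1 = 0.1^4 (score 40), P2 = 1
        # (score 0) at depth 10, so the Ascore gap is 40.
        seq = "ACGCK"
        ions1 = {lbl: m for lbl, z, m in fragment_ions(seq, [(1, remnant)])}
        peaks = [ions1["b2"], ions1["b3"], ions1["y2"], ions1["y3"]]
        spec = make_spectrum(sorted(peaks))
        res = localize(spec, seq, remnant, [1, 3], peak_depth=10, fragment_da=0.4)
        assert res.best_site == 2
        assert res.runner_up_site == 4
        assert res.ascore == pytest.approx(40.0, abs=1e-6)

    def test_symmetric_no_evidence_gives_zero(self, remnant):
        spec = make_spectrum([])
        res = localize(spec, "ACGCK", remnant, [1, 3])
        assert res.ascore == 0.0

    def test_invariant_to_intensity_scaling(self, remnant, rng):
        seq = "ACGACGACK"
        sites = [1, 4]
        mzs = rng.uniform(100, 900, size=14)
        inten = rng.uniform(0.1, 1.0, size=14)
        res1 = localize(make_spectrum(mzs, inten), seq, remnant, sites)
        res2 = localize(make_spectrum(mzs, inten * 1000.0), seq, remnant, sites)
        assert (res1.best_site, res1.ascore) == (res2.best_site, res2.ascore)

    def test_non_cys_candidate_rejected(self, remnant):
        with pytest.raises(ValueError):
            localize(make_spectrum([300.0]), "ACK", remnant, [0])


def psm(score, pid="P1", decoy=False, i=[0]):
    i[0] += 1
    return PSM(
        spectrum_id=f"s{i[0]}",
        protein_id=pid,
        peptide=interval("ACDEFK", pid),
        mods=(),
        charge=2,
        score=score,
        is_decoy=decoy,
        replicate="R1",
    )


class TestAssignFdr:
    def test_all_targets_above_all_decoys_retained(self):
        targets = [psm(s, pid=f"P{j}") for j, s in enumerate((10, 11, 12))]
        decoys = [psm(s, decoy=True) for s in (1, 2, 3)]
        retained = assign_fdr(targets, decoys)
        assert len(retained) == 3
        assert all(p.q_value == 0.0 for p in retained)

    def test_interleaved_scores_q_one_half(self):
        targets = [psm(10), psm(8)]
        decoys = [psm(9, decoy=True), psm(7, decoy=True)]
        assign_fdr(targets, decoys, peptide_q=1.0, protein_q=1.0)
        by_score = {p.score: p.q_value for p in targets}
        assert by_score[8] == pytest.approx(0.5)

    def test_empty_decoys_warns_and_retains(self):
        targets = [psm(5, pid=f"P{j}") for j in range(3)]
        with pytest.warns(UserWarning):
            retained = assign_fdr(targets, [])
        assert len(retained) == 3

    def test_no_targets_is_an_error(self):
        with pytest.raises(ValueError):
            assign_fdr([], [psm(1, decoy=True)])

    def test_q_monotone_non_increasing_in_score(self, rng):
        targets = [psm(float(s)) for s in rng.integers(0, 40, size=60)]
        decoys = [psm(float(s), decoy=True) for s in rng.integers(0, 30, size=60)]
        assign_fdr(targets, decoys, peptide_q=1.0, protein_q=1.0)
        ordered = sorted(targets, key=lambda p: p.score)
        qs = [p.q_value for p in ordered]
        assert all(q1 >= q2 for q1, q2 in zip(qs, qs[1:]))

    def test_protein_tier_filters_weak_proteins(self):
        # strong protein A, weak protein B at the same peptide q
        targets = [psm(30, "A"), psm(29, "A"), psm(5, "B")]
        decoys = [psm(5, "rev_X", decoy=True), psm(4, "rev_Y", decoy=True)]
        retained = assign_fdr(targets, decoys, peptide_q=1.0, protein_q=0.4)
        assert {p.protein_id for p in retained} == {"A"}


class TestFdrCalibration:
    def test_realized_fdp_bounded_on_planted_mixture(self, rng):
        """With planted high-scoring true PSMs over a null score background,
        the realized false-discovery proportion at the 5% q threshold stays
        below 10% averaged over many simulated searches."""
        fdps = []
        for _ in range(200):
            true_scores = rng.normal(30, 3, size=30)
            false_scores = rng.binomial(40, 0.25, size=70).astype(float)
            decoy_scores = rng.binomial(40, 0.25, size=100).astype(float)
            targets = [psm(s, pid=f"T{j}") for j, s in
                       enumerate(np.concatenate([true_scores, false_scores]))]
            decoys = [psm(s, pid=f"D{j}", decoy=True)
                      for j, s in enumerate(decoy_scores)]
            retained = assign_fdr(targets, decoys, peptide_q=0.05, protein_q=1.0)
            if not retained:
                continue
            n_false = sum(1 for p in retained if int(p.protein_id[1:]) >= 30)
            fdps.append(n_false / len(retained))
        assert np.mean(fdps) <= 0.10
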