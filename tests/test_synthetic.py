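"""Generators: determinism, round-trips, planted-truth recovery."""

import io
import json

import numpy as np
import pytest

from cnslim import (
    LXVP_CN,
    STXXP,
    RunConfig,
    fit_itc,
    fit_michaelis_menten,
    fit_site_rate,
    scan_sequence,
    screen_proteins,
    write_fasta,
)
from cnslim.disorder import filter_hits_by_disorder
from cnslim.kinetics import group_by_site
from cnslim.synthetic import (
    GenerationError,
    gen_itc,
    gen_pnpp,
    gen_screen_dataset,
    gen_timecourses,
)


def fasta_bytes(records):
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


class TestScreenGenerator:
    def test_same_seed_bit_identical(self):
        a = gen_screen_dataset(n_proteins=5, n_decoys=1, seed=42)
        b = gen_screen_dataset(n_proteins=5, n_decoys=1, seed=42)
        assert fasta_bytes(a.records) == fasta_bytes(b.records)
        for pid in a.tracks:
            assert np.array_equal(a.tracks[pid].scores, b.tracks[pid].scores)
        assert a.truth_json() == b.truth_json()

    def test_different_seed_differs(self):
        a = gen_screen_dataset(n_proteins=3, seed=1)
        b = gen_screen_dataset(n_proteins=3, seed=2)
        assert fasta_bytes(a.records) != fasta_bytes(b.records)

    def test_planted_motifs_are_the_only_hits(self):
        ds = gen_screen_dataset(n_proteins=8, sites_per_protein=2, seed=11)
        truth = {t.protein_id: t for t in ds.truth}
        for rec in ds.records:
            t = truth[rec.id]
            lx = scan_sequence(rec, LXVP_CN)
            st = scan_sequence(rec, STXXP)
            assert [h.anchor for h in lx] == [t.lxvp_anchor]
            assert [h.anchor for h in st] == t.stxxp_anchors
            assert [h.anchor_letter for h in st] == t.stxxp_letters

    def test_disorder_profile_is_decisive(self):
        ds = gen_screen_dataset(n_proteins=5, seed=4)
        for t in ds.truth:
            track = ds.tracks[t.protein_id]
            assert np.all(track.scores_in(*t.idr_span) >= 0.45)
            lo = np.delete(track.scores, np.s_[t.idr_span[0] - 1 : t.idr_span[1]])
            assert np.all(lo <= 0.2)

    def test_decoys_sit_in_ordered_sequence_and_are_filtered(self):
        ds = gen_screen_dataset(n_proteins=6, n_decoys=2, seed=9)
        for rec in ds.records:
            t = next(x for x in ds.truth if x.protein_id == rec.id)
            assert len(t.decoy_anchors) == 2
            hits = scan_sequence(rec, STXXP)
            kept = filter_hits_by_disorder(hits, ds.tracks[rec.id], 0.4)
            kept_anchors = {h.anchor for h in kept}
            assert kept_anchors == set(t.stxxp_anchors)
            assert kept_anchors.isdisjoint(t.decoy_anchors)

    def test_pipeline_reproduces_truth_exactly(self):
        ds = gen_screen_dataset(n_proteins=10, sites_per_protein=2, n_decoys=1,
                                separation_window=(10, 35), seed=0)
        report = screen_proteins(ds.records, ds.tracks, RunConfig())
        assert report.summary["cohort_all_pairs"]["frac_sep_10_35"] == 1.0
        per_protein = report.summary["cohort_all_pairs"]["sites_per_protein"]
        assert per_protein == {t.protein_id: len(t.stxxp_anchors) for t in ds.truth}
        found = {
            (row.protein_id, row.stxxp_anchor, row.separation)
            for row in report.pairings.itertuples()
        }
        expected = {
            (t.protein_id, a, s)
            for t in ds.truth
            for a, s in zip(t.stxxp_anchors, t.separations)
        }
        assert found == expected

    def test_infeasible_plan_raises(self):
        with pytest.raises(GenerationError):
            gen_screen_dataset(n_proteins=1, length=40, seed=0)
        with pytest.raises(GenerationError):
            gen_screen_dataset(separation_window=(2, 3), seed=0)


class TestTimecourseGenerator:
    def test_seed_determinism(self):
        a, _ = gen_timecourses({"s": 98.0}, noise_sd=0.02, seed=8)
        b, _ = gen_timecourses({"s": 98.0}, noise_sd=0.02, seed=8)
        for x, y in zip(a, b):
            assert np.array_equal(x.intensities, y.intensities)

    def test_resistant_site_is_flat_and_fits_to_zero(self):
        tcs, truth = gen_timecourses({"pT779": 98.0, "pS785": 0.0}, seed=0)
        groups = group_by_site(tcs)
        fit_t = fit_site_rate(groups["pT779"])
        fit_s = fit_site_rate(groups["pS785"])
        assert fit_t.k_dephos == pytest.approx(98.0, rel=1e-6)
        assert fit_s.k_dephos == pytest.approx(0.0, abs=1e-9)
        assert truth["k_dephos_1e-3_per_h"]["pS785"] == 0.0

    def test_reported_se_comparable_to_empirical_spread(self):
        ests, ses = [], []
        for rep in range(100):
            tcs, _ = gen_timecourses({"s": 98.0}, noise_sd=0.02, seed=rep)
            fit = fit_site_rate(tcs)
            ests.append(fit.k_dephos)
            ses.append(fit.k_se)
        sd = np.std(ests, ddof=1)
        assert sd / 2 < np.median(ses) < sd * 2


class TestItcPnppGenerators:
    def test_itc_seed_determinism_and_truth(self):
        a, truth = gen_itc(1.0, 59e-9, -12.0, noise_sd=0.3, seed=5)
        b, _ = gen_itc(1.0, 59e-9, -12.0, noise_sd=0.3, seed=5)
        assert np.array_equal(a.heats, b.heats)
        assert truth["K_D_M"] == 59e-9

    def test_noiseless_itc_recovers_truth(self):
        exp, truth = gen_itc(1.0, 21e-9, -8.5, seed=0)
        fit = fit_itc(exp)
        assert fit.K_D == pytest.approx(truth["K_D_M"], rel=1e-4)

    def test_pnpp_grid_includes_zero_and_recovers(self):
        S, v, truth = gen_pnpp(0.5e-3, 1e-6, seed=0)
        assert S[0] == 0.0 and v[0] == 0.0
        fit = fit_michaelis_menten(S, v, enzyme_total=0.5e-6)
        assert fit.Km == pytest.approx(truth["Km_M"], rel=1e-6)

    def test_pnpp_seed_determinism(self):
        _, v1, _ = gen_pnpp(0.5e-3, 1e-6, noise_sd=0.02, seed=3)
        _, v2, _ = gen_pnpp(0.5e-3, 1e-6, noise_sd=0.02, seed=3)
        assert np.array_equal(v1, v2)
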