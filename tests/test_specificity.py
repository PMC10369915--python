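"""Cutoff calibration, hit calling, logos, and scan matrices."""

import numpy as np
import pandas as pd
import pytest

from sh2screen import (
    EnrichmentTable,
    PeptideEntry,
    PeptideLibrary,
    ScreenTruth,
    ValidationError,
    calibrate_cutoff,
    call_hits,
    compare_domains,
    enrichment_scores,
    frequencies,
    hit_overlap,
    logo_matrix,
    make_fixture_library,
    scan_matrix,
    simulate_screen,
    weights_from_position_preferences,
)
from sh2screen.specificity import HitSet


def _et(scores: dict, domain="WT"):
    df = pd.Series(scores, name="r1").to_frame()
    df.index.name = "id"
    return EnrichmentTable(domain, df, ["lib"])


def _lib_with_controls(site_scores: dict, control_scores: dict,
                       length=5) -> tuple[PeptideLibrary, EnrichmentTable]:
    entries = [
        PeptideEntry(pid, "AAYAA", "wildtype_site", phospho_index=2)
        for pid in site_scores
    ] + [
        PeptideEntry(cid, "AAAAA", "tyr_free_control")
        for cid in control_scores
    ]
    lib = PeptideLibrary("lib", tuple(entries), length)
    return lib, _et({**site_scores, **control_scores})


class TestCalibrateCutoff:
    def test_brute_force_over_sorted_controls(self):
        # 100 controls scoring 1..100; 2% above means exactly 2 allowed
        controls = {f"c{i}": float(i) for i in range(1, 101)}
        lib, et = _lib_with_controls({"p1": 50.0}, controls)
        cutoff = calibrate_cutoff(et, lib, max_control_fraction=0.02)
        assert cutoff == 98.0

    def test_all_zero_controls_fall_back_to_floor(self):
        lib, et = _lib_with_controls({"p1": 5.0}, {"c1": 0.0, "c2": 0.0})
        assert calibrate_cutoff(et, lib, 0.5) == 0.0
        assert calibrate_cutoff(et, lib, 0.5, floor=0.25) == 0.25

    def test_no_controls_rejected(self):
        lib = PeptideLibrary(
            "lib",
            (PeptideEntry("p1", "AAYAA", "wildtype_site"),
             PeptideEntry("c0", "AAAAA", "tyr_free_control")),
            5,
        )
        et = _et({"p1": 5.0})  # control absent from the score table
        with pytest.raises(ValidationError, match="control"):
            calibrate_cutoff(et, lib, 0.02)


class TestCallHits:
    def test_strictly_greater_than_cutoff(self):
        lib, et = _lib_with_controls(
            {"p1": 4.0, "p2": 3.2, "p3": 1.0}, {"c1": 0.5}
        )
        hits = call_hits(et, lib, cutoff=3.2)
        assert hits.hit_ids == {"p1"}

    def test_zero_cutoff_keeps_all_positive_eligible(self):
        lib, et = _lib_with_controls(
            {"p1": 4.0, "p2": 0.0}, {"c1": 9.0}
        )
        hits = call_hits(et, lib, cutoff=0.0)
        assert hits.hit_ids == {"p1"}  # controls never eligible

    def test_antitone_in_cutoff(self):
        rng = np.random.default_rng(0)
        scores = {f"p{i}": float(s) for i, s in
                  enumerate(rng.exponential(2.0, size=200))}
        lib, et = _lib_with_controls(scores, {"c1": 0.1})
        previous = None
        for cutoff in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            hits = call_hits(et, lib, cutoff).hit_ids
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_per_replicate_mode_is_stricter(self):
        df = pd.DataFrame({"r1": [4.0, 4.0], "r2": [4.0, 2.0]},
                          index=pd.Index(["p1", "p2"], name="id"))
        et = EnrichmentTable("WT", df, ["lib"])
        lib = PeptideLibrary("lib", (
            PeptideEntry("p1", "AAYAA", "wildtype_site"),
            PeptideEntry("p2", "CCYCC", "wildtype_site"),
            PeptideEntry("c1", "AAAAA", "tyr_free_control"),
        ), 5)
        assert call_hits(et, lib, 2.5, mode="mean").hit_ids == {"p1", "p2"}
        assert call_hits(et, lib, 2.5, mode="per_replicate").hit_ids == {"p1"}


class TestHitOverlap:
    def _hs(self, label, ids):
        return HitSet(label, 3.2, frozenset(ids), 0.0)

    def test_two_set_venn_counts(self):
        report = hit_overlap([
            self._hs("WT", {"a", "b", "c"}), self._hs("T42A", {"b", "c", "d"})
        ])
        assert report.count("WT") == 1
        assert report.count("T42A") == 1
        assert report.count("WT", "T42A") == 2
        assert report.union_size == 4
        assert sum(report.region_counts.values()) == report.union_size

    def test_identical_sets_all_in_intersection(self):
        report = hit_overlap([self._hs("A", {"x", "y"}),
                              self._hs("B", {"x", "y"})])
        assert report.count("A", "B") == 2
        assert report.count("A") == 0

    def test_disjoint_sets_have_empty_intersection(self):
        report = hit_overlap([self._hs("A", {"x"}), self._hs("B", {"y"})])
        assert report.count("A", "B") == 0
        assert report.union_size == 2


class TestLogoMatrix:
    def _library(self):
        # position -1 residues: A, A, C, C across four single-Tyr peptides
        peps = ["DAYAA", "DAYCC", "DCYAA", "DCYCC"]
        entries = tuple(
            PeptideEntry(f"p{i}", p, "wildtype_site", phospho_index=2)
            for i, p in enumerate(peps)
        ) + (PeptideEntry("c1", "DDDDD", "tyr_free_control"),)
        return PeptideLibrary("lib", entries, 5)

    def test_full_library_logo_is_zero_for_any_pseudocount(self):
        lib = self._library()
        hits = HitSet("WT", 0.0, frozenset(lib.single_tyrosine_ids()), 0.0)
        for pc in (0.0, 0.5, 1.0, 3.0):
            logo = logo_matrix(hits, lib, pseudocount=pc)
            assert np.allclose(logo.values.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_frequency_gives_plus_one_bit(self):
        lib = self._library()
        hits = HitSet("WT", 0.0, frozenset({"p0", "p1"}), 0.0)
        logo = logo_matrix(hits, lib, pseudocount=0.0)
        # A at -1 occurs at freq 1.0 in hits vs 0.5 in library: log2(2) = 1
        assert logo.values.at[-1, "A"] == pytest.approx(1.0)

    def test_absent_residue_matches_pseudocount_formula(self):
        lib = self._library()
        hits = HitSet("WT", 0.0, frozenset({"p0", "p1"}), 0.0)
        pc = 1.0
        logo = logo_matrix(hits, lib, pseudocount=pc)
        expected = np.log2(((0 + pc) / (2 + 20 * pc))
                           / ((2 + pc) / (4 + 20 * pc)))
        assert logo.values.at[-1, "C"] == pytest.approx(expected)
        assert np.isfinite(logo.values.to_numpy()).all()

    def test_frequency_weighted_exponential_sums_to_one(self):
        lib = self._library()
        hits = HitSet("WT", 0.0, frozenset({"p0", "p2"}), 0.0)
        pc = 1.0
        logo = logo_matrix(hits, lib, pseudocount=pc)
        for pos in logo.values.index:
            n_lib, _ = _position_counts_for(lib, pos)
            f_lib = (n_lib + pc) / (n_lib.sum() + 20 * pc)
            total = float((f_lib * 2.0 ** logo.values.loc[pos]).sum())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_hit_set_rejected(self):
        lib = self._library()
        with pytest.raises(ValidationError):
            logo_matrix(HitSet("WT", 0.0, frozenset(), 0.0), lib)

    def test_recovers_generating_preferences_from_synthetic_screen(self):
        # peptides selected under a position-weight truth: the logo's sign
        # at strongly favored/disfavored residues must match the truth
        lib = make_fixture_library(400, 40, 9, seed=9)
        prefs = {(-2, "V"): 8.0, (1, "A"): 8.0, (2, "E"): 6.0,
                 (-1, "W"): 0.125}
        weights = weights_from_position_preferences(lib, prefs)
        truth = ScreenTruth(weights, depth_input=300_000,
                            depth_selected=300_000, seed=13)
        ct_in, ct_sel = simulate_screen(lib, truth)
        et = enrichment_scores(frequencies(ct_in, 1), frequencies(ct_sel, 1),
                               domain_label="synthetic")
        cutoff = calibrate_cutoff(et, lib, 0.02)
        hits = call_hits(et, lib, cutoff)
        assert len(hits) >= 20
        logo = logo_matrix(hits, lib, pseudocount=1.0, window=(-4, 4))
        for (pos, aa), factor in prefs.items():
            value = logo.values.at[pos, aa]
            assert (value > 0) == (factor > 1), (pos, aa, value)


def test_render_logo_writes_an_image(tmp_path):
    from sh2screen.specificity import render_logo

    lib = make_fixture_library(30, 5, 9, seed=2)
    hits = HitSet("WT", 0.0, frozenset(lib.single_tyrosine_ids()[:10]), 0.0)
    logo = logo_matrix(hits, lib, pseudocount=1.0, window=(-3, 3))
    out = tmp_path / "logo.png"
    render_logo(logo, out, title="demo")
    assert out.stat().st_size > 0


def _position_counts_for(lib, pos):
    counts = pd.Series(0.0, index=list("ACDEFGHIKLMNPQRSTVWY"))
    for e in lib.entries:
        if e.phospho_index is None:
            continue
        i = e.phospho_index + pos
        if 0 <= i < len(e.peptide):
            counts[e.peptide[i]] += 1
    return counts, counts.sum()


class TestScanMatrix:
    def _scan_setup(self):
        wt = "VDYGE"
        entries = [PeptideEntry("wt", wt, "wildtype_site", phospho_index=2)]
        scores = {"wt": 2.0}
        # +1 position (index 3) G->A scores 8.0 (4x wt); -2 V->I equals wt
        entries.append(PeptideEntry("m1", "VDYAE", "scan_variant",
                                    phospho_index=2))
        scores["m1"] = 8.0
        entries.append(PeptideEntry("m2", "IDYGE", "scan_variant",
                                    phospho_index=2))
        scores["m2"] = 2.0
        lib = PeptideLibrary("scan", tuple(entries), 5,
                             require_controls=False)
        return lib, _et(scores)

    def test_log2_ratios_and_wildtype_zero(self):
        lib, et = self._scan_setup()
        sm = scan_matrix(et, lib, "wt")
        assert sm.values.at[1, "A"] == pytest.approx(2.0)   # 4x -> +2
        assert sm.values.at[-2, "I"] == pytest.approx(0.0)  # equal to wt
        for i, aa in enumerate(sm.wt_peptide):
            assert sm.values.at[i - 2, aa] == 0.0

    def test_low_input_variants_flagged_missing(self):
        lib, et = self._scan_setup()
        input_counts = pd.Series({"wt": 500, "m1": 3, "m2": 500})
        sm = scan_matrix(et, lib, "wt", min_input_count=10,
                         input_counts=input_counts)
        assert np.isnan(sm.values.at[1, "A"])
        assert bool(sm.missing.at[1, "A"])

    def test_zero_wildtype_score_rejected(self):
        lib, _ = self._scan_setup()
        et = _et({"wt": 0.0, "m1": 8.0, "m2": 2.0})
        with pytest.raises(ValidationError, match="wild-type"):
            scan_matrix(et, lib, "wt")


class TestCompareDomains:
    def test_identical_tables_have_no_flags(self):
        et = _et({"p1": 2.0, "p2": 4.0})
        cmp = compare_domains(et, _et({"p1": 2.0, "p2": 4.0}, domain="T42A"))
        assert np.allclose(cmp.table["log2_ratio"], 0.0)
        assert not cmp.table["flagged"].any()

    def test_tenfold_difference_is_flagged(self):
        a = _et({"p1": 1.0, "p2": 1.0})
        b = _et({"p1": 10.0, "p2": 1.0}, domain="T42A")
        cmp = compare_domains(a, b, log2_ratio_threshold=1.0)
        assert bool(cmp.table.at["p1", "flagged"])
        assert not bool(cmp.table.at["p2", "flagged"])

    def test_one_sided_peptides_excluded_and_reported(self):
        a = _et({"p1": 1.0, "only_a": 2.0})
        b = _et({"p1": 1.0, "only_b": 2.0}, domain="T42A")
        cmp = compare_domains(a, b)
        assert list(cmp.table.index) == ["p1"]
        assert cmp.only_a == ["only_a"] and cmp.only_b == ["only_b"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            compare_domains(_et({"a": 1.0}), _et({"b": 1.0}, domain="X"))
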