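"""The three integrative analyses: enrichment, chemistry selection,
abundance-disorder correlation."""

import numpy as np
import pytest

from protannot import (
    Proteome,
    ResidueClass,
    abundance_disorder,
    chemistry_select,
    fraction_of_class,
    fraction_of_classes,
    ptm_enrichment,
    rk_idr_split,
)
from protannot.analysis import tail_percentile_threshold
from protannot.exceptions import InsufficientDataError
from protannot.synth import SyntheticSpec, generate

from conftest import random_proteome


def brute_force_enrichment(proteome, site_type, target, idr_type, track, threshold):
    """Independent per-residue scan (no numpy, no shared helpers)."""
    counts = dict(ti=0, mi=0, tf=0, mf=0)
    for protein in proteome:
        if track not in protein.tracks:
            continue
        acc = protein.track(track).values
        for pos in range(1, len(protein) + 1):
            if protein.sequence[pos - 1] != target:
                continue
            in_idr = any(
                d.start <= pos <= d.stop
                for d in protein.domains if d.domain_type == idr_type
            )
            modified = any(
                s.site_type == site_type for s in protein.sites_at(pos)
            )
            if in_idr:
                counts["ti"] += 1
                counts["mi"] += modified
            elif acc[pos - 1] >= threshold:
                counts["tf"] += 1
                counts["mf"] += modified
    return counts


class TestPtmEnrichment:
    def test_hand_computed_four_serine_protein(self):
        proteome = Proteome()
        protein = proteome.add_protein("P1", "SSSS")
        protein.add_domain(1, 2, "IDR")
        protein.add_track("accessibility", values=[1, 1, 1, 1])
        protein.add_site(1, "phospho", "S")
        result = ptm_enrichment(proteome, "phospho", "S",
                                accessibility_threshold=0.5)
        assert result.n_target_idr == 2 and result.n_modified_idr == 1
        assert result.n_target_folded_accessible == 2
        assert result.n_modified_folded_accessible == 0
        assert result.fraction_idr == pytest.approx(0.5)
        assert result.fraction_folded_accessible == pytest.approx(0.0)

    def test_single_modified_residue_per_stratum_gives_unit_ratio(self):
        proteome = Proteome()
        protein = proteome.add_protein("P1", "SSSS")
        protein.add_domain(1, 2, "IDR")
        protein.add_track("accessibility", values=[1, 1, 1, 1])
        protein.add_site(1, "phospho", "S")
        protein.add_site(3, "phospho", "S")
        result = ptm_enrichment(proteome, "phospho", "S",
                                accessibility_threshold=0.5)
        assert result.fraction_idr == pytest.approx(0.5)
        assert result.fraction_folded_accessible == pytest.approx(0.5)
        assert result.ratio == pytest.approx(1.0)

    def test_inaccessible_folded_stratum_is_undefined(self):
        proteome = Proteome()
        protein = proteome.add_protein("P1", "SSSS")
        protein.add_domain(1, 2, "IDR")
        protein.add_track("accessibility", values=[1, 1, 0, 0])
        protein.add_site(1, "phospho", "S")
        result = ptm_enrichment(proteome, "phospho", "S",
                                accessibility_threshold=0.5)
        assert result.n_target_folded_accessible == 0
        assert result.fraction_folded_accessible is None
        assert result.ratio is None

    def test_proteins_without_track_are_skipped_and_tallied(self):
        proteome = Proteome()
        proteome.add_protein("P1", "SSSS")
        p2 = proteome.add_protein("P2", "SS")
        p2.add_track("accessibility", values=[1, 1])
        result = ptm_enrichment(proteome, "phospho", "S")
        assert result.n_skipped_proteins == 1
        assert result.n_proteins == 1

    def test_counts_match_brute_force_scan(self, rng):
        for _ in range(5):
            proteome = random_proteome(rng, n_proteins=10, max_sites=15)
            result = ptm_enrichment(proteome, "phospho", "S",
                                    idr_domain_type="IDR",
                                    accessibility_track="rsa",
                                    accessibility_threshold=0.5)
            expected = brute_force_enrichment(
                proteome, "phospho", "S", "IDR", "rsa", 0.5)
            assert result.n_target_idr == expected["ti"]
            assert result.n_modified_idr == expected["mi"]
            assert result.n_target_folded_accessible == expected["tf"]
            assert result.n_modified_folded_accessible == expected["mf"]

    def test_raising_threshold_never_grows_folded_denominator(self, rng):
        proteome = random_proteome(rng, n_proteins=10)
        last = None
        for threshold in (0.0, 0.25, 0.5, 0.75, 1.0):
            result = ptm_enrichment(proteome, "phospho", "S",
                                    accessibility_track="rsa",
                                    accessibility_threshold=threshold)
            if last is not None:
                assert result.n_target_folded_accessible <= last
            last = result.n_target_folded_accessible

    def test_planted_probabilities_recovered(self):
        spec = SyntheticSpec(n_proteins=400, seed=101)
        proteome = generate(spec).proteome
        result = ptm_enrichment(proteome, spec.site_type, spec.target_residue,
                                spec.idr_domain_type,
                                accessibility_track=spec.accessibility_track)
        for fraction, p, n in [
            (result.fraction_idr, spec.p_idr, result.n_target_idr),
            (result.fraction_folded_accessible, spec.p_folded,
             result.n_target_folded_accessible),
        ]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(fraction - p) < 3 * se
        assert result.ratio > 1


def build_candidates(fractions, residue_for_fraction="F", filler="G",
                     length=10):
    """One protein per candidate domain whose aromatic fraction is as given
    and whose charged+aliphatic fraction is 0."""
    proteome = Proteome()
    for i, f in enumerate(fractions):
        k = round(f * length)
        seq = residue_for_fraction * k + filler * (length - k)
        protein = proteome.add_protein(f"C{i:03d}", seq)
        protein.add_domain(1, length, "IDR")
    return proteome


class TestChemistrySelect:
    def test_top_20_percent_of_ten_graded_candidates(self):
        proteome = build_candidates([i / 10 for i in range(10)])
        sel = chemistry_select(proteome, "IDR", "aromatic",
                               ["charged", "aliphatic"], min_length=1)
        assert sel.candidate_count == 10
        selected_fracs = sorted(
            fraction_of_class(d, "aromatic") for _, d in sel.selected
        )
        assert selected_fracs == pytest.approx([0.8, 0.9])

    def test_no_depletion_filter_equals_pure_top_cut(self):
        proteome = build_candidates([i / 10 for i in range(10)])
        sel = chemistry_select(proteome, "IDR", "aromatic", ["charged"],
                               deplete_percentile=100, min_length=1)
        top_only = chemistry_select(proteome, "IDR", "aromatic", [],
                                    min_length=1)
        assert [d for _, d in sel.selected] == [d for _, d in top_only.selected]

    def test_degenerate_percentiles(self):
        proteome = build_candidates([i / 10 for i in range(10)])
        everything = chemistry_select(proteome, "IDR", "aromatic", ["charged"],
                                      enrich_percentile=100,
                                      deplete_percentile=100, min_length=1)
        assert len(everything) == 10
        tied_max = chemistry_select(proteome, "IDR", "aromatic", [],
                                    enrich_percentile=0, min_length=1)
        assert [fraction_of_class(d, "aromatic") for _, d in tied_max.selected] \
            == pytest.approx([0.9])

    def test_min_length_filters_candidates(self):
        proteome = Proteome()
        p = proteome.add_protein("P1", "F" * 40)
        p.add_domain(1, 10, "IDR")
        p.add_domain(11, 40, "IDR")
        sel = chemistry_select(proteome, "IDR", "aromatic", min_length=30)
        assert sel.candidate_count == 1

    def test_few_candidates_warns(self):
        proteome = build_candidates([0.1, 0.9])
        sel = chemistry_select(proteome, "IDR", "aromatic", min_length=1)
        assert sel.warnings

    def test_zero_candidates_empty_selection(self):
        sel = chemistry_select(Proteome(), "IDR", "aromatic")
        assert len(sel) == 0 and sel.candidate_count == 0

    def test_matches_brute_force_double_threshold_scan(self, rng):
        proteome = random_proteome(rng, n_proteins=60, min_len=20, max_len=60,
                                   max_domains=4, with_tracks=False)
        sel = chemistry_select(proteome, "IDR", "aromatic",
                               ["charged", "aliphatic"],
                               enrich_percentile=30, deplete_percentile=40,
                               min_length=5)
        # independent scan: explicit sort-based nearest-rank thresholds
        candidates = [
            (p.unique_id, d) for p in proteome
            for d in p.domains
            if d.domain_type == "IDR" and len(d) >= 5
        ]
        fe = [fraction_of_class(d, "aromatic") for _, d in candidates]
        fd = [fraction_of_classes(d, ["charged", "aliphatic"])
              for _, d in candidates]
        n = len(candidates)
        k = max(1, int(np.ceil(0.30 * n)))
        m = max(1, int(np.ceil(0.40 * n)))
        thr_e = sorted(fe, reverse=True)[k - 1]
        thr_d = sorted(fd)[m - 1]
        expected = [
            (uid, d) for (uid, d), e, dd in zip(candidates, fe, fd)
            if e >= thr_e and dd <= thr_d
        ]
        assert sel.selected == expected


class TestTailPercentile:
    def test_nearest_rank_examples(self):
        values = [i / 10 for i in range(10)]
        assert tail_percentile_threshold(values, 20, "upper") == 0.8
        assert tail_percentile_threshold(values, 5, "lower") == 0.0
        assert tail_percentile_threshold(values, 100, "upper") == 0.0
        assert tail_percentile_threshold(values, 0, "upper") == 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            tail_percentile_threshold([], 20, "upper")


class TestRkIdrSplit:
    def test_pure_r_and_k_idrs_land_in_exactly_one_list(self):
        proteome = Proteome()
        p1 = proteome.add_protein("P1", "RRRRRR")
        p1.add_domain(1, 6, "IDR")
        p2 = proteome.add_protein("P2", "KKKKKK")
        p2.add_domain(1, 6, "IDR")
        arg, lys = rk_idr_split(proteome, enrich_percentile=50,
                                deplete_percentile=50, min_length=1)
        assert [uid for uid, _ in arg.selected] == ["P1"]
        assert [uid for uid, _ in lys.selected] == ["P2"]

    def test_mixed_rk_idr_appears_in_both_under_permissive_thresholds(self):
        proteome = Proteome()
        p = proteome.add_protein("P1", "RKRKRK")
        p.add_domain(1, 6, "IDR")
        arg, lys = rk_idr_split(proteome, enrich_percentile=100,
                                deplete_percentile=100, min_length=1)
        assert [uid for uid, _ in arg.selected] == ["P1"]
        assert [uid for uid, _ in lys.selected] == ["P1"]

    def test_matches_single_residue_chemistry_select(self, rng):
        proteome = random_proteome(rng, n_proteins=40, min_len=20,
                                   with_tracks=False)
        arg, lys = rk_idr_split(proteome, enrich_percentile=40, min_length=5)
        direct = chemistry_select(
            proteome, "IDR", ResidueClass("arginine", "R"),
            [ResidueClass("lysine", "K")],
            enrich_percentile=40, deplete_percentile=100, min_length=5)
        assert arg.selected == direct.selected


def tiny_abundance_proteome(disorders, abundances, length=10):
    proteome = Proteome()
    for i, (f, a) in enumerate(zip(disorders, abundances)):
        protein = proteome.add_protein(f"P{i}", "KGKGKGKGKG"[:length])
        covered = round(f * length)
        if covered:
            protein.add_domain(1, covered, "IDR")
        protein.attributes["abundance"] = str(a)
    return proteome


class TestAbundanceDisorder:
    def test_perfect_anti_ranking(self):
        proteome = tiny_abundance_proteome([0.9, 0.5, 0.1], [1, 10, 100])
        result = abundance_disorder(proteome)
        assert result.disorder_correlation == pytest.approx(-1.0)

    def test_equal_abundances_flagged_not_raised(self):
        proteome = tiny_abundance_proteome([0.9, 0.5, 0.1], [7, 7, 7])
        result = abundance_disorder(proteome)
        assert result.disorder_correlation is None
        assert any("disorder" in f for f in result.flags)

    def test_insufficient_data(self):
        proteome = tiny_abundance_proteome([0.9, 0.5], [1, 10])
        with pytest.raises(InsufficientDataError):
            abundance_disorder(proteome)

    def test_missing_and_nonpositive_abundances_skipped(self):
        proteome = tiny_abundance_proteome([0.9, 0.7, 0.5, 0.3, 0.1],
                                           [1, 10, 100, 1000, 10000])
        proteome.protein("P0").attributes["abundance"] = "-5"
        del proteome.protein("P1").attributes["abundance"]
        result = abundance_disorder(proteome)
        assert result.n_skipped == 2 and result.n_proteins == 3

    def test_invariant_to_monotone_transform_of_abundance(self, rng):
        disorders = rng.random(30)
        abundances = 10 ** rng.normal(2, 1, size=30)
        p1 = tiny_abundance_proteome(disorders, abundances)
        p2 = tiny_abundance_proteome(disorders, abundances ** 3 * 7)
        r1 = abundance_disorder(p1)
        r2 = abundance_disorder(p2)
        assert r1.disorder_correlation == pytest.approx(r2.disorder_correlation)

    def test_log_transform_flag_does_not_change_rank_statistic(self, rng):
        disorders = rng.random(20)
        abundances = 10 ** rng.normal(2, 1, size=20)
        proteome = tiny_abundance_proteome(disorders, abundances)
        r_log = abundance_disorder(proteome, log_transform=True)
        r_raw = abundance_disorder(proteome, log_transform=False)
        assert r_log.disorder_correlation == pytest.approx(r_raw.disorder_correlation)

    def test_bins_partition_the_proteins(self, rng):
        disorders = rng.random(50)
        abundances = 10 ** rng.normal(2, 1, size=50)
        result = abundance_disorder(tiny_abundance_proteome(disorders, abundances))
        assert result.binned["n"].sum() == result.n_proteins

    def test_planted_rank_correlation_recovered(self):
        spec = SyntheticSpec(n_proteins=2000, seed=7)
        proteome = generate(spec).proteome
        result = abundance_disorder(proteome, idr_domain_type=spec.idr_domain_type)
        assert result.disorder_correlation < 0
        assert abs(result.disorder_correlation - (-0.5)) < 0.08

    def test_idr_charge_weighting_is_length_weighted(self):
        proteome = Proteome()
        # IDR1 "KKKK" charged fraction 1 (len 4); IDR2 "GGGGGGGG" 0 (len 8)
        protein = proteome.add_protein("P1", "KKKKGGGGGGGG")
        protein.add_domain(1, 4, "IDR")
        protein.add_domain(5, 12, "IDR")
        protein.attributes["abundance"] = "10"
        for i, a in enumerate((1, 100)):
            q = proteome.add_protein(f"Q{i}", "KGKGKG")
            q.add_domain(1, 6, "IDR")
            q.attributes["abundance"] = str(a)
        result = abundance_disorder(proteome)
        assert result.n_proteins_with_idr == 3
        # P1's IDR charge must be the length-weighted (1*4 + 0*8)/12, which
        # shows up in the bin containing P1 (abundance 10, middle rank)
        mid_bin = result.binned.sort_values("mean_abundance").iloc[1]
        assert mid_bin["mean_idr_charged_fraction"] == pytest.approx(4 / 12)
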