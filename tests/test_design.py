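"""Candidate enumeration, scoring, filtering, tiling and mismatch controls."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phageaso import (
    DesignConfig,
    apply_filters,
    design_asos,
    enumerate_candidates,
    extract_tir,
    make_mismatch_control,
    purine_fraction,
    revcomp,
    self_complementarity,
    tile_window,
)
from phageaso.design import score_candidates
from phageaso.genome_io import TirWindow
from phageaso.offtarget import count_offtarget_tirs

from conftest import CONTROL_ASO


def brute_selfcomp(seq: str) -> int:
    """O(L^4) oracle: longest substring whose revcomp occurs in seq."""
    best = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if revcomp(seq[i:j]) in seq:
                best = max(best, j - i)
    return best


class TestEnumerate:
    def test_wide_window_gives_71_11mers(self, small_genome):
        genome, _ = small_genome
        tir = extract_tir(genome, "SYN_0003", -37, 44)
        cands = enumerate_candidates(tir, 11)
        assert len(cands) == 71
        for c in cands:
            assert c.aso_seq == revcomp(c.target_site_seq)

    def test_window_equal_to_length_gives_single_candidate(self):
        tir = TirWindow(gene="g", seq="ACAATTATGTC", offset_from=-8, offset_to=3)
        (cand,) = enumerate_candidates(tir, 11)
        assert cand.target_site_seq == tir.seq
        assert (cand.site_from, cand.site_to) == (-8, 3)

    def test_control_sequence_is_revcomp_of_its_site(self):
        tir = TirWindow(gene="g", seq="ACAATTATGTC", offset_from=-8, offset_to=3)
        (cand,) = enumerate_candidates(tir, 11)
        assert cand.aso_seq == CONTROL_ASO

    def test_short_window_warns_and_returns_empty(self):
        tir = TirWindow(gene="g", seq="ACAATT", offset_from=-6, offset_to=-1)
        with pytest.warns(UserWarning, match="shorter"):
            assert enumerate_candidates(tir, 11) == []

    def test_antisense_identity_over_all_sites(self, small_genome):
        """revcomp(aso_seq) occurs in the TIR exactly at the recorded offsets."""
        genome, _ = small_genome
        tir = extract_tir(genome, "SYN_0001", -30, 15)
        offs = tir.offsets()
        for c in enumerate_candidates(tir, 11):
            i = offs.index(c.site_from)
            assert tir.seq[i : i + 11] == revcomp(c.aso_seq)
            assert offs[i + 10] == c.site_to


class TestPurineFraction:
    def test_printed_control_is_6_elevenths(self):
        assert purine_fraction(CONTROL_ASO) == pytest.approx(6 / 11)

    @pytest.mark.parametrize("seq,expected", [("CCCC", 0.0), ("AGAGAG", 1.0)])
    def test_extremes(self, seq, expected):
        assert purine_fraction(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            purine_fraction("")


class TestSelfComplementarity:
    def test_palindrome_scores_full_length(self):
        assert self_complementarity("GAATTC") == 6

    def test_homopolymer_scores_zero(self):
        assert self_complementarity("AAAAAAAAAAA") == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=11))
        assert self_complementarity(seq) == brute_selfcomp(seq)


class TestApplyFilters:
    def test_all_bounds_satisfied_passes(self):
        cand = _scored_stub(tm=50.0, purine=0.27, selfcomp=4, cum2=0)
        (out,) = apply_filters([cand])
        assert out.passes and out.rank == 1 and out.fail_reasons == ()

    def test_hot_tm_fails(self):
        cand = _scored_stub(tm=60.0, purine=0.27, selfcomp=4, cum2=0)
        (out,) = apply_filters([cand])
        assert not out.passes and "tm" in out.fail_reasons

    def test_printed_control_fails_purine_filter(self):
        """The non-targeting control oligomer violates the 25-35% purine rule."""
        cand = _scored_stub(tm=50.0, purine=purine_fraction(CONTROL_ASO),
                            selfcomp=4, cum2=0)
        (out,) = apply_filters([cand])
        assert not out.passes and "purine" in out.fail_reasons

    def test_offtarget_rule_is_strictly_less_than(self):
        ok = _scored_stub(tm=50.0, purine=0.30, selfcomp=3, cum2=2)
        bad = _scored_stub(tm=50.0, purine=0.30, selfcomp=3, cum2=3)
        out = apply_filters([ok, bad])
        assert [c.passes for c in out] == [True, False]

    def test_idempotent(self, design_genome):
        genome, _ = design_genome
        df1 = design_asos(genome, genes=["SYN_0001", "SYN_0002"])
        df2 = design_asos(genome, genes=["SYN_0001", "SYN_0002"])
        assert df1.equals(df2)

    def test_pass_set_equals_brute_force_predicate(self, design_genome):
        """Filter verdicts match an independent re-evaluation of the rule."""
        from phageaso.genome_io import extract_all_tirs

        genome, _ = design_genome
        cfg = DesignConfig()
        tirs = extract_all_tirs(genome, cfg.window_from, cfg.window_to)
        tir_sets = [(genome.id, tirs)]
        tir = extract_tir(genome, "SYN_0005", cfg.window_from, cfg.window_to)
        cands = score_candidates(enumerate_candidates(tir, cfg.length), cfg)
        for c in cands:
            c.offtargets = count_offtarget_tirs(
                c.target_site_seq, c.gene, tir_sets, cfg.report_mm
            )
        ranked = apply_filters(cands, cfg)
        for c in ranked:
            expected = (
                cfg.tm_min <= c.tm_c <= cfg.tm_max
                and cfg.purine_min <= c.purine_frac <= cfg.purine_max
                and c.selfcomp <= cfg.selfcomp_max
                and int(c.offtargets.cumulative_by_mm[cfg.offtarget_criterion_mm])
                < cfg.max_offtarget_tirs
            )
            assert c.passes == expected

    def test_deterministic_tsv_output(self, design_genome):
        genome, _ = design_genome
        a = design_asos(genome, genes=["SYN_0004"]).to_csv(sep="\t", index=False)
        b = design_asos(genome, genes=["SYN_0004"]).to_csv(sep="\t", index=False)
        assert a == b


class TestTileWindow:
    def test_default_tiling_yields_71_scored_candidates(self, small_genome):
        genome, _ = small_genome
        cands = tile_window(genome, "SYN_0004")
        assert len(cands) == 71
        assert all(c.tm_c is not None and c.purine_frac is not None for c in cands)
        assert all(c.passes is None for c in cands)  # tiling is unfiltered

    def test_empirical_tm_band_subset(self, small_genome):
        """Post-hoc Tm filtering of the tiled set (35-58 band) is a subset."""
        genome, _ = small_genome
        cands = tile_window(genome, "SYN_0004")
        band = [c for c in cands if 35.0 <= c.tm_c <= 58.0]
        assert set(c.aso_seq for c in band) <= set(c.aso_seq for c in cands)

    def test_single_candidate_over_start_codon(self, small_genome):
        genome, _ = small_genome
        (cand,) = tile_window(genome, "SYN_0004", offset_from=1, offset_to=11)
        assert cand.target_site_seq.startswith("ATG")
        assert (cand.site_from, cand.site_to) == (1, 11)


class TestMismatchControl:
    def test_two_central_mismatches_on_11mer(self):
        ctl = make_mismatch_control(CONTROL_ASO, 2)
        diff = [i + 1 for i, (a, b) in enumerate(zip(CONTROL_ASO, ctl)) if a != b]
        assert len(diff) == 2
        assert set(diff) <= {5, 6, 7}

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_hamming_distance_exactly_k(self, k):
        ctl = make_mismatch_control(CONTROL_ASO, k)
        assert sum(a != b for a, b in zip(CONTROL_ASO, ctl)) == k

    @pytest.mark.parametrize("k", [0, 10])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            make_mismatch_control(CONTROL_ASO, k)

    def test_control_never_perfectly_matches_target_tir(self, small_genome):
        """The k=2 control of each tiled candidate has no exact site in the TIR."""
        genome, _ = small_genome
        tir = extract_tir(genome, "SYN_0001", -37, 44)
        for cand in tile_window(genome, "SYN_0001"):
            ctl_site = revcomp(make_mismatch_control(cand, 2))
            assert ctl_site not in tir.seq


class TestDesignPipeline:
    def test_under_designed_flag_consistent(self, design_genome):
        genome, _ = design_genome
        df = design_asos(genome, genes=["SYN_0001", "SYN_0002", "SYN_0003"])
        for gene, grp in df.groupby("gene"):
            n_pass = int(grp["passes"].sum())
            assert grp["under_designed"].iloc[0] == (n_pass < 2)

    def test_frame_has_offtarget_columns(self, design_genome):
        genome, _ = design_genome
        df = design_asos(genome, genes=["SYN_0001"])
        for m in range(5):
            assert f"ot_mm{m}" in df.columns and f"cum_mm{m}" in df.columns


def _scored_stub(tm, purine, selfcomp, cum2):
    """A minimal scored candidate with an injected off-target profile."""
    from phageaso.offtarget import OffTargetProfile

    cand_site = "ACAATTATGTC"
    from phageaso.design import AsoCandidate

    c = AsoCandidate(
        gene="stub",
        target_site_seq=cand_site,
        site_from=-8,
        site_to=3,
        aso_seq=revcomp(cand_site),
        tm_c=tm,
        purine_frac=purine,
        selfcomp=selfcomp,
    )
    prof = OffTargetProfile(query_gene="stub", report_mm=4)
    counts = np.zeros(5, dtype=int)
    counts[2] = cum2  # all mass at exactly 2 mismatches
    prof.per_genome["x"] = counts
    c.offtargets = prof
    return c
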