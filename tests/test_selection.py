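"""Fusion-ORF rule and ampicillin survival model."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from orfsieve import (Clone, Fragment, Library, SelectionParams, clone_mic,
                      is_fusion_orf, select_library, survival_probability)
from orfsieve.selection import survival_sweep


def make_clone(insert="GCTGCAGCT", quality=0.5, orf=None, leader="Sec"):
    orf = is_fusion_orf(insert) if orf is None else orf
    frag = Fragment("g", 0, len(insert), "+")
    return Clone(frag, insert, leader, quality, orf)


class TestFusionOrfRule:
    @pytest.mark.parametrize(
        "insert,expected",
        [
            ("GCTGCAGCT", True),       # 9 nt, stop-free
            ("GCTTAAGCT", False),      # TAA at codon 2
            ("GCTGCAG", False),        # length 7 breaks the lactamase frame
            ("GCTTGAGCT", False),      # TGA stop
        ],
    )
    def test_stated_examples(self, insert, expected):
        assert is_fusion_orf(insert) is expected

    def test_amber_suppression_reads_through_tag_only(self):
        assert not is_fusion_orf("GCTTAGGCT")
        assert is_fusion_orf("GCTTAGGCT", amber_suppression=True)
        assert not is_fusion_orf("GCTTAAGCT", amber_suppression=True)
        assert not is_fusion_orf("GCTTGAGCT", amber_suppression=True)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            is_fusion_orf("GCTNNNGCT")
        with pytest.raises(ValueError):
            is_fusion_orf("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_agrees_with_bruteforce_codon_scan(self, insert):
        brute = len(insert) % 3 == 0 and all(
            insert[i : i + 3] not in ("TAA", "TAG", "TGA")
            for i in range(0, len(insert), 3)
        )
        assert is_fusion_orf(insert) is brute
        if len(insert) % 3 == 0:  # biopython translation as independent route
            assert brute is ("*" not in str(Seq(insert).translate()))

    def test_random_insert_acceptance_matches_closed_form(self, rng):
        # fixed 300 nt inserts: acceptance = P(100 codons stop-free) = (61/64)^100
        n, n_codons = 120_000, 100
        codes = rng.integers(0, 4, size=(n, 3 * n_codons))
        inserts = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
        hits = sum(
            is_fusion_orf(inserts[i * 300 : (i + 1) * 300]) for i in range(n)
        )
        expect = (61 / 64) ** n_codons
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(hits / n - expect) < 4 * se

    def test_length_must_be_multiple_of_three(self, rng):
        # the 1/3 frame-compatibility factor: off-length inserts never pass
        for L in (299, 301):
            insert = "".join(rng.choice(list("ACGT"), size=L))
            assert not is_fusion_orf(insert)


class TestSurvivalModel:
    def test_clone_mic_boundaries(self):
        p = SelectionParams()
        assert clone_mic(make_clone(quality=0.0, orf=True), p) == p.mic_base
        assert clone_mic(make_clone(quality=1.0, orf=True), p) == p.mic_max
        assert clone_mic(make_clone(quality=0.9, orf=False), p) == p.mic_nonorf

    def test_mic_monotone_in_quality(self):
        p = SelectionParams()
        mics = [clone_mic(make_clone(quality=q, orf=True), p)
                for q in np.linspace(0, 1, 11)]
        assert all(a <= b for a, b in zip(mics, mics[1:]))

    def test_survival_is_one_on_chloramphenicol_only(self):
        clone = make_clone(quality=0.0, orf=False)
        assert survival_probability(clone, 0.0, SelectionParams()) == 1.0

    def test_survival_half_at_mic(self):
        p = SelectionParams()
        clone = make_clone(quality=0.5, orf=True)
        assert survival_probability(clone, clone_mic(clone, p), p) == pytest.approx(0.5)

    def test_survival_monotone_nonincreasing_in_amp(self):
        p = SelectionParams()
        clone = make_clone(quality=0.7, orf=True)
        probs = [survival_probability(clone, a, p)
                 for a in (0, 0.25, 0.5, 1, 2.5, 5, 10, 25, 50, 100)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SelectionParams(mic_nonorf=0.0)
        with pytest.raises(ValueError):
            SelectionParams(logistic_slope=-1.0)
        with pytest.raises(ValueError):
            survival_probability(make_clone(), -1.0, SelectionParams())


class TestSelectLibrary:
    def _library(self, n, rng, orf_quality=None):
        clones = []
        for i in range(n):
            q = float(rng.random()) if orf_quality is None else orf_quality
            orf = bool(rng.random() < 0.5)
            clones.append(make_clone(quality=q, orf=orf))
        return Library("Sec", tuple(clones))

    def test_everyone_survives_at_amp_zero(self, rng):
        lib = self._library(500, rng)
        survivors, rate = select_library(lib, 0.0, rng=rng)
        assert rate == 1.0 and len(survivors) == len(lib)

    def test_nobody_survives_far_above_mic_max(self, rng):
        params = SelectionParams(mic_max=10.0, logistic_slope=8.0)
        lib = self._library(500, rng)
        _, rate = select_library(lib, 10_000.0, params, rng)
        assert rate < 0.01

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            select_library(Library("Sec", ()), 1.0, rng=rng)

    def test_survival_rate_definition(self, rng):
        lib = self._library(400, rng)
        survivors, rate = select_library(lib, 5.0, rng=rng)
        assert rate == len(survivors) / len(lib)


class TestGenicEnrichment:
    def test_stop_mechanics_alone_enrich_genic_and_grow_with_length(
        self, medium_genome, rng
    ):
        """ORF filtering with no folding model already enriches genic frames
        above the 1/6 chance level, more strongly for longer fragments."""
        from orfsieve import LengthDistribution, draw_fragments
        from orfsieve.classification import MappedRead, ReadClass, classify_read
        from orfsieve.fragmentation import insert_sequence

        genome, genes = medium_genome
        genes = sorted(genes, key=lambda g: g.start)

        def genic_fraction_among_orfs(L, n=6_000):
            dist = LengthDistribution(min=L, max=L, mean=L, shape="uniform")
            counts = {"genic": 0, "orf": 0}
            for f in draw_fragments(genome, n, dist, rng):
                if not is_fusion_orf(insert_sequence(f, genome)):
                    continue
                counts["orf"] += 1
                hit = MappedRead("", f.start, f.end, f.cloned_strand)
                cls, _ = classify_read(hit, genes, genome)
                counts["genic"] += cls is ReadClass.GENIC_ORF
            return counts["genic"] / counts["orf"]

        short, long = genic_fraction_among_orfs(99), genic_fraction_among_orfs(600)
        assert short > 1 / 6
        assert long > short

    def test_genic_fraction_among_survivors_nondecreasing_in_amp(
        self, medium_genome
    ):
        from orfsieve.config import RunConfig
        from orfsieve.pipeline import build_library
        from orfsieve.classification import MappedRead, ReadClass, classify_read

        genome, genes = medium_genome
        genes = sorted(genes, key=lambda g: g.start)
        cfg = RunConfig(seed=42, n_clones=20_000)
        lib = build_library(genome, genes, "Sec", cfg, np.random.default_rng(42))

        def is_genic(clone):
            if not clone.fusion_orf:
                return False
            hit = MappedRead("", clone.fragment.start, clone.fragment.end,
                             clone.fragment.cloned_strand)
            return classify_read(hit, genes, genome)[0] is ReadClass.GENIC_ORF

        fracs = []
        for amp in (0.0, 2.5, 25.0, 100.0):
            survivors, _ = select_library(lib, amp, cfg.selection,
                                          np.random.default_rng(7))
            fracs.append(np.mean([is_genic(c) for c in survivors.clones]))
        # allow a small Monte-Carlo wobble between adjacent concentrations
        assert all(b >= a - 0.02 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]

    def test_sweep_survival_nonincreasing(self, rng):
        clones = tuple(make_clone(quality=float(rng.random()),
                                  orf=bool(rng.random() < 0.3))
                       for _ in range(2_000))
        lib = Library("Sec", clones)
        sweep = survival_sweep(lib, (0, 0.25, 1, 5, 25, 100), rng=rng)
        rates = [r for _, r in sweep]
        assert rates[0] == 1.0
        assert all(b <= a + 0.02 for a, b in zip(rates, rates[1:]))
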