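"""Hit parsing, partial-domain merging and overlap resolution."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tryptome import hit_processing as hp

CFG = hp.PipelineConfig()


def make_hit(
    protein="P1",
    family="Trypsin",
    ali=(10, 60),
    hmm=(1, 110),
    i_evalue=1e-10,
    full_evalue=1e-10,
):
    return hp.DomainHit(
        protein_id=protein,
        family=family,
        accession="-",
        ali_start=ali[0],
        ali_end=ali[1],
        hmm_start=hmm[0],
        hmm_end=hmm[1],
        i_evalue=i_evalue,
        full_evalue=full_evalue,
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

DOMTBL_TEXT = """\
# comment line
#
# another comment
Trypsin PF00089.29 220 P0001 - 400 1e-20 150.0 0.1 1 2 1e-18 1e-18 120.0 0.1 1 110 10 60 8 62 0.95 synthetic
ShK - 35 P0001 - 400 1e-08 50.0 0.1 2 2 0.01 0.01 40.0 0.1 1 35 200 234 198 236 0.90 synthetic
"""


class TestParsing:
    def test_comments_skipped_and_fields_mapped(self, tmp_path):
        f = tmp_path / "t.domtblout"
        f.write_text(DOMTBL_TEXT)
        hits = hp.parse_domtblout(f)
        assert len(hits) == 2
        first = hits[0]
        assert (first.protein_id, first.family) == ("P0001", "Trypsin")
        assert (first.ali_start, first.ali_end) == (10, 60)
        assert (first.hmm_start, first.hmm_end) == (1, 110)
        assert first.full_evalue == pytest.approx(1e-20)
        assert first.i_evalue == pytest.approx(1e-18)

    def test_empty_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "empty.domtblout"
        f.write_text("# only comments\n")
        assert hp.parse_domtblout(f) == []

    def test_malformed_row_names_line_number(self, tmp_path):
        f = tmp_path / "bad.domtblout"
        f.write_text("# header\nTrypsin PF00089 220 P1 short row\n")
        with pytest.raises(hp.DomtbloutParseError, match="line 2"):
            hp.parse_domtblout(f)

    def test_generator_round_trip(self, hit_bundle):
        """Re-parsing the generator's table preserves every field and row order."""
        path, _truth = hit_bundle
        hits = hp.parse_domtblout(path)
        assert hits  # nonempty
        # every hit satisfies the format invariants verbatim
        for h in hits:
            assert h.ali_start <= h.ali_end and h.hmm_start <= h.hmm_end

    def test_searchio_oracle_agrees(self, hit_bundle):
        """Independent reader (Bio.SearchIO hmmscan domtab) sees the same hits."""
        from Bio import SearchIO

        path, _ = hit_bundle
        ours = hp.parse_domtblout(path)
        theirs = []
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    theirs.append(
                        (
                            qresult.id,
                            hit.id,
                            hsp.query_start + 1,  # SearchIO is 0-based half-open
                            hsp.query_end,
                            float(hsp.evalue),
                            float(hit.evalue),
                        )
                    )
        mine = [
            (h.protein_id, h.family, h.ali_start, h.ali_end, h.i_evalue, h.full_evalue)
            for h in ours
        ]
        assert sorted(mine) == sorted(theirs)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

class TestSelection:
    def test_full_evalue_threshold_boundary(self):
        hits = [
            make_hit(protein="A", full_evalue=1e-06),
            make_hit(protein="B", full_evalue=1e-04),
        ]
        assert hp.select_trypsin_proteins(hits, CFG) == {"A"}

    def test_exclusion_list_removes_passing_protein(self):
        hits = [make_hit(protein="A", full_evalue=1e-08)]
        cfg = hp.with_exclusions(CFG, {"A"})
        assert hp.select_trypsin_proteins(hits, cfg) == set()

    def test_non_trypsin_hits_never_select(self):
        hits = [make_hit(protein="A", family="ShK", full_evalue=1e-30)]
        assert hp.select_trypsin_proteins(hits, CFG) == set()

    def test_planted_truth_recovery(self, hit_bundle):
        """All planted trypsin proteins selected; no above-threshold decoy is."""
        path, truth = hit_bundle
        hits = hp.parse_domtblout(path)
        selected = hp.select_trypsin_proteins(hits, CFG)
        assert selected == set(truth)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMerging:
    def test_two_complementary_partials_merge(self):
        """Two non-overlapping partial trypsin hits become one contiguous domain."""
        hits = [
            make_hit(ali=(10, 60), hmm=(1, 110), i_evalue=1e-12),
            make_hit(ali=(80, 130), hmm=(120, 230), i_evalue=1e-09),
        ]
        placed = hp.merge_partial_domains(hits, CFG)["P1"]
        assert len(placed) == 1
        d = placed[0]
        assert (d.start, d.end, d.merged_from) == (10, 130, 2)
        assert d.i_evalue == pytest.approx(1e-12)

    def test_single_hit_unchanged(self):
        placed = hp.merge_partial_domains([make_hit()], CFG)["P1"]
        assert len(placed) == 1 and placed[0].merged_from == 1

    def test_nested_profile_coords_do_not_merge(self):
        # second hit covers a subset of the profile: redundant, not partial
        hits = [
            make_hit(ali=(10, 60), hmm=(1, 110)),
            make_hit(ali=(80, 130), hmm=(20, 100)),
        ]
        placed = hp.merge_partial_domains(hits, CFG)["P1"]
        assert len(placed) == 2

    def test_overlapping_protein_coords_do_not_merge(self):
        hits = [
            make_hit(ali=(10, 90), hmm=(1, 110)),
            make_hit(ali=(85, 130), hmm=(120, 230)),
        ]
        placed = hp.merge_partial_domains(hits, CFG)["P1"]
        assert len(placed) == 2

    def test_three_partials_against_exhaustive_oracle(self):
        """Chained merging agrees with exhaustively checking the complementarity
        predicate over all orderings of three planted partials."""
        parts = [
            make_hit(ali=(5, 50), hmm=(1, 70), i_evalue=1e-8),
            make_hit(ali=(60, 110), hmm=(80, 150), i_evalue=1e-11),
            make_hit(ali=(120, 170), hmm=(160, 225), i_evalue=1e-6),
        ]
        # oracle: all consecutive pairs in ali order must be complementary
        ordered = sorted(parts, key=lambda h: h.ali_start)
        assert all(
            hp._complementary(a, b) for a, b in zip(ordered, ordered[1:])
        )
        for perm in itertools.permutations(parts):
            placed = hp.merge_partial_domains(list(perm), CFG)["P1"]
            assert len(placed) == 1
            assert (placed[0].start, placed[0].end) == (5, 170)
            assert placed[0].merged_from == 3
            assert placed[0].i_evalue == pytest.approx(1e-11)


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def pd(family, start, end, ie):
    return hp.PlacedDomain(family=family, start=start, end=end, i_evalue=ie)


class TestOverlapResolution:
    def test_small_overlap_keeps_both(self):
        # 6 shared aa / 86 aa (shorter) ~ 7% <= 20%
        doms = [pd("A", 1, 100, 1e-10), pd("B", 95, 180, 1e-3)]
        assert len(hp.resolve_overlaps(doms, CFG)) == 2

    def test_large_overlap_drops_higher_evalue(self):
        # 51 shared aa / 71 aa ~ 72% > 20% -> B loses
        doms = [pd("A", 1, 100, 1e-10), pd("B", 50, 120, 1e-3)]
        kept = hp.resolve_overlaps(doms, CFG)
        assert [d.family for d in kept] == ["A"]

    def test_single_domain_identity(self):
        doms = [pd("A", 1, 100, 1e-10)]
        assert hp.resolve_overlaps(doms, CFG) == doms

    def test_zero_overlap_threshold_is_degenerate(self):
        cfg = hp.PipelineConfig(overlap_frac_max=1e-9)
        doms = [pd("A", 1, 100, 1e-10), pd("B", 100, 180, 1e-3)]
        assert len(hp.resolve_overlaps(doms, cfg)) == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ABCDEF"),
                st.integers(1, 200),
                st.integers(10, 120),
                st.floats(1e-20, 1e-2),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_resolution_properties(self, raw):
        """No surviving pair violates the overlap rule; idempotent; order-free."""
        doms = [pd(f, s, s + length, ie) for f, s, length, ie in raw]
        kept = hp.resolve_overlaps(doms, CFG)
        for a, b in itertools.combinations(kept, 2):
            assert hp.overlap_fraction(a, b) <= CFG.overlap_frac_max
        assert hp.resolve_overlaps(kept, CFG) == kept
        rng = random.Random(0)
        for _ in range(3):
            shuffled = doms[:]
            rng.shuffle(shuffled)
            assert hp.resolve_overlaps(shuffled, CFG) == kept


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

class TestBuildArchitectures:
    def test_associated_domain_ievalue_boundary(self):
        base = [make_hit(protein="P", ali=(1, 220), hmm=(1, 220))]
        passing = base + [
            make_hit(protein="P", family="ShK", ali=(300, 334), hmm=(1, 35), i_evalue=0.04)
        ]
        failing = base + [
            make_hit(protein="P", family="ShK", ali=(300, 334), hmm=(1, 35), i_evalue=0.06)
        ]
        assert hp.build_architectures(passing, CFG)[0].key == "Trypsin|ShK"
        assert hp.build_architectures(failing, CFG)[0].key == "Trypsin"

    def test_planted_architectures_recovered(self, hit_bundle):
        path, truth = hit_bundle
        archs = hp.build_architectures(hp.parse_domtblout(path), CFG)
        recovered = {a.protein_id: a.key for a in archs}
        assert recovered == truth

    def test_order_invariance_of_keys(self, hit_bundle):
        path, _ = hit_bundle
        hits = hp.parse_domtblout(path)
        baseline = {a.protein_id: a.key for a in hp.build_architectures(hits, CFG)}
        rng = random.Random(1)
        shuffled = hits[:]
        rng.shuffle(shuffled)
        assert {a.protein_id: a.key for a in hp.build_architectures(shuffled, CFG)} == baseline

    def test_architecture_key_regenerates_from_domains(self, hit_bundle):
        path, _ = hit_bundle
        for a in hp.build_architectures(hp.parse_domtblout(path), CFG):
            assert a.key == "|".join(d.family for d in a.domains)
            starts = [d.start for d in a.domains]
            assert starts == sorted(starts)
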