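"""PAM compilation, site enumeration, strand handling, scoring context."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_sites, random_records, revcomp

from minipam.genome_io import Genome
from minipam.pam_engine import (
    PAM_REGISTRY,
    PamSpec,
    compile_pam,
    enumerate_sites,
    extract_context,
    filter_gg_start,
    get_pam_spec,
)


def site_key(s):
    return (s.contig, s.start, s.strand, s.protospacer, s.pam)


class TestCompilePam:
    @pytest.mark.parametrize(
        "pattern,seq,expected",
        [
            ("NGN", "TGA", True),
            ("NGN", "TAA", False),
            ("NRN", "CAC", True),
            ("NRN", "CTC", False),
            ("NGG", "AGG", True),
            ("NGG", "ANG", False),  # genome N never matches pattern G
            ("NGG", "NGG", False),  # genome N never matches pattern N
            ("NGH", "TGA", True),
            ("NGH", "TGG", False),
            ("NAN", "CAT", True),
        ],
    )
    def test_matcher(self, pattern, seq, expected):
        assert compile_pam(pattern)(seq) is expected

    @given(
        pattern=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=4),
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_matcher_agrees_with_per_position_sets(self, pattern, seq):
        from conftest import IUPAC_SETS

        expected = len(seq) == len(pattern) and all(
            b in IUPAC_SETS[p] for b, p in zip(seq, pattern)
        )
        assert compile_pam(pattern)(seq) is expected

    def test_invalid_pattern_character(self):
        with pytest.raises(ValueError):
            compile_pam("NXG")

    def test_registry_contains_required_patterns(self):
        patterns = {spec.pam_pattern for spec in PAM_REGISTRY.values()}
        assert {"NGG", "NGN", "NRN", "NYN", "NNN", "NGH", "NAN"} <= patterns

    def test_get_pam_spec_by_name_pattern_or_custom(self):
        assert get_pam_spec("SpG").pam_pattern == "NGN"
        assert get_pam_spec("NRN").name == "SpRY"
        custom = get_pam_spec("TTTV")
        assert custom.pam_pattern == "TTTV"


class TestEnumerateSites:
    def test_brute_force_oracle_small_genome(self):
        g = Genome(records={"c": "AAAACGGTTT"})
        spec = PamSpec("toy", "NGG", spacer_length=2)
        got = {site_key(s) for s in enumerate_sites(g, spec, with_context=False)}
        assert got == naive_sites(g.records, "NGG", spacer_len=2)

    @pytest.mark.parametrize("pattern", ["NGG", "NGN", "NRN", "NNN", "NGH", "NAN"])
    def test_brute_force_oracle_random_genomes(self, rng, pattern):
        for _ in range(5):
            records = random_records(rng, n_contigs=2, length=400)
            g = Genome(records=records)
            spec = PamSpec("t", pattern)
            got = {site_key(s) for s in enumerate_sites(g, spec, with_context=False)}
            assert got == naive_sites(records, pattern)

    def test_closed_form_count_nnn(self, rng):
        L = 777
        records = random_records(rng, n_contigs=1, length=L)
        g = Genome(records=records)
        sites = enumerate_sites(g, PamSpec("nnn", "NNN"), with_context=False)
        assert len(sites) == 2 * max(0, L - 23 + 1)

    def test_empty_genome(self):
        assert enumerate_sites(Genome(records={}), PAM_REGISTRY["SpCas9"]) == []

    def test_sorted_output(self, rng):
        g = Genome(records=random_records(rng, n_contigs=3, length=300))
        sites = enumerate_sites(g, PAM_REGISTRY["Cas-NNN"], with_context=False)
        keys = [(s.contig, s.start, s.strand) for s in sites]
        assert keys == sorted(keys)

    def test_strand_symmetry(self, rng):
        """Enumerating the reverse complement yields the strand-swapped,
        coordinate-mirrored site set."""
        records = random_records(rng, length=300)
        g = Genome(records=records)
        g_rc = Genome(records={c: revcomp(s) for c, s in records.items()})
        spec = PAM_REGISTRY["SpG"]
        fwd = {site_key(s) for s in enumerate_sites(g, spec, with_context=False)}
        M = 300
        mirrored = {
            (c, M - start - 20, {"+": "-", "-": "+"}[strand], proto, pam)
            for (c, start, strand, proto, pam) in (
                site_key(s) for s in enumerate_sites(g_rc, spec, with_context=False)
            )
        }
        assert fwd == mirrored

    def test_pattern_containment(self, rng):
        records = random_records(rng, length=600)
        g = Genome(records=records)

        def keys(p):
            return {site_key(s)[:3] for s in enumerate_sites(g, get_pam_spec(p), with_context=False)}

        assert keys("NGG") <= keys("NGN") <= keys("NNN")
        assert keys("NRN") <= keys("NNN")
        assert keys("NGH") & keys("NGG") == set()
        assert keys("NGH") | keys("NGG") == keys("NGN")

    def test_protospacer_N_flagged_pam_N_never_matches(self):
        seq = "TTTTTT" + "GGACGNACGTACGTACGTAC" + "AGG" + "TTTTTT"
        g = Genome(records={"c": seq})
        sites = enumerate_sites(g, PAM_REGISTRY["SpCas9"])
        flagged = [s for s in sites if s.start == 6 and s.strand == "+"]
        assert len(flagged) == 1 and flagged[0].contains_N
        # N inside the PAM kills the site even under pattern N
        g2 = Genome(records={"c": "TTTTTT" + "GGACGTACGTACGTACGTAC" + "ANG" + "TTTTTT"})
        assert all(
            s.start != 6 or s.strand != "+"
            for s in enumerate_sites(g2, PAM_REGISTRY["SpCas9"])
        )


class TestContext:
    def test_containment_and_length(self, tiny_genome):
        sites = [
            s for s in enumerate_sites(tiny_genome, PAM_REGISTRY["SpCas9"])
            if s.strand == "+" and s.start == 6
        ]
        (site,) = sites
        assert len(site.context35) == 35
        assert site.context35[6:26] == site.protospacer
        assert site.context35[26:29] == site.pam

    def test_minus_strand_context_is_revcomp_of_plus_window(self, rng):
        records = random_records(rng, length=400)
        g = Genome(records=records)
        seq = records["c0"]
        for site in enumerate_sites(g, PAM_REGISTRY["SpG"]):
            if site.strand == "-" and site.context35 is not None:
                window = seq[site.start - 9 : site.end + 6]
                assert site.context35 == revcomp(window)

    def test_edge_truncated_near_contig_start(self):
        seq = "TTT" + "GGACGTACGTACGTACGTAC" + "AGG" + "T" * 20
        g = Genome(records={"c": seq})
        (site,) = [
            s for s in enumerate_sites(g, PAM_REGISTRY["SpCas9"])
            if s.strand == "+" and s.start == 3
        ]
        assert site.edge_truncated and site.context35 is None

    def test_extract_context_matches_enumeration(self, tiny_genome):
        sites = enumerate_sites(tiny_genome, PAM_REGISTRY["SpCas9"], with_context=False)
        for s in sites:
            again = extract_context(s, tiny_genome)
            assert (again.context35 is None) == again.edge_truncated


class TestFilterGgStart:
    def test_keep_and_drop(self, tiny_genome):
        sites = enumerate_sites(tiny_genome, PAM_REGISTRY["SpCas9"])
        kept = filter_gg_start(sites)
        assert all(s.protospacer.startswith("GG") for s in kept)
        assert any(s.protospacer.startswith("GG") for s in sites)

    def test_idempotent(self, rng):
        g = Genome(records=random_records(rng, length=500))
        sites = enumerate_sites(g, PAM_REGISTRY["SpG"], with_context=False)
        once = filter_gg_start(sites)
        assert filter_gg_start(once) == once


class TestCutPosition:
    def test_plus_strand(self):
        from minipam.pam_engine import TargetSite

        s = TargetSite("c", 100, 120, "+", "A" * 20, "AGG")
        assert s.cut_position == 117  # 3 bp 5' of the PAM at 120

    def test_minus_strand(self):
        from minipam.pam_engine import TargetSite

        # PAM occupies [97,100) on the plus strand; cut 3 bp into the spacer
        s = TargetSite("c", 100, 120, "-", "A" * 20, "AGG")
        assert s.cut_position == 102
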