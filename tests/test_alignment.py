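"""Alignment container, I/O, Dayhoff recoding and the two observed statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import phylopp as pp
from phylopp.alignment import (AMINO20, AlignmentError, composition_counts,
                               write_phylip, write_recoded)


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_fasta_roundtrip(self, tiny_aln, tmp_path):
        p = tmp_path / "a.fasta"
        pp.write_fasta(tiny_aln, p)
        back = pp.read_alignment(p, "fasta")
        assert back.taxa == tiny_aln.taxa
        assert (back.matrix == tiny_aln.matrix).all()

    def test_two_record_fasta(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">s1\nACDE\nFGHI\n>s2\nACDE\nFGHL\n")
        aln = pp.read_alignment(p, "fasta")
        assert aln.n_taxa == 2 and aln.n_sites == 8

    def test_phylip_header_agreement(self, tmp_path):
        p = tmp_path / "a.phy"
        p.write_text("4 10\n" + "".join(
            f"tax{i} ACDEFGHIKL\n" for i in range(1, 5)))
        aln = pp.read_alignment(p, "phylip")
        assert aln.n_taxa == 4 and aln.n_sites == 10

    def test_phylip_interleaved(self, tmp_path):
        p = tmp_path / "i.phy"
        p.write_text("2 8\ns1 ACDE\ns2 ACDE\nFGHI\nFGHL\n")
        aln = pp.read_alignment(p, "phylip")
        assert aln.n_sites == 8
        assert "".join(aln.matrix[1]) == "ACDEFGHL"

    def test_phylip_roundtrip(self, tiny_aln, tmp_path):
        p = tmp_path / "rt.phy"
        write_phylip(tiny_aln, p)
        back = pp.read_alignment(p, "phylip")
        assert (back.matrix == tiny_aln.matrix).all()

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">s1\nACDE\n>s2\nACD\n")
        with pytest.raises(AlignmentError, match="ragged"):
            pp.read_alignment(p, "fasta")

    def test_unknown_symbol_names_position(self):
        with pytest.raises(AlignmentError, match="'O'.*tax2.*column 1"):
            pp.Alignment.from_sequences(["tax1", "tax2"], ["AC", "AO"])

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            pp.Alignment.from_sequences(["s", "s"], ["AC", "AC"])

    def test_case_normalized(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">s1\nacde\n>s2\nacdl\n")
        aln = pp.read_alignment(p, "fasta")
        assert (aln.matrix[0] == list("ACDE")).all()


# ---------------------------------------------------------------------------
# Dayhoff recoding
# ---------------------------------------------------------------------------

class TestRecode:
    def test_cysteine_singleton_class(self):
        aln = pp.Alignment.from_sequences(["a", "b", "c"], ["CC", "CC", "CC"])
        rec = pp.dayhoff_recode(aln)
        assert len(set(rec.matrix[:, 0])) == 1
        assert pp.site_diversity(rec).mean == 1.0

    def test_basic_residues_merge(self):
        aln = pp.Alignment.from_sequences(["a", "b", "c"], ["K", "R", "H"])
        rec = pp.dayhoff_recode(aln)
        assert len(set(rec.matrix[:, 0])) == 1

    def test_alphabet_bound_six(self):
        seqs = [AMINO20, AMINO20[::-1]]
        rec = pp.dayhoff_recode(pp.Alignment.from_sequences(["a", "b"], seqs))
        assert rec.alphabet == "dayhoff6"
        assert len(set(rec.matrix.ravel())) <= 6

    def test_missing_preserved_and_double_recode_rejected(self):
        aln = pp.Alignment.from_sequences(["a", "b"], ["A-X", "CW*"])
        rec = pp.dayhoff_recode(aln)
        assert (rec.missing_mask() == aln.missing_mask()).all()
        assert rec.matrix[0, 1] == "-"
        with pytest.raises(AlignmentError):
            pp.dayhoff_recode(rec)

    def test_scheme_partition_validated(self):
        with pytest.raises(ValueError, match="cover"):
            pp.RecodingScheme("broken", {"A": "ACD"})

    def test_recoded_writer_emits_sidecar(self, tmp_path):
        aln = pp.Alignment.from_sequences(["a", "b"], ["KR", "HD"])
        rec = pp.dayhoff_recode(aln)
        out = tmp_path / "rec.fasta"
        write_recoded(rec, out)
        sidecar = tmp_path / "rec.classes.tsv"
        assert sidecar.exists()
        lines = dict(l.split("\t") for l in sidecar.read_text().splitlines())
        assert lines["B"] == "C"  # cysteine singleton


# ---------------------------------------------------------------------------
# composition X²
# ---------------------------------------------------------------------------

class TestCompositionChisq:
    def test_identical_rows_zero(self, identical_rows_aln):
        assert pp.composition_chisq(identical_rows_aln).chisq == pytest.approx(0.0)

    def test_two_symbol_hand_value(self):
        # two taxa, two symbols used: global freq 0.5/0.5, expected 2/cell,
        # four cells each contributing (4-2)^2/2 = 2 -> X² = 8
        aln = pp.Alignment.from_sequences(["a", "b"], ["AAAA", "CCCC"])
        assert pp.composition_chisq(aln).chisq == pytest.approx(8.0)

    def test_matches_contingency_oracle(self, sim_aln):
        counts = composition_counts(sim_aln)
        counts = counts[:, counts.sum(axis=0) > 0]
        oracle = chi2_contingency(counts, correction=False).statistic
        assert pp.composition_chisq(sim_aln).chisq == pytest.approx(oracle, rel=1e-9)

    def test_row_and_column_reordering_invariant(self, sim_aln):
        base = pp.composition_chisq(sim_aln).chisq
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(sim_aln.n_taxa)
        perm_cols = rng.permutation(sim_aln.n_sites)
        shuffled = pp.Alignment(
            [sim_aln.taxa[i] for i in perm_rows],
            sim_aln.matrix[perm_rows][:, perm_cols],
        )
        assert pp.composition_chisq(shuffled).chisq == pytest.approx(base, rel=1e-12)

    def test_all_missing_taxon_named(self):
        aln = pp.Alignment.from_sequences(["good", "empty"], ["AC", "--"])
        with pytest.raises(AlignmentError, match="empty"):
            pp.composition_chisq(aln)

    def test_gaps_excluded_from_counts(self):
        with_gaps = pp.Alignment.from_sequences(["a", "b"], ["AC--", "AC-X"])
        bare = pp.Alignment.from_sequences(["a", "b"], ["AC", "AC"])
        assert (pp.composition_chisq(with_gaps).chisq
                == pytest.approx(pp.composition_chisq(bare).chisq))


# ---------------------------------------------------------------------------
# site diversity
# ---------------------------------------------------------------------------

class TestSiteDiversity:
    def test_constant_alignment_mean_one(self, identical_rows_aln):
        div = pp.site_diversity(identical_rows_aln)
        assert (div.per_site == 1).all() and div.mean == 1.0

    def test_distinct_count_is_set_cardinality(self):
        aln = pp.Alignment.from_sequences(["a", "b", "c", "d"], ["A", "C", "A", "G"])
        assert pp.site_diversity(aln).per_site[0] == 3

    def test_all_missing_column_warned_and_excluded(self):
        aln = pp.Alignment.from_sequences(["a", "b"], ["A-C", "A-C"])
        with pytest.warns(UserWarning, match="all-missing"):
            div = pp.site_diversity(aln)
        assert len(div.per_site) == 2 and div.n_excluded_columns == 1

    def test_fully_missing_alignment_rejected(self):
        aln = pp.Alignment.from_sequences(["a", "b"], ["--", "XX"])
        with pytest.raises(AlignmentError):
            pp.site_diversity(aln)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@st.composite
def random_alignments(draw):
    n_taxa = draw(st.integers(2, 6))
    n_sites = draw(st.integers(1, 12))
    rows = draw(st.lists(
        st.text(alphabet=AMINO20 + "-X", min_size=n_sites, max_size=n_sites),
        min_size=n_taxa, max_size=n_taxa))
    for row in rows:
        if not set(row) - set("-X"):
            return None
    return pp.Alignment.from_sequences([f"t{i}" for i in range(n_taxa)], rows)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_alignments())
def test_recoding_never_raises_diversity(aln):
    """Recoding merges residue classes, so mean site diversity cannot rise,
    X² stays non-negative, and missing positions are untouched."""
    if aln is None:
        return
    rec = pp.dayhoff_recode(aln)
    assert (rec.missing_mask() == aln.missing_mask()).all()
    try:
        before = pp.site_diversity(aln).mean
    except AlignmentError:
        return
    after = pp.site_diversity(rec).mean
    assert after <= before + 1e-12
    try:
        assert pp.composition_chisq(rec).chisq >= 0.0
    except AlignmentError:
        pass  # a taxon that is entirely missing
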