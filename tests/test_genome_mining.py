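"""Candidate extraction, filtering and sequence descriptors."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrmine import genome_mining as gm
from utrmine import synthetic as syn
from tests.conftest import parse_gbk

MINIMAL_GBK = """\
LOCUS       TESTREP                  400 bp    DNA     linear   UNK 01-JAN-2000
DEFINITION  minimal test replicon.
ACCESSION   TESTREP
VERSION     TESTREP
KEYWORDS    .
SOURCE      .
  ORGANISM  .
FEATURES             Location/Qualifiers
     gene            101..200
                     /locus_tag="GENE_A"
     gene            complement(251..350)
                     /locus_tag="GENE_B"
ORIGIN
{origin}
//
"""


def _origin(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        parts = [chunk[j : j + 10] for j in range(0, len(chunk), 10)]
        lines.append(f"{i + 1:>9} " + " ".join(parts).lower())
    return "\n".join(lines)


def test_parse_genome_converts_coordinates():
    """GenBank 1-based inclusive 101..200 becomes 0-based half-open [100, 200)."""
    seq = "A" * 400
    genes = gm.parse_genome(io.StringIO(MINIMAL_GBK.format(origin=_origin(seq))))
    assert [g.gene_id for g in genes] == ["GENE_A", "GENE_B"]
    a, b = genes
    assert (a.start, a.end, a.strand) == (100, 200, "+")
    assert (b.start, b.end, b.strand) == (250, 350, "-")
    assert [g.genome_index for g in genes] == [0, 1]


def test_parse_genome_empty_feature_table_raises():
    gbk = MINIMAL_GBK.format(origin=_origin("A" * 400))
    gbk = "\n".join(
        line for line in gbk.splitlines() if "gene" not in line and "locus_tag" not in line
    )
    with pytest.raises(gm.EmptyGenomeError):
        gm.parse_genome(io.StringIO(gbk))


def test_extraction_matches_generator_truth(tandem_genome):
    genbank, truth = tandem_genome
    genes, seq = parse_gbk(genbank)
    assert len(genes) == 5
    cands = gm.extract_candidate_utrs(genes, seq)
    gm.filter_by_length(cands)
    gm.apply_restriction_filter(cands)
    assert len(cands) == len(truth)
    for c, (_, row) in zip(cands, truth.iterrows()):
        assert c.sequence == row["sequence"]
        assert c.length == row["length"]
        assert ",".join(sorted(c.filter_flags)) == row["flags"]


def test_tandem_gap_yields_unflagged_candidate():
    """Two plus-strand genes with an 80 bp gap give one clean 80 bp candidate."""
    spec = syn.GenomeSpec(n_genes=2, gap_lengths=(80,), strand_pattern=("+", "+"), seed=3)
    genbank, _ = syn.generate_genome(spec)
    genes, seq = parse_gbk(genbank)
    cands = gm.extract_candidate_utrs(genes, seq)
    assert len(cands) == 1
    (c,) = cands
    assert c.length == 80 and c.filter_flags == set()
    assert c.gene_id == "SYN_0001" and c.upstream_gene_id == "SYN_0000"


def test_divergent_pair_both_flagged_opposing():
    spec = syn.GenomeSpec(n_genes=2, gap_lengths=(100,), strand_pattern=("-", "+"), seed=4)
    genbank, _ = syn.generate_genome(spec)
    genes, seq = parse_gbk(genbank)
    cands = gm.extract_candidate_utrs(genes, seq)
    assert len(cands) == 2
    assert all("opposing_orientation" in c.filter_flags for c in cands)
    # both read the same intergenic DNA, one per coding strand
    assert cands[0].sequence == gm._revcomp(cands[1].sequence)


def test_overlapping_tandem_genes_flagged_overlap():
    spec = syn.GenomeSpec(n_genes=2, gap_lengths=(0,), strand_pattern=("+", "+"), seed=5)
    genbank, _ = syn.generate_genome(spec)
    genes, seq = parse_gbk(genbank)
    cands = gm.extract_candidate_utrs(genes, seq)
    (c,) = cands
    assert "overlap" in c.filter_flags and c.sequence == ""


def _brute_force_candidates(genes, seq):
    """Independent oracle: direct slicing between neighbor coordinates."""
    out = []
    for i, g in enumerate(genes):
        if g.strand == "+":
            if i == 0:
                continue
            nb = genes[i - 1]
            region = seq[nb.end : g.start] if nb.end < g.start else ""
            cand_seq = region
        else:
            if i == len(genes) - 1:
                continue
            nb = genes[i + 1]
            region = seq[g.end : nb.start] if g.end < nb.start else ""
            cand_seq = gm._revcomp(region) if region else ""
        flags = set()
        if not region:
            flags.add("overlap")
        if nb.strand != g.strand:
            flags.add("opposing_orientation")
        out.append((g.gene_id, cand_seq, flags))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_extraction_oracle_equivalence(seed):
    """On random genomes of <= 50 genes the extraction equals brute force."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 51))
    spec = syn.GenomeSpec(
        n_genes=n,
        gap_lengths=tuple(int(g) for g in rng.choice([0, 20, 61, 80, 171], size=n - 1)),
        strand_pattern=tuple(rng.choice(["+", "-"], size=n)),
        seed=seed,
    )
    genbank, _ = syn.generate_genome(spec)
    genes, seq = parse_gbk(genbank)
    got = [
        (c.gene_id, c.sequence, c.filter_flags)
        for c in gm.extract_candidate_utrs(genes, seq)
    ]
    assert got == _brute_force_candidates(genes, seq)


def test_strand_symmetry():
    """Reverse-complementing the genome and flipping strands leaves every
    candidate's coding-strand sequence and flags unchanged."""
    spec = syn.GenomeSpec(
        n_genes=6,
        gap_lengths=(70, 0, 100, 130, 65),
        strand_pattern=("+", "-", "+", "+", "-", "+"),
        seed=9,
    )
    genbank, _ = syn.generate_genome(spec)
    genes, seq = parse_gbk(genbank)
    L = len(seq)
    flipped = [
        gm.GeneRecord(
            gene_id=g.gene_id,
            start=L - g.end,
            end=L - g.start,
            strand="-" if g.strand == "+" else "+",
            feature_class=g.feature_class,
            genome_index=i,
        )
        for i, g in enumerate(reversed(genes))
    ]
    fwd = {c.gene_id: c for c in gm.extract_candidate_utrs(genes, seq)}
    rev = {c.gene_id: c for c in gm.extract_candidate_utrs(flipped, gm._revcomp(seq))}
    assert fwd.keys() == rev.keys()
    for gid in fwd:
        assert fwd[gid].sequence == rev[gid].sequence
        assert fwd[gid].filter_flags == rev[gid].filter_flags


@pytest.mark.parametrize(
    "length,expected_flag",
    [(59, "too_short"), (60, None), (170, None), (171, "too_long")],
)
def test_length_filter_boundaries(length, expected_flag):
    c = gm.CandidateUTR("C1", "g1", "A" * length, "g0", "+")
    gm.filter_by_length([c])
    if expected_flag:
        assert c.filter_flags == {expected_flag}
    else:
        assert c.filter_flags == set()


def test_filters_are_idempotent(mixed_strand_genome):
    _, genbank, _ = mixed_strand_genome
    genes, seq = parse_gbk(genbank)
    cands = gm.extract_candidate_utrs(genes, seq)
    counts = {c.gene_id: 100.0 for c in cands[:3]}
    for fn in (
        lambda cs: gm.filter_by_length(cs),
        lambda cs: gm.filter_by_transcriptome(cs, counts),
        lambda cs: gm.apply_restriction_filter(cs),
    ):
        fn(cands)
        snapshot = [set(c.filter_flags) for c in cands]
        fn(cands)
        assert [set(c.filter_flags) for c in cands] == snapshot


def test_transcriptome_filter_flags_and_annotates():
    cands = [
        gm.CandidateUTR("C1", "gA", "A" * 70, "g0", "+"),
        gm.CandidateUTR("C2", "gB", "A" * 70, "gA", "+"),
    ]
    gm.filter_by_transcriptome(cands, {"gA": 1234.0})
    assert cands[0].read_count == 1234.0 and cands[0].passes
    assert "no_transcript" in cands[1].filter_flags and cands[1].read_count is None


def test_count_table_duplicate_gene_raises(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text("gene_id\test_counts\ngA\t10\ngA\t20\n")
    with pytest.raises(ValueError, match="duplicate"):
        gm.read_count_table(str(p))


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAGGTCTCAA", [("BsaI", 3, "+")]),
        ("AAGAGACCAA", [("BsaI", 3, "-")]),
        ("ATATATATAT", []),
    ],
)
def test_scan_restriction_sites_examples(seq, expected):
    hits = gm.scan_restriction_sites(seq)
    assert [(h.enzyme, h.position, h.strand) for h in hits] == expected


def test_scan_rejects_ambiguity_codes():
    with pytest.raises(ValueError, match="alphabet"):
        gm.scan_restriction_sites("AANGGTCTC")


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=6, max_size=60))
def test_restriction_hits_reflect_under_revcomp(seq):
    fwd = gm.scan_restriction_sites(seq)
    rev = gm.scan_restriction_sites(gm._revcomp(seq))
    flip = {"+": "-", "-": "+"}
    reflected = sorted(
        (h.enzyme, len(seq) - h.position - 4, flip[h.strand]) for h in fwd
    )
    assert sorted((h.enzyme, h.position, h.strand) for h in rev) == reflected


@pytest.mark.parametrize("seq,pct", [("ATAT", 0.0), ("GCGC", 100.0), ("ATGC", 50.0)])
def test_gc_content_examples(seq, pct):
    assert gm.gc_content(seq) == pct


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=80))
def test_gc_content_revcomp_invariant(seq):
    assert gm.gc_content(seq) == pytest.approx(gm.gc_content(gm._revcomp(seq)))


def test_gc_content_empty_raises():
    with pytest.raises(ValueError):
        gm.gc_content("")


def test_find_motif_planted_and_span_arithmetic():
    """A 10-mer planted so its span is 20-29 is recovered there, and every
    reported span covers exactly the motif length."""
    motif = "TTACAAGAAA"
    rng = np.random.default_rng(0)
    bg = "".join(rng.choice(list("CG"), size=76))  # motif-free background
    seq = bg[:19] + motif + bg[29:]
    spans = gm.find_motif(seq, motif)
    assert spans == [(20, 29)]
    assert all(e - s + 1 == len(motif) for s, e in spans)
    assert gm.find_motif(seq, "AAAAAAAAAAAA" * 10) == []
    assert gm.find_motif("ACGT", "TTT") == []


def test_surviving_view(mixed_strand_genome):
    _, genbank, truth = mixed_strand_genome
    genes, seq = parse_gbk(genbank)
    cands = gm.extract_candidate_utrs(genes, seq)
    gm.filter_by_length(cands)
    gm.apply_restriction_filter(cands)
    expected = set(truth.loc[truth["flags"] == "", "gene_id"])
    assert {c.gene_id for c in gm.surviving(cands)} == expected
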