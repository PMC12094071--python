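"""Extraction and filtering of candidate 5' UTRs from an annotated genome.

A candidate 5' UTR is the intergenic stretch immediately upstream of a gene on
its coding strand: for a plus-strand gene, the region between the end of the
previous gene and its own start; for a minus-strand gene, the region between
its own end and the start of the next gene, reverse-complemented onto the
coding strand. Candidates are never deleted by filters — each filter only adds
a flag — so attrition through the pipeline stays fully auditable and the
surviving set is the flag-free view.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction

__all__ = [
    "GeneRecord",
    "CandidateUTR",
    "RestrictionHit",
    "RESTRICTION_SITES",
    "parse_genome",
    "extract_candidate_utrs",
    "filter_by_length",
    "filter_by_transcriptome",
    "apply_restriction_filter",
    "scan_restriction_sites",
    "gc_content",
    "find_motif",
    "surviving",
    "read_count_table",
]

#: Recognition sequences of the type-IIS enzymes screened against. Golden-Gate
#: assembly cuts outside these sites, so an internal occurrence on either
#: strand would fragment the insert during cloning.
RESTRICTION_SITES: dict[str, str] = {
    "BsaI": "GGTCTC",
    "BsmBI": "CGTCTC",
    "BbsI": "GAAGAC",
}

#: Filter flags a candidate can accumulate.
FILTER_FLAGS = frozenset(
    {
        "opposing_orientation",
        "overlap",
        "too_short",
        "too_long",
        "no_transcript",
        "restriction_site",
    }
)

_DNA = re.compile(r"^[ACGT]*$")


class EmptyGenomeError(ValueError):
    """Raised when a GenBank record contains no gene features."""


class GenomeParseError(ValueError):
    """Raised for malformed GenBank input, naming the offending feature."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, with 0-based half-open coordinates.

    GenBank positions (1-based inclusive) are converted on parse; Biopython
    already stores features this way internally.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    feature_class: str = "CDS"  # CDS, tRNA, rRNA or other
    genome_index: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GenomeParseError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeParseError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")


@dataclass
class CandidateUTR:
    """An extracted intergenic 5' UTR with its filter audit trail.

    ``sequence`` is given on the coding strand of the downstream gene, so the
    base adjacent to the start codon is always the last base of ``sequence``.
    """

    candidate_id: str
    gene_id: str
    sequence: str
    upstream_gene_id: str
    upstream_strand: str
    read_count: float | None = None
    filter_flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def passes(self) -> bool:
        return not self.filter_flags


@dataclass(frozen=True)
class RestrictionHit:
    """An occurrence of a type-IIS recognition site (1-based start)."""

    enzyme: str
    position: int
    strand: str


def parse_genome(genbank: IO[str] | str) -> list[GeneRecord]:
    """Read gene features from a GenBank flat file into genome order.

    Parameters
    ----------
    genbank
        Path or open text handle of a GenBank file with ``gene`` features.

    Returns
    -------
    list of GeneRecord, ordered along the replicon, coordinates 0-based
    half-open.

    Raises
    ------
    EmptyGenomeError
        If no gene features are present.
    GenomeParseError
        For features without a locus tag or with invalid coordinates.
    """
    try:
        record = next(SeqIO.parse(genbank, "genbank"))
    except StopIteration:
        raise EmptyGenomeError("GenBank input contains no records") from None
    except ValueError as exc:
        raise GenomeParseError(f"malformed GenBank input: {exc}") from exc

    genes: list[GeneRecord] = []
    class_by_id: dict[str, str] = {}
    # tRNA/rRNA feature types refine the class of the matching gene feature
    for feat in record.features:
        if feat.type in ("tRNA", "rRNA", "CDS"):
            ids = feat.qualifiers.get("locus_tag", [])
            if ids:
                class_by_id.setdefault(ids[0], feat.type)
    for feat in record.features:
        if feat.type != "gene":
            continue
        ids = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", []))
        if not ids:
            raise GenomeParseError(
                f"gene feature at {feat.location} lacks a locus_tag/gene qualifier"
            )
        gene_id = ids[0]
        strand = "-" if feat.location.strand == -1 else "+"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
                feature_class=class_by_id.get(gene_id, "other"),
                genome_index=len(genes),
            )
        )
    if not genes:
        raise EmptyGenomeError("GenBank record has an empty gene table")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise GenomeParseError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_candidate_utrs(
    genes: list[GeneRecord],
    genome_sequence: str,
    *,
    circular: bool = False,
    id_prefix: str = "CPL",
) -> list[CandidateUTR]:
    """Extract the upstream intergenic region of every gene.

    For each gene the region between it and its upstream neighbor (previous
    gene for '+', next gene for '-') is sliced from the genome; minus-strand
    candidates are reverse-complemented so every sequence reads 5'->3' toward
    the start codon. Neighbors on the opposite strand yield the flag
    ``opposing_orientation``; a non-positive gap yields ``overlap`` with an
    empty sequence. On a linear replicon, a gene with no upstream neighbor
    (first '+' gene, last '-' gene) produces no candidate; with
    ``circular=True`` the region wraps around the origin.
    """
    n = len(genome_sequence)
    for g in genes:
        if g.end > n:
            raise IndexError(
                f"gene {g.gene_id!r} extends to {g.end} beyond sequence length {n}"
            )
    candidates: list[CandidateUTR] = []
    for i, gene in enumerate(genes):
        if gene.strand == "+":
            neighbor = genes[i - 1] if i > 0 else (genes[-1] if circular else None)
        else:
            neighbor = (
                genes[i + 1]
                if i + 1 < len(genes)
                else (genes[0] if circular else None)
            )
        if neighbor is None or neighbor is gene:
            continue
        if gene.strand == "+":
            lo, hi = neighbor.end, gene.start
        else:
            lo, hi = gene.end, neighbor.start
        wraps = circular and hi < lo and neighbor is not gene and (
            (gene.strand == "+" and i == 0) or (gene.strand == "-" and i == len(genes) - 1)
        )
        flags: set[str] = set()
        if wraps:
            seq = genome_sequence[lo:] + genome_sequence[:hi]
        elif hi <= lo:
            seq = ""
            flags.add("overlap")
        else:
            seq = genome_sequence[lo:hi]
        if gene.strand == "-" and seq:
            seq = _revcomp(seq)
        if neighbor.strand != gene.strand:
            flags.add("opposing_orientation")
        candidates.append(
            CandidateUTR(
                candidate_id=f"{id_prefix}{len(candidates):04d}",
                gene_id=gene.gene_id,
                sequence=seq.upper(),
                upstream_gene_id=neighbor.gene_id,
                upstream_strand=neighbor.strand,
                filter_flags=flags,
            )
        )
    return candidates


def filter_by_length(
    candidates: Iterable[CandidateUTR], min_len: int = 60, max_len: int = 170
) -> list[CandidateUTR]:
    """Flag candidates strictly shorter than ``min_len`` or strictly longer
    than ``max_len``; the bounds themselves are retained. Returns its input
    list for chaining (mutates flags in place; idempotent)."""
    out = list(candidates)
    for c in out:
        c.filter_flags.discard("too_short")
        c.filter_flags.discard("too_long")
        if c.length < min_len:
            c.filter_flags.add("too_short")
        elif c.length > max_len:
            c.filter_flags.add("too_long")
    return out


def filter_by_transcriptome(
    candidates: Iterable[CandidateUTR], count_table: Mapping[str, float]
) -> list[CandidateUTR]:
    """Merge with a transcriptome count table keyed by gene_id.

    Candidates absent from the table are flagged ``no_transcript`` — this is
    the mechanism that drops tRNA/rRNA and silent genes; present candidates
    are annotated with their read count.
    """
    out = list(candidates)
    for c in out:
        c.filter_flags.discard("no_transcript")
        if c.gene_id in count_table:
            c.read_count = float(count_table[c.gene_id])
        else:
            c.read_count = None
            c.filter_flags.add("no_transcript")
    return out


def read_count_table(path_or_handle: IO[str] | str) -> dict[str, float]:
    """Load a two-column TSV (gene_id, est_counts) into a dict.

    Raises ``ValueError`` on a duplicated gene_id (ambiguous merge).
    """
    import pandas as pd

    df = pd.read_csv(path_or_handle, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("count table needs two columns: gene_id, est_counts")
    gene_col, count_col = df.columns[0], df.columns[1]
    if df[gene_col].duplicated().any():
        dups = df.loc[df[gene_col].duplicated(), gene_col].tolist()
        raise ValueError(f"duplicate gene_id(s) in count table: {dups[:5]}")
    return dict(zip(df[gene_col].astype(str), df[count_col].astype(float)))


def scan_restriction_sites(sequence: str) -> list[RestrictionHit]:
    """Locate BsaI/BsmBI/BbsI recognition sites on both strands.

    Returns every occurrence of the recognition 6-mer (strand '+') and of its
    reverse complement (strand '-'), with the 1-based start of the match on
    the given sequence. Overlapping occurrences are all reported.
    """
    seq = sequence.upper()
    if not _DNA.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"unsupported alphabet: sequence contains {bad}")
    hits: list[RestrictionHit] = []
    for enzyme, site in RESTRICTION_SITES.items():
        for strand, needle in (("+", site), ("-", _revcomp(site))):
            start = seq.find(needle)
            while start != -1:
                hits.append(RestrictionHit(enzyme=enzyme, position=start + 1, strand=strand))
                start = seq.find(needle, start + 1)
    hits.sort(key=lambda h: (h.position, h.enzyme, h.strand))
    return hits


def apply_restriction_filter(candidates: Iterable[CandidateUTR]) -> list[CandidateUTR]:
    """Flag every candidate whose sequence carries >=1 type-IIS site."""
    out = list(candidates)
    for c in out:
        c.filter_flags.discard("restriction_site")
        if c.sequence and scan_restriction_sites(c.sequence):
            c.filter_flags.add("restriction_site")
    return out


def gc_content(sequence: str) -> float:
    """GC percentage of a sequence (exact fraction times 100)."""
    if not sequence:
        raise ValueError("gc_content of an empty sequence is undefined")
    if not _DNA.match(sequence.upper()):
        raise ValueError("sequence must be over {A,C,G,T}")
    return 100.0 * gc_fraction(Seq(sequence))


def find_motif(sequence: str, motif: str) -> list[tuple[int, int]]:
    """Exact-match motif scan; returns 1-based inclusive (start, end) spans.

    Overlapping matches are all reported; a motif longer than the sequence
    simply yields no spans. Matching is on the given strand only.
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    seq, needle = sequence.upper(), motif.upper()
    spans: list[tuple[int, int]] = []
    start = seq.find(needle)
    while start != -1:
        spans.append((start + 1, start + len(needle)))
        start = seq.find(needle, start + 1)
    return spans


def surviving(candidates: Iterable[CandidateUTR]) -> list[CandidateUTR]:
    """The flag-free view: candidates that passed every filter applied."""
    return [c for c in candidates if c.passes]
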