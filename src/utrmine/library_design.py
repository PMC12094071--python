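"""Two-tranche candidate selection and 150 bp Golden-Gate oligo assembly.

Synthesis orders are capped: here at 500 sequences of exactly 150 bp each.
Selection fills the order in two tranches — first the shortest surviving
candidates (everything from 60 to 98 bp fits untrimmed inside the 150 bp
envelope with flanks), then, from the remainder sorted by transcriptome read
count, a fixed number per order of magnitude of read count so the library
spans the expression range. Inserts longer than 98 bp are trimmed from the
5' end, keeping the bases nearest the start codon. Each oligo is padded with
seeded random bases to exactly 150 bp, re-drawing any pad that would create a
type-IIS site outside the intended flank sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from utrmine.genome_mining import CandidateUTR, scan_restriction_sites

__all__ = [
    "SelectionPlan",
    "OligoDesign",
    "DEFAULT_LEFT_FLANK",
    "DEFAULT_RIGHT_FLANK",
    "select_candidates",
    "decade_bin",
    "trim_to_insert",
    "build_oligo",
    "design_library",
]

logger = logging.getLogger(__name__)

# Placeholder entry-vector flanks with correct BsaI geometry: the left flank
# carries a plus-strand GGTCTC followed by a spacer base and the 4-nt fusion
# overhang; the right flank mirrors it with the site on the minus strand
# (GAGACC). The real flanks come from the destination vector and are supplied
# via config.
DEFAULT_LEFT_FLANK = "AAGGTCTCATATG"
DEFAULT_RIGHT_FLANK = "CGCTTGAGACCTT"


class DesignInfeasibleError(ValueError):
    """Insert plus flanks exceed the synthesis envelope."""


class EmptyLibraryError(ValueError):
    """No surviving candidates to design from."""


@dataclass(frozen=True)
class SelectionPlan:
    """Parameters of the two-tranche pick.

    cap: total library size; tranche1_size shortest candidates first (all
    lengths <= tranche1_max_len fit untrimmed); then per_decade top-count
    candidates from each order of magnitude of read count.
    """

    cap: int = 500
    tranche1_size: int = 350
    tranche1_max_len: int = 98
    per_decade: int = 50


@dataclass(frozen=True)
class OligoDesign:
    """A finished synthesis oligo with its provenance."""

    candidate_id: str
    insert: str
    left_flank: str
    right_flank: str
    pad: str
    oligo: str
    seed: int
    pre_trim_length: int = 0

    def __post_init__(self) -> None:
        assert self.insert in self.oligo


def decade_bin(count: float) -> int:
    """Order-of-magnitude bin of a read count: floor(log10) for count >= 1,
    -1 for counts in (0, 1). Counts <= 0 have no bin (ValueError)."""
    if count <= 0:
        raise ValueError("decade_bin undefined for nonpositive counts")
    return math.floor(math.log10(count)) if count >= 1 else -1


def select_candidates(
    survivors: list[CandidateUTR], plan: SelectionPlan = SelectionPlan()
) -> list[CandidateUTR]:
    """Deterministic two-tranche selection, truncated at ``plan.cap``.

    Tranche 1: the ``tranche1_size`` shortest survivors (gene_id tiebreak).
    Tranche 2: among the remainder with a positive read count, the
    ``per_decade`` highest-count candidates per decade bin, bins in ascending
    order. Under-filled bins contribute all their members; no backfilling.
    A shortfall against the cap is logged, not raised.
    """
    for c in survivors:
        if c.read_count is None:
            raise ValueError(f"candidate {c.candidate_id} has no read_count")
    by_length = sorted(survivors, key=lambda c: (c.length, c.gene_id))
    tranche1 = by_length[: plan.tranche1_size]
    remainder = by_length[plan.tranche1_size :]

    bins: dict[int, list[CandidateUTR]] = {}
    for c in remainder:
        if c.read_count and c.read_count > 0:
            bins.setdefault(decade_bin(c.read_count), []).append(c)
    tranche2: list[CandidateUTR] = []
    for b in sorted(bins):
        members = sorted(bins[b], key=lambda c: (-c.read_count, c.gene_id))
        tranche2.extend(members[: plan.per_decade])

    selection = (tranche1 + tranche2)[: plan.cap]
    if len(selection) < plan.cap:
        logger.warning(
            "selection shortfall: %d candidates for a cap of %d",
            len(selection),
            plan.cap,
        )
    return selection


def trim_to_insert(sequence: str, target_len: int = 98) -> str:
    """Trim from the 5' end to ``target_len``, keeping the 3'-most bases
    (those adjacent to the start codon); shorter sequences pass unchanged."""
    if len(sequence) <= target_len:
        return sequence
    return sequence[-target_len:]


def _site_spans(sequence: str) -> list[tuple[int, int]]:
    # 0-based half-open spans of all type-IIS hits
    return [(h.position - 1, h.position - 1 + 6) for h in scan_restriction_sites(sequence)]


def build_oligo(
    insert: str,
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    total_len: int = 150,
    rng: np.random.Generator | None = None,
    *,
    seed: int = 0,
    pad_side: str = "5prime",
    max_redraws: int = 100,
    pre_trim_length: int | None = None,
) -> OligoDesign:
    """Assemble one synthesis oligo of exactly ``total_len`` bases.

    The pad of seeded random bases sits outside the cloned region (5' of the
    left restriction site by default, configurable to 3'). After each draw the
    whole oligo is scanned: any type-IIS site touching the pad — created
    inside it or straddling its junction — triggers a re-draw, at most
    ``max_redraws`` times.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if scan_restriction_sites(insert):
        raise DesignInfeasibleError("insert contains a type-IIS restriction site")
    pad_len = total_len - len(insert) - len(left_flank) - len(right_flank)
    if pad_len < 0:
        raise DesignInfeasibleError(
            f"insert ({len(insert)} bp) + flanks exceed the {total_len} bp envelope"
        )
    core = left_flank + insert + right_flank
    if pad_side == "5prime":
        pad_span = (0, pad_len)
    elif pad_side == "3prime":
        pad_span = (len(core), len(core) + pad_len)
    else:
        raise ValueError("pad_side must be '5prime' or '3prime'")

    bases = np.array(list("ACGT"))
    for _ in range(max_redraws + 1):
        pad = "".join(rng.choice(bases, size=pad_len)) if pad_len else ""
        oligo = pad + core if pad_side == "5prime" else core + pad
        stray = [
            s
            for s in _site_spans(oligo)
            if s[1] > pad_span[0] and s[0] < pad_span[1]
        ]
        if not stray:
            return OligoDesign(
                candidate_id="",
                insert=insert,
                left_flank=left_flank,
                right_flank=right_flank,
                pad=pad,
                oligo=oligo,
                seed=seed,
                pre_trim_length=pre_trim_length if pre_trim_length is not None else len(insert),
            )
    raise DesignInfeasibleError(
        f"could not draw a pad free of type-IIS sites within {max_redraws} attempts"
    )


def design_library(
    survivors: list[CandidateUTR],
    plan: SelectionPlan = SelectionPlan(),
    *,
    left_flank: str = DEFAULT_LEFT_FLANK,
    right_flank: str = DEFAULT_RIGHT_FLANK,
    total_len: int = 150,
    trim_target: int = 98,
    seed: int = 0,
) -> list[OligoDesign]:
    """Select, trim and assemble the full oligo library.

    Each candidate's pad is drawn from an independent stream spawned from
    ``seed``, so the library is reproducible as a whole and per oligo.
    """
    if not survivors:
        raise EmptyLibraryError("no surviving candidates to design a library from")
    selection = select_candidates(survivors, plan)
    root = np.random.default_rng(seed)
    streams = root.spawn(len(selection))
    designs = []
    for cand, stream in zip(selection, streams):
        insert = trim_to_insert(cand.sequence, trim_target)
        d = build_oligo(
            insert,
            left_flank,
            right_flank,
            total_len,
            stream,
            seed=seed,
            pre_trim_length=cand.length,
        )
        designs.append(
            OligoDesign(
                candidate_id=cand.candidate_id,
                insert=d.insert,
                left_flank=d.left_flank,
                right_flank=d.right_flank,
                pad=d.pad,
                oligo=d.oligo,
                seed=seed,
                pre_trim_length=cand.length,
            )
        )
    return designs
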