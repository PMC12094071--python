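"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three kinds of real input:

* an annotated genome (GenBank) with controllable intergenic gap lengths,
  strand topology, and planted restriction sites / motifs, together with a
  ground-truth table of every expected candidate 5' UTR and its filter flags;
* a transcriptome read-count table spanning a chosen set of count decades;
* dual-fluorophore plate-reader curves: logistic biomass, GFP proportional to
  biomass, promoter-driven mCherry constructed so the differential-activity
  ratio of the noise-free curves equals a prescribed ground truth, plus media
  background and Gaussian noise.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from utrmine.fluorescence import PlateTimeSeries
from utrmine.genome_mining import RESTRICTION_SITES, scan_restriction_sites

__all__ = [
    "GenomeSpec",
    "CurveSpec",
    "generate_genome",
    "generate_counts",
    "generate_plate_timeseries",
    "make_cohort_specs",
    "cohort_to_long_frame",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for a synthetic annotated replicon.

    ``gap_lengths`` are the intergenic distances between consecutive genes
    (length ``n_genes - 1``); ``strand_pattern`` assigns each gene's strand.
    ``planted_restriction_sites`` maps a gene index to an enzyme whose site is
    written into that gene's upstream candidate region;``planted_motifs``
    plants an exact motif at a 1-based offset of the candidate (coding-strand
    orientation). Margins pad the replicon ends so terminal genes have
    sequence context.
    """

    n_genes: int
    gap_lengths: tuple[int, ...]
    strand_pattern: tuple[str, ...]
    gene_length: int = 300
    margin: int = 50
    planted_restriction_sites: tuple[tuple[int, str], ...] = ()
    planted_motifs: tuple[tuple[int, str, int], ...] = ()
    feature_classes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gap_lengths) != self.n_genes - 1:
            raise ValueError(
                f"need {self.n_genes - 1} gap lengths for {self.n_genes} genes, "
                f"got {len(self.gap_lengths)}"
            )
        if len(self.strand_pattern) != self.n_genes:
            raise ValueError("strand_pattern length must equal n_genes")
        if any(g < 0 for g in self.gap_lengths):
            raise ValueError("gap lengths must be nonnegative")
        if self.feature_classes and len(self.feature_classes) != self.n_genes:
            raise ValueError("feature_classes length must equal n_genes")


def _random_dna(rng: np.random.Generator, n: int, avoid_sites: bool = True) -> str:
    """Random sequence; re-drawn until free of type-IIS sites when asked."""
    for _ in range(200):
        seq = "".join(rng.choice(_BASES, size=n)) if n else ""
        if not avoid_sites or not scan_restriction_sites(seq):
            return seq
    raise RuntimeError("could not draw a site-free sequence")  # pragma: no cover


def generate_genome(spec: GenomeSpec) -> tuple[str, pd.DataFrame]:
    """Build a GenBank record and the ground-truth candidate table.

    Returns the GenBank text and a DataFrame with one row per expected
    candidate 5' UTR: its id, downstream gene, coding-strand sequence, length,
    upstream neighbor and strand, and the comma-joined flags the length /
    orientation / overlap / restriction filters must assign. Parsing the
    GenBank back and extracting candidates must reproduce this table exactly.
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.feature_classes or ("CDS",) * spec.n_genes

    gene_seqs = [_random_dna(rng, spec.gene_length) for _ in range(spec.n_genes)]
    gap_seqs = [_random_dna(rng, g) for g in spec.gap_lengths]

    # plant restriction sites in the upstream gap of the indicated gene
    planted_rs = dict(spec.planted_restriction_sites)
    for gi, enzyme in planted_rs.items():
        gap_idx = gi - 1 if spec.strand_pattern[gi] == "+" else gi
        if not 0 <= gap_idx < len(gap_seqs):
            raise ValueError(f"gene index {gi} has no upstream gap to plant into")
        gap = gap_seqs[gap_idx]
        site = RESTRICTION_SITES[enzyme]
        if len(gap) < len(site):
            raise ValueError(f"gap {gap_idx} too short to plant {enzyme} site")
        mid = (len(gap) - len(site)) // 2
        gap_seqs[gap_idx] = gap[:mid] + site + gap[mid + len(site) :]

    # plant motifs at a candidate-frame offset (coding strand of the gene)
    for gi, motif, offset in spec.planted_motifs:
        strand = spec.strand_pattern[gi]
        gap_idx = gi - 1 if strand == "+" else gi
        gap = gap_seqs[gap_idx]
        if offset < 1 or offset + len(motif) - 1 > len(gap):
            raise ValueError(f"motif does not fit at offset {offset} of gap {gap_idx}")
        if strand == "+":
            s = offset - 1
            gap_seqs[gap_idx] = gap[:s] + motif + gap[s + len(motif) :]
        else:
            rc = str(Seq(motif).reverse_complement())
            s = len(gap) - (offset - 1) - len(motif)
            gap_seqs[gap_idx] = gap[:s] + rc + gap[s + len(rc) :]

    lead = _random_dna(rng, spec.margin)
    tail = _random_dna(rng, spec.margin)
    genome = lead
    starts: list[int] = []
    for i, gseq in enumerate(gene_seqs):
        starts.append(len(genome))
        genome += gseq
        if i < len(gap_seqs):
            genome += gap_seqs[i]
    genome += tail

    record = SeqRecord(
        Seq(genome),
        id="SYNREP1",
        name="SYNREP1",
        description="synthetic replicon",
        annotations={"molecule_type": "DNA", "date": "01-JAN-2000", "topology": "linear"},
    )
    for i in range(spec.n_genes):
        loc = FeatureLocation(starts[i], starts[i] + spec.gene_length,
                              strand=1 if spec.strand_pattern[i] == "+" else -1)
        quals = {"locus_tag": [f"SYN_{i:04d}"]}
        record.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        ftype = classes[i] if classes[i] in ("CDS", "tRNA", "rRNA") else "misc_feature"
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=dict(quals)))
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")

    # ground truth, mirroring the extraction conventions by construction
    rows = []
    k = 0
    for i in range(spec.n_genes):
        strand = spec.strand_pattern[i]
        if strand == "+":
            if i == 0:
                continue
            neighbor, gap = i - 1, gap_seqs[i - 1]
            seq = gap
        else:
            if i == spec.n_genes - 1:
                continue
            neighbor, gap = i + 1, gap_seqs[i]
            seq = str(Seq(gap).reverse_complement())
        flags: set[str] = set()
        if len(seq) == 0:
            flags.add("overlap")
            seq = ""
        if spec.strand_pattern[neighbor] != strand:
            flags.add("opposing_orientation")
        if len(seq) < 60:
            flags.add("too_short")
        elif len(seq) > 170:
            flags.add("too_long")
        if seq and scan_restriction_sites(seq):
            flags.add("restriction_site")
        rows.append(
            {
                "candidate_id": f"CPL{k:04d}",
                "gene_id": f"SYN_{i:04d}",
                "sequence": seq,
                "length": len(seq),
                "upstream_gene_id": f"SYN_{neighbor:04d}",
                "upstream_strand": spec.strand_pattern[neighbor],
                "flags": ",".join(sorted(flags)),
            }
        )
        k += 1
    return buf.getvalue(), pd.DataFrame(rows)


def generate_counts(
    gene_ids: list[str],
    decades: tuple[int, ...] = (1, 2, 3),
    per_decade_n: int = 50,
    seed: int = 0,
    omit_fraction: float = 0.1,
) -> pd.DataFrame:
    """Read-count table spanning the given decades, with omissions.

    Per decade ``d``, ``per_decade_n`` genes get counts uniform in
    [10^d, 10^(d+1)); at least ``omit_fraction`` of genes (and any beyond the
    decade quota) are left out of the table to exercise the transcriptome
    filter.
    """
    if not decades:
        raise ValueError("decades must be nonempty")
    rng = np.random.default_rng(seed)
    ids = list(gene_ids)
    rng.shuffle(ids)
    n_omit = max(int(round(omit_fraction * len(ids))), 0)
    usable = ids[: len(ids) - n_omit] if n_omit else ids
    rows = []
    it = iter(usable)
    for d in decades:
        for _ in range(per_decade_n):
            try:
                gid = next(it)
            except StopIteration:
                break
            rows.append({"gene_id": gid, "est_counts": float(rng.uniform(10.0**d, 10.0 ** (d + 1)))})
    df = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    return df


@dataclass(frozen=True)
class CurveSpec:
    """Ground truth for one strain's plate-reader curves.

    Biomass follows a logistic, OD(t) = K / (1 + exp(-r (t - t0))). GFP is
    proportional to biomass (``gfp_per_biomass`` AU per OD unit) with a shared
    linear fluorophore-accumulation drift after the stationary onset that
    affects GFP and mCherry identically, so their ratio stays flat late in
    stationary phase. mCherry is built as RFU_true(t) x FI(GFP): RFU_true is a
    plateau at ``true_ratio x strength`` through mid-exponential phase,
    ramping linearly to a plateau at ``strength`` (the stationary RFU level)
    before stationary onset. Noise-free, the analysis recovers
    ``true_ratio`` exactly.
    """

    strain: str
    K: float = 1.0
    r: float = 0.5  # 1/h
    t0: float = 10.0  # h, inflection
    gfp_per_biomass: float = 50_000.0  # AU per OD unit
    true_ratio: float = 1.0
    strength: float = 0.1  # stationary RFU level
    active: bool = True
    noise_sd: float = 0.02  # fraction of clean signal
    media_background: float = 50.0  # AU, both channels
    media_od: float = 0.04
    drift_rate: float = 0.02  # 1/h shared accumulation after stationary onset
    sampling: tuple[float, float, float] = (0.0, 36.0, 0.25)  # h
    seed: int = 0


def _logistic(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def _rfu_true(t: np.ndarray, spec: CurveSpec) -> np.ndarray:
    """Plateau-ramp-plateau activity profile hitting the prescribed ratio."""
    t_stat = spec.t0 + np.log(99.0) / spec.r  # OD reaches 99% of K
    margin = 0.2 * (t_stat - spec.t0)
    t1, t2 = spec.t0 + margin, t_stat - margin
    a_e = spec.true_ratio * spec.strength
    a_s = spec.strength
    out = np.empty_like(t)
    out[t <= t1] = a_e
    out[t >= t2] = a_s
    ramp = (t > t1) & (t < t2)
    out[ramp] = a_e + (a_s - a_e) * (t[ramp] - t1) / (t2 - t1)
    return out


def generate_plate_timeseries(
    curve_specs: list[CurveSpec],
) -> tuple[list[PlateTimeSeries], pd.DataFrame]:
    """Simulate plate-reader curves for a set of strains plus ground truth.

    Returns one :class:`PlateTimeSeries` per spec (with matched media-control
    vectors) and a truth table recording each strain's true ratio, class and
    activity status.
    """
    series: list[PlateTimeSeries] = []
    rows = []
    for spec in curve_specs:
        t_start, t_end, dt = spec.sampling
        t = np.arange(t_start, t_end + dt / 2, dt)
        if t.size < 5:
            raise ValueError("sampling grid must contain at least 5 points")
        rng = np.random.default_rng(spec.seed)
        od_clean = _logistic(t, spec.K, spec.r, spec.t0)
        t_stat_true = spec.t0 + np.log(99.0) / spec.r
        drift = 1.0 + spec.drift_rate * np.clip(t - t_stat_true, 0.0, None)
        gfp_fi = spec.gfp_per_biomass * od_clean * drift
        if spec.active:
            mch_fi = _rfu_true(t, spec) * gfp_fi
        else:
            # no functional reporter: residual mCherry at the strength level
            mch_fi = spec.strength * gfp_fi
        noise = spec.noise_sd

        def jitter(clean: np.ndarray) -> np.ndarray:
            return clean + rng.normal(0.0, noise * np.abs(clean) + 1e-12, clean.shape) if noise else clean.copy()

        series.append(
            PlateTimeSeries(
                time=t,
                od600=jitter(od_clean) + spec.media_od,
                mcherry_raw=jitter(mch_fi) + jitter(np.full_like(t, spec.media_background)),
                gfp_raw=jitter(gfp_fi) + jitter(np.full_like(t, spec.media_background)),
                media_mcherry=jitter(np.full_like(t, spec.media_background)),
                media_gfp=jitter(np.full_like(t, spec.media_background)),
                media_od=jitter(np.full_like(t, spec.media_od)),
                strain=spec.strain,
            )
        )
        if spec.active:
            if spec.true_ratio < 0.7:
                cls = "stationary_biased"
            elif spec.true_ratio > 1.3:
                cls = "exponential_biased"
            else:
                cls = "unbiased"
        else:
            cls = ""
        rows.append(
            {
                "strain": spec.strain,
                "true_ratio": spec.true_ratio if spec.active else np.nan,
                "true_class": cls,
                "active": spec.active,
                "strength": spec.strength,
            }
        )
    return series, pd.DataFrame(rows)


def make_cohort_specs(
    n_stationary: int = 12,
    n_unbiased: int = 10,
    n_exponential: int = 3,
    n_inactive: int = 8,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    min_strength: float = 0.005,
    max_strength: float = 0.61,
    background_strength: float = 0.0005,
) -> list[CurveSpec]:
    """Curve specs for a sorted-candidate cohort plus the background strain.

    Defaults emulate the characterized cohort: 33 sorted strains of which 25
    are active — 12 stationary-biased, 10 unbiased, 3 exponential-biased —
    and 8 below detection. Active stationary-RFU strengths are log-spaced
    over [``min_strength``, ``max_strength``] (two orders of magnitude);
    inactive strains and the background strain sit at ``background_strength``.
    True ratios are drawn away from the 0.7 / 1.3 decision bounds:
    stationary-biased in [0.35, 0.60], unbiased in [0.85, 1.15],
    exponential-biased in [1.45, 1.90].
    """
    rng = np.random.default_rng(seed)
    n_active = n_stationary + n_unbiased + n_exponential
    ratios = np.concatenate(
        [
            rng.uniform(0.35, 0.60, n_stationary),
            rng.uniform(0.85, 1.15, n_unbiased),
            rng.uniform(1.45, 1.90, n_exponential),
        ]
    )
    strengths = np.geomspace(max_strength, min_strength, n_active) if n_active else np.array([])
    specs = [
        CurveSpec(
            strain=f"CPL{i:04d}",
            true_ratio=float(ratios[i]),
            strength=float(strengths[i]),
            active=True,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n_active)
    ]
    specs += [
        CurveSpec(
            strain=f"CPL{n_active + j:04d}",
            true_ratio=1.0,
            strength=background_strength,
            active=False,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for j in range(n_inactive)
    ]
    specs.append(
        CurveSpec(
            strain="background",
            true_ratio=1.0,
            strength=background_strength,
            active=False,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    return specs


def cohort_to_long_frame(series: list[PlateTimeSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into the long-format plate TSV plus a well map.

    Each strain gets one sample well; one shared media-control well is taken
    from the first strain's media vectors; the strain named 'background' is
    marked as the background well.
    """
    records = []
    wells = []
    for i, ts in enumerate(series):
        well = f"W{i + 1:03d}"
        role = "background" if ts.strain == "background" else "sample"
        wells.append({"well": well, "strain": ts.strain, "role": role})
        for j in range(ts.time.size):
            records.append(
                {
                    "well": well,
                    "strain": ts.strain,
                    "time_h": ts.time[j],
                    "od600": ts.od600[j],
                    "mcherry": ts.mcherry_raw[j],
                    "gfp": ts.gfp_raw[j],
                }
            )
    media = series[0]
    well = "MEDIA"
    wells.append({"well": well, "strain": "media", "role": "media"})
    for j in range(media.time.size):
        records.append(
            {
                "well": well,
                "strain": "media",
                "time_h": media.time[j],
                "od600": media.media_od[j] if media.media_od is not None else 0.0,
                "mcherry": media.media_mcherry[j],
                "gfp": media.media_gfp[j],
            }
        )
    return pd.DataFrame(records), pd.DataFrame(wells)
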