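"""Orchestration of the mine -> design -> analyze stages with file I/O.

Every stage is a pure function over the library modules plus readers/writers
for the plain-text interchange formats: GenBank and count-table TSV in,
candidate FASTA + attrition TSV, order-sheet TSV + JSON manifest, and
per-strain profile TSV + class summary out. A resolved :class:`PipelineConfig`
is embedded in each run's manifest so any run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from utrmine import fluorescence as fl
from utrmine import genome_mining as gm
from utrmine import library_design as ld
from utrmine import synthetic as syn

__all__ = [
    "PipelineConfig",
    "run_mine",
    "run_design",
    "run_analyze",
    "run_simulate",
    "analyze_cohort",
    "write_candidates_fasta",
    "write_attrition_table",
]


@dataclass
class PipelineConfig:
    """All tunables of the three stages, round-trippable through YAML."""

    # mining
    min_len: int = 60
    max_len: int = 170
    circular: bool = False
    # design
    cap: int = 500
    tranche1_size: int = 350
    tranche1_max_len: int = 98
    per_decade: int = 50
    trim_target: int = 98
    oligo_length: int = 150
    left_flank: str = ld.DEFAULT_LEFT_FLANK
    right_flank: str = ld.DEFAULT_RIGHT_FLANK
    # analysis
    sg_window: int = 21
    sg_polyorder: int = 3
    ratio_window: int = 3
    ratio_low: float = 0.7
    ratio_high: float = 1.3
    detect_k: float = 3.0
    gfp_eps: float = 1e-9
    # shared
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def write_candidates_fasta(candidates: list[gm.CandidateUTR], path: str | Path) -> None:
    """FASTA with per-record header: id, gene, length and flags."""
    with open(path, "w") as fh:
        for c in candidates:
            flags = ",".join(sorted(c.filter_flags)) or "none"
            fh.write(f">{c.candidate_id} gene={c.gene_id} length={c.length} flags={flags}\n")
            seq = c.sequence or "N"
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_attrition_table(candidates: list[gm.CandidateUTR], path: str | Path) -> pd.DataFrame:
    """One row per candidate, one boolean column per filter flag."""
    rows = []
    for c in candidates:
        row = {
            "candidate_id": c.candidate_id,
            "gene_id": c.gene_id,
            "length": c.length,
            "upstream_gene_id": c.upstream_gene_id,
            "upstream_strand": c.upstream_strand,
            "read_count": c.read_count if c.read_count is not None else "",
        }
        for flag in sorted(gm.FILTER_FLAGS):
            row[flag] = flag in c.filter_flags
        row["passes"] = c.passes
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def run_mine(
    genome_path: str | Path,
    counts_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Extract candidates, apply all filters, write FASTA + attrition TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = gm.parse_genome(str(genome_path))
    from Bio import SeqIO

    genome_seq = str(next(SeqIO.parse(str(genome_path), "genbank")).seq)
    candidates = gm.extract_candidate_utrs(genes, genome_seq, circular=config.circular)
    gm.filter_by_length(candidates, config.min_len, config.max_len)
    counts = gm.read_count_table(str(counts_path))
    gm.filter_by_transcriptome(candidates, counts)
    gm.apply_restriction_filter(candidates)
    write_candidates_fasta(candidates, out / "candidates.fasta")
    table = write_attrition_table(candidates, out / "attrition.tsv")
    return table


def _load_candidates_from_attrition(path: str | Path) -> list[gm.CandidateUTR]:
    """Rebuild surviving candidates from a mine run (attrition + FASTA)."""
    att = pd.read_csv(path, sep="\t")
    seqs: dict[str, str] = {}
    fasta = Path(path).with_name("candidates.fasta")
    from Bio import SeqIO

    for rec in SeqIO.parse(str(fasta), "fasta"):
        seqs[rec.id] = str(rec.seq)
    out = []
    for _, row in att.iterrows():
        flags = {f for f in gm.FILTER_FLAGS if bool(row[f])}
        out.append(
            gm.CandidateUTR(
                candidate_id=row["candidate_id"],
                gene_id=row["gene_id"],
                sequence="" if "overlap" in flags else seqs.get(row["candidate_id"], ""),
                upstream_gene_id=row["upstream_gene_id"],
                upstream_strand=row["upstream_strand"],
                read_count=float(row["read_count"]) if row["read_count"] != "" and pd.notna(row["read_count"]) else None,
                filter_flags=flags,
            )
        )
    return out


def run_design(
    mine_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Select and assemble the oligo library; write order sheet + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates = _load_candidates_from_attrition(Path(mine_dir) / "attrition.tsv")
    survivors = gm.surviving(candidates)
    if not survivors:
        raise ld.EmptyLibraryError("mine run produced zero surviving candidates")
    plan = ld.SelectionPlan(
        cap=config.cap,
        tranche1_size=config.tranche1_size,
        tranche1_max_len=config.tranche1_max_len,
        per_decade=config.per_decade,
    )
    designs = ld.design_library(
        survivors,
        plan,
        left_flank=config.left_flank,
        right_flank=config.right_flank,
        total_len=config.oligo_length,
        trim_target=config.trim_target,
        seed=config.seed,
    )
    sheet = pd.DataFrame(
        [
            {
                "candidate_id": d.candidate_id,
                "insert": d.insert,
                "oligo": d.oligo,
                "insert_length": len(d.insert),
                "pre_trim_length": d.pre_trim_length,
                "pad_length": len(d.pad),
                "oligo_length": len(d.oligo),
                "seed": d.seed,
            }
            for d in designs
        ]
    )
    sheet.to_csv(out / "order_sheet.tsv", sep="\t", index=False)
    with open(out / "oligos.fasta", "w") as fh:
        for d in designs:
            fh.write(f">{d.candidate_id}\n{d.oligo}\n")
    manifest = dataclasses.asdict(config)
    manifest["n_survivors"] = len(survivors)
    manifest["n_oligos"] = len(designs)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return sheet


def analyze_cohort(
    series: list[fl.PlateTimeSeries],
    config: PipelineConfig = PipelineConfig(),
    background_strain: str = "background",
) -> pd.DataFrame:
    """Profile every strain and classify detectable ones.

    The background strain supplies the noise floor: a strain is detectable if
    its stationary RFU exceeds the background's late-stationary mean by more
    than ``detect_k`` standard deviations. Only detectable strains receive a
    phase class.
    """
    kwargs = dict(
        sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder,
        ratio_window=config.ratio_window,
        low=config.ratio_low,
        high=config.ratio_high,
        eps=config.gfp_eps,
    )
    bg_ts = next((s for s in series if s.strain == background_strain), None)
    if bg_ts is None:
        raise ValueError(f"background strain {background_strain!r} not found in cohort")
    bg_fi_m = fl.background_correct(bg_ts.mcherry_raw, bg_ts.media_mcherry).values
    bg_fi_g = fl.background_correct(bg_ts.gfp_raw, bg_ts.media_gfp).values
    bg_rfu = fl.compute_rfu(bg_fi_m, bg_fi_g, eps=config.gfp_eps)
    bg_od = fl.smooth_series(bg_ts.od600, config.sg_window, config.sg_polyorder)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        _, bg_tstat = fl.find_growth_phases(bg_od, bg_ts.time)
    bg_mask = bg_ts.time >= bg_tstat
    if bg_mask.sum() < 10:  # late plateau too short: take the last 10 samples
        bg_mask = np.zeros_like(bg_mask)
        bg_mask[-10:] = True
    bg_samples = bg_rfu[bg_mask]

    rows = []
    for ts in series:
        if ts.strain == background_strain:
            continue
        fi_m = fl.background_correct(ts.mcherry_raw, ts.media_mcherry).values
        fi_g = fl.background_correct(ts.gfp_raw, ts.media_gfp).values
        rfu = fl.compute_rfu(fi_m, fi_g, eps=config.gfp_eps)
        od = fl.smooth_series(ts.od600, config.sg_window, config.sg_polyorder)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            t_mid, t_stat = fl.find_growth_phases(od, ts.time)
        rfu_stat = fl._window_mean(rfu, ts.time, t_stat, config.ratio_window)
        detectable = fl.detect_active(rfu_stat, bg_samples, k=config.detect_k)
        ratio = np.nan
        cls = ""
        if detectable:
            ratio = fl.differential_activity(
                rfu, ts.time, t_mid, t_stat, window=config.ratio_window
            )
            cls = fl.classify_phase_bias(ratio, low=config.ratio_low, high=config.ratio_high)
        rows.append(
            {
                "strain": ts.strain,
                "t_midexp": t_mid,
                "t_stat": t_stat,
                "rfu_midexp": fl._window_mean(rfu, ts.time, t_mid, config.ratio_window),
                "rfu_stat": rfu_stat,
                "differential_activity": ratio,
                "phase_class": cls,
                "detectable": detectable,
            }
        )
    return pd.DataFrame(rows)


def read_plate_long(
    plate_path: str | Path, wellmap_path: str | Path
) -> list[fl.PlateTimeSeries]:
    """Assemble per-strain series from the long-format plate TSV + well map.

    The well map must mark exactly one ``media`` well (the control) and may
    mark one ``background`` well; every other well is a sample.
    """
    plate = pd.read_csv(plate_path, sep="\t")
    wells = pd.read_csv(wellmap_path, sep="\t")
    media_wells = wells.loc[wells["role"] == "media", "well"].tolist()
    if not media_wells:
        raise ValueError(f"well map {wellmap_path} contains no media-control well")
    media = plate[plate["well"] == media_wells[0]].sort_values("time_h")
    out = []
    for well, grp in plate[plate["well"] != media_wells[0]].groupby("well"):
        grp = grp.sort_values("time_h")
        strain = str(grp["strain"].iloc[0])
        out.append(
            fl.PlateTimeSeries(
                time=grp["time_h"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                mcherry_raw=grp["mcherry"].to_numpy(),
                gfp_raw=grp["gfp"].to_numpy(),
                media_mcherry=media["mcherry"].to_numpy(),
                media_gfp=media["gfp"].to_numpy(),
                media_od=media["od600"].to_numpy(),
                strain=strain,
            )
        )
    return out


def run_analyze(
    plate_path: str | Path,
    wellmap_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile a plate run and write per-strain profiles + class summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = read_plate_long(plate_path, wellmap_path)
    profiles = analyze_cohort(series, config)
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    det = profiles[profiles["detectable"]]
    summary = (
        det["phase_class"].value_counts().reindex(fl.PHASE_CLASSES, fill_value=0).rename("n_strains")
    )
    summary_df = summary.reset_index().rename(columns={"index": "phase_class"})
    summary_df.loc[len(summary_df)] = ["detectable_total", int(det.shape[0])]
    summary_df.loc[len(summary_df)] = ["total", int(profiles.shape[0])]
    summary_df.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    return profiles, summary_df


def run_simulate(
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    *,
    n_genes: int = 761,
    n_survivor_target: int = 722,
) -> None:
    """Write a full synthetic input set: genome, counts, plate data, truth.

    The genome carries tandem plus-strand genes with gaps inside the length
    window so the mined survivor count equals ``n_survivor_target``; the
    plate data emulate the characterized cohort (25 active of 33, classes
    12/10/3).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    spec = syn.GenomeSpec(
        n_genes=n_genes,
        gap_lengths=tuple(int(g) for g in rng.integers(60, 171, n_genes - 1)),
        strand_pattern=("+",) * n_genes,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genbank, truth = syn.generate_genome(spec)
    (out / "genome.gbk").write_text(genbank)
    truth.to_csv(out / "genome_truth.tsv", sep="\t", index=False)

    candidate_genes = truth["gene_id"].tolist()
    rng.shuffle(candidate_genes)
    keep = sorted(candidate_genes[:n_survivor_target])
    per_dec = -(-len(keep) // 3)  # ceil so three decades cover the set
    counts = syn.generate_counts(
        keep, decades=(1, 2, 3), per_decade_n=per_dec,
        seed=int(rng.integers(0, 2**31 - 1)), omit_fraction=0.0,
    )
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)

    specs = syn.make_cohort_specs(seed=int(rng.integers(0, 2**31 - 1)))
    series, cohort_truth = syn.generate_plate_timeseries(specs)
    plate, wellmap = syn.cohort_to_long_frame(series)
    plate.to_csv(out / "plate.tsv", sep="\t", index=False)
    wellmap.to_csv(out / "wellmap.tsv", sep="\t", index=False)
    cohort_truth.to_csv(out / "cohort_truth.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
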