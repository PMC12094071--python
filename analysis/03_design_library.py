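"""Design the 500-oligo synthesis library from the mined survivors.

Applies the two-tranche selection (350 shortest candidates, then the 50
highest-expressed per read-count decade), trims inserts from the 5' end to
98 bp, and assembles 150 bp oligos with Golden-Gate flanks and seeded random
padding screened against BsaI/BsmBI/BbsI sites.
"""

from pathlib import Path

import pandas as pd

from utrmine import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = pl.PipelineConfig.from_yaml(SCRATCH / "sim" / "config.yaml")
    sheet = pl.run_design(SCRATCH / "mine", SCRATCH / "design", cfg)
    summary = pd.DataFrame(
        [
            {"quantity": "library_size", "value": len(sheet)},
            {"quantity": "oligo_length_bp", "value": int(sheet["oligo_length"].max())},
            {"quantity": "max_insert_bp", "value": int(sheet["insert_length"].max())},
            {"quantity": "min_insert_bp", "value": int(sheet["insert_length"].min())},
            {"quantity": "trimmed_inserts", "value": int(
                (sheet["pre_trim_length"] > sheet["insert_length"]).sum()
            )},
            {"quantity": "mean_pad_bp", "value": round(sheet["pad_length"].mean(), 1)},
        ]
    )
    summary.to_csv(RESULTS / "03_library_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
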