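"""Profile the simulated reporter cohort and classify growth-phase bias.

Runs the normalization chain — media-background subtraction, mCherry/GFP
ratio (RFU), Savitzky-Golay OD smoothing, max-slope / max-OD phase
timepoints — then forms the differential-activity ratio (mid-exponential RFU
over stationary RFU) and classifies each detectable strain with the 0.7/1.3
thresholds. With the simulated cohort the detectable set is 25 of 33 and the
class split is 12 stationary-biased / 10 unbiased / 3 exponential-biased,
with stationary RFU spanning roughly 0.005-0.61.
"""

from pathlib import Path

import pandas as pd

from utrmine import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = pl.PipelineConfig.from_yaml(SCRATCH / "sim" / "config.yaml")
    profiles, summary = pl.run_analyze(
        SCRATCH / "sim" / "plate.tsv", SCRATCH / "sim" / "wellmap.tsv",
        SCRATCH / "analyze", cfg,
    )
    truth = pd.read_csv(SCRATCH / "sim" / "cohort_truth.tsv", sep="\t")
    merged = profiles.merge(truth, on="strain")
    act = merged[merged["active"]]
    agree = (act["phase_class"] == act["true_class"]).mean()

    det = profiles[profiles["detectable"]]
    out = summary.copy()
    out.loc[len(out)] = ["class_agreement_with_truth", round(float(agree), 3)]
    out.loc[len(out)] = ["max_stationary_rfu", round(float(det["rfu_stat"].max()), 3)]
    out.loc[len(out)] = ["min_stationary_rfu", round(float(det["rfu_stat"].min()), 4)]
    out.to_csv(RESULTS / "04_cohort_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
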