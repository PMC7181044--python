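#!/usr/bin/env python
"""Scan stepwise static windows and select the optimal SUVR window.

For every 30-min candidate window (start 0, 10, ..., 60 min, plus the full
scan) the windowed SUVR of each animal is regressed on its Logan DVR, per
region. The optimal window is the one where cortex, hippocampus and
striatum all reach r^2 >= 0.90 with the regression slope closest to 1
(midbrain is excluded: its signal emerges too late and weakly).
"""

import json
from pathlib import Path

import pandas as pd

from taupet.frames import default_schedule, read_tac_csv, write_results_csv
from taupet.suvr import select_optimal_window, window_scan

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    schedule = default_schedule()
    tacs = {
        p.stem[len("tac_"):]: read_tac_csv(p)
        for p in sorted((BASE / "cohort").glob("tac_*.csv"))
    }
    dvr = pd.read_csv(BASE / "dvr.csv")

    scan = window_scan(tacs, dvr, schedule)
    write_results_csv(BASE / "window_scan.csv", scan)
    win, report = select_optimal_window(scan)

    payload = {
        "optimal_window_min": [win.start, win.end],
        "windows": report.to_dict(orient="records"),
    }
    (BASE / "optimal_window.json").write_text(json.dumps(payload, indent=1) + "\n")

    print("per-window selection report (midbrain excluded):")
    print(report.round(4).to_string(index=False))
    print(f"\noptimal static window: {win.label()} min post-injection")
    r2 = scan[scan.win_start >= 40].groupby("region")["r2"].min().round(3)
    print("minimum r^2 across windows starting >= 40 min, by region:")
    print(r2.to_string())


if __name__ == "__main__":
    main()
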