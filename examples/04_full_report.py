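"""The full pipeline: CSV in, per-segment per-side metric report out.

Writes a two-sided three-iteration reach fixture to CSV, reads it back,
runs every metric for both arms and exports JSON + CSV reports.  The same
run is available from the shell:

    armkin synth reach --iterations 3 --side both --out reach.csv
    armkin analyze --input reach.csv --target 200,600,1300 \
        --export-json report.json --export-csv report.csv
"""

import tempfile
from pathlib import Path

from armkin import AnalysisConfig, SynthSpec, export_report, generate_reach, read_recording, run_analysis, write_recording

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    spec = SynthSpec(amplitude=300.0, duration=1.0, rate=200.0, n_iterations=3, arm_side="both")
    rec, truth = generate_reach(spec)
    write_recording(rec, tmp / "reach.csv")

    config = AnalysisConfig(input=read_recording(tmp / "reach.csv"), target=dict(truth.targets))
    report = run_analysis(config)
    export_report(report, "json", tmp / "report.json")
    export_report(report, "csv", tmp / "report.csv")

    computed = [v for v in report.values if v.value is not None]
    print(f"{len(computed)} metric values over {report.provenance['n_segments']} segments x 2 sides")
    print(f"{len(report.rom)} task-level ROM results\n")
    print("segment 1, right arm:")
    for v in report.values:
        if v.segment == "1" and v.side == "right":
            print(f"  {v.name:24s} {v.value:10.4f} {v.unit}")
    for r in report.rom:
        if r.side == "right":
            print(f"  {r.joint + ' ROM':24s} {r.rom:10.4f} deg")
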