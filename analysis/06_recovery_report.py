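"""Run the full parameter-recovery pipeline (every experiment class, one
seed) and write the reference-comparison report.

Writes: results/report.json, results/report.txt
"""

from pathlib import Path

from myokin.pipeline import default_config, format_report, run_pipeline, write_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = run_pipeline(default_config(seed=1))
    write_report(report, OUT)
    print(format_report(report))


if __name__ == "__main__":
    main()
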