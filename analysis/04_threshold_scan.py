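"""Threshold scan and ROC of the baseline connectome against ground truth.

Consumes the matrices written by 03_baseline_connectome.py, sweeps the
acceptance threshold from 0 to 100% in 1% steps, and writes the full
accuracy/TP-rate/FP-rate table plus the optimum to results/scan_six_region.csv.
"""

from pathlib import Path

from tractvalid import connectome as cn
from tractvalid import validation as va


def main():
    base = Path("results/baseline")
    if not (base / "sci_curv180_fa0.csv").exists():
        raise SystemExit("run analysis/03_baseline_connectome.py first")
    sci = cn.SciMatrix.from_csv(base / "sci_curv180_fa0.csv")
    truth = va.TernaryTruth.from_csv(base / "truth.csv")
    scan = va.threshold_scan(sci, truth)
    scan.table.to_csv("results/scan_six_region.csv", index=False)
    head = scan.table.head(8)
    print(head.to_string(index=False))
    print("...")
    print(f"optimum threshold {scan.optimum_threshold:g}% "
          f"(accuracy {scan.optimum_accuracy:.1f}%)")
    auc_points = scan.roc()
    print(f"ROC endpoints: fp/tp at t=0 -> {tuple(auc_points[0])}, "
          f"at t=100 -> {tuple(auc_points[-1])}")


if __name__ == "__main__":
    main()
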