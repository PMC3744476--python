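#!/usr/bin/env python
"""Detect barren circles in the simulated landscape and score the result.

Runs the morphological detector (Otsu threshold, disk opening, component
filtering) on results/simulated/landscape.png, writes the detections table,
and evaluates precision/recall/area bias against the known ground truth —
the synthetic analogue of checking aerial-photograph analysis against
ground survey (the original comparison found an 11.4% area underestimate).
"""

import json
from pathlib import Path

from fairycircles.detection import detect_circles, evaluate_detection, write_detections_csv
from fairycircles.geometry import CirclePattern
from fairycircles.rasters import read_raster

SIM = Path("results/simulated")
OUT = Path("results")


def main() -> None:
    image = read_raster(SIM / "landscape.png")
    truth = CirclePattern.from_csv(SIM / "circles_true.csv")
    detected = detect_circles(image)
    write_detections_csv(detected, OUT / "detections.csv")
    score = evaluate_detection(detected, truth)
    (OUT / "detection_eval.json").write_text(json.dumps(score, indent=2))
    print(f"detected {len(detected)} of {truth.n} circles")
    print(
        f"precision {score['precision']:.3f}, recall {score['recall']:.3f}, "
        f"area bias {score['area_bias_pct']:+.1f}%"
    )


if __name__ == "__main__":
    main()
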