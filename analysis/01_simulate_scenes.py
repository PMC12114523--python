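#!/usr/bin/env python
"""Render the study's synthetic scenes and export images plus ground truth.

Writes the TIFF stacks and annotation files (large/binary) under
``scratch/scenes/`` and the ground-truth tables (text) under ``results/``:
a pearled axon, a branch-point scene at the cohort-mean calibers, one time
lapse per dynamics event class, and the dividing-cell scene.
"""

import argparse
import logging
from pathlib import Path

from caliberkit import (
    CaliberProfileSpec,
    DynamicsEventSpec,
    render_axon_image,
    render_branch_scene,
    render_dividing_scene,
    render_timelapse,
    straight_axon_spec,
    write_annotations,
    write_stack,
)
from caliberkit.io import stage, write_results
from caliberkit.pipeline import default_dividing_scene

logging.basicConfig(level=logging.INFO)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/scenes"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.scratch.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    with stage("pearled axon"):
        profile = CaliberProfileSpec(0.25, pearls=((5.0, 0.35, 0.8), (11.0, 0.3, 1.0), (16.0, 0.35, 0.7)))
        spec = straight_axon_spec(20.0, profile, rng_seed=args.seed)
        stack, truth = render_axon_image(spec)
        write_stack(stack, args.scratch / "pearled_axon.tif")
        write_results(truth, args.results / "pearled_axon_truth.csv")

    with stage("branch scene"):
        scene = render_branch_scene(0.43, 0.32, 0.20, rng_seed=args.seed + 1)
        write_stack(scene.stack, args.scratch / "branch_scene.tif")
        write_annotations(scene.annotations, args.scratch / "branch_scene.json")

    with stage("dynamics time lapses"):
        events = {
            "traveling_pearl": DynamicsEventSpec(
                "traveling_pearl",
                dict(center_s_um=4.0, amplitude_um=0.4, width_s_um=0.7, speed_um_per_frame=1.0),
            ),
            "focal_inflation_deflation": DynamicsEventSpec(
                "focal_inflation_deflation",
                dict(center_s_um=5.0, amplitude_um=0.35, width_s_um=0.8,
                     start_frame=0, rise_frames=3, fall_frames=3),
            ),
            "segment_widening_narrowing": DynamicsEventSpec(
                "segment_widening_narrowing",
                dict(span_um=(4.0, 10.0), scale_factor=1.5, start_frame=1,
                     rise_frames=1, hold_frames=8, fall_frames=1),
            ),
            "constriction_point": DynamicsEventSpec(
                "constriction_point",
                dict(center_s_um=5.0, depth_um=0.22, width_s_um=0.6, on_frames=(3, 4)),
            ),
        }
        for name, ev in events.items():
            spec = straight_axon_spec(16.0, 0.3 if "constriction" not in name else 0.45,
                                      rng_seed=args.seed + 2)
            stack, truth = render_timelapse(spec, [ev], n_frames=8)
            write_stack(stack, args.scratch / f"dynamics_{name}.tif")
            write_results(truth, args.results / f"dynamics_{name}_truth.csv")
            print(f"{name}: {stack.n_frames} frames at {stack.frame_interval_min:.0f} min")

    with stage("dividing-cell scene"):
        scene_spec, axon_spec = default_dividing_scene(seed=args.seed + 3)
        render = render_dividing_scene(scene_spec, axon_spec)
        write_stack(render.stack, args.scratch / "dividing_scene.tif")
        write_annotations(render.annotations, args.scratch / "dividing_scene.json")
        write_results(render.truth, args.results / "dividing_scene_truth.csv")
        print(
            f"dividing scene: round frame {render.round_frame} -> flat frame "
            f"{render.flat_frame}; border lengths {list(render.border_lengths_um)}"
        )


if __name__ == "__main__":
    main()
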