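"""A full synthetic operation pushed through the sizing pipeline.

Generates a synthetic CABG: a patient context (MCA diameters, haematocrit
trace), a stage-structured embolic event stream with ground-truth
diameters, and the forward-modelled raw MEBR stream.  The pipeline then
filters at 7 dB, annotates showers, sizes every event and prints the
per-stage medians next to the generator's calibration.
"""

import numpy as np

from airemboli import (
    default_protocol,
    detect_showers,
    filter_detections,
    sample_operation,
    sample_patient,
    size_stream,
    synthesize_stream,
)

patient = sample_patient(seed=101, procedure="CABG")
protocol = default_protocol("CABG")
truth, curtains = sample_operation(protocol, patient, seed=102)
stream = synthesize_stream(truth, patient, seed=103)

print(f"patient: MCA {patient.mca_diameter_left:.2f}/{patient.mca_diameter_right:.2f} mm, "
      f"haematocrit {patient.haematocrit_samples[0][1]:.2f} at start")
print(f"generated {len(stream)} raw signals over {truth['time_s'].max():.0f} s")

events = filter_detections(list(zip(stream["time_s"], stream["side"], stream["mebr_db"])))
print(f"{len(events)} signals at or above the 7 dB detection threshold")
showers = detect_showers(events)
print(f"{len(showers)} showers (>5 emboli/s)")

stage_of = dict(zip(zip(stream["time_s"], stream["side"]), stream["stage"]))
for e in events:
    e.phase = stage_of[(e.time, e.side)]

diameters, stages = [], []
for side in ("left", "right"):
    for e, b in zip(
        [e for e in events if e.side == side and not e.curtain_member],
        size_stream(events, patient, side),
    ):
        if b is not None:
            diameters.append(b.diameter)
            stages.append(e.phase)

diameters = np.array(diameters)
stages = np.array(stages)
print(f"\nrecovered median diameter: {np.median(diameters):.1f} um over {len(diameters)} events")
for stage, calib in (("CPB", 28.0), ("post-AxC", 72.0)):
    sel = np.isin(stages, [stage])
    if sel.any():
        print(f"  {stage:>9}: median {np.median(diameters[sel]):5.1f} um "
              f"(generator calibration {calib:.0f} um, n={sel.sum()})")
print(
    "\nStage medians recover the generator's calibration through the full"
    "\nmeasure-then-invert loop; the residual gap is measurement noise."
)
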