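"""Linear sway measures of quiet stance: path length, sway area, ratios.

Generates one synthetic subject's 60 s eyes-open and eyes-closed
centre-of-pressure traces, applies the standard zero-phase low-pass filter,
and prints the conventional stabilometry summaries.
"""

from swayrqa import (
    CohortSpec,
    SubjectParams,
    butterworth_filter,
    confidence_ellipse,
    gen_quiet_stance,
    log_area_ratio,
    path_length,
    romberg_ratio,
)

spec = CohortSpec(master_seed=42)
subject = SubjectParams(subject_id="demo", v=0.6, seed=42)

traces = {
    eyes: butterworth_filter(gen_quiet_stance(subject, eyes, spec))
    for eyes in ("open", "closed")
}
paths = {eyes: path_length(t) for eyes, t in traces.items()}
areas = {eyes: confidence_ellipse(t).area for eyes, t in traces.items()}

for eyes in ("open", "closed"):
    print(f"eyes {eyes}: path {paths[eyes] / 1000:.2f} m, "
          f"95% ellipse area {areas[eyes]:.0f} mm^2")
print(f"Romberg ratio (closed/open path): {romberg_ratio(paths['closed'], paths['open']):.2f}")
print(f"log sway-area ratio (open/closed): {log_area_ratio(areas['open'], areas['closed']):+.2f}")
print()
print("A Romberg ratio above 1 means this subject sways more without vision;")
print("the log area ratio is the area-based analogue (0 = equal areas).")
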