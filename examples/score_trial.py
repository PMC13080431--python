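"""Score-mode basics: turn a rater's toggle stream into a status table.

A rater watching a 6-min, 30 fps trial toggles a mobile/immobile switch;
each toggle is a "mark" at a video frame. The marks and the expected
initial state fully determine the run-length mobility status table and the
immobility times.
"""

from tstscore import (
    TrialClock,
    marks_to_table,
    partial_immobility,
    table_to_timeline,
    total_immobility,
)

clock = TrialClock(fps=30.0, n_frames=10800)  # 6 min at 30 fps

# the rater toggled at these frames (mouse starts mobile)
marks = [900, 2700, 3600, 5400, 6300, 9000]
table = marks_to_table(marks, initial_state=1, clock=clock,
                       scorer="rater_A", trial_id="demo_trial")

print("Mobility status table (state, start frame, frames, start s, dur s):")
for seg in table.segments:
    print(f"  {seg.mobility_state}  {seg.mark_frame:>6}  {seg.interval_frames:>6}"
          f"  {seg.mark_sec:>9.3f}  {seg.interval_sec:>8.3f}")

timeline = table_to_timeline(table)
t_f = total_immobility(timeline)
t_p = partial_immobility(timeline, exclude_sec=120.0)
print(f"\nT_f = {t_f:.1f} s   (cumulative immobility over the whole trial)")
print(f"T_p = {t_p:.1f} s   (immobility after the first 2 min, the value")
print("                 usually reported for this assay)")
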