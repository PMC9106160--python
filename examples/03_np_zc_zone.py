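"""The NP-ZC zone: where the true toe-off hides.

The dual-minima rule marks toe-off at the negative peak (NP) of the shank
velocity, which precedes the true toe-off; the subsequent negative-to-
positive zero crossing (ZC) comes after it.  This script detects both per
cycle and shows that the force-plate toe-off falls inside the [NP, ZC]
interval — the zone a refined estimator should target.
"""
from gaitevents import detect_events, reference_events, zero_crossing_to
from gaitevents.kinematics import shank_signal_from_markers
from gaitevents.simulate import SyntheticConfig, generate_trial

config = SyntheticConfig(seed=3, n_cycles=8)
trial = generate_trial(config)
signal = shank_signal_from_markers(trial.markers, "sound")
events = detect_events(signal)
true_to = [e.time_s for e in reference_events(trial.force, sides=["sound"])
           if e.kind == "TO"]

ms_times = {e.cycle_index: e.time_s for e in events if e.kind == "MS"}
print("cycle   NP (det. TO)   true TO      ZC     TO inside [NP, ZC]?")
for to in (e for e in events if e.kind == "TO"):
    zc = zero_crossing_to(signal.omega, signal.fs, to, until_s=ms_times[to.cycle_index])
    truth = min(true_to, key=lambda t: abs(t - to.time_s))
    inside = to.time_s <= truth <= zc.time_s
    print(f"  {to.cycle_index}     {to.time_s:8.3f} s   {truth:8.3f} s "
          f"{zc.time_s:8.3f} s   {'yes' if inside else 'NO'}")
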