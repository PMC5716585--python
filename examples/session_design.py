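"""Pseudo-randomised 2AFC session schedules.

Generates an interleaved (dog-style) and a blocked (human-style) session,
prints the head of each, and shows the validator both passing a generated
schedule and catching a deliberately broken one.
"""

from acuityfit import (
    SessionSchedule,
    Trial,
    generate_dog_session,
    generate_human_session,
    validate_schedule,
)

dog = generate_dog_session([2, 4, 6, 8, 10, 12, 14, 16], trials_per_freq=20, seed=1)
print(f"dog session: {len(dog.trials)} trials "
      f"({sum(t.warmup for t in dog.trials)} warm-ups + {len(dog.scored)} scored)")
for i, t in enumerate(dog.trials[:6]):
    tag = "warm-up" if t.warmup else "scored"
    print(f"  trial {i}: {t.frequency:>4} cpd, rewarded {t.correct_side:<5} ({tag})")
print(f"  validator: {validate_schedule(dog) or 'no violations'}")

human = generate_human_session([30, 39, 44, 50, 64, 70, 78], trials_per_freq=20, seed=7)
blocks = []
for t in human.trials:
    if not blocks or blocks[-1] != t.frequency:
        blocks.append(t.frequency)
print(f"human session: {len(human.trials)} trials in ascending blocks {blocks}")

# three identical sides in a row violate the design
broken = SessionSchedule(
    trials=tuple(Trial(4.0, s) for s in ("left", "left", "left", "right")),
    mode="dog_interleaved", seed=0,
)
print("broken schedule ->", validate_schedule(broken)[0])
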