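"""Run one simulated participant through the adaptive-contrast experiment.

A reduced geometry (100 words, 4 sessions x 2 blocks x 100 trials) keeps the
run fast while preserving the schedule contract: each word appears 8 times,
twice per spatial-frequency condition, never twice in a block. The
per-condition staircase (start 35%, step 16% halved at each reversal, floor
1%) should hold accuracy near 50% once converged.
"""

import temposample as ts

words = ts.demo_words(100, seed=0)
schedule = ts.build_trial_schedule(words, n_sessions=4, blocks_per_session=2,
                                   trials_per_block=100, seed=1)
ts.validate_schedule(schedule, 4, 2, 100)
print(f"schedule: {len(schedule)} trials over 8 blocks, contract verified")

observer = ts.make_paperlike_observer(seed=0)
log = ts.run_simulated_experiment(schedule, observer, seed=2, participant_id=0)

print("\nall sessions:")
print(ts.summarize_log(log).to_string(index=False))
late = log[log.session >= 3]
print("\nfinal two sessions (staircase converged):")
print(ts.summarize_log(late).to_string(index=False))
# accuracy_pct should sit near 50% per condition; mean_contrast_pct should be
# higher for the extreme spatial-frequency bands (conditions 1 and 4) than
# for the intermediate ones.
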