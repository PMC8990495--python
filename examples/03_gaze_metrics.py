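"""Score eye-movement pattern (A-B scale) and consistency (entropies).

Samples scanpaths from each archetype and scores them against the two
representative patterns.  Data generated by Pattern A's generator should
score positive on the A-B scale, Pattern B's negative; the eyes-focused
pattern should show lower conditional entropies (more consistent gaze
transitions).
"""

from gazehmm import ab_scale, fixation_entropies, sample_sequences
from gazehmm.synth import make_prototypes

protos = make_prototypes()

for name, generator in (("Pattern A (broad)", protos.pattern_a),
                        ("Pattern B (eyes-focused)", protos.pattern_b)):
    seqs = sample_sequences(generator, n_trials=32, length_dist=6, seed=11)
    score = ab_scale(seqs, protos.pattern_a, protos.pattern_b)
    prof = fixation_entropies(generator)
    print(f"{name}:")
    print(f"  A-B scale = {score.value:+.4f} "
          f"(mean ll under A {score.ll_a:.1f}, under B {score.ll_b:.1f} nats)")
    print(f"  entropies (bits): h1 = {prof.h1:.3f}, "
          f"h2|1 = {prof.h2_given_1:.3f}, h3|2 = {prof.h3_given_2:.3f}")

# The A-B scale is positive when the data are more A-like and negative when
# more B-like; Pattern B's near-zero conditional entropies reflect its highly
# predictable broad -> eyes -> eyes scanpath routine.
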