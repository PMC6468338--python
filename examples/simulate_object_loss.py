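"""How object loss biases the presented-object-only estimate.

Simulates the two-round unique-object procedure on a known population of
1000 with capture probability 0.3 per round, sweeping the probability that
a marked individual still has the object at capture 2. Under the
presented-only recapture definition, every lost object removes a recapture
and inflates the estimate by roughly 1/retention; counting correct photo
identifications as recaptures (definition 1) restores the estimate.
"""

from crcpse import SimulationConfig, recovery_study

REPS = 300

print("ideal closed population (retention 1.0):")
res = recovery_study(SimulationConfig(true_n=1000, seed=42), REPS)
print(f"  mean N_hat {res.mean_n_hat:7.1f}  relative bias {res.relative_bias:+.3f}"
      f"  95% CI coverage {res.coverage:.3f}")

print("\nobject loss, photo identification perfect:")
for retention in (0.7, 0.5):
    cfg = SimulationConfig(true_n=1000, retention_prob=retention,
                           photo_id_accuracy=1.0, seed=42)
    d2 = recovery_study(cfg, REPS, definition="def2")
    d1 = recovery_study(cfg, REPS, definition="def1")
    print(f"  retention {retention:.1f}: def2 mean N_hat {d2.mean_n_hat:7.1f} "
          f"(x{d2.mean_n_hat / 1000:.2f} of truth), def1 mean N_hat {d1.mean_n_hat:7.1f}")

print()
print("With retention 0.5 the presented-only estimate roughly doubles, the")
print("same mechanism that separates a town's two published estimates when")
print("participants lose or sell the objects between rounds; the photo-sheet")
print("definition recovers the truth when identification is accurate.")
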