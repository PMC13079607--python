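"""Directional face-heart transfer entropy on a coupled synthetic cohort.

The generator injects heart->face coupling (face spike amplitudes mix in the
held heart spike magnitude five frames earlier, strength 0.8).  Transfer
entropy in both directions, at the 50-frame window with a 5-frame history,
should rank the injected direction higher; the sorted-curve view shows the
per-participant asymmetry.
"""

import warnings

import numpy as np

from mmskit import TEConfig, build_te_curves, te_both_directions, gen_coupled_cohort
from mmskit.synth import CouplingSpec, SyntheticCohortConfig

warnings.filterwarnings("ignore", message="skipped")

cfg = SyntheticCohortConfig(
    n_participants=5, duration=120.0, seed=8,
    coupling=CouplingSpec("heart->face", lag=5, strength=0.8),
)
cohort = gen_coupled_cohort(cfg)
te_cfg = TEConfig(window=50, history_fraction=0.10, total_frames=None,
                  estimator="gaussian")

pairs = {}
for (pid, task, cond), st in sorted(cohort.streams.items()):
    n = min(len(st["face_mms"]), len(st["heart_frames"]))
    hf, fh = te_both_directions(st["face_mms"].values[:n],
                                st["heart_frames"].values[:n], te_cfg)
    pairs[f"{pid}/{cond}"] = {"heart->face": hf, "face->heart": fh}
    print(f"{pid} {cond:8s} TE(heart->face) = {hf.te_bits:.4f} bits, "
          f"TE(face->heart) = {fh.te_bits:.4f} bits")

hf_mean = np.mean([p["heart->face"].te_bits for p in pairs.values()])
fh_mean = np.mean([p["face->heart"].te_bits for p in pairs.values()])
print(f"\ncohort mean: heart->face {hf_mean:.4f} vs face->heart {fh_mean:.4f} "
      f"-> injected direction {'recovered' if hf_mean > fh_mean else 'NOT recovered'}")

curves = build_te_curves(pairs, sort_direction="face->heart")
print("sorted-curve differences (matched heart->face minus sorted face->heart):")
print(np.round(curves.differences, 4))
# Positive differences: knowing the heart's recent past reduces uncertainty
# about the face stream more than the reverse, matching the injected coupling.
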