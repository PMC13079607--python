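"""Facial micro-movement spikes from landmark trajectories.

Generates a 68-point landmark table whose ophthalmic (V1) region carries a
known Gamma(3, 0.1) spike signature, runs the analysis pipeline (speed
profiles -> MMS standardization -> pooled Gamma fit), and prints the
recovered parameters next to the injected truth.
"""

import numpy as np

from mmskit import (
    fit_gamma_mle,
    gen_face_landmarks,
    mms_transform,
    pool_region_mms,
    speed_profile,
)
from mmskit.regions import DEFAULT_REGIONS
from mmskit.synth import RegimeSpec

TRUE_SHAPE, TRUE_SCALE = 3.0, 0.1

table = gen_face_landmarks({"V1": RegimeSpec(TRUE_SHAPE, TRUE_SCALE)},
                           duration=60.0, fps=30, seed=0)
print(f"landmark table: {len(table)} frames x {table.shape[1]} columns")

per_landmark = {}
for lm in DEFAULT_REGIONS["V1"]:
    sp = speed_profile(table[f"x_{lm}"].to_numpy(), table[f"y_{lm}"].to_numpy(), 30)
    per_landmark[lm] = mms_transform(sp.values, fps=30)

pooled = pool_region_mms(per_landmark, "V1")
fit = fit_gamma_mle(pooled)
print(f"pooled V1 spikes: n = {len(pooled)}, "
      f"mean magnitude = {pooled.mean():.3f}")
print(f"Gamma shape: {fit.shape:.3f}  (true {TRUE_SHAPE}; "
      f"95% CI {fit.ci_shape[0]:.3f}-{fit.ci_shape[1]:.3f})")
print(f"Gamma scale (= NSR): {fit.scale:.4f}  (true {TRUE_SCALE}; "
      f"95% CI {fit.ci_scale[0]:.4f}-{fit.ci_scale[1]:.4f})")
print(f"skewness 2/sqrt(shape) = {fit.skewness:.3f}")
# The NSR is the noise-to-signal ratio of the spike process: higher values
# mean noisier, more dispersed facial micro-movements.
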