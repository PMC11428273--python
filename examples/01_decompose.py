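"""Decompose a synthetic BOLD-like signal into band-limited modes.

Builds one subject with two oscillatory components (~0.012 Hz and ~0.04 Hz)
plus AR(1) noise, runs variational mode decomposition with K=4, and shows
which modes the < 0.05 Hz rule keeps.
"""

import numpy as np

from boldcast import (SyntheticConfig, VmdConfig, generate_subject,
                      reconstruct, select_low_modes, vmd_decompose)

cfg = SyntheticConfig(n_subjects=1, m=3, T=600, seed=0)
subject = generate_subject(cfg, 0)
print(f"subject {subject.subject_id}: {subject.n_regions} regions x "
      f"{subject.n_timepoints} timepoints at TR {subject.tr_seconds} s")

x = subject.data[0]
result = vmd_decompose(x, VmdConfig(K=4))
hz = result.center_freqs_hz(cfg.tr_seconds)
print(f"converged after {result.n_iter} sweeps")
for k, f in enumerate(hz):
    print(f"  mode {k + 1}: center frequency {f:.4f} Hz")

kept = select_low_modes(result, cfg.tr_seconds, f_max_hz=0.05)
print(f"modes below 0.05 Hz (kept for forecasting): {[k + 1 for k in kept]}")

rec = reconstruct(result)
mid = slice(60, 540)
err = np.linalg.norm(rec[mid] - x[mid]) / np.linalg.norm(x[mid])
print(f"relative L2 reconstruction error (central 80%): {err:.4f}")
# The two lowest modes sit near the generating bands (0.008-0.016 and
# 0.03-0.05 Hz); the higher modes absorb the AR(1) noise floor.
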