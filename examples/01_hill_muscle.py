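"""Isolated Hill muscle–tendon unit on a test rig.

Holds the soleus at a fixed total length under a stimulation step
(isometric contraction), then releases it against a constant load
(quick release).  Prints the steady isometric force — which should
approach F_max when the tendon can carry it — and the shortening
velocity the force–velocity relation dictates under the load.
"""

import numpy as np

from neurogait.muscle import DEFAULT_MUSCLES
from neurogait.synthetic import single_muscle_rig

sol = DEFAULT_MUSCLES[3]
l_iso = sol.l_opt + sol.l_slack * (1 + sol.eps_ref)

iso = single_muscle_rig(sol, "isometric", duration=1.0, l_total=l_iso)
print(f"SOL isometric: steady force {iso['force'][-1]:.0f} N "
      f"(F_max = {sol.f_max:.0f} N), activation {iso['activation'][-1]:.3f}")

qr = single_muscle_rig(sol, "quick_release", duration=0.6, load=0.25)
n = len(qr["t"])
v_late = np.mean(qr["v_ce"][int(0.8 * n):]) / sol.l_opt
print(f"SOL quick release vs 25% F_max load: CE shortening at "
      f"{v_late:.2f} l_opt/s (negative = shortening, cap {-sol.v_max} l_opt/s)")
print("The lighter the load, the faster the shortening — the classic "
      "Hill trade-off.")
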