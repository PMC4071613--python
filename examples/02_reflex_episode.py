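"""One feedback-driven walking episode.

Runs the reflex controller with the shipped reference parameters (the
result of the in-repo scaled-down optimization; hand-set defaults if the
file is absent) on flat ground for up to 10 s, then prints what the gait
did: distance, speed, footfall events, and whether the model fell.
"""

import json
import os

import numpy as np

from neurogait.engine import EpisodeConfig, run_episode
from neurogait.optimize import controller_from_params, default_parameter_vector

ref = os.path.join(os.path.dirname(__file__), "..", "src", "neurogait",
                   "_reference", "reference_params.json")
if os.path.exists(ref):
    with open(ref) as fh:
        params = np.asarray(json.load(fh)["params"])
    print("using the shipped reference parameter vector")
else:
    params = default_parameter_vector()
    print("reference vector not found; using hand-set defaults")

log = run_episode(EpisodeConfig(duration=10.0),
                  controller=controller_from_params(params))
duration = log.times[-1] - log.times[0]
print(f"simulated {duration:.2f} s, covered {log.distance:.2f} m "
      f"({log.distance / max(duration, 1e-9):.2f} m/s), fell={log.fell}")
print(f"left touchdowns at {np.round(log.touchdowns[0], 2)} s")
print(f"left takeoffs   at {np.round(log.takeoffs[0], 2)} s")
print("Steps come from nothing but delayed reflex loops: no trajectory "
      "is prescribed anywhere.")
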