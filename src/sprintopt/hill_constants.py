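"""Characteristic-curve coefficient sets for the Hill-type muscle model.

Version-tagged so alternative parameterizations can be swapped in from
configuration. The default set follows the widely used exponential tendon /
Gaussian-sum active force-length / logarithmic force-velocity family for
implicit tendon-force-state muscle dynamics.
"""

VERSION = "degroote-2016-v1"

TENDON = {"c1": 0.200, "c2": 0.995, "c3": 0.250, "kT": 35.0}

# rows: (b1, b2, b3, b4); f_act(l) = sum b1*exp(-0.5*(l-b2)^2/(b3+b4*l)^2)
ACTIVE_FL = [
    (0.815, 1.055, 0.162, 0.0633),
    (0.433, 0.717, -0.0299, 0.200),
    (0.100, 1.000, 0.354, 0.000),
]

# f_v(v) = d1*log(d2*v + d3 + sqrt((d2*v + d3)^2 + 1)) + d4
FORCE_VELOCITY = {"d1": -0.318, "d2": -8.149, "d3": -0.374, "d4": 0.886}

# f_pe(l) = (exp(kpe*(l - 1)/e0) - 1)/(exp(kpe) - 1)
PASSIVE_FL = {"kpe": 4.0, "e0": 0.6}
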