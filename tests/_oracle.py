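"""Independent reference implementations used only by the tests.

``hgf_reference`` is a literal, scalar-by-scalar transcription of the
one-step belief-update equations, kept deliberately separate from the
package's filter so the two can be compared as independent routes.
"""

import math


def hgf_reference(u_seq, params, variant="standard"):
    """Transcribe the update equations trial by trial; returns list of dicts."""
    ka2 = params["kappa2"]
    om2 = params["omega2"]
    th = params["theta"]
    mu2 = params["mu2_0"]
    s2 = params["sigma2_0"]
    mu3 = params["mu3_0"]
    s3 = params["sigma3_0"]
    m3 = params.get("m3", 0.0)
    ph3 = params.get("phi3", 0.0)
    out = []
    for u in u_seq:
        muhat2 = mu2
        if variant == "mean_reverting":
            muhat3 = mu3 + ph3 * (m3 - mu3)
        else:
            muhat3 = mu3
        muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
        v2 = math.exp(ka2 * mu3 + om2)
        delta1 = u - muhat1
        pihat2 = 1.0 / (s2 + v2)
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        mu2_new = muhat2 + delta1 / pi2
        s2_new = 1.0 / pi2
        pihat3 = 1.0 / (s3 + th)
        w2 = v2 * pihat2
        delta2 = (s2_new + (mu2_new - muhat2) ** 2) * pihat2 - 1.0
        pi3 = pihat3 + 0.5 * ka2 * ka2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        mu3_new = muhat3 + 0.5 * ka2 * (w2 / pi3) * delta2
        out.append(dict(muhat1=muhat1, pihat1=pihat1, muhat2=muhat2,
                        pihat2=pihat2, pi2=pi2, mu2=mu2_new, sigma2=s2_new,
                        muhat3=muhat3, pihat3=pihat3, pi3=pi3, mu3=mu3_new,
                        sigma3=1.0 / pi3, delta1=delta1, delta2=delta2,
                        v2=v2, w2=w2))
        mu2, s2, mu3, s3 = mu2_new, s2_new, mu3_new, 1.0 / pi3
    return out
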