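"""Published reference estimates bundled for offline cross-checks.

The motivating study — saliva co-methylation modules mediating the link
between childhood family emotional health and fronto-limbic brain volumes
in 98 young adults — reports bootstrap mediation decompositions for eleven
module-eigengene / region pairs. Its individual-level data are access
restricted, so those printed point estimates and 95% percentile CIs are
bundled here as a reference table: they let the arithmetic identities of
linear mediation (IDE + DE = TE), the derived proportion-mediated
percentages, and the full/partial classification rule be exercised against
real published numbers without any restricted inputs.
"""

from __future__ import annotations

import pandas as pd

from .mediation import EffectEstimate, MediationResult

# (mediator, outcome) -> {effect: (estimate, ci_lower, ci_upper)}
_PUBLISHED = {
    ("Burlywood", "right_hippocampus"): {
        "IDE": (-111.2, -255.5, -17.9),
        "DE": (-254.4, -528.2, -15.8),
        "TE": (-365.7, -641.0, -151.0),
    },
    ("Darkolivegreen1", "right_hippocampus"): {
        "IDE": (-65.6, -161.3, -1.6),
        "DE": (-302.9, -553.6, -84.3),
        "TE": (-368.5, -623.6, -152.7),
    },
    ("Thistle2", "right_hippocampus"): {
        "IDE": (-64.4, -156.6, -5.6),
        "DE": (-308.5, -567.7, -79.2),
        "TE": (-372.9, -640.1, -150.5),
    },
    ("Chocolate2", "right_hippocampus"): {
        "IDE": (-82.8, -204.7, 4.9),
        "DE": (-281.5, -585.5, -24.2),
        "TE": (-364.3, -635.0, -144.5),
    },
    ("Cornflowerblue", "right_hippocampus"): {
        "IDE": (-48.3, -132.5, 14.3),
        "DE": (-321.5, -606.7, -96.5),
        "TE": (-369.8, -641.6, -151.8),
    },
    ("Aliceblue", "right_hippocampus"): {
        "IDE": (-53.4, -146.6, 6.6),
        "DE": (-317.6, -591.1, -98.8),
        "TE": (-371.1, -642.8, -162.5),
    },
    ("Yellow", "right_hippocampus"): {
        "IDE": (-39.7, -115.2, 14.7),
        "DE": (-332.2, -610.1, -113.6),
        "TE": (-371.9, -642.0, -158.7),
    },
    ("Darkgray", "left_amygdala"): {
        "IDE": (-47.4, -115.8, 8.9),
        "DE": (-135.2, -293.1, 22.0),
        "TE": (-182.5, -324.2, -38.6),
    },
    ("Darkolivegreen", "left_amygdala"): {
        "IDE": (-32.1, -89.7, 21.8),
        "DE": (-152.5, -310.8, 4.6),
        "TE": (-184.6, -323.9, -39.9),
    },
    ("Lavenderblush2", "left_amygdala"): {
        "IDE": (-30.4, -93.4, 13.7),
        "DE": (-156.4, -301.0, -3.0),
        "TE": (-186.9, -324.4, -44.0),
    },
    ("Pink4", "right_amygdala"): {
        "IDE": (-47.9, -117.4, -3.7),
        "DE": (-156.1, -338.9, 12.9),
        "TE": (-204.1, -380.1, -44.2),
    },
}

# FEH contrast behind the published decomposition: poorest observed family
# emotional health (34) versus the best (70).
PUBLISHED_TREAT, PUBLISHED_CONTROL = 34.0, 70.0
PUBLISHED_N_BOOT = 10_000


def published_mediation_results() -> list[MediationResult]:
    """The published mediation table as :class:`MediationResult` objects.

    Per-effect bootstrap p-values were not printed, so ``p`` is NaN; the
    classification rule needs only the CIs.
    """
    out = []
    for (mediator, outcome), effects in _PUBLISHED.items():
        est = {eff: EffectEstimate(b, lo, hi, float("nan"))
               for eff, (b, lo, hi) in effects.items()}
        out.append(MediationResult(
            mediator=mediator, outcome=outcome, effects=est,
            treat_value=PUBLISHED_TREAT, control_value=PUBLISHED_CONTROL,
            n_boot=PUBLISHED_N_BOOT, seed=0))
    return out


def published_mediation_table() -> pd.DataFrame:
    """Long-format view of the published mediation estimates."""
    rows = []
    for (mediator, outcome), effects in _PUBLISHED.items():
        for eff, (b, lo, hi) in effects.items():
            rows.append({"mediator": mediator, "outcome": outcome,
                         "effect": eff, "b": b,
                         "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)
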