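"""Packaged models, stimulus protocols and analytically solvable toys.

The model zoo ships the ten-variable simplified NF-kB/IkBa/A20 oscillator
(the reduction pipeline's standard starting point), the printed four-variable
continuous-input minimal model, and the six-variable pulsed-input minimal
model, all as structured text files with the published parameter values
(rates in 1/s, concentrations in uM; periods are reported in minutes by the
metrics layer).  Known transcription inconsistencies in the published closed
forms are preserved in ``*-printed`` variants so they remain testable; the
default builders use the algorithmically derived forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .model_core import ODESystemSpec, StimulusProtocol, parse_model
from .qssa import reduce_iteratively, reduce_once

__all__ = [
    "ModelZooEntry",
    "MODEL_ZOO",
    "load_fixture_text",
    "load_model",
    "build_sm",
    "build_minimal_continuous",
    "build_minimal_pulsed",
    "build_protocols",
    "continuous_protocol",
    "pulsed_protocol",
    "build_toy_tikhonov",
    "PUBLISHED_PARAMETERS",
    "PUBLISHED_REST_STATE",
]

#: canonical pulse protocol: 5-min pulses of k24 = 1 every 100 min
PULSE_PERIOD_MIN = 100.0
PULSE_WIDTH_MIN = 5.0

#: published rate constants (short name -> value; units as in the SM fixture)
PUBLISHED_PARAMETERS = {
    "k1": 3.3, "k2": 0.08, "k3": 0.08, "k4": 0.5, "k5": 1.4e-7, "k6": 0.5,
    "k7": 3e-4, "k8": 5e-4, "k9": 1.4e-7, "k10": 0.5, "k11": 4.8e-4,
    "k12": 4.5e-3, "k13": 6.7e-4, "k14": 3.35e-4, "k15": 2.6e-3,
    "k16": 5.2e-5, "k17": 0.074, "k18": 0.37, "k19": 0.1, "k20": 6e-4,
    "k21": 1.8e-3, "k22": 4e-3, "k23": 3e-3, "k": 0.065, "h": 2,
}

#: published rest state of the parent 14-variable model (uM), restricted to
#: the simplified model's variables
PUBLISHED_REST_STATE = {
    "p": 3.81e-3, "q": 1.58e-2, "r": 9.79e-3, "s": 5.44e-3, "u": 2.07e-5,
    "v": 0.08, "w": 0.0, "x": 6.46e-6, "y": 7.19e-4, "z": 0.0,
}

#: rest-state overrides used when equilibrating the NF-kB fixtures without
#: stimulus: all IKK neutral, nuclear NF-kB at k1*k3, everything else zero
SM_EQUILIBRATION_OVERRIDES = {
    "v": PUBLISHED_PARAMETERS["k2"],
    "r": PUBLISHED_PARAMETERS["k1"] * PUBLISHED_PARAMETERS["k3"],
}


def load_fixture_text(name: str) -> str:
    return resources.files("qssareduce.data").joinpath(name).read_text()


def load_model(name: str) -> ODESystemSpec:
    """Parse a packaged ``.model`` fixture by file name."""
    return parse_model(load_fixture_text(name))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_sm() -> ODESystemSpec:
    """The ten-variable simplified NF-kB/IkBa/A20 oscillator."""
    return load_model("sm.model")


def build_minimal_continuous(as_printed: bool = False) -> ODESystemSpec:
    """Four-variable minimal model for continuous stimulation (q, r, u, x).

    With ``as_printed`` the literal published closed forms (constants A and
    B(x)) are used.  By default the model is derived algorithmically from the
    ten-variable system -- z, p, y, v, s eliminated at zeroth order and w at
    first order -- which is the authoritative route given the bookkeeping
    inconsistencies in the printed constants.
    """
    if as_printed:
        return load_model("minimal_continuous_printed.model")
    system = build_sm()
    for var in ("z", "p", "y", "v", "s"):
        system = reduce_once(system, var, 0)
    return reduce_once(system, "w", 1)


def build_minimal_pulsed(fix_typo: bool = True) -> ODESystemSpec:
    """Six-variable minimal model for pulsed stimulation (q, r, s, u, v, x).

    ``fix_typo=False`` reproduces the published nuclear-IkBa equation
    verbatim (production term k13*k1*pbar); the default uses k13*k1*q as in
    the ten-variable system, whose s equation the elimination of z, p, y, w
    leaves untouched.
    """
    name = "minimal_pulsed.model" if fix_typo else "minimal_pulsed_printed.model"
    return load_model(name)


def continuous_protocol() -> StimulusProtocol:
    """Saturating dose held on for the whole simulation (k24 = 1)."""
    return StimulusProtocol("k24", default=1.0)


def pulsed_protocol(n_pulses: int = 12, period_min: float = PULSE_PERIOD_MIN,
                    width_min: float = PULSE_WIDTH_MIN,
                    amplitude: float = 1.0) -> StimulusProtocol:
    """Pulse train: ``width_min``-minute pulses every ``period_min`` minutes."""
    segs = [(i * period_min * 60.0, (i * period_min + width_min) * 60.0,
             amplitude) for i in range(n_pulses)]
    return StimulusProtocol("k24", default=0.0, segments=segs)


def build_protocols(n_pulses: int = 12) -> dict:
    return {"continuous": continuous_protocol(),
            "pulsed": pulsed_protocol(n_pulses)}


def build_toy_tikhonov(eps: float = 0.1) -> ODESystemSpec:
    """Linear fast-slow pair with a closed-form slow manifold.

        dx/dt = -z,      eps * dz/dt = x - z.

    The exact slow eigenvalue is (-1 + sqrt(1 - 4*eps)) / (2*eps)
    = -(1 + eps) + O(eps^2); the zeroth-order QSSA gives dx/dt = -x (rate
    error O(eps)) and the first-order QSSA dx/dt = -(1+eps)x (rate error
    O(eps^2)), so reduction errors of both orders are computable in closed
    form.
    """
    text = f"""
label = tikhonov-toy

[variables]
x = 1.0
z = 1.0

[parameters]
eps = {eps!r}

[equations]
x' = -z
z' = (x - z)/eps
"""
    return parse_model(text)


# ---------------------------------------------------------------------------
# Zoo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelZooEntry:
    """A packaged model with its default protocol and documented behaviour."""

    label: str
    builder: object
    protocol: str                 # "continuous" or "pulsed"
    reference_period_min: float | None
    note: str

    def load(self) -> ODESystemSpec:
        return self.builder()

    def default_protocol(self) -> StimulusProtocol:
        return build_protocols()[self.protocol]


MODEL_ZOO = {
    "SM": ModelZooEntry(
        "SM", build_sm, "continuous", 100.5,
        "ten-variable simplified model; sustained ~100-min oscillation of "
        "nuclear NF-kB under continuous stimulation"),
    "minimal-continuous": ModelZooEntry(
        "minimal-continuous", build_minimal_continuous, "continuous", 73.8,
        "four-variable end point of the continuous-input reduction "
        "(z0p0y0v0s0w1, derived closed forms)"),
    "minimal-continuous-printed": ModelZooEntry(
        "minimal-continuous-printed",
        lambda: build_minimal_continuous(as_printed=True), "continuous", 73.8,
        "four-variable minimal model with the published closed forms kept "
        "verbatim"),
    "minimal-pulsed": ModelZooEntry(
        "minimal-pulsed", build_minimal_pulsed, "pulsed", 100.0,
        "six-variable pulsed-input model (*z0p0y0w0); entrains 1:1 to "
        "100-min pulses"),
    "minimal-pulsed-printed": ModelZooEntry(
        "minimal-pulsed-printed",
        lambda: build_minimal_pulsed(fix_typo=False), "pulsed", 100.0,
        "pulsed-input model with the published s-equation term kept verbatim"),
}


def reduce_continuous_lineage(order_policy=None, sequence=None, n_steps=6,
                              **kwargs):
    """Convenience: run the standard continuous-input reduction of the SM."""
    return reduce_iteratively(build_sm(), continuous_protocol(),
                              n_steps=n_steps, order_policy=order_policy,
                              sequence=sequence, **kwargs)
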