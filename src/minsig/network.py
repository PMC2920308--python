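"""Minimal two-pathway signaling network: parameters, reaction channels, regimes.

The network couples a one-step deterministic pathway (type A: the stimulus
directly activates the downstream species X3) with a three-step fast-slow-fast
stochastic pathway (type B: stimulus -> X1* -> X2* -> X3*).  Both pathways
produce the same activated downstream species, joining them in a loop.  All
reactions are irreversible, mass-action, and catalytic in the activator:
a firing converts one inactive substrate copy to its active form and leaves
the activator count unchanged, so each species' total copy number is
conserved.

Which pathway dominates depends on the stimulus copy number ``x0``.  Two
closed-form thresholds (from a parameter sensitivity analysis of the coupled
Langevin equations) split the ``(k_b2, x0)`` plane into a deterministic
type A region, a stochastic type B region, and a mixed band in between; see
:func:`classify_regime_analytic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "NetworkParameters",
    "ReactionChannel",
    "RegimeLabel",
    "RegimeClassification",
    "ValidationReport",
    "build_reaction_channels",
    "validate_parameters",
    "classify_regime_analytic",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class NetworkParameters:
    """One model instance: stimulus, initial copy numbers, rate constants.

    Parameters
    ----------
    x0
        Stimulus copy number (dimensionless count, constant in time; the
        stimulus acts catalytically and is never consumed).  ``None`` means
        "not yet chosen" — engines refuse to run until it is set.
    x1_total, x2_total, x3_total
        Initial inactive copy numbers of the three signaling species.  All
        active counts start at zero, so these are also the conserved totals.
    k_a
        Type A rate constant (per activator copy per substrate copy per unit
        time): one-step activation of X3 by the stimulus.
    k_b1
        Type B first fast step (stimulus activates X1).  Chosen larger than
        ``k_a`` so the stochastic pathway engages first under weak stimuli.
    k_b2
        Type B slow intermediate step (X1* activates X2).  The small value of
        this constant is what makes type B signaling slow and stochastic; it
        sets the time scale of activation under weak stimuli.
    k_b3
        Type B final fast step (X2* activates X3).  Must be much larger than
        ``k_b2`` to produce all-or-none activation.
    """

    x0: float | None = None
    x1_total: int = 100
    x2_total: int = 100
    x3_total: int = 100
    k_a: float = 1e-5
    k_b1: float = 1.0
    k_b2: float = 1e-4
    k_b3: float = 1.0

    def with_x0(self, x0: float) -> "NetworkParameters":
        return replace(self, x0=x0)


class RegimeLabel(Enum):
    """Which pathway dominates the signaling response."""

    TYPE_A = "TYPE_A"
    MIXED = "MIXED"
    TYPE_B = "TYPE_B"


@dataclass(frozen=True)
class ReactionChannel:
    """One mass-action reaction channel.

    The rate law is ``rate_constant * activator_count * substrate_count``.
    ``activator`` is a state-field name (``"x0"`` for the stimulus, else an
    active count such as ``"x1a"``); ``substrate`` names the inactive pool
    consumed.  ``state_update`` holds the integer deltas applied on firing,
    including the per-channel firing counter — the activator is untouched
    (catalysis).
    """

    name: str
    activator: str
    substrate: str
    rate_constant: float
    state_update: dict[str, int] = field(hash=False)


@dataclass
class ValidationReport:
    """Findings from :func:`validate_parameters`; never raised, only returned."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass(frozen=True)
class RegimeClassification:
    """Analytic regime label plus the two thresholds that produced it.

    ``type_a_threshold`` is the stimulus above which type A dominates for all
    times; ``type_b_threshold`` the stimulus below which type B dominates from
    the beginning.  Either may be ``inf`` when ``k_a == 0`` (a pure type B
    network dominates at any stimulus).
    """

    label: RegimeLabel
    type_a_threshold: float
    type_b_threshold: float


def build_reaction_channels(params: NetworkParameters) -> list[ReactionChannel]:
    """Return the four reaction channels of the minimal network.

    Channels (in fixed order A, B1, B2, B3):

    * ``A``  — stimulus activates X3 directly (rate ``k_a * x0 * x3``),
    * ``B1`` — stimulus activates X1 (``k_b1 * x0 * x1``),
    * ``B2`` — X1* activates X2 (``k_b2 * x1a * x2``), the slow step,
    * ``B3`` — X2* activates X3 (``k_b3 * x2a * x3``).

    A and B3 both produce activated X3: the two pathways are joined in a loop.

    Raises
    ------
    ValueError
        If the parameter set has validation errors (negative values,
        non-integer totals, missing ``x0``).
    """
    report = validate_parameters(params)
    if not report.ok:
        raise ValueError("invalid parameters: " + "; ".join(report.errors))
    return [
        ReactionChannel(
            "A", "x0", "x3", params.k_a, {"x3": -1, "x3a": +1, "fireA": +1}
        ),
        ReactionChannel(
            "B1", "x0", "x1", params.k_b1, {"x1": -1, "x1a": +1, "fireB1": +1}
        ),
        ReactionChannel(
            "B2", "x1a", "x2", params.k_b2, {"x2": -1, "x2a": +1, "fireB2": +1}
        ),
        ReactionChannel(
            "B3", "x2a", "x3", params.k_b3, {"x3": -1, "x3a": +1, "fireB3": +1}
        ),
    ]


def validate_parameters(params: NetworkParameters) -> ValidationReport:
    """Check a parameter set; return errors and structural warnings.

    Errors: negative values, non-integer totals, missing stimulus.  Warnings
    flag violations of the orderings that make the network minimal — the slow
    step must be well below the final fast step (``k_b2 < k_b3 / 10``) and the
    type B entry step must outrun type A (``k_b1 > k_a``) — but do not forbid
    running: zeroed constants are the supported way to isolate one pathway.
    """
    report = ValidationReport()
    if params.x0 is None:
        report.errors.append("x0 is not set (stimulus copy number is required)")
    elif params.x0 < 0 or not math.isfinite(params.x0):
        report.errors.append(f"negative or non-finite stimulus x0 = {params.x0}")
    for name in ("x1_total", "x2_total", "x3_total"):
        total = getattr(params, name)
        if total != int(total):
            report.errors.append(f"non-integer total {name} = {total}")
        if total < 0:
            report.errors.append(f"negative total {name} = {total}")
    for name in ("k_a", "k_b1", "k_b2", "k_b3"):
        k = getattr(params, name)
        if k < 0 or not math.isfinite(k):
            report.errors.append(f"negative or non-finite rate constant {name} = {k}")
    if report.errors:
        return report
    if params.k_b2 >= params.k_b3 / 10:
        report.warnings.append(
            "slow-fast ordering violated: k_b2 = "
            f"{params.k_b2:g} is not well below k_b3 = {params.k_b3:g} "
            "(expected k_b2 << k_b3)"
        )
    if params.k_b1 <= params.k_a:
        report.warnings.append(
            "pathway-entry ordering violated: k_b1 = "
            f"{params.k_b1:g} <= k_a = {params.k_a:g} (expected k_b1 > k_a)"
        )
    return report


def classify_regime_analytic(params: NetworkParameters) -> RegimeClassification:
    """Classify the signaling regime from the two closed-form thresholds.

    Type A dominates for all times when

        ``x0 > k_b3 * sqrt(k_b2 * x1_total * x2_total) / k_a``

    and type B dominates from the beginning when

        ``x0 < k_b2 * x1_total * x2_total / (k_a * x3_total)``.

    Stimuli between the two thresholds give MIXED signaling.  With ``k_a = 0``
    both thresholds are unbounded and any stimulus is TYPE_B (the type A
    channel cannot fire).
    """
    if params.x0 is None:
        raise ValueError("x0 must be set to classify the regime")
    if params.k_a == 0.0:
        return RegimeClassification(RegimeLabel.TYPE_B, math.inf, math.inf)
    thr_a = (
        params.k_b3
        * math.sqrt(params.k_b2 * params.x1_total * params.x2_total)
        / params.k_a
    )
    if params.x3_total == 0:
        thr_b = math.inf
    else:
        thr_b = (
            params.k_b2 * params.x1_total * params.x2_total
            / (params.k_a * params.x3_total)
        )
    if params.x0 > thr_a:
        label = RegimeLabel.TYPE_A
    elif params.x0 < thr_b:
        label = RegimeLabel.TYPE_B
    else:
        label = RegimeLabel.MIXED
    return RegimeClassification(label, thr_a, thr_b)


def _base() -> NetworkParameters:
    return NetworkParameters(
        x0=None,
        x1_total=100,
        x2_total=100,
        x3_total=100,
        k_a=1e-5,
        k_b1=1.0,
        k_b2=1e-4,
        k_b3=1.0,
    )


_PRESETS = {
    # Base parameter set (stimulus left unset): totals 100/100/100,
    # k_a = 1e-5, k_b3 = 1.0; k_b1 = 1.0 (>> k_a) and k_b2 = 1e-4 (<< k_b3).
    # With these values the type A threshold is 1e5 and the type B
    # threshold is 1e3, so the stimulus presets below sit firmly in each
    # regime of the phase diagram.
    "base": _base,
    "weak": lambda: _base().with_x0(50.0),  # < 1e3: stochastic type B
    "intermediate": lambda: _base().with_x0(5e4),  # between thresholds: mixed
    "strong": lambda: _base().with_x0(2e5),  # > 1e5: deterministic type A
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> NetworkParameters:
    """Return a named parameter set (``base``, ``weak``, ``intermediate``,
    ``strong``)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(_PRESETS)}"
        ) from None
    return factory()
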