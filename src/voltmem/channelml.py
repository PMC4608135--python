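"""Reader/writer for a documented ChannelML-dialect subset.

Only kinetics that map exactly onto first-order gate models are accepted;
anything else raises :class:`ChannelMLError` naming the offending element —
unsupported rate laws are never silently approximated.

Supported per-gate encodings (units: mV, ms, mS/cm^2 — "Physiological
Units" in ChannelML terms):

* closed inf/tau form::

      <gate name="m" instances="1">
        <steady_state expr_form="sigmoid" midpoint="-17" slope="0.1565"/>
        <time_course expr_form="constant" tau="1.0"/>
      </gate>

  ``steady_state`` takes either ``slope`` (1/mV, positive = activation
  convention) or the ChannelML ``scale`` B in mV, where
  x_inf = 1/(1 + exp((V - midpoint)/B)); the two are related by
  slope = -1/B.  ``time_course`` may be ``constant`` (tau) or ``gaussian``
  (amplitude, center, width, baseline).

* alpha/beta transition rates in the three standard closed forms::

      <transition name="alpha" expr_form="sigmoid|exponential|exp_linear"
                  rate="A" scale="B" midpoint="Vhalf"/>

The ``<current_voltage_relation>`` element must carry ``cond_law="ohmic"``,
an ``ion`` attribute, and a ``<q10_settings q10_factor=".."
experimental_temp=".."/>`` child — a missing experiment temperature is an
error, since timescales cannot be recalibrated without it.
"""

from __future__ import annotations

import io
import os
import xml.etree.ElementTree as ET

from .errors import ChannelMLError
from .kinetics import (
    ChannelModel,
    ConstantTimescale,
    GaussianTimescale,
    GateSpec,
    HHRate,
    RatePair,
    SigmoidSteadyState,
)

__all__ = ["read_channelml", "write_channelml"]

_RATE_FORMS = ("sigmoid", "exponential", "exp_linear")


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find(elem, name):
    for child in elem:
        if _localname(child.tag) == name:
            yield child


def _req(elem, attr: str, context: str) -> str:
    val = elem.get(attr)
    if val is None:
        raise ChannelMLError(f"{context}: missing required attribute {attr!r}")
    return val


def _parse_steady_state(elem, gate_name: str) -> SigmoidSteadyState:
    form = _req(elem, "expr_form", f"gate {gate_name!r} steady_state")
    if form != "sigmoid":
        raise ChannelMLError(
            f"gate {gate_name!r}: unsupported steady_state expr_form {form!r}"
        )
    midpoint = float(_req(elem, "midpoint", f"gate {gate_name!r} steady_state"))
    if elem.get("slope") is not None:
        slope = float(elem.get("slope"))
    elif elem.get("scale") is not None:
        slope = -1.0 / float(elem.get("scale"))
    else:
        raise ChannelMLError(
            f"gate {gate_name!r} steady_state: need 'slope' (1/mV) or 'scale' (mV)"
        )
    return SigmoidSteadyState(v_half=midpoint, slope=slope)


def _parse_time_course(elem, gate_name: str):
    form = _req(elem, "expr_form", f"gate {gate_name!r} time_course")
    if form == "constant":
        return ConstantTimescale(float(_req(elem, "tau", f"gate {gate_name!r} time_course")))
    if form == "gaussian":
        ctx = f"gate {gate_name!r} time_course"
        return GaussianTimescale(
            amplitude_ms=float(_req(elem, "amplitude", ctx)),
            center_mv=float(_req(elem, "center", ctx)),
            width_mv=float(_req(elem, "width", ctx)),
            baseline_ms=float(_req(elem, "baseline", ctx)),
        )
    raise ChannelMLError(
        f"gate {gate_name!r}: unsupported time_course expr_form {form!r}"
    )


def _parse_transition(elem, gate_name: str) -> HHRate:
    ctx = f"gate {gate_name!r} transition {elem.get('name')!r}"
    form = _req(elem, "expr_form", ctx)
    if form not in _RATE_FORMS:
        raise ChannelMLError(f"{ctx}: unsupported kinetics expr_form {form!r}")
    return HHRate(
        form=form,
        rate=float(_req(elem, "rate", ctx)),
        scale=float(_req(elem, "scale", ctx)),
        midpoint=float(_req(elem, "midpoint", ctx)),
    )


def _parse_gate(elem) -> GateSpec:
    name = _req(elem, "name", "gate")
    exponent = int(elem.get("instances", "1"))
    steady = next(_find(elem, "steady_state"), None)
    time_course = next(_find(elem, "time_course"), None)
    transitions = {t.get("name"): t for t in _find(elem, "transition")}
    unknown = [
        _localname(c.tag) for c in elem
        if _localname(c.tag) not in ("steady_state", "time_course", "transition")
    ]
    if unknown:
        raise ChannelMLError(
            f"gate {name!r}: unsupported kinetics element(s) {unknown} "
            "(only steady_state/time_course/transition are recognized)"
        )

    rates = None
    ss = tc = None
    if transitions:
        if steady is not None or time_course is not None:
            raise ChannelMLError(
                f"gate {name!r}: mixed transition and closed-form kinetics"
            )
        if set(transitions) != {"alpha", "beta"}:
            raise ChannelMLError(
                f"gate {name!r}: transitions must be exactly alpha and beta, "
                f"got {sorted(transitions)}"
            )
        rates = RatePair(
            alpha=_parse_transition(transitions["alpha"], name),
            beta=_parse_transition(transitions["beta"], name),
        )
    else:
        if steady is None or time_course is None:
            raise ChannelMLError(
                f"gate {name!r}: need both steady_state and time_course "
                "(or an alpha/beta transition pair)"
            )
        ss = _parse_steady_state(steady, name)
        tc = _parse_time_course(time_course, name)

    role = elem.get("role")
    if role is None:
        # infer from monotonicity: decreasing steady state = inactivation
        if rates is not None:
            lo, hi = rates.steady_state(-150.0), rates.steady_state(150.0)
            role = "inactivation" if lo > hi else "activation"
        else:
            role = "inactivation" if ss.slope < 0 else "activation"
    return GateSpec(name=name, role=role, exponent=exponent,
                    steady_state_form=ss, timescale_form=tc, rates=rates)


def read_channelml(source) -> ChannelModel:
    """Parse a channel definition from a path, file object or XML string."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        tree = ET.parse(source)
        root = tree.getroot()
    elif isinstance(source, str):
        root = ET.fromstring(source)
    else:
        root = ET.parse(source).getroot()

    if _localname(root.tag) != "channelml":
        raise ChannelMLError(f"root element is {_localname(root.tag)!r}, expected 'channelml'")
    units = root.get("units")
    if units is not None and units != "Physiological Units":
        raise ChannelMLError(f"unsupported units declaration {units!r}")

    ctype = next(_find(root, "channel_type"), None)
    if ctype is None:
        raise ChannelMLError("no channel_type element")
    name = _req(ctype, "name", "channel_type")

    cvr = next(_find(ctype, "current_voltage_relation"), None)
    if cvr is None:
        raise ChannelMLError(f"channel {name!r}: no current_voltage_relation")
    if cvr.get("cond_law", "ohmic") != "ohmic":
        raise ChannelMLError(
            f"channel {name!r}: unsupported cond_law {cvr.get('cond_law')!r}"
        )
    ion = _req(cvr, "ion", f"channel {name!r}")

    q10_elem = next(_find(cvr, "q10_settings"), None)
    if q10_elem is None or q10_elem.get("experimental_temp") is None:
        raise ChannelMLError(
            f"channel {name!r}: missing q10_settings/experimental_temp "
            "(timescales cannot be recalibrated without it)"
        )
    t_exp = float(q10_elem.get("experimental_temp"))
    q10 = float(q10_elem.get("q10_factor", "3"))

    gates = tuple(_parse_gate(g) for g in _find(cvr, "gate"))
    fixed = cvr.get("fixed_reversal")
    return ChannelModel(
        id=name, ion=ion, gates=gates, experiment_temperature_c=t_exp, q10=q10,
        fixed_reversal_mv=float(fixed) if fixed is not None else None,
    )


def write_channelml(channel: ChannelModel) -> str:
    """Serialize a channel to the fixture schema; inverse of :func:`read_channelml`."""
    root = ET.Element("channelml", {"units": "Physiological Units"})
    ctype = ET.SubElement(root, "channel_type", {"name": channel.id})
    cvr_attrs = {"cond_law": "ohmic", "ion": channel.ion}
    if channel.fixed_reversal_mv is not None:
        cvr_attrs["fixed_reversal"] = repr(channel.fixed_reversal_mv)
    cvr = ET.SubElement(ctype, "current_voltage_relation", cvr_attrs)
    if channel.experiment_temperature_c is None:
        raise ChannelMLError(
            f"channel {channel.id!r}: experiment temperature required for export"
        )
    ET.SubElement(cvr, "q10_settings", {
        "q10_factor": repr(channel.q10),
        "experimental_temp": repr(channel.experiment_temperature_c),
    })
    for gate in channel.gates:
        g = ET.SubElement(cvr, "gate", {
            "name": gate.name, "instances": str(gate.exponent), "role": gate.role,
        })
        if gate.rates is not None:
            for rname, rate in (("alpha", gate.rates.alpha), ("beta", gate.rates.beta)):
                ET.SubElement(g, "transition", {
                    "name": rname, "expr_form": rate.form, "rate": repr(rate.rate),
                    "scale": repr(rate.scale), "midpoint": repr(rate.midpoint),
                })
        else:
            ss = gate.steady_state_form
            ET.SubElement(g, "steady_state", {
                "expr_form": "sigmoid", "midpoint": repr(ss.v_half),
                "slope": repr(ss.slope),
            })
            tc = gate.timescale_form
            if isinstance(tc, ConstantTimescale):
                ET.SubElement(g, "time_course",
                              {"expr_form": "constant", "tau": repr(tc.tau_ms)})
            elif isinstance(tc, GaussianTimescale):
                ET.SubElement(g, "time_course", {
                    "expr_form": "gaussian", "amplitude": repr(tc.amplitude_ms),
                    "center": repr(tc.center_mv), "width": repr(tc.width_mv),
                    "baseline": repr(tc.baseline_ms),
                })
            else:
                raise ChannelMLError(
                    f"gate {gate.name!r}: timescale form "
                    f"{type(tc).__name__} has no fixture-schema encoding"
                )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")
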